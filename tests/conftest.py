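import numpy as np
import pytest

from prsport import (
    PopulationModel,
    PopulationSpec,
    attach_populations,
    compute_prs,
    harmonize,
    load_weights,
    read_genotypes,
    scale_scores,
    write_fixture,
)


@pytest.fixture(scope="session")
def two_pop_model():
    """A small two-population study: mild EUR-like vs differentiated, shifted AFR-like."""
    return PopulationModel(
        n_snps=200,
        populations=[
            PopulationSpec("EUR", 60, 0.005, 0.0),
            PopulationSpec("AFR", 60, 0.08, 0.05),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def fixture_dir(two_pop_model, tmp_path_factory):
    """Written VCF/TSV fixture exercising all harmonization paths."""
    return write_fixture(
        two_pop_model,
        tmp_path_factory.mktemp("fixture"),
        ref_effect_fraction=0.3,
        palindromic_fraction=0.1,
        absent_fraction=0.05,
        alias_fraction=0.05,
        missing_rate=0.02,
    )


@pytest.fixture(scope="session")
def harmonized(fixture_dir):
    table = load_weights(fixture_dir.weights)
    matrix, log = read_genotypes(fixture_dir.vcf, table, alias_map=fixture_dir.alias_map)
    matrix = attach_populations(matrix, fixture_dir.pop_map)
    return table, harmonize(matrix, table, drop_palindromic=True, log=log)


@pytest.fixture(scope="session")
def scored(harmonized):
    table, hset = harmonized
    return scale_scores(compute_prs(hset, table))


def random_matrix(rng, n_samples, n_snps, missing_rate=0.0):
    """Ad-hoc in-memory genotype matrix in harmonized orientation."""
    from prsport import GenotypeMatrix

    dosages = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    if missing_rate:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    snp_ids = np.array([f"rs{j}" for j in range(n_snps)], dtype=object)
    return GenotypeMatrix(
        dosages,
        np.array([f"s{i}" for i in range(n_samples)], dtype=object),
        snp_ids,
        np.array(["A"] * n_snps, dtype=object),
        np.array(["G"] * n_snps, dtype=object),
    )
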
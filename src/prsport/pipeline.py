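"""End-to-end orchestration: load -> harmonize -> score -> stratify -> ancestry.

Every run writes the full table bundle (scores, quantile table, quintile
transfer matrices for every population pair, PCA scores, per-population
PRS-PC1 correlations, top-SNP frequency comparison, exclusion log) plus a
JSON manifest recording parameters, versions and the SNP count at every
filter step — exclusion bookkeeping is a first-class output, not a side
effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import (
    compare_effect_allele_freqs,
    genotype_pca,
    prs_pc1_correlation,
    top_effect_snps,
)
from .genotypes import attach_populations, read_genotypes
from .harmonize import harmonize
from .scoring import compute_prs, scale_scores
from .simulate import PopulationModel, PopulationSpec, write_fixture
from .stratify import assign_quintiles, cross_population_shift, summarize_population
from .weights import load_weights, orient_to_risk_increasing


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Mirrors the YAML config file key-for-key; CLI flags override file
    values on conflict.
    """

    vcf: str
    weights: str
    pop_map: str
    out_dir: str
    alias_map: str | None = None
    double_weighted: bool = False
    drop_palindromic: bool = True
    missing_policy: str = "mean_dosage"
    n_components: int = 2
    top_k: int = 20
    reference_population: str | None = None  # default: first label seen
    freq_pop_a: str | None = None  # default: reference population
    freq_pop_b: str | None = None  # default: last label seen
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_paths(self) -> None:
        for key in ("vcf", "weights", "pop_map", "alias_map"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config {key}: no such file {val!r}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns output paths plus the manifest dict."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "prsport",
        "version": __version__,
        "config": asdict(config),
        "counts": {},
    }

    table = _stage("load_weights")(load_weights)(
        config.weights, double_weighted=config.double_weighted
    )
    manifest["counts"]["model_snps"] = table.n_snps

    matrix, log = _stage("read_genotypes")(read_genotypes)(
        config.vcf, table, alias_map=config.alias_map
    )
    matrix = _stage("attach_populations")(attach_populations)(matrix, config.pop_map)
    manifest["counts"]["snps_in_vcf"] = matrix.n_snps
    manifest["counts"]["samples"] = matrix.n_samples

    hset = _stage("harmonize")(harmonize)(
        matrix, table, drop_palindromic=config.drop_palindromic, log=log
    )
    manifest["counts"]["snps_scored"] = hset.matrix.n_snps
    manifest["counts"]["excluded"] = hset.log.counts()
    if hset.matrix.n_snps + len(hset.log) != table.n_snps:
        raise PipelineError("stage 'harmonize': SNP conservation violated")

    scores = _stage("scoring")(
        lambda: scale_scores(
            compute_prs(hset, table, missing_policy=config.missing_policy)
        )
    )()

    labels = list(dict.fromkeys(scores.require_populations()))
    reference = config.reference_population or labels[0]
    pop_a = config.freq_pop_a or reference
    pop_b = config.freq_pop_b or labels[-1]

    qtable = _stage("stratify")(summarize_population)(scores)
    transfer_rows = []
    for ref in labels:
        for target in labels:
            frac = _stage("stratify")(cross_population_shift)(
                scores, qtable, ref, target
            )
            transfer_rows.append(
                {"reference": ref, "target": target,
                 **{f"q{i + 1}": frac[i] for i in range(5)}}
            )
    transfer = pd.DataFrame(transfer_rows)
    assignments = _stage("stratify")(assign_quintiles)(scores, qtable, reference)

    pca = _stage("pca")(genotype_pca)(hset.matrix, n_components=config.n_components)
    corr_rows = []
    for pop in labels:
        r, p = _stage("prs_pc1_correlation")(prs_pc1_correlation)(
            scores, hset.matrix, pop
        )
        corr_rows.append({"population": pop, "r": r, "abs_r": abs(r), "p_value": p})
    corr = pd.DataFrame(corr_rows)

    top = _stage("top_snps")(top_effect_snps)(
        table, min(config.top_k, table.n_snps)
    )
    top = orient_to_risk_increasing(top)
    freqs = _stage("freqs")(compare_effect_allele_freqs)(hset, top, pop_a, pop_b)

    paths = {
        "scores": scores.write_tsv(out / "scores.tsv"),
        "quantiles": qtable.write_tsv(out / "quantiles.tsv"),
        "quintile_assignments": out / "quintile_assignments.tsv",
        "quintile_transfer": out / "quintile_transfer.tsv",
        "pca_scores": pca.write_tsv(out / "pca_scores.tsv"),
        "prs_pc1_correlation": out / "prs_pc1_correlation.tsv",
        "top_snp_freqs": out / "top_snp_freqs.tsv",
        "exclusions": hset.log.write_tsv(out / "exclusions.tsv"),
        "manifest": out / "manifest.json",
    }
    assignments.to_csv(paths["quintile_assignments"], sep="\t", index=False)
    transfer.to_csv(
        paths["quintile_transfer"], sep="\t", index=False, float_format="%.17g"
    )
    corr.to_csv(
        paths["prs_pc1_correlation"], sep="\t", index=False, float_format="%.17g"
    )
    freqs.to_csv(paths["top_snp_freqs"], sep="\t", index=False, float_format="%.17g")

    manifest["populations"] = labels
    manifest["reference_population"] = reference
    manifest["explained_variance_fraction"] = [
        float(v) for v in pca.explained_variance_fraction
    ]
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"paths": paths, "manifest": manifest}


DEMO_POPULATIONS = [
    # two undifferentiated European-like cohorts, then four populations with
    # increasing differentiation and risk-allele frequency shift
    PopulationSpec("EST", 400, 0.003, 0.0),
    PopulationSpec("EUR", 400, 0.003, 0.0),
    PopulationSpec("AMR", 400, 0.02, 0.03),
    PopulationSpec("SAS", 400, 0.03, 0.06),
    PopulationSpec("EAS", 400, 0.05, 0.09),
    PopulationSpec("AFR", 400, 0.08, 0.12),
]


def demo_simulation(out_dir, seed: int = 0) -> dict:
    """Desk-scale recreation of the portability problem.

    Six synthetic populations (1000 SNPs, 400 samples each): two
    undifferentiated European-like cohorts whose quintile thresholds agree,
    and four with growing differentiation and directional risk-allele
    shifts, producing ordered PRS distribution shifts and a PCA that
    separates the populations.  Writes the fixture plus the full report
    bundle and returns paths, manifest and the fixture object.
    """
    out_dir = Path(out_dir)
    model = PopulationModel(
        n_snps=1000,
        populations=[
            PopulationSpec(p.label, p.n_samples, p.fst, p.shift)
            for p in DEMO_POPULATIONS
        ],
        seed=seed,
    )
    fixture = write_fixture(
        model,
        out_dir / "fixture",
        ref_effect_fraction=0.3,
        palindromic_fraction=0.1,
        absent_fraction=0.05,
        alias_fraction=0.02,
        missing_rate=0.01,
    )
    config = RunConfig(
        vcf=str(fixture.vcf),
        weights=str(fixture.weights),
        pop_map=str(fixture.pop_map),
        alias_map=str(fixture.alias_map) if fixture.alias_map else None,
        out_dir=str(out_dir / "report"),
        double_weighted=model.pi_range is not None,
        drop_palindromic=True,
        reference_population="EUR",
        freq_pop_a="EUR",
        freq_pop_b="AFR",
        seed=seed,
    )
    result = run_pipeline(config)
    result["fixture"] = fixture
    result["model"] = model
    return result
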
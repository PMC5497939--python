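"""Synthetic multi-population genotypes, weights and phenotypes.

The generator reproduces the mechanism behind cross-population PRS shifts:
per-population allele frequencies diverge from a shared ancestral
frequency under the Balding-Nichols model

    p_pop ~ Beta(p(1-F)/F, (1-p)(1-F)/F),

whose mean is the ancestral p and variance F*p*(1-p), with F playing the
role of F_ST.  An optional directional shift delta moves each SNP's
risk-allele frequency (the effect allele when w > 0, the other allele when
w < 0) by delta in one or more populations, which raises that population's
expected raw PRS by exactly 2*delta*sum(|w_i|) — the analytic handle on
the distribution shifts seen between continental populations.  Genotypes
are Hardy-Weinberg Binomial(2, p_pop) draws with SNPs in linkage
equilibrium: the shift mechanism under study is frequency-driven, not
LD-driven, so independent SNPs keep every oracle closed-form.

Everything is deterministic under the model seed; sub-streams are derived
per operation so call order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .genotypes import GenotypeMatrix
from .scoring import ScoreSet
from .weights import WeightTable, build_weight_table, write_weights

# non-palindromic allele pairs used for synthetic SNPs
_SAFE_PAIRS = [
    ("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
    ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

FREQ_CLIP = (0.01, 0.99)  # keeps every SNP polymorphic for PCA scaling


@dataclass
class PopulationSpec:
    """One synthetic population: label, size, differentiation F, shift delta."""

    label: str
    n_samples: int
    fst: float
    shift: float = 0.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"population {self.label!r}: need >= 2 samples")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"population {self.label!r}: F must lie in (0, 1)")
        if self.shift < 0:
            raise ValueError(f"population {self.label!r}: shift must be >= 0")


@dataclass
class PopulationModel:
    """Full parameterization of a synthetic multi-population study."""

    n_snps: int
    populations: list
    ancestral_freq_range: tuple = (0.1, 0.9)
    weight_mean: float = 0.0
    weight_sd: float = 0.1
    pi_range: tuple | None = None  # set for a double-weighted (T2D-style) model
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not self.populations:
            raise ValueError("at least one population is required")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("population labels must be unique")
        for p in self.populations:
            p.validate()
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must lie strictly inside (0, 1)")
        if self.pi_range is not None:
            plo, phi = self.pi_range
            if not 0.0 <= plo <= phi <= 1.0:
                raise ValueError("pi_range must lie within [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), int(stream)])


@dataclass
class TruthSet:
    """Ground truth of one simulation: frequencies, alleles and weights."""

    snp_ids: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray
    ancestral_freqs: np.ndarray
    pop_freqs: dict  # label -> effect-allele frequency per SNP
    betas: np.ndarray
    pis: np.ndarray | None
    weights: np.ndarray

    def weight_table(self, model_name: str = "synthetic") -> WeightTable:
        return build_weight_table(
            self.snp_ids, self.effect_alleles, self.other_alleles,
            self.betas, self.pis, model_name=model_name,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "effect_allele": self.effect_alleles,
                "other_allele": self.other_alleles,
                "ancestral_freq": self.ancestral_freqs,
                "beta": self.betas,
                "pi": self.pis if self.pis is not None else np.nan,
                "weight": self.weights,
            }
        )
        for label, freqs in self.pop_freqs.items():
            frame[f"freq_{label}"] = freqs
        return frame


def simulate_frequencies(model: PopulationModel) -> TruthSet:
    """Draw ancestral and per-population effect-allele frequencies + weights.

    Ancestral frequencies are uniform on ``model.ancestral_freq_range``;
    each population's frequencies are Balding-Nichols Beta draws around
    them, then populations with ``shift > 0`` have every SNP's risk-allele
    frequency moved toward the risk allele by ``shift``.  All frequencies
    are clipped to [0.01, 0.99].
    """
    rng = model.rng(1)
    m = model.n_snps
    p_anc = rng.uniform(*model.ancestral_freq_range, size=m)
    betas = rng.normal(model.weight_mean, model.weight_sd, size=m)
    if model.pi_range is not None:
        pis = rng.uniform(*model.pi_range, size=m)
        weights = betas * pis
    else:
        pis = None
        weights = betas.copy()
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), size=m)
    effect = np.array([_SAFE_PAIRS[i][0] for i in pair_idx], dtype=object)
    other = np.array([_SAFE_PAIRS[i][1] for i in pair_idx], dtype=object)

    risk_sign = np.sign(weights)  # shift direction per SNP; 0-weight SNPs unshifted
    pop_freqs: dict = {}
    for spec in model.populations:
        a = p_anc * (1.0 - spec.fst) / spec.fst
        b = (1.0 - p_anc) * (1.0 - spec.fst) / spec.fst
        p_pop = rng.beta(a, b)
        if spec.shift > 0:
            p_pop = p_pop + spec.shift * risk_sign
        pop_freqs[spec.label] = np.clip(p_pop, *FREQ_CLIP)

    snp_ids = np.array([f"rs{j + 1:06d}" for j in range(m)], dtype=object)
    return TruthSet(
        snp_ids=snp_ids,
        effect_alleles=effect,
        other_alleles=other,
        ancestral_freqs=p_anc,
        pop_freqs=pop_freqs,
        betas=betas,
        pis=pis,
        weights=weights,
    )


def simulate_genotypes(truth: TruthSet, model: PopulationModel) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, p_pop) per SNP/sample.

    Dosages count the effect allele; the matrix is constructed with
    ``alt = effect_allele`` so it is already in harmonized orientation.
    Deterministic under the model seed.
    """
    rng = model.rng(2)
    blocks, sample_ids, pops = [], [], []
    for spec in model.populations:
        p = truth.pop_freqs[spec.label]
        blocks.append(rng.binomial(2, p, size=(spec.n_samples, model.n_snps)))
        sample_ids.extend(f"{spec.label}_{i:05d}" for i in range(spec.n_samples))
        pops.extend([spec.label] * spec.n_samples)
    return GenotypeMatrix(
        np.vstack(blocks).astype(float),
        np.asarray(sample_ids, dtype=object),
        truth.snp_ids,
        truth.other_alleles,  # REF = other allele
        truth.effect_alleles,  # ALT = effect allele
        np.asarray(pops, dtype=object),
    )


def expected_prs_moments(
    truth: TruthSet, table: WeightTable, population: str
) -> tuple[float, float]:
    """Analytic raw-PRS mean and variance for one population.

    Under HWE and linkage equilibrium,
    mean = sum_i 2 w_i p_i  and  variance = sum_i 2 w_i^2 p_i (1 - p_i).
    """
    if population not in truth.pop_freqs:
        raise KeyError(f"population {population!r} not in truth set")
    freq_of = dict(zip(truth.snp_ids, truth.pop_freqs[population]))
    try:
        p = np.array([freq_of[s] for s in table.snp_ids])
    except KeyError as exc:
        raise ValueError(f"weight table SNP missing from truth: {exc}") from exc
    w = table.weights
    mean = float(np.sum(2.0 * w * p))
    var = float(np.sum(2.0 * w**2 * p * (1.0 - p)))
    return mean, var


def simulate_phenotypes(
    scores: ScoreSet, true_or: float, prevalence_target: float, seed: int
) -> np.ndarray:
    """Binary phenotype from a logistic model on the scaled PRS.

    P(case) = expit(alpha + log(true_or) * scaled_PRS), with the intercept
    alpha solved numerically so the mean case probability equals
    ``prevalence_target``.
    """
    scaled = scores.require_scaled()
    if not 0.0 < prevalence_target < 1.0:
        raise ValueError("prevalence_target must lie strictly in (0, 1)")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    slope = np.log(true_or)

    def mean_prev(alpha: float) -> float:
        return float(expit(alpha + slope * scaled).mean()) - prevalence_target

    alpha = brentq(mean_prev, -60.0, 60.0, xtol=1e-12)
    rng = np.random.default_rng(int(seed) % (2**31))
    prob = expit(alpha + slope * scaled)
    return (rng.random(len(prob)) < prob).astype(int)


@dataclass
class Fixture:
    """Paths and in-memory objects of one written synthetic fixture."""

    vcf: Path
    weights: Path
    pop_map: Path
    truth_tsv: Path
    alias_map: Path | None
    truth: TruthSet
    matrix: GenotypeMatrix  # effect-allele dosages incl. simulated missingness
    table: WeightTable
    categories: pd.DataFrame  # snp_id, category in {standard, ref_effect, palindromic, absent, aliased}


def write_fixture(
    model: PopulationModel,
    out_dir,
    ref_effect_fraction: float = 0.3,
    palindromic_fraction: float = 0.1,
    absent_fraction: float = 0.05,
    alias_fraction: float = 0.0,
    missing_rate: float = 0.0,
) -> Fixture:
    """Simulate a study and write it as VCF + TSV files.

    The VCF is constructed to exercise every harmonization path with exact,
    seed-deterministic counts (fractions are rounded to whole SNPs and the
    category sets are disjoint):

    * ``ref_effect_fraction`` of SNPs have the effect allele as VCF REF, so
      their dosages must be flipped (2 - d) downstream;
    * ``palindromic_fraction`` get A/T or C/G alleles, to be dropped by the
      strand-ambiguity filter;
    * ``absent_fraction`` are omitted from the VCF entirely (``not_in_vcf``);
    * ``alias_fraction`` appear in the VCF under an alternative ID resolved
      through the written alias map;
    * ``missing_rate`` of genotype calls are written as ``./.``.

    Reading the files back through ``genotype_io`` + ``harmonize`` recovers
    the in-memory effect-allele dosage matrix exactly (minus absent SNPs).
    """
    fracs = (ref_effect_fraction, palindromic_fraction, absent_fraction, alias_fraction)
    if any(f < 0 for f in fracs) or sum(fracs[1:3]) + fracs[0] + fracs[3] > 1.0:
        raise ValueError("category fractions must be >= 0 and sum to <= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = simulate_frequencies(model)
    m = model.n_snps
    rng = model.rng(3)
    perm = rng.permutation(m)
    n_pal = int(round(palindromic_fraction * m))
    n_abs = int(round(absent_fraction * m))
    n_ref = int(round(ref_effect_fraction * m))
    n_ali = int(round(alias_fraction * m))
    pal_idx = perm[:n_pal]
    abs_idx = perm[n_pal : n_pal + n_abs]
    ref_idx = perm[n_pal + n_abs : n_pal + n_abs + n_ref]
    ali_idx = perm[n_pal + n_abs + n_ref : n_pal + n_abs + n_ref + n_ali]

    # give palindromic SNPs strand-ambiguous alleles
    for j in pal_idx:
        eff, oth = _PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))]
        truth.effect_alleles[j] = eff
        truth.other_alleles[j] = oth

    matrix = simulate_genotypes(truth, model)
    if missing_rate > 0:
        miss = rng.random(matrix.dosages.shape) < missing_rate
        dosages = matrix.dosages.copy()
        dosages[miss] = np.nan
        matrix = GenotypeMatrix(
            dosages, matrix.sample_ids, matrix.snp_ids,
            matrix.ref, matrix.alt, matrix.populations,
        )

    category = np.full(m, "standard", dtype=object)
    category[ref_idx] = "ref_effect"
    category[pal_idx] = "palindromic"
    category[abs_idx] = "absent"
    category[ali_idx] = "aliased"
    categories = pd.DataFrame({"snp_id": truth.snp_ids, "category": category})

    table = truth.weight_table(
        model_name="synthetic_double" if model.pi_range is not None else "synthetic"
    )
    weights_path = write_weights(table, out_dir / "weights.tsv")

    vcf_path = out_dir / "genotypes.vcf"
    _write_vcf(vcf_path, matrix, truth, set(abs_idx), set(ref_idx), set(ali_idx))

    pop_map_path = out_dir / "populations.tsv"
    with open(pop_map_path, "w") as fh:
        for sid, pop in zip(matrix.sample_ids, matrix.populations):
            fh.write(f"{sid}\t{pop}\n")

    alias_path = None
    if n_ali:
        alias_path = out_dir / "aliases.tsv"
        with open(alias_path, "w") as fh:
            for j in sorted(ali_idx):
                fh.write(f"alt_{truth.snp_ids[j]}\t{truth.snp_ids[j]}\n")

    truth_path = out_dir / "truth.tsv"
    truth_frame = truth.to_frame()
    truth_frame["category"] = category
    truth_frame.to_csv(truth_path, sep="\t", index=False, float_format="%.17g")

    return Fixture(
        vcf=vcf_path,
        weights=weights_path,
        pop_map=pop_map_path,
        truth_tsv=truth_path,
        alias_map=alias_path,
        truth=truth,
        matrix=matrix,
        table=table,
        categories=categories,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(path, matrix, truth, absent, ref_effect, aliased) -> None:
    n_samples = matrix.n_samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={matrix.n_snps + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j in range(matrix.n_snps):
            if j in absent:
                continue
            sid = truth.snp_ids[j]
            vcf_id = f"alt_{sid}" if j in aliased else sid
            eff, oth = truth.effect_alleles[j], truth.other_alleles[j]
            if j in ref_effect:
                ref, alt = eff, oth  # ALT dosage = 2 - effect dosage
                convert = lambda d: 2.0 - d
            else:
                ref, alt = oth, eff
                convert = lambda d: d
            gts = []
            for i in range(n_samples):
                d = matrix.dosages[i, j]
                gts.append("./." if np.isnan(d) else _GT_STRINGS[int(convert(d))])
            fh.write(
                f"1\t{j + 1}\t{vcf_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
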
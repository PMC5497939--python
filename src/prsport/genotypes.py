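"""Genotype extraction from multi-sample VCF.

Model SNPs are matched by ID (or via a user-supplied alias map), never by
position; dosages at this stage count the VCF ALT allele — orientation to
the model's effect allele is the harmonization step's job.  Absent and
multiallelic records are excluded and logged, mirroring the role of a
missing-SNP supplementary list.  No imputation is ever performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .weights import WeightTable

EXCLUSION_REASONS = ("not_in_vcf", "palindromic", "allele_mismatch", "multiallelic")


@dataclass
class ExclusionLog:
    """Per-SNP exclusion records; each SNP appears at most once."""

    snp_ids: list = field(default_factory=list)
    reasons: list = field(default_factory=list)

    def add(self, snp_id: str, reason: str) -> None:
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        if snp_id in self.snp_ids:
            raise ValueError(f"SNP {snp_id!r} already excluded")
        self.snp_ids.append(snp_id)
        self.reasons.append(reason)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def counts(self) -> dict:
        out = {r: 0 for r in EXCLUSION_REASONS}
        for r in self.reasons:
            out[r] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "reason": self.reasons})

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with optional population labels.

    ``dosages`` is float64 with values in {0, 1, 2} and NaN for missing
    genotypes.  ``ref``/``alt`` carry the VCF alleles per SNP; after
    harmonization ``alt`` is the allele the dosages count.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if not (len(self.snp_ids) == len(self.ref) == len(self.alt) == m):
            raise ValueError("snp_ids/ref/alt length does not match dosage columns")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations length does not match samples")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def population_labels(self) -> list:
        if self.populations is None:
            raise ValueError("no population labels attached")
        seen: list = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def samples_in(self, population: str) -> np.ndarray:
        """Boolean mask of samples belonging to ``population``."""
        if self.populations is None:
            raise ValueError("no population labels attached")
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"population {population!r} has no samples")
        return mask

    def subset_snps(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeMatrix(
            self.dosages[:, keep_mask],
            self.sample_ids,
            self.snp_ids[keep_mask],
            self.ref[keep_mask],
            self.alt[keep_mask],
            self.populations,
        )

    def subset_samples(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeMatrix(
            self.dosages[keep_mask],
            self.sample_ids[keep_mask],
            self.snp_ids,
            self.ref,
            self.alt,
            None if self.populations is None else self.populations[keep_mask],
        )


def _load_two_column_map(path_or_map, what: str) -> dict:
    if isinstance(path_or_map, dict):
        return dict(path_or_map)
    frame = pd.read_csv(path_or_map, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{what} file must have two tab-separated columns")
    out: dict = {}
    for key, val in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        if key in out and out[key] != val:
            raise ValueError(f"{what}: conflicting entries for {key!r}")
        out[key] = val
    if not out:
        raise ValueError(f"{what} file is empty")
    return out


def read_genotypes(
    vcf_path, table: WeightTable, alias_map=None
) -> tuple[GenotypeMatrix, ExclusionLog]:
    """Extract ALT-allele dosages for a model's SNPs from a VCF.

    Parameters
    ----------
    vcf_path : path
        VCF 4.x, plain or bgzipped, with GT genotypes.
    table : WeightTable
        Defines the wanted SNP set and the column order of the result.
    alias_map : path or dict, optional
        Maps alternative VCF IDs to model SNP IDs (a static stand-in for
        live dbSNP alias resolution).

    Returns the dosage matrix (columns = model SNPs found, in weight-table
    order) and an :class:`ExclusionLog` with one ``not_in_vcf`` entry per
    model SNP absent from the VCF and ``multiallelic`` entries for sites
    with more than one ALT allele.
    """
    from cyvcf2 import VCF

    aliases = {} if alias_map is None else _load_two_column_map(alias_map, "alias map")
    model_ids = list(table.snp_ids)
    wanted = set(model_ids)

    vcf = VCF(str(vcf_path))
    sample_ids = np.asarray(vcf.samples, dtype=object)
    found: dict = {}
    excluded_multi: set = set()
    for variant in vcf:
        vid = variant.ID
        if vid in wanted:
            mid = vid
        elif vid in aliases and aliases[vid] in wanted:
            mid = aliases[vid]
        else:
            continue
        if mid in found or mid in excluded_multi:
            warnings.warn(f"duplicate VCF record for SNP {mid!r}; keeping the first")
            continue
        if len(variant.ALT) != 1:
            excluded_multi.add(mid)
            continue
        geno = np.asarray([g[:2] for g in variant.genotypes], dtype=float)
        dose = geno.sum(axis=1)
        dose[(geno < 0).any(axis=1)] = np.nan
        found[mid] = (dose, variant.REF, variant.ALT[0])
    vcf.close()

    log = ExclusionLog()
    keep_ids, cols, refs, alts = [], [], [], []
    for mid in model_ids:
        if mid in found:
            dose, ref, alt = found[mid]
            keep_ids.append(mid)
            cols.append(dose)
            refs.append(ref)
            alts.append(alt)
        elif mid in excluded_multi:
            log.add(mid, "multiallelic")
        else:
            log.add(mid, "not_in_vcf")

    dosages = (
        np.column_stack(cols) if cols else np.empty((len(sample_ids), 0), dtype=float)
    )
    matrix = GenotypeMatrix(dosages, sample_ids, keep_ids, refs, alts)
    return matrix, log


def attach_populations(matrix: GenotypeMatrix, map_file) -> GenotypeMatrix:
    """Attach a population label to every sample from a two-column map.

    ``map_file`` may be a TSV path (sample <TAB> population, no header) or a
    dict.  Every sample in the matrix must be mapped; an unmapped sample is
    a hard error naming it, as is a duplicate map entry with conflicting
    labels.
    """
    pop_map = _load_two_column_map(map_file, "population map")
    labels = []
    for sid in matrix.sample_ids:
        if sid not in pop_map:
            raise ValueError(f"sample {sid!r} missing from population map")
        labels.append(pop_map[sid])
    return GenotypeMatrix(
        matrix.dosages,
        matrix.sample_ids,
        matrix.snp_ids,
        matrix.ref,
        matrix.alt,
        np.asarray(labels, dtype=object),
    )
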
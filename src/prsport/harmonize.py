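"""Allele harmonization between a weight table and VCF genotypes.

Strand-ambiguous (palindromic, A/T or C/G) SNPs are dropped outright when
the filter is on — their orientation cannot be resolved between datasets.
For the rest, dosages are oriented so they count the model's effect allele:
kept as-is when the effect allele is the VCF ALT, flipped to ``2 - dosage``
when it is the REF.  Any other allele configuration is excluded as an
``allele_mismatch``; no strand flipping is attempted for non-palindromic
mismatches, which keeps the procedure deterministic and guess-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import ExclusionLog, GenotypeMatrix
from .weights import VALID_BASES, WeightTable

_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is its own reverse complement (A/T or C/G)."""
    if a1 not in VALID_BASES or a2 not in VALID_BASES:
        raise ValueError(f"invalid base in allele pair ({a1!r}, {a2!r})")
    if a1 == a2:
        raise ValueError("allele pair must contain two distinct bases")
    return frozenset((a1, a2)) in _PALINDROMIC_PAIRS


@dataclass
class HarmonizedSet:
    """Harmonized dosage matrix plus the cumulative exclusion log.

    In ``matrix``, dosages count the effect allele and ``alt``/``ref`` are
    rewritten to the effect/other allele of each retained SNP.
    """

    matrix: GenotypeMatrix
    log: ExclusionLog


def harmonize(
    matrix: GenotypeMatrix,
    table: WeightTable,
    drop_palindromic: bool = True,
    log: ExclusionLog | None = None,
) -> HarmonizedSet:
    """Orient dosage columns to the weight table's effect alleles.

    Parameters
    ----------
    matrix : GenotypeMatrix
        ALT-dosage matrix whose columns are a subset of ``table``'s SNPs.
    table : WeightTable
        Supplies effect/other alleles per SNP.
    drop_palindromic : bool
        Drop A/T and C/G SNPs (the CHD-style filter); double-weighted T2D
        pipelines may leave it off.
    log : ExclusionLog, optional
        Extended in place with ``palindromic`` / ``allele_mismatch``
        entries; a fresh log is created when omitted.

    Missing dosages pass through untouched (their policy belongs to
    scoring).  Flipping a column twice restores it, and retained + dropped
    always equals the input column count.
    """
    if log is None:
        log = ExclusionLog()
    lookup = table.frame.set_index("snp_id")
    missing = [s for s in matrix.snp_ids if s not in lookup.index]
    if missing:
        raise ValueError(f"matrix column {missing[0]!r} not in weight table")

    keep = np.zeros(matrix.n_snps, dtype=bool)
    dosages = matrix.dosages.copy()
    new_ref = matrix.ref.copy()
    new_alt = matrix.alt.copy()
    for j, sid in enumerate(matrix.snp_ids):
        effect = str(lookup.at[sid, "effect_allele"])
        other = str(lookup.at[sid, "other_allele"])
        ref, alt = str(matrix.ref[j]), str(matrix.alt[j])
        if drop_palindromic and is_palindromic(effect, other):
            log.add(sid, "palindromic")
            continue
        if effect == alt and other == ref:
            pass  # already counts the effect allele
        elif effect == ref and other == alt:
            dosages[:, j] = 2.0 - dosages[:, j]  # NaN stays NaN
        else:
            log.add(sid, "allele_mismatch")
            continue
        new_ref[j] = other
        new_alt[j] = effect
        keep[j] = True

    harmonized = GenotypeMatrix(
        dosages[:, keep],
        matrix.sample_ids,
        matrix.snp_ids[keep],
        new_ref[keep],
        new_alt[keep],
        matrix.populations,
    )
    return HarmonizedSet(harmonized, log)
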
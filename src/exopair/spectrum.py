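"""Substitution-class spectrum and flanking-sequence context.

Single-base substitutions are collapsed over strand into the six canonical
base-pair classes (C:G>T:A, C:G>A:T, C:G>G:C, T:A>C:G, T:A>A:T, T:A>G:C);
C:G>T:A and T:A>C:G are the transitions, the other four transversions. The
module tabulates per-patient class counts and fractions for the
tumor-specific and non-tumor-specific variant sets, compares a class
between the two sets by rank-sum test on per-patient fractions, and builds
position x base probability matrices of the sequence flanking variant loci
(sequence-logo input).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import ranksum_test
from .models import BASES, COMPLEMENT, ValidationError, VariantSite

SUBSTITUTION_CLASSES = (
    "C:G>T:A", "C:G>A:T", "C:G>G:C", "T:A>C:G", "T:A>A:T", "T:A>G:C",
)

# pyrimidine-reference representative of each class
_PYR_PAIR_TO_CLASS = {
    ("C", "T"): "C:G>T:A",
    ("C", "A"): "C:G>A:T",
    ("C", "G"): "C:G>G:C",
    ("T", "C"): "T:A>C:G",
    ("T", "A"): "T:A>A:T",
    ("T", "G"): "T:A>G:C",
}


def classify_substitution(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution."""
    if ref not in BASES or alt not in BASES:
        raise ValidationError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError("ref and alt bases are identical")
    if ref in ("A", "G"):  # collapse purine reference onto pyrimidine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return _PYR_PAIR_TO_CLASS[(ref, alt)]


@dataclass
class SpectrumTable:
    """Per-patient and pooled substitution-class counts per specificity group.

    ``counts[group]`` is a patients x classes integer frame; fractions are
    NaN for patients with zero variants in that group (flagged in
    ``empty_rows``).
    """

    counts: dict
    fractions: dict
    pooled_counts: pd.DataFrame
    pooled_fractions: pd.DataFrame
    empty_rows: dict

    def groups(self):
        return list(self.counts)


def spectrum_table(patients, groups=("tumor", "non_tumor")) -> SpectrumTable:
    """Tabulate class counts/fractions per patient for each specificity group."""
    pids = [p.patient_id for p in patients]
    counts, fractions, empty = {}, {}, {}
    pooled = {}
    for group in groups:
        mat = pd.DataFrame(
            0, index=pids, columns=list(SUBSTITUTION_CLASSES), dtype=int
        )
        for p in patients:
            for v in p.variants:
                if v.specificity == group:
                    mat.loc[p.patient_id, classify_substitution(v.ref, v.alt)] += 1
        totals = mat.sum(axis=1)
        frac = mat.div(totals.where(totals > 0), axis=0)
        counts[group] = mat
        fractions[group] = frac
        empty[group] = list(totals.index[totals == 0])
        pooled[group] = mat.sum(axis=0)
    pooled_counts = pd.DataFrame(pooled).T
    pooled_tot = pooled_counts.sum(axis=1)
    pooled_fractions = pooled_counts.div(pooled_tot.where(pooled_tot > 0), axis=0)
    return SpectrumTable(counts, fractions, pooled_counts, pooled_fractions, empty)


@dataclass
class ClassComparison:
    substitution_class: str
    statistic: Optional[float]
    pvalue: Optional[float]
    skipped: bool = False
    reason: Optional[str] = None


def compare_class_groups(
    table: SpectrumTable,
    substitution_class: str,
    group_a: str = "tumor",
    group_b: str = "non_tumor",
) -> ClassComparison:
    """Rank-sum comparison of per-patient class fractions between two groups.

    Patients with no variants in a group carry no fraction and are dropped
    from that group's sample; a group left with all-zero totals is flagged
    and the test skipped.
    """
    if substitution_class not in SUBSTITUTION_CLASSES:
        raise ValidationError(f"unknown substitution class {substitution_class!r}")
    a = table.fractions[group_a][substitution_class].dropna().to_numpy()
    b = table.fractions[group_b][substitution_class].dropna().to_numpy()
    if a.size < 2 or b.size < 2:
        return ClassComparison(
            substitution_class, None, None, skipped=True,
            reason="fewer than two patients with variants in a group",
        )
    stat, p = ranksum_test(a, b)
    return ClassComparison(substitution_class, stat, p)


def flanking_matrix(
    variants: Sequence[VariantSite],
    genome,
    k: int,
    collapse_pyrimidine: bool = False,
):
    """Empirical base probabilities at offsets -k..+k around variant loci.

    Each column (offset) sums to 1 over A/C/G/T; the offset-0 column is the
    reference-base distribution of the variants themselves. Loci within k of
    a contig end are skipped and counted. When ``collapse_pyrimidine`` is
    set, loci whose reference base is a purine contribute the reverse
    complement of their context.

    Returns ``(matrix, n_skipped)``.
    """
    if genome.sequence is None:
        raise ValidationError("flanking analysis requires a genome with sequence")
    if k < 0:
        raise ValidationError("k must be >= 0")
    offsets = list(range(-k, k + 1))
    counts = pd.DataFrame(0, index=list(BASES), columns=offsets, dtype=float)
    skipped = 0
    for v in variants:
        seq = genome.sequence.get(v.chrom)
        if seq is None:
            raise ValidationError(f"no sequence for chromosome {v.chrom!r}")
        i = v.pos - 1
        if i - k < 0 or i + k >= len(seq):
            skipped += 1
            continue
        window = seq[i - k : i + k + 1]
        if collapse_pyrimidine and v.ref in ("A", "G"):
            window = "".join(COMPLEMENT[b] for b in reversed(window))
        for off, base in zip(offsets, window):
            counts.loc[base, off] += 1
    totals = counts.sum(axis=0)
    matrix = counts.div(totals.where(totals > 0), axis=1)
    return matrix, skipped
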
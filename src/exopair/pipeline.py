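"""Paired-exome variant filtering cascade and specificity calling.

Stages, in order: site-quality gate (MQ0/DP/QUAL/QD), exonic location with a
ten-read floor, Fisher exact tumor-vs-non-tumor specificity call, removal of
shared (germline-like) sites with >= 5 alt reads in both tissues, masking of
hypermutable 1,000-bp windows holding more than ten variants, and removal of
known-SNP positions. Surviving sites carry an audit trail of the stages they
passed. Every filter is contractive (output is a subset of its input) and
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from ._stats import fisher_two_sided
from .models import (
    GenomeModel,
    GenomeModelError,
    PatientPair,
    PipelineThresholds,
    ValidationError,
    VariantSite,
    sites_by_position,
)
from .spectrum import classify_substitution

STAGES = ("input", "quality", "exonic_depth", "fisher", "germline", "window", "snp")


def apply_quality_filter(sites: Sequence[VariantSite], t: PipelineThresholds) -> list:
    """Drop sites failing any caller-quality gate.

    A site is removed when (MQ0 >= mq0_max AND MQ0/DP > ratio max), or
    DP < dp_min, or QUAL < qual_min, or QD < qd_min. Order is preserved.
    """
    kept = []
    for s in sites:
        s.validate()
        ratio = s.mq0 / s.dp if s.dp > 0 else float("inf") if s.mq0 > 0 else 0.0
        hard_to_validate = s.mq0 >= t.mq0_max and ratio > t.mq0_dp_ratio_max
        if hard_to_validate or s.dp < t.dp_min or s.qual < t.qual_min or s.qd < t.qd_min:
            continue
        if "quality" not in s.audit:
            s.audit.append("quality")
        kept.append(s)
    return kept


def filter_exonic_depth(
    sites: Sequence[VariantSite], genome: GenomeModel, t: PipelineThresholds
) -> list:
    """Keep CDS sites covered by >= exonic_min_reads in at least one tissue.

    Annotates the gene id of surviving sites. Raises
    :class:`GenomeModelError` for chromosomes absent from the model.
    """
    kept = []
    for s in sites:
        txs = genome.transcripts_at(s.chrom, s.pos)  # raises on unknown chrom
        if not txs:
            continue
        if max(s.tumor_depth, s.normal_depth) < t.exonic_min_reads:
            continue
        s.gene = txs[0].gene
        if "exonic_depth" not in s.audit:
            s.audit.append("exonic_depth")
        kept.append(s)
    return kept


def fisher_specificity(site: VariantSite, t: PipelineThresholds) -> tuple:
    """Two-sided Fisher exact specificity call on the alt/ref read table.

    The 2x2 table is [[tumor_alt, tumor_ref], [normal_alt, normal_ref]].
    Returns ``(p_value, label)`` with label ``tumor`` when P < alpha and the
    odds ratio exceeds 1, ``non_tumor`` when P < alpha and it is below 1,
    ``unclassified`` otherwise. The odds ratio used for the direction call is
    Haldane-corrected only when a cell is zero; the P-value never is.
    """
    p, odds = fisher_two_sided(
        [[site.tumor_alt, site.tumor_ref], [site.normal_alt, site.normal_ref]]
    )
    if p < t.fisher_alpha and odds > 1.0:
        label = "tumor"
    elif p < t.fisher_alpha and odds < 1.0:
        label = "non_tumor"
    else:
        label = "unclassified"
    site.fisher_p = p
    site.specificity = label
    return p, label


def classify_specificity(sites: Sequence[VariantSite], t: PipelineThresholds) -> list:
    """Label every site and keep those called tumor- or non-tumor-specific."""
    kept = []
    for s in sites:
        if s.specificity in ("tumor", "non_tumor") and s.fisher_p is not None:
            pass  # idempotent re-entry
        else:
            fisher_specificity(s, t)
        if s.specificity in ("tumor", "non_tumor"):
            if "fisher" not in s.audit:
                s.audit.append("fisher")
            kept.append(s)
    return kept


def filter_shared_germline(sites: Sequence[VariantSite], t: PipelineThresholds) -> list:
    """Remove sites with >= germline_min_alt supporting reads in both tissues.

    Removed sites are relabelled ``shared`` (constitutional or non-specific
    calls) so they leave both specificity sets.
    """
    kept = []
    for s in sites:
        if s.tumor_alt >= t.germline_min_alt and s.normal_alt >= t.germline_min_alt:
            s.specificity = "shared"
            continue
        if "germline" not in s.audit:
            s.audit.append("germline")
        kept.append(s)
    return kept


def mask_hypermutable(sites: Sequence[VariantSite], t: PipelineThresholds):
    """Remove all variants inside any window_bp window holding more than
    window_max_variants of them (likely local mis-alignment artifacts).

    Windows slide per chromosome over the pooled (both specificity classes)
    variants of one patient. Returns ``(kept, removed)``; input order is
    preserved in ``kept``.
    """
    by_chrom = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    removed_keys = set()
    for chrom, group in by_chrom.items():
        pos = np.array(sorted(s.pos for s in group))
        n = len(pos)
        j = 0
        flag = np.zeros(n, dtype=bool)
        for i in range(n):
            while j < n and pos[j] <= pos[i] + t.window_bp - 1:
                j += 1
            if j - i > t.window_max_variants:
                flag[i:j] = True
        bad = set(pos[flag].tolist())
        for s in group:
            if s.pos in bad:
                removed_keys.add((s.chrom, s.pos))
    kept, removed = [], []
    for s in sites:
        if (s.chrom, s.pos) in removed_keys:
            removed.append(s)
        else:
            if "window" not in s.audit:
                s.audit.append("window")
            kept.append(s)
    return kept, removed


def remove_known_snps(sites: Sequence[VariantSite], snp_positions: Iterable) -> list:
    """Drop sites whose (chrom, 1-based pos) is in the known-SNP list."""
    snp = set(snp_positions)
    kept = []
    for s in sites:
        if (s.chrom, s.pos) in snp:
            s.in_snp_db = True
            continue
        if "snp" not in s.audit:
            s.audit.append("snp")
        kept.append(s)
    return kept


def annotate_consequence(site: VariantSite, genome: GenomeModel) -> str:
    """Coding consequence of a single-base substitution.

    Translates the reference and alternate codons with the standard genetic
    code, reverse-complementing for minus-strand transcripts. Stop gain and
    stop loss both map to the single ``stop`` class.
    """
    txs = genome.transcripts_at(site.chrom, site.pos)
    if not txs:
        site.consequence = "noncoding"
        return "noncoding"
    tx = txs[0]
    if tx.cds_length % 3 != 0:
        raise GenomeModelError(f"CDS of {tx.gene} not divisible by 3")
    if tx.seq is None:
        raise GenomeModelError(f"no CDS sequence for {tx.gene}")
    offset = site.pos - 1 - tx.cds_start
    if tx.seq[offset] != site.ref:
        raise GenomeModelError(
            f"reference mismatch at {site.chrom}:{site.pos} in {tx.gene}"
        )
    alt_seq = tx.seq[:offset] + site.alt + tx.seq[offset + 1 :]
    if tx.strand == "+":
        codon_idx = offset // 3
        ref_codon = tx.seq[3 * codon_idx : 3 * codon_idx + 3]
        alt_codon = alt_seq[3 * codon_idx : 3 * codon_idx + 3]
    else:
        ref_rc = str(Seq(tx.seq).reverse_complement())
        alt_rc = str(Seq(alt_seq).reverse_complement())
        tpos = tx.cds_length - 1 - offset
        codon_idx = tpos // 3
        ref_codon = ref_rc[3 * codon_idx : 3 * codon_idx + 3]
        alt_codon = alt_rc[3 * codon_idx : 3 * codon_idx + 3]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        label = "synonymous"
    elif "*" in (ref_aa, alt_aa):
        label = "stop"
    else:
        label = "nonsynonymous"
    site.consequence = label
    return label


@dataclass
class PipelineResult:
    tumor_specific: dict  # patient_id -> list[VariantSite]
    non_tumor_specific: dict
    stage_counts: pd.DataFrame  # stages x patients
    recurrence: pd.DataFrame  # genes tumor-mutated in >= 2 patients
    kataegis: pd.DataFrame  # C>T diagnostic on masked windows

    def all_tumor(self) -> list:
        return [s for sites in self.tumor_specific.values() for s in sites]

    def all_non_tumor(self) -> list:
        return [s for sites in self.non_tumor_specific.values() for s in sites]


def _kataegis_row(pid, masked, background):
    """Binomial test of the C:G>T:A fraction inside masked windows against
    the patient-wide fraction; masked clusters from mis-alignment should not
    show the C>T excess characteristic of kataegis."""
    n_masked = len(masked)
    if n_masked == 0 or not background:
        return {"patient_id": pid, "n_masked": n_masked, "n_ct_masked": 0,
                "baseline_ct_fraction": np.nan, "binom_p": np.nan}
    is_ct = lambda s: classify_substitution(s.ref, s.alt) == "C:G>T:A"
    k = sum(is_ct(s) for s in masked)
    base = sum(is_ct(s) for s in background) / len(background)
    base = min(max(base, 1e-12), 1 - 1e-12)
    p = stats.binomtest(k, n_masked, base, alternative="greater").pvalue
    return {"patient_id": pid, "n_masked": n_masked, "n_ct_masked": k,
            "baseline_ct_fraction": base, "binom_p": float(p)}


def run_pipeline(
    cohort: Sequence[PatientPair],
    genome: GenomeModel,
    snp_positions: Iterable,
    t: Optional[PipelineThresholds] = None,
) -> PipelineResult:
    """Run the full cascade per patient and annotate consequences.

    Stage counts at the specificity stage and beyond count labelled
    (tumor + non_tumor) sites only.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    t = t or PipelineThresholds()
    snp_positions = set(snp_positions)
    counts = {stage: {} for stage in STAGES}
    tumor, non_tumor = {}, {}
    kataegis_rows = []
    for patient in cohort:
        sites = sites_by_position(patient.variants)
        counts["input"][patient.patient_id] = len(sites)
        sites = apply_quality_filter(sites, t)
        counts["quality"][patient.patient_id] = len(sites)
        post_quality = list(sites)
        sites = filter_exonic_depth(sites, genome, t)
        counts["exonic_depth"][patient.patient_id] = len(sites)
        sites = classify_specificity(sites, t)
        counts["fisher"][patient.patient_id] = len(sites)
        sites = filter_shared_germline(sites, t)
        counts["germline"][patient.patient_id] = len(sites)
        sites, masked = mask_hypermutable(sites, t)
        counts["window"][patient.patient_id] = len(sites)
        kataegis_rows.append(_kataegis_row(patient.patient_id, masked, post_quality))
        sites = remove_known_snps(sites, snp_positions)
        counts["snp"][patient.patient_id] = len(sites)
        for s in sites:
            annotate_consequence(s, genome)
        tumor[patient.patient_id] = [s for s in sites if s.specificity == "tumor"]
        non_tumor[patient.patient_id] = [s for s in sites if s.specificity == "non_tumor"]

    stage_counts = pd.DataFrame(counts).T
    stage_counts["total"] = stage_counts.sum(axis=1)

    gene_patients = {}
    for pid, sites in tumor.items():
        for g in {s.gene for s in sites if s.gene}:
            gene_patients.setdefault(g, set()).add(pid)
    rec = [
        {"gene": g, "n_patients": len(pids)}
        for g, pids in sorted(gene_patients.items())
        if len(pids) >= 2
    ]
    recurrence = pd.DataFrame(rec, columns=["gene", "n_patients"])
    if not recurrence.empty:
        recurrence = recurrence.sort_values(
            ["n_patients", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    kataegis = pd.DataFrame(kataegis_rows)
    return PipelineResult(tumor, non_tumor, stage_counts, recurrence, kataegis)
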
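"""Synthetic paired-cohort generator.

Emulates the statistical structure the downstream analysis assumes: a small
cohort of tumor / adjacent-tissue exome pairs with patient-variable somatic
burden, a designated chromosome arm carrying a multiplicative mutation-rate
excess in the advanced subgroup, a C:G>T:A-dominant substitution spectrum
with a tumor-exclusive T:A>A:T class, germline-shared variants, planted
hypermutable clusters, known-SNP contaminants, and expression profiles in
which each patient's mutated genes are down-shifted and selected gene sets
differ between grade subgroups.

Read counts follow the regime the specificity test operates in: per-tissue
depth is negative-binomial, variant-supporting reads binomial at the tissue
VAF (0.3 for tumor-specific somatic sites, ~0 in the other tissue apart
from a small sequencing-error rate, 0.5 in both tissues for germline).

Ground truth (per-site labels) is emitted in a sidecar table that the
analysis modules never read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .models import (
    Arm,
    BASES,
    GenomeModel,
    PatientPair,
    SizingError,
    Transcript,
    ValidationError,
    VariantSite,
    sites_by_position,
)
from .spectrum import SUBSTITUTION_CLASSES

TRUTH_LABELS = ("somatic_tumor", "somatic_normal", "germline", "cluster", "snp")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Counts are per patient unless noted; ``spectrum_weights_*`` are ordered
    as :data:`exopair.spectrum.SUBSTITUTION_CLASSES` and must sum to 1.
    """

    seed: int = 0
    n_early: int = 6
    n_advanced: int = 6
    n_chromosomes: int = 10
    arm_length: int = 10_000_000  # bp, both arms
    genes_per_arm: int = 25
    cds_length_range: tuple = (300, 2400)  # bounds; drawn multiple of 3
    mean_tumor_variants: float = 50.0
    mean_normal_variants: float = 30.0
    enriched_arm: str = "1q"
    arm_enrichment_factor: float = 3.0  # advanced-group tumor variants only
    spectrum_weights_tumor: tuple = (0.45, 0.12, 0.08, 0.20, 0.07, 0.08)
    spectrum_weights_normal: tuple = (0.47, 0.13, 0.08, 0.22, 0.0, 0.10)
    germline_fraction: float = 0.15
    hypermutable_foci: int = 1
    hypermutable_width: int = 1000
    hypermutable_sites: int = 15
    cluster_vaf: float = 0.5  # misalignment artifacts: every read mismatches
    snp_fraction: float = 0.10
    depth_mean: float = 30.0
    depth_dispersion: float = 8.0  # negative-binomial size parameter
    tumor_vaf: float = 0.3
    germline_vaf: float = 0.5
    error_rate: float = 0.005  # sequencing-error alt rate in the other tissue
    quality_fail_rate: float = 0.05  # forced failure rate per quality gate
    n_gene_sets: int = 50
    gene_set_size: tuple = (15, 60)
    expression_effect: float = 2.0  # down-shift of a patient's mutated genes
    noise_sd: float = 1.0
    go_effect: tuple = (
        ("GS000", "advanced", 2.0),
        ("GS001", "advanced", 2.0),
        ("GS002", "advanced", 2.0),
        ("GS003", "early", 2.0),
        ("GS004", "early", 2.0),
    )
    with_sequence: bool = False

    def __post_init__(self):
        for weights in (self.spectrum_weights_tumor, self.spectrum_weights_normal):
            if len(weights) != len(SUBSTITUTION_CLASSES):
                raise ValidationError("spectrum weights need one entry per class")
            if any(w < 0 for w in weights):
                raise ValidationError("spectrum weights must be non-negative")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValidationError("spectrum weights must sum to 1 per tissue")
        if self.arm_enrichment_factor < 1.0:
            raise ValidationError("arm_enrichment_factor must be >= 1")
        non_negative = (
            self.n_early, self.n_advanced, self.mean_tumor_variants,
            self.mean_normal_variants, self.germline_fraction,
            self.hypermutable_foci, self.snp_fraction, self.noise_sd,
        )
        if any(v < 0 for v in non_negative):
            raise ValidationError("counts, fractions and noise must be >= 0")
        if self.arm_length <= 0 or self.n_chromosomes <= 0 or self.genes_per_arm <= 0:
            raise ValidationError("genome dimensions must be positive")

    @property
    def n_patients(self) -> int:
        return self.n_early + self.n_advanced


@dataclass
class SyntheticCohort:
    """Generated cohort plus the never-analyzed ground-truth sidecar."""

    patients: list
    snp_positions: set  # {(chrom, 1-based pos), ...}
    truth: pd.DataFrame

    def patient(self, patient_id: str) -> PatientPair:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def grades(self) -> dict:
        return {p.patient_id: p.grade_group for p in self.patients}


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome_model(config: SyntheticConfig) -> GenomeModel:
    """Random genome: equal-length p/q arms, non-overlapping single-exon CDS.

    Genes are placed one per equal-width slot inside each arm so packing is
    overlap-free by construction; CDS lengths are multiples of 3 drawn from
    ``cds_length_range``.
    """
    rng = _rng(config, 1)
    lo, hi = config.cds_length_range
    lo, hi = max(3, lo), max(3, hi)
    slot = config.arm_length // config.genes_per_arm
    if hi + 2 > slot:
        raise SizingError(
            f"{config.genes_per_arm} genes of CDS up to {hi} bp do not fit in a "
            f"{config.arm_length} bp arm"
        )
    chrom_lengths, arms, transcripts = {}, [], []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        chrom_lengths[chrom] = 2 * config.arm_length
        for arm_idx, arm_label in enumerate(("p", "q")):
            start = arm_idx * config.arm_length
            arm = Arm(chrom, f"{c}{arm_label}", start, start + config.arm_length)
            arms.append(arm)
            for g in range(config.genes_per_arm):
                cds_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
                slot_start = arm.start + g * slot
                offset = int(rng.integers(0, slot - cds_len))
                cds_start = slot_start + offset
                strand = "+" if rng.random() < 0.5 else "-"
                seq = "".join(rng.choice(list(BASES), size=cds_len))
                transcripts.append(
                    Transcript(
                        gene=f"GENE_{arm.name}_{g:03d}",
                        chrom=chrom,
                        strand=strand,
                        cds_start=cds_start,
                        cds_end=cds_start + cds_len,
                        seq=seq,
                    )
                )
    sequence = None
    if config.with_sequence:
        sequence = {}
        for chrom, length in chrom_lengths.items():
            seq = rng.choice(list(BASES), size=length)
            sequence[chrom] = "".join(seq)
        # keep CDS sequences consistent with the full reference
        transcripts = [
            replace(tx, seq=sequence[tx.chrom][tx.cds_start:tx.cds_end])
            for tx in transcripts
        ]
    model = GenomeModel(chrom_lengths, arms, transcripts, sequence)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

# alt base for each (ref, class-index) combination; class order as
# SUBSTITUTION_CLASSES; purine refs are the strand-complement of the class.
_ALT_BY_REF = {
    "C": {0: "T", 1: "A", 2: "G"},
    "G": {0: "A", 1: "T", 2: "C"},
    "T": {3: "C", 4: "A", 5: "G"},
    "A": {3: "G", 4: "T", 5: "C"},
}

# reference bases compatible with each class index
_CLASS_REFS = ("CG", "CG", "CG", "TA", "TA", "TA")


def _draw_class(weights, rng) -> int:
    """Class index drawn from the configured marginal weights."""
    return int(rng.choice(len(SUBSTITUTION_CLASSES), p=np.asarray(weights, dtype=float)))


def _draw_alt(ref: str, weights, rng) -> str:
    """Alt base conditional on a fixed reference base (renormalized weights)."""
    options = _ALT_BY_REF[ref]
    idx = list(options)
    w = np.asarray([weights[i] for i in idx], dtype=float)
    w = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
    return options[int(rng.choice(idx, p=w))]


def _nb_depth(rng, config, n, minimum=1):
    p = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    return np.maximum(rng.negative_binomial(config.depth_dispersion, p, n), minimum)


def _site_metrics(rng, config, dp_true):
    """Caller site metrics with independent forced failures per quality gate."""
    q = config.quality_fail_rate
    fail_mq0, fail_dp, fail_qual, fail_qd = (rng.random(4) < q)
    dp = int(rng.integers(0, 5)) if fail_dp else int(dp_true)
    if fail_mq0:
        mq0 = max(4, dp // 10 + 1)  # guarantees mq0>=4 and mq0/dp>0.1
    else:
        mq0 = int(rng.integers(0, 4))
    qual = float(rng.uniform(1.0, 49.9)) if fail_qual else float(rng.uniform(60.0, 900.0))
    qd = float(rng.uniform(0.05, 1.49)) if fail_qd else float(rng.uniform(2.0, 20.0))
    return mq0, dp, qual, qd, bool(fail_mq0 or fail_dp or fail_qual or fail_qd)


def _paired_counts(rng, config, kind):
    """(tumor_alt, tumor_ref, normal_alt, normal_ref, dp_true) for one site."""
    dt = int(_nb_depth(rng, config, 1)[0])
    dn = int(_nb_depth(rng, config, 1)[0])
    if kind in ("tumor", "cluster"):
        vaf = config.cluster_vaf if kind == "cluster" else config.tumor_vaf
        ta = int(rng.binomial(dt, vaf))
        na = int(rng.binomial(dn, config.error_rate))
    elif kind == "normal":
        ta = int(rng.binomial(dt, config.error_rate))
        na = int(rng.binomial(dn, config.tumor_vaf))
    elif kind == "germline":
        dt, dn = max(dt, 10), max(dn, 10)
        ta = int(np.clip(rng.binomial(dt, config.germline_vaf), 5, dt))
        na = int(np.clip(rng.binomial(dn, config.germline_vaf), 5, dn))
    else:  # pragma: no cover
        raise ValueError(kind)
    return ta, dt - ta, na, dn - na, dt + dn


def generate_cohort(config: SyntheticConfig, genome: GenomeModel) -> SyntheticCohort:
    """Plant per-patient variant sites with ground-truth labels.

    Tumor-specific sites are drawn over arms with length-proportional rates,
    the designated arm multiplied by ``arm_enrichment_factor`` for advanced
    patients. All sites sit inside CDS (exome capture); positions are unique
    per patient and never collide with the known-SNP position pool except
    for sites explicitly labelled ``snp``.
    """
    if config.n_patients == 0:
        raise ValidationError("cohort needs at least one patient")
    rng = _rng(config, 2)
    arms = genome.arms
    arm_names = [a.name for a in arms]
    if config.enriched_arm not in arm_names:
        raise ValidationError(f"enriched_arm {config.enriched_arm!r} not in genome")
    tx_by_arm = {a.name: [] for a in arms}
    for tx in genome.transcripts:
        arm = genome.arm_of(tx.chrom, tx.cds_start + 1)
        tx_by_arm[arm.name].append(tx)

    lengths = np.array([a.length for a in arms], dtype=float)
    base_probs = lengths / lengths.sum()

    # global known-SNP pool, inside CDS, generated before any other placement
    pool_size = max(
        100, int(4 * config.snp_fraction * config.mean_tumor_variants * config.n_patients)
    )
    snp_positions = set()
    all_tx = genome.transcripts
    while len(snp_positions) < pool_size:
        tx = all_tx[int(rng.integers(len(all_tx)))]
        pos = int(tx.cds_start + rng.integers(tx.cds_length)) + 1
        snp_positions.add((tx.chrom, pos))
    snp_pool = sorted(snp_positions)

    patients, truth_rows = [], []

    def place_site(patient_taken, arm_name, ref_options):
        """Pick (tx, pos) whose reference base suits the drawn substitution
        class, free of per-patient and SNP-pool collisions."""
        for _ in range(2000):
            candidates = tx_by_arm[arm_name]
            t = candidates[int(rng.integers(len(candidates)))]
            p = int(t.cds_start + rng.integers(t.cds_length)) + 1
            key = (t.chrom, p)
            if key in patient_taken or key in snp_positions:
                continue
            if t.seq[p - 1 - t.cds_start] not in ref_options:
                continue
            patient_taken.add(key)
            return t, p
        raise SizingError("could not place a variant without collision")

    def make_site(patient_taken, kind, weights, arm_name=None,
                  label=None, in_snp_db=False, fixed_key=None):
        if fixed_key is not None:
            # position fixed (cluster focus / SNP pool): draw the class
            # conditional on the reference base found there
            t, p = fixed_key
            ref = t.seq[p - 1 - t.cds_start]
            alt = _draw_alt(ref, weights, rng)
        else:
            # free placement: draw the class from the marginal weights first
            # so pooled class fractions reproduce the configured spectrum
            cls = _draw_class(weights, rng)
            t, p = place_site(patient_taken, arm_name, _CLASS_REFS[cls])
            ref = t.seq[p - 1 - t.cds_start]
            alt = _ALT_BY_REF[ref][cls]
        ta, tr, na, nr, dp_true = _paired_counts(rng, config, kind)
        mq0, dp, qual, qd, fails = _site_metrics(rng, config, dp_true)
        site = VariantSite(
            chrom=t.chrom, pos=p, ref=ref, alt=alt,
            tumor_alt=ta, tumor_ref=tr, normal_alt=na, normal_ref=nr,
            mq0=mq0, dp=dp, qual=qual, qd=qd, in_snp_db=in_snp_db,
        )
        arm = genome.arm_of(t.chrom, p)
        truth_rows.append({
            "patient_id": pid, "chrom": t.chrom, "pos": p, "ref": ref,
            "alt": alt, "label": label, "gene": t.gene, "arm": arm.name,
            "fails_quality": fails,
        })
        return site

    grades = ["early"] * config.n_early + ["advanced"] * config.n_advanced
    w_t = config.spectrum_weights_tumor
    w_n = config.spectrum_weights_normal

    for idx, grade in enumerate(grades, start=1):
        pid = f"P{idx:02d}"
        taken = set()
        sites = []

        probs = base_probs.copy()
        if grade == "advanced" and config.arm_enrichment_factor > 1.0:
            probs[arm_names.index(config.enriched_arm)] *= config.arm_enrichment_factor
            probs = probs / probs.sum()

        n_t = rng.poisson(config.mean_tumor_variants)
        arm_draws = rng.choice(len(arms), size=n_t, p=probs)
        for ai in arm_draws:
            s = make_site(taken, "tumor", w_t, arm_name=arm_names[ai],
                          label="somatic_tumor")
            sites.append(s)

        n_n = rng.poisson(config.mean_normal_variants)
        arm_draws = rng.choice(len(arms), size=n_n, p=base_probs)
        for ai in arm_draws:
            s = make_site(taken, "normal", w_n, arm_name=arm_names[ai],
                          label="somatic_normal")
            sites.append(s)

        if config.germline_fraction > 0:
            lam = config.germline_fraction * (
                config.mean_tumor_variants + config.mean_normal_variants
            )
            for _ in range(rng.poisson(lam)):
                ai = int(rng.choice(len(arms), p=base_probs))
                s = make_site(taken, "germline", w_n, arm_name=arm_names[ai],
                              label="germline")
                sites.append(s)

        for _ in range(config.hypermutable_foci):
            wide = [tx for tx in genome.transcripts
                    if tx.cds_length >= config.hypermutable_width + 3]
            if not wide:
                raise SizingError(
                    "no CDS wide enough for the configured hypermutable focus"
                )
            tx = wide[int(rng.integers(len(wide)))]
            span = min(config.hypermutable_width, tx.cds_length)
            w0 = int(rng.integers(0, tx.cds_length - span + 1))
            offsets = rng.choice(span, size=config.hypermutable_sites, replace=False)
            for off in offsets:
                pos = tx.cds_start + w0 + int(off) + 1
                key = (tx.chrom, pos)
                if key in taken or key in snp_positions:
                    continue
                taken.add(key)
                s = make_site(taken, "cluster", w_t, label="cluster",
                              fixed_key=(tx, pos))
                sites.append(s)

        n_s = rng.poisson(config.snp_fraction * config.mean_tumor_variants)
        tx_at = {}
        for (chrom, pos) in snp_pool:
            tx_at.setdefault((chrom, pos), genome.transcripts_at(chrom, pos)[0])
        picks = rng.choice(len(snp_pool), size=min(n_s, len(snp_pool)), replace=False)
        for k in picks:
            chrom, pos = snp_pool[int(k)]
            if (chrom, pos) in taken:
                continue
            taken.add((chrom, pos))
            s = make_site(taken, "tumor", w_t, label="snp", in_snp_db=True,
                          fixed_key=(tx_at[(chrom, pos)], pos))
            sites.append(s)

        patients.append(
            PatientPair(patient_id=pid, grade_group=grade,
                        variants=sites_by_position([s for s in sites if s]))
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "label", "gene",
                 "arm", "fails_quality"],
    )
    return SyntheticCohort(patients, snp_positions, truth)


# ---------------------------------------------------------------------------
# gene sets and expression
# ---------------------------------------------------------------------------

def generate_gene_sets(config: SyntheticConfig, genome: GenomeModel) -> GeneSetCollection:
    """Random gene sets ("GS000", ...) drawn without replacement from the genome."""
    rng = _rng(config, 3)
    genes = np.array(genome.genes)
    lo, hi = config.gene_set_size
    if hi > genes.size:
        raise SizingError("gene sets larger than the genome's gene count")
    sets = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"GS{i:03d}"] = tuple(sorted(members))
    return GeneSetCollection(sets=sets, source="synthetic")


def mutated_genes_by_patient(cohort: SyntheticCohort) -> dict:
    """Ground-truth tumor-specific mutated genes per patient (sidecar-derived)."""
    truth = cohort.truth
    out = {}
    for p in cohort.patients:
        rows = truth[(truth.patient_id == p.patient_id) & (truth.label == "somatic_tumor")]
        out[p.patient_id] = set(rows.gene)
    return out


def generate_expression(
    config: SyntheticConfig,
    genome: GenomeModel,
    cohort: SyntheticCohort,
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Genes x patients expression matrix with planted mutation and set effects.

    Baseline values are i.i.d. Normal(0, noise_sd); each patient's mutated
    genes are shifted by ``-expression_effect`` in that patient's column;
    each ``go_effect`` triple shifts the member genes of one set in the
    samples of one grade subgroup.
    """
    rng = _rng(config, 4)
    genes = genome.genes
    gene_index = {g: i for i, g in enumerate(genes)}
    pids = [p.patient_id for p in cohort.patients]
    mat = rng.normal(0.0, config.noise_sd, size=(len(genes), len(pids)))

    mutated = mutated_genes_by_patient(cohort)
    for j, pid in enumerate(pids):
        for g in mutated[pid]:
            mat[gene_index[g], j] -= config.expression_effect

    grades = cohort.grades
    for set_id, subgroup, shift in config.go_effect:
        if set_id not in gene_sets.sets:
            raise ValidationError(f"go_effect references unknown gene set {set_id!r}")
        if subgroup not in ("early", "advanced"):
            raise ValidationError(f"go_effect subgroup must be early/advanced, got {subgroup!r}")
        for g in gene_sets.sets[set_id]:
            if g not in gene_index:
                raise ValidationError(f"go_effect gene {g!r} not in genome")
            for j, pid in enumerate(pids):
                if grades[pid] == subgroup:
                    mat[gene_index[g], j] += shift
    return pd.DataFrame(mat, index=genes, columns=pids)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: GenomeModel
    cohort: SyntheticCohort
    gene_sets: GeneSetCollection
    expression: pd.DataFrame


def generate_all(config: SyntheticConfig) -> SyntheticBundle:
    """Genome, cohort, gene sets and expression from one config (deterministic)."""
    genome = generate_genome_model(config)
    cohort = generate_cohort(config, genome)
    gene_sets = generate_gene_sets(config, genome)
    expression = generate_expression(config, genome, cohort, gene_sets)
    return SyntheticBundle(config, genome, cohort, gene_sets, expression)
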
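"""Core domain types shared across the analysis stages.

The central objects are :class:`VariantSite` (one candidate single-base
variant with paired tumor/non-tumor supporting-read counts and the caller's
site-quality metrics), :class:`PatientPair` (one tumor / adjacent-tissue
pair with its grade group), and :class:`GenomeModel` (chromosome arms,
single-exon CDS transcripts and optional reference sequence).

Coordinates are 1-based inclusive on :class:`VariantSite` (VCF convention);
arm and CDS intervals are 0-based half-open internally and converted at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONSEQUENCES = ("synonymous", "nonsynonymous", "stop", "noncoding", "unassigned")
SPECIFICITIES = ("tumor", "non_tumor", "shared", "unclassified")
GRADE_GROUPS = ("early", "advanced")


class ValidationError(ValueError):
    """Invalid user input or domain-object state."""


class SizingError(ValidationError):
    """Requested synthetic layout cannot be packed into the genome."""


class GenomeModelError(ValueError):
    """Inconsistent genome model (unknown chromosome, broken frame, ...)."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Arm:
    """Chromosome arm, 0-based half-open interval on its chromosome."""

    chrom: str
    name: str  # e.g. "1q"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if the 1-based position lies on this arm."""
        return self.start <= pos - 1 < self.end


@dataclass(frozen=True)
class Transcript:
    """Single-exon CDS transcript; ``seq`` is the plus-strand genomic CDS sequence."""

    gene: str
    chrom: str
    strand: str  # '+' or '-'
    cds_start: int  # 0-based half-open
    cds_end: int
    seq: Optional[str] = None

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    def contains(self, pos: int) -> bool:
        return self.cds_start <= pos - 1 < self.cds_end


@dataclass
class GenomeModel:
    chrom_lengths: dict
    arms: list
    transcripts: list
    sequence: Optional[dict] = None

    def __post_init__(self):
        self._tx_trees = {}
        for tx in self.transcripts:
            self._tx_trees.setdefault(tx.chrom, IntervalTree()).addi(
                tx.cds_start, tx.cds_end, tx
            )
        self._arms_by_chrom = {}
        for arm in self.arms:
            self._arms_by_chrom.setdefault(arm.chrom, []).append(arm)

    # -- lookups -------------------------------------------------------
    def arm_of(self, chrom: str, pos: int) -> Optional[Arm]:
        """Arm containing the 1-based position, or None."""
        if chrom not in self.chrom_lengths:
            raise GenomeModelError(f"unknown chromosome {chrom!r}")
        for arm in self._arms_by_chrom.get(chrom, ()):
            if arm.contains(pos):
                return arm
        return None

    def transcripts_at(self, chrom: str, pos: int) -> list:
        if chrom not in self.chrom_lengths:
            raise GenomeModelError(f"unknown chromosome {chrom!r}")
        tree = self._tx_trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos - 1)]

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        txs = self.transcripts_at(chrom, pos)
        return txs[0].gene if txs else None

    @property
    def genes(self) -> list:
        return [tx.gene for tx in self.transcripts]

    def ref_base(self, chrom: str, pos: int) -> Optional[str]:
        """Reference base at a 1-based position, from sequence or CDS sequence."""
        if self.sequence is not None and chrom in self.sequence:
            return self.sequence[chrom][pos - 1]
        for tx in self.transcripts_at(chrom, pos):
            if tx.seq is not None:
                return tx.seq[pos - 1 - tx.cds_start]
        return None

    def validate(self) -> None:
        for tx in self.transcripts:
            if tx.cds_length % 3 != 0:
                raise GenomeModelError(
                    f"CDS length of {tx.gene} not divisible by 3"
                )
        for chrom, arms in self._arms_by_chrom.items():
            spans = sorted((a.start, a.end) for a in arms)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise GenomeModelError(f"overlapping arms on {chrom}")


@dataclass
class VariantSite:
    """One candidate SNV with paired read counts and caller site metrics.

    ``dp`` is the caller's site depth and is not required to equal the sum
    of the per-tissue AD counts.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_alt: int
    tumor_ref: int
    normal_alt: int
    normal_ref: int
    mq0: int = 0
    dp: int = 0
    qual: float = 100.0
    qd: float = 5.0
    gene: Optional[str] = None
    in_snp_db: bool = False
    consequence: str = "unassigned"
    specificity: str = "unclassified"
    fisher_p: Optional[float] = None
    audit: list = field(default_factory=list)

    @property
    def tumor_depth(self) -> int:
        return self.tumor_alt + self.tumor_ref

    @property
    def normal_depth(self) -> int:
        return self.normal_alt + self.normal_ref

    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"invalid bases at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        counts = (
            self.tumor_alt, self.tumor_ref, self.normal_alt, self.normal_ref,
            self.mq0, self.dp,
        )
        if any(c < 0 for c in counts):
            raise ValidationError(
                f"negative count metric at {self.chrom}:{self.pos}"
            )
        if self.fisher_p is not None and not (0.0 <= self.fisher_p <= 1.0):
            raise ValidationError(f"fisher_p outside [0,1] at {self.chrom}:{self.pos}")


@dataclass
class PatientPair:
    """A tumor / adjacent non-tumor pair and its cohort metadata."""

    patient_id: str
    grade_group: str  # 'early' | 'advanced'
    variants: list = field(default_factory=list)
    expression_column: Optional[str] = None

    def __post_init__(self):
        if self.grade_group not in GRADE_GROUPS:
            raise ValidationError(
                f"grade_group must be one of {GRADE_GROUPS}, got {self.grade_group!r}"
            )
        if self.expression_column is None:
            self.expression_column = self.patient_id


@dataclass(frozen=True)
class PipelineThresholds:
    """Cutoffs of the filtering cascade.

    Defaults are the method's standard cutoffs: sites are dropped when hard to
    validate (MQ0 >= 4 and MQ0/DP > 0.1), low coverage (DP < 5), low
    quality (QUAL < 50.0) or low quality-by-depth (QD < 1.5); exonic sites
    need >= 10 supporting reads in at least one tissue; specificity is
    called at Fisher P < 0.01; shared sites need >= 5 alt reads in both
    tissues; hypermutable windows hold > 10 variants per 1,000 bp.
    """

    mq0_max: int = 4
    mq0_dp_ratio_max: float = 0.1
    dp_min: int = 5
    qual_min: float = 50.0
    qd_min: float = 1.5
    exonic_min_reads: int = 10
    fisher_alpha: float = 0.01
    germline_min_alt: int = 5
    window_bp: int = 1000
    window_max_variants: int = 10

    def __post_init__(self):
        numeric = (
            self.mq0_max, self.mq0_dp_ratio_max, self.dp_min, self.qual_min,
            self.qd_min, self.exonic_min_reads, self.germline_min_alt,
            self.window_bp, self.window_max_variants,
        )
        if any(v <= 0 for v in numeric):
            raise ValidationError("all thresholds must be > 0")
        if not 0.0 < self.fisher_alpha < 1.0:
            raise ValidationError("fisher_alpha must lie in (0, 1)")


def sites_by_position(sites: Sequence[VariantSite]) -> list:
    return sorted(sites, key=lambda s: (s.chrom, s.pos, s.alt))
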
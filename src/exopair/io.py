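"""Readers and writers for the pipeline's file formats.

Variant tables travel either as two-sample VCF (samples TUMOR and NORMAL,
FORMAT fields AD and DP, INFO fields DP/MQ0/QD) or as a versioned flat TSV
dialect; both encode the same :class:`~exopair.models.VariantSite` fields.
Other formats: 2-column known-SNP TSV, GMT gene sets, cytoband-style arm
TSV, transcript TSV, FASTA reference, genes x samples expression TSV and
2-column edge lists. File coordinates are 1-based inclusive; arm/CDS
intervals are converted to half-open on load.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import GeneSetCollection
from .models import (
    Arm,
    FormatError,
    GenomeModel,
    PatientPair,
    Transcript,
    VariantSite,
)

TSV_DIALECT_HEADER = "#exopair-variants v1"

_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "tumor_alt", "tumor_ref", "normal_alt",
    "normal_ref", "mq0", "dp", "qual", "qd", "gene", "in_snp_db",
    "consequence", "specificity", "fisher_p", "audit",
]


# ---------------------------------------------------------------------------
# variant TSV dialect
# ---------------------------------------------------------------------------

def variants_to_frame(sites: Sequence[VariantSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append({
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
            "tumor_alt": s.tumor_alt, "tumor_ref": s.tumor_ref,
            "normal_alt": s.normal_alt, "normal_ref": s.normal_ref,
            "mq0": s.mq0, "dp": s.dp,
            "qual": repr(float(s.qual)), "qd": repr(float(s.qd)),
            "gene": s.gene if s.gene is not None else "",
            "in_snp_db": int(s.in_snp_db),
            "consequence": s.consequence, "specificity": s.specificity,
            "fisher_p": "" if s.fisher_p is None else repr(s.fisher_p),
            "audit": ",".join(s.audit),
        })
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def frame_to_variants(frame: pd.DataFrame) -> list:
    sites = []
    for _, r in frame.iterrows():
        fisher_p = r.get("fisher_p", "")
        fisher_p = None if fisher_p in ("", None) or pd.isna(fisher_p) else float(fisher_p)
        gene = r.get("gene", "")
        audit = r.get("audit", "")
        sites.append(VariantSite(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            tumor_alt=int(r.tumor_alt), tumor_ref=int(r.tumor_ref),
            normal_alt=int(r.normal_alt), normal_ref=int(r.normal_ref),
            mq0=int(r.mq0), dp=int(r.dp), qual=float(r.qual), qd=float(r.qd),
            gene=None if gene in ("", None) or pd.isna(gene) else str(gene),
            in_snp_db=bool(int(r.get("in_snp_db", 0))),
            consequence=str(r.get("consequence", "unassigned")),
            specificity=str(r.get("specificity", "unclassified")),
            fisher_p=fisher_p,
            audit=[] if audit in ("", None) or pd.isna(audit) else str(audit).split(","),
        ))
    return sites


def write_variants_tsv(sites: Sequence[VariantSite], path, extra: Optional[pd.DataFrame] = None) -> None:
    frame = variants_to_frame(sites)
    if extra is not None:  # unknown columns survive a round trip
        frame = pd.concat([frame, extra.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        fh.write(TSV_DIALECT_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_variants_tsv(path, with_extras: bool = False):
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != TSV_DIALECT_HEADER:
            raise FormatError(f"{path}: missing dialect header {TSV_DIALECT_HEADER!r}")
        frame = pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=[],
                            float_precision="round_trip")
    sites = frame_to_variants(frame)
    if with_extras:
        extras = frame[[c for c in frame.columns if c not in _VARIANT_COLUMNS]]
        return sites, extras
    return sites


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(contigs: dict) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Caller site depth")
    header.info.add("MQ0", 1, "Integer", "Mapping-quality-zero read count")
    header.info.add("QD", 1, "Float", "Quality by depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Sample read depth")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    return header


def write_vcf(sites: Sequence[VariantSite], path, genome: Optional[GenomeModel] = None) -> None:
    """Two-sample VCF with per-tissue AD/DP and site metrics in INFO/QUAL."""
    if genome is not None:
        contigs = dict(genome.chrom_lengths)
    else:
        contigs = {}
        for s in sites:
            contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos + 1)
    header = _vcf_header(contigs)
    ordered = sorted(sites, key=lambda s: (list(contigs).index(s.chrom), s.pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in ordered:
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos - 1, stop=s.pos,
                alleles=(s.ref, s.alt), qual=s.qual,
            )
            rec.info["DP"] = s.dp
            rec.info["MQ0"] = s.mq0
            rec.info["QD"] = s.qd
            rec.samples["TUMOR"]["AD"] = (s.tumor_ref, s.tumor_alt)
            rec.samples["TUMOR"]["DP"] = s.tumor_depth
            rec.samples["NORMAL"]["AD"] = (s.normal_ref, s.normal_alt)
            rec.samples["NORMAL"]["DP"] = s.normal_depth
            vcf.write(rec)


def read_vcf(path) -> list:
    """Load a two-sample (TUMOR/NORMAL) VCF; multi-allelic records are rejected."""
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if samples != ["TUMOR", "NORMAL"]:
            raise FormatError(f"{path}: expected samples TUMOR,NORMAL, got {samples}")
        for i, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: record {i} at {rec.contig}:{rec.pos} is multi-allelic"
                )
            try:
                t_ad = rec.samples["TUMOR"]["AD"]
                n_ad = rec.samples["NORMAL"]["AD"]
            except KeyError as exc:
                raise FormatError(f"{path}: record {i} lacks AD field") from exc
            if t_ad is None or n_ad is None or t_ad[0] is None:
                raise FormatError(f"{path}: record {i} lacks AD field")
            sites.append(VariantSite(
                chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                tumor_alt=int(t_ad[1]), tumor_ref=int(t_ad[0]),
                normal_alt=int(n_ad[1]), normal_ref=int(n_ad[0]),
                mq0=int(rec.info.get("MQ0", 0)), dp=int(rec.info.get("DP", 0)),
                qual=float(rec.qual if rec.qual is not None else 0.0),
                qd=float(rec.info.get("QD", 0.0)),
            ))
    return sites


# ---------------------------------------------------------------------------
# SNP list, GMT, edges, expression
# ---------------------------------------------------------------------------

def write_snp_list(positions: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in sorted(positions):
            fh.write(f"{chrom}\t{pos}\n")


def read_snp_list(path) -> set:
    positions = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("chrom")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                positions.add((parts[0], int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad position {parts[1]!r}") from exc
    return positions


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source, *genes]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """GMT reader; duplicate members within a set are dropped with a warning."""
    sets = {}
    source = "custom"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs name, description, members")
            name, source = parts[0], parts[1] or source
            if not name:
                raise FormatError(f"{path}:{lineno}: empty gene-set name")
            genes, seen = [], set()
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate gene {g!r} in {name!r}")
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = tuple(genes)
    return GeneSetCollection(sets=sets, source=source)


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def read_edge_list(path) -> list:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            edges.append((parts[0], parts[1]))
    return edges


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

def write_arms_tsv(arms: Sequence[Arm], path) -> None:
    """Cytoband-style table; start/end are 1-based inclusive in the file."""
    with open(path, "w") as fh:
        fh.write("chrom\tarm\tstart\tend\n")
        for a in arms:
            fh.write(f"{a.chrom}\t{a.name}\t{a.start + 1}\t{a.end}\n")


def read_arms_tsv(path) -> list:
    """Load arms; zero-length (acrocentric) arms are dropped with a warning."""
    arms = []
    frame = pd.read_csv(path, sep="\t")
    for _, r in frame.iterrows():
        start, end = int(r.start) - 1, int(r.end)
        if end <= start:
            warnings.warn(f"dropping zero-length arm {r.arm!r}")
            continue
        arms.append(Arm(str(r.chrom), str(r.arm), start, end))
    return arms


def write_transcripts_tsv(transcripts: Sequence[Transcript], path, with_seq: bool = True) -> None:
    with open(path, "w") as fh:
        cols = ["gene", "chrom", "strand", "cds_start", "cds_end"]
        if with_seq:
            cols.append("seq")
        fh.write("\t".join(cols) + "\n")
        for tx in transcripts:
            row = [tx.gene, tx.chrom, tx.strand, str(tx.cds_start + 1), str(tx.cds_end)]
            if with_seq:
                row.append(tx.seq or "")
            fh.write("\t".join(row) + "\n")


def read_transcripts_tsv(path) -> list:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    txs = []
    for _, r in frame.iterrows():
        seq = str(r["seq"]) if "seq" in frame.columns and r["seq"] else None
        txs.append(Transcript(
            gene=str(r.gene), chrom=str(r.chrom), strand=str(r.strand),
            cds_start=int(r.cds_start) - 1, cds_end=int(r.cds_end), seq=seq,
        ))
    return txs


def write_genome_model(genome: GenomeModel, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_arms_tsv(genome.arms, outdir / "arms.tsv")
    write_transcripts_tsv(genome.transcripts, outdir / "transcripts.tsv")
    pd.Series(genome.chrom_lengths, name="length").rename_axis("chrom").to_csv(
        outdir / "chromosomes.tsv", sep="\t"
    )
    if genome.sequence is not None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in genome.sequence.items()
        ]
        SeqIO.write(records, outdir / "genome.fa", "fasta")


def read_genome_model(indir) -> GenomeModel:
    indir = Path(indir)
    arms = read_arms_tsv(indir / "arms.tsv")
    transcripts = read_transcripts_tsv(indir / "transcripts.tsv")
    chroms = pd.read_csv(indir / "chromosomes.tsv", sep="\t", index_col="chrom")
    sequence = None
    fasta = indir / "genome.fa"
    if fasta.exists():
        sequence = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    model = GenomeModel(
        chrom_lengths={str(c): int(l) for c, l in chroms["length"].items()},
        arms=arms, transcripts=transcripts, sequence=sequence,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# cohort-level helpers
# ---------------------------------------------------------------------------

def write_patient_metadata(patients: Sequence[PatientPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tgrade_group\n")
        for p in patients:
            fh.write(f"{p.patient_id}\t{p.grade_group}\n")


def read_patient_metadata(path) -> dict:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame.patient_id.astype(str), frame.grade_group.astype(str)))


def parse_config_file(path) -> dict:
    """Flat ``key = value`` config text; '#' starts a comment."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key] = value
    return out
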
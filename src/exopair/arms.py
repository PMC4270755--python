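"""Chromosome-arm mutation burden: rates, Fisher enrichment, ES matrix.

The per-patient enrichment score for arm i normalizes the tumor-specific
in-arm/out-of-arm odds by the same odds of the patient's non-tumoral
(background) variants:

    ES_ij = [(Nt_ij + c) / (Nt_-ij + c)] / [(Nn_ij + c) / (Nn_-ij + c)]

with a symmetric pseudocount c (0.5 by default, the Haldane-Anscombe
convention) guarding empty arms. Scores below 1 are truncated to zero in
the display matrix only; statistics always run on the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import fisher_two_sided, ranksum_test
from .models import Arm, ValidationError, VariantSite


def _arm_of(variant: VariantSite, arms: Sequence[Arm]) -> Arm:
    for arm in arms:
        if arm.chrom == variant.chrom and arm.contains(variant.pos):
            return arm
    raise ValidationError(
        f"variant {variant.chrom}:{variant.pos} lies outside every arm"
    )


def arm_counts(variants: Iterable[VariantSite], arms: Sequence[Arm]) -> pd.Series:
    counts = pd.Series(0, index=[a.name for a in arms], dtype=int)
    for v in variants:
        counts[_arm_of(v, arms).name] += 1
    return counts


def rates_per_10mb(variants_by_group: dict, arms: Sequence[Arm]) -> pd.DataFrame:
    """Mutations per 10 Mb per arm for each named variant group.

    ``variants_by_group`` maps a group label (e.g. 'tumor', 'non_tumor') to
    its variants; every variant must map to exactly one arm.
    """
    lengths = pd.Series({a.name: a.length for a in arms}, dtype=float)
    zero_arms = lengths.index[lengths == 0]
    out = {}
    for group, variants in variants_by_group.items():
        counts = arm_counts(variants, arms)
        out[(group, "count")] = counts
        out[(group, "rate_per_10mb")] = counts / (lengths / 1e7)
    table = pd.DataFrame(out)
    if len(zero_arms):
        table = table.drop(index=zero_arms)
    return table


@dataclass
class ArmFisherResult:
    arm: str
    table: tuple  # ((t_in, t_out), (n_in, n_out))
    oddsratio: float
    pvalue: float


def arm_fisher(
    tumor_variants: Sequence[VariantSite],
    nontumor_variants: Sequence[VariantSite],
    arm: Arm,
    arms: Optional[Sequence[Arm]] = None,
) -> ArmFisherResult:
    """Two-sided Fisher test of in-arm vs out-of-arm counts, tumor vs non-tumor."""
    def split(variants):
        inside = sum(1 for v in variants if arm.chrom == v.chrom and arm.contains(v.pos))
        return inside, len(variants) - inside

    t_in, t_out = split(tumor_variants)
    n_in, n_out = split(nontumor_variants)
    if t_in + t_out == 0 or n_in + n_out == 0:
        raise ValidationError("both variant groups must be non-empty")
    p, odds = fisher_two_sided([[t_in, t_out], [n_in, n_out]])
    return ArmFisherResult(arm.name, ((t_in, t_out), (n_in, n_out)), odds, p)


def arm_fisher_all(tumor_variants, nontumor_variants, arms) -> pd.DataFrame:
    rows = []
    for arm in arms:
        r = arm_fisher(tumor_variants, nontumor_variants, arm)
        rows.append({
            "arm": r.arm,
            "tumor_in": r.table[0][0], "tumor_out": r.table[0][1],
            "non_tumor_in": r.table[1][0], "non_tumor_out": r.table[1][1],
            "oddsratio": r.oddsratio, "pvalue": r.pvalue,
        })
    return pd.DataFrame(rows).set_index("arm")


def enrichment_score(
    tumor_in: int, tumor_out: int, normal_in: int, normal_out: int,
    pseudocount: float = 0.5,
) -> float:
    """Raw (untruncated) per-patient per-arm enrichment score."""
    cells = (tumor_in, tumor_out, normal_in, normal_out)
    if any(c < 0 for c in cells):
        raise ValidationError("negative variant counts")
    c = pseudocount
    return ((tumor_in + c) / (tumor_out + c)) / ((normal_in + c) / (normal_out + c))


def truncate_es(raw: float) -> float:
    """Display convention: scores below 1 are reported as 0."""
    return raw if raw >= 1.0 else 0.0


@dataclass
class EsMatrices:
    raw: pd.DataFrame  # arms x patients, untruncated
    truncated: pd.DataFrame


def es_matrix(
    tumor_by_patient: dict,
    nontumor_by_patient: dict,
    arms: Sequence[Arm],
    pseudocount: float = 0.5,
) -> EsMatrices:
    """ES for every (arm, patient); raw for statistics, truncated for display."""
    arm_names = [a.name for a in arms]
    pids = list(tumor_by_patient)
    raw = pd.DataFrame(index=arm_names, columns=pids, dtype=float)
    for pid in pids:
        ct = arm_counts(tumor_by_patient[pid], arms)
        cn = arm_counts(nontumor_by_patient.get(pid, []), arms)
        tt, tn = int(ct.sum()), int(cn.sum())
        for name in arm_names:
            raw.loc[name, pid] = enrichment_score(
                int(ct[name]), tt - int(ct[name]),
                int(cn[name]), tn - int(cn[name]),
                pseudocount,
            )
    truncated = raw.where(raw >= 1.0, 0.0)
    return EsMatrices(raw=raw, truncated=truncated)


def subgroup_es_comparison(raw_es: pd.DataFrame, grades: dict) -> pd.DataFrame:
    """Per-arm rank-sum comparison of raw ES between advanced and early patients.

    Exact null distribution for group sizes <= 12 without ties. Returns a
    frame indexed by arm with the statistic, P-value and group means.
    """
    missing = [pid for pid in raw_es.columns if pid not in grades]
    if missing:
        raise ValidationError(f"missing grade labels for {missing}")
    adv = [pid for pid in raw_es.columns if grades[pid] == "advanced"]
    early = [pid for pid in raw_es.columns if grades[pid] == "early"]
    if len(adv) < 2 or len(early) < 2:
        raise ValidationError("need >= 2 patients per grade group")
    rows = []
    for arm in raw_es.index:
        a = raw_es.loc[arm, adv].to_numpy(dtype=float)
        e = raw_es.loc[arm, early].to_numpy(dtype=float)
        stat, p = ranksum_test(a, e)
        rows.append({
            "arm": arm, "statistic": stat, "pvalue": p,
            "mean_advanced": float(np.mean(a)), "mean_early": float(np.mean(e)),
            "contrast": float(np.mean(a) - np.mean(e)),
        })
    return pd.DataFrame(rows).set_index("arm")
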
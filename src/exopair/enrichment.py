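"""Functional enrichment of mutated genes and expression integration.

Covers: EASE-score (conservative jackknifed Fisher) enrichment of mutated
gene lists; expression normalization (log2 -> quantile -> per-sample
centering); per-patient directional KS enrichment scores of gene sets,
signed -log10(P); mutated-vs-wild-type expression comparison; selection of
gene sets whose per-patient scores differ between grade subgroups; and an
interaction-degree hub summary on a user-supplied edge list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import P_FLOOR, ks_one_sided, ttest_two_sided
from .models import ValidationError


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicates within a set are not allowed."""

    sets: Dict[str, tuple]
    source: str = "custom"
    min_size: Optional[int] = None  # filter already applied, if any

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not name:
                raise ValidationError("empty gene-set name")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes in set {name!r}")

    def filter_min_size(self, min_genes: int = 10) -> "GeneSetCollection":
        """Retain sets with more than ``min_genes`` members."""
        kept = {n: g for n, g in self.sets.items() if len(g) > min_genes}
        return GeneSetCollection(sets=kept, source=self.source, min_size=min_genes)

    def __len__(self):
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------

def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the cross-sample mean distribution.

    Each column's sorted values are replaced by the across-column means of
    the sorted values; tied values receive the mean of their tied quantiles.
    Idempotent: the columns of the output share one value multiset.
    """
    values = df.to_numpy(dtype=float)
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """log2 transform, quantile normalize, then center each sample to mean 0."""
    arr = raw.to_numpy(dtype=float)
    if np.any(arr <= 0):
        i, j = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"nonpositive intensity at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    logged = pd.DataFrame(np.log2(arr), index=raw.index, columns=raw.columns)
    normed = quantile_normalize(logged)
    return normed - normed.mean(axis=0)


# ---------------------------------------------------------------------------
# directional KS enrichment
# ---------------------------------------------------------------------------

@dataclass
class KsScore:
    score: float  # signed -log10(min-side P); + means set up-shifted
    d_plus: float
    d_minus: float
    p_plus: float
    p_minus: float
    flagged: bool = False
    reason: Optional[str] = None


_NULL_KS = KsScore(0.0, 0.0, 0.0, 1.0, 1.0, flagged=True)


def ks_enrichment(profile: pd.Series, gene_set: Iterable) -> KsScore:
    """Directional KS enrichment of a gene set within one expression profile.

    Compares set-member values against non-member values: D+ tests the
    members stochastically larger, D- smaller. The signed score is
    -log10 of the more significant side's P (floored at 1e-300), positive
    when the up side wins. Degenerate sets (empty intersection, or no
    non-member contrast) give a flagged zero score.
    """
    members = profile.index.isin(set(gene_set))
    n, m = int(members.sum()), int((~members).sum())
    if n == 0:
        return KsScore(0.0, 0.0, 0.0, 1.0, 1.0, True, "set does not intersect profile")
    if m == 0:
        return KsScore(0.0, 0.0, 0.0, 1.0, 1.0, True, "set covers the whole profile")
    inside = profile.to_numpy(dtype=float)[members]
    outside = profile.to_numpy(dtype=float)[~members]
    d_plus, p_plus = ks_one_sided(inside, outside, "larger")
    d_minus, p_minus = ks_one_sided(inside, outside, "smaller")
    if p_plus < p_minus:
        score = -np.log10(max(p_plus, P_FLOOR))
    elif p_minus < p_plus:
        score = np.log10(max(p_minus, P_FLOOR))
    else:
        score = 0.0
    return KsScore(float(score), d_plus, d_minus, p_plus, p_minus)


def enrichment_matrix(expression: pd.DataFrame, collection: GeneSetCollection) -> pd.DataFrame:
    """Gene-set x sample matrix of signed KS enrichment scores."""
    data = {
        sample: {
            name: ks_enrichment(expression[sample], genes).score
            for name, genes in collection.sets.items()
        }
        for sample in expression.columns
    }
    return pd.DataFrame(data, columns=list(expression.columns)).loc[list(collection.sets)]


# ---------------------------------------------------------------------------
# EASE
# ---------------------------------------------------------------------------

def ease_score(n_list: int, n_set: int, n_overlap: int, background: int) -> float:
    """Conservative enrichment P: one-sided Fisher with the overlap cell
    decremented by one (the EASE jackknife). Overlap of 0 or 1 gives P = 1.
    """
    if n_overlap > min(n_list, n_set):
        raise ValidationError("overlap exceeds list or set size")
    if background < n_list + n_set - n_overlap:
        raise ValidationError("background smaller than the union of list and set")
    if n_overlap <= 1:
        return 1.0
    a = n_overlap - 1
    b = n_list - n_overlap
    c = n_set - n_overlap
    d = background - n_list - n_set + n_overlap
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def ease_table(
    mutated_genes: Iterable,
    collection: GeneSetCollection,
    background: int,
    bh: bool = False,
) -> pd.DataFrame:
    """EASE enrichment of a mutated-gene list against every set in the collection."""
    mutated = set(mutated_genes)
    rows = []
    for name, genes in collection.sets.items():
        overlap = mutated & set(genes)
        rows.append({
            "term": name,
            "set_size": len(genes),
            "gene_count": len(overlap),
            "ease_p": ease_score(len(mutated), len(genes), len(overlap), background),
            "genes": ",".join(sorted(overlap)),
        })
    table = pd.DataFrame(rows).sort_values("ease_p").reset_index(drop=True)
    if bh and len(table):
        table["bh_q"] = multipletests(table["ease_p"], method="fdr_bh")[1]
    return table


def select_mutated_go_terms(collection: GeneSetCollection, mutated_genes: Iterable):
    """Sets containing at least one mutated gene, with their hits recorded.

    Returns ``(filtered_collection, hits)`` where hits maps term -> tuple of
    the mutated genes found in it.
    """
    mutated = set(mutated_genes)
    kept, hits = {}, {}
    for name, genes in collection.sets.items():
        inter = mutated & set(genes)
        if inter:
            kept[name] = genes
            hits[name] = tuple(sorted(inter))
    return (
        GeneSetCollection(sets=kept, source=collection.source,
                          min_size=collection.min_size),
        hits,
    )


# ---------------------------------------------------------------------------
# MT vs WT expression
# ---------------------------------------------------------------------------

@dataclass
class MtWtResult:
    statistic: float
    pvalue: float
    mean_mt: float
    mean_wt: float
    n_mt: int
    n_wt: int


def compare_mt_wt_expression(
    expression: pd.DataFrame, mutated_by_patient: dict
) -> MtWtResult:
    """Pooled two-tailed t-test of mutated-gene vs wild-type expression.

    For each patient, that patient's mutated genes contribute their values
    in the patient's own sample to the MT pool; all remaining genes in that
    sample form the WT pool.
    """
    mt, wt = [], []
    for pid, genes in mutated_by_patient.items():
        if pid not in expression.columns:
            raise ValidationError(f"patient {pid!r} absent from expression matrix")
        col = expression[pid]
        mask = col.index.isin(set(genes))
        mt.extend(col[mask].tolist())
        wt.extend(col[~mask].tolist())
    if len(mt) < 2 or len(wt) < 2:
        raise ValidationError("need >= 2 expression values on each side")
    t, p = ttest_two_sided(mt, wt)
    return MtWtResult(t, p, float(np.mean(mt)), float(np.mean(wt)), len(mt), len(wt))


# ---------------------------------------------------------------------------
# subgroup-differential gene-set selection
# ---------------------------------------------------------------------------

def differential_go_selection(
    scores: pd.DataFrame,
    grades: dict,
    alpha: float = 0.05,
    fold: float = 2.0,
    fold_mode: str = "magnitude_ratio",
    hits: Optional[dict] = None,
    bh: bool = False,
):
    """Gene sets whose per-patient scores separate the grade subgroups.

    Per term: two-sample Student t-test of per-patient scores early vs
    advanced, plus a fold criterion. ``magnitude_ratio`` (default) compares
    group mean score magnitudes offset by +1 (zero guard) in either
    direction; ``signed_diff`` instead requires the absolute difference of
    signed group means to exceed ``fold``. A term is selected when
    P < alpha and the fold criterion holds. Returns ``(table,
    selected_genes)`` where selected_genes is the union of mutated genes
    hitting the selected terms (empty if ``hits`` is not given).
    """
    adv = [pid for pid in scores.columns if grades.get(pid) == "advanced"]
    early = [pid for pid in scores.columns if grades.get(pid) == "early"]
    if len(adv) < 2 or len(early) < 2:
        raise ValidationError("need >= 2 patients per grade group")
    rows = []
    for term in scores.index:
        a = scores.loc[term, adv].to_numpy(dtype=float)
        e = scores.loc[term, early].to_numpy(dtype=float)
        t, p = ttest_two_sided(a, e)
        ma, me = np.abs(a).mean(), np.abs(e).mean()
        if fold_mode == "magnitude_ratio":
            ratio = max((ma + 1.0) / (me + 1.0), (me + 1.0) / (ma + 1.0))
            fold_ok = ratio > fold
        elif fold_mode == "signed_diff":
            ratio = abs(a.mean() - e.mean())
            fold_ok = ratio > fold
        else:
            raise ValidationError(f"unknown fold_mode {fold_mode!r}")
        rows.append({
            "term": term, "statistic": t, "pvalue": p, "fold": ratio,
            "mean_advanced": float(a.mean()), "mean_early": float(e.mean()),
            "selected": bool(p < alpha and fold_ok),
        })
    table = pd.DataFrame(rows).set_index("term")
    if bh and len(table):
        table["bh_q"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    selected_genes = set()
    if hits:
        for term in table.index[table.selected]:
            selected_genes.update(hits.get(term, ()))
    return table, sorted(selected_genes)


# ---------------------------------------------------------------------------
# interaction degrees
# ---------------------------------------------------------------------------

def interaction_degree(genes: Iterable, edges: Iterable) -> pd.DataFrame:
    """Undirected degree of each gene in the induced subgraph of an edge list.

    Self-loops are dropped with a warning and duplicate edges collapsed.
    Rows are ranked by decreasing degree, ties broken lexicographically.
    """
    genes = list(dict.fromkeys(genes))
    gene_set = set(genes)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for u, v in edges:
        if u == v:
            warnings.warn(f"dropping self-loop on {u!r}", stacklevel=2)
            continue
        if u in gene_set and v in gene_set:
            graph.add_edge(u, v)
    rows = [{"gene": g, "degree": graph.degree(g)} for g in genes]
    return (
        pd.DataFrame(rows)
        .sort_values(["degree", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
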
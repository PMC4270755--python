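"""Independent brute-force oracles used to verify the statistical kernels.

Everything here is written from first principles (hypergeometric sums,
exhaustive rank enumeration, quadratic window scans) and deliberately avoids
the code paths and library calls it is used to check.
"""

from __future__ import annotations

import itertools
import math


def hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """P(top-left cell = a) for a 2x2 table with fixed margins."""
    n = row1 + row2
    return math.comb(row1, a) * math.comb(row2, col1 - a) / math.comb(n, col1)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exhaustive enumeration over same-margin tables.

    Sums the probabilities of all tables whose point probability does not
    exceed the observed one (up to the conventional 1+1e-7 relative slack
    for floating-point ties).
    """
    row1, row2, col1 = a + b, c + d, a + c
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom_pmf(x, row1, row2, col1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher P: upper hypergeometric tail sum."""
    row1, row2, col1 = a + b, c + d, a + c
    hi = min(col1, row1)
    return min(sum(hypergeom_pmf(x, row1, row2, col1) for x in range(a, hi + 1)), 1.0)


def _sup_ecdf_diff(member_flags, n: int, m: int, direction: str) -> float:
    """Scan pooled observations in ascending rank order and return
    sup (F_other - F_member) for 'larger' (members stochastically larger)
    or sup (F_member - F_other) for 'smaller'."""
    best = -1.0
    cs = co = 0
    for is_member in member_flags:
        if is_member:
            cs += 1
        else:
            co += 1
        diff = co / m - cs / n if direction == "larger" else cs / n - co / m
        best = max(best, diff)
    return best


def ks_one_sided_oracle(values, others, which: str) -> tuple:
    """Exact one-sided two-sample KS P by enumeration of rank assignments.

    Assumes no ties. Returns ``(statistic, p_value)``: D+ for
    ``which='larger'`` (set stochastically larger), D- otherwise; the P is
    the fraction of all C(n+m, n) equally likely rank assignments whose
    statistic reaches the observed one.
    """
    n, m = len(values), len(others)
    pooled = sorted([(v, True) for v in values] + [(o, False) for o in others])
    flags = [f for _, f in pooled]
    d_obs = _sup_ecdf_diff(flags, n, m, which)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        member = [False] * (n + m)
        for i in combo:
            member[i] = True
        total += 1
        if _sup_ecdf_diff(member, n, m, which) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def ranksum_two_sided_oracle(x, y) -> float:
    """Exact two-sided rank-sum P by full enumeration (no ties)."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(x), len(y)
    obs = sum(ranks[v] for v in x)
    mu = n * (n + m + 1) / 2
    dev = abs(obs - mu)
    count = total = 0
    for combo in itertools.combinations(pooled, n):
        w = sum(ranks[v] for v in combo)
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / total


def window_mask_oracle(positions, window_bp: int, max_variants: int) -> set:
    """Positions removed by the hypermutable-window rule, O(n^2) scan.

    A position is removed when some window of ``window_bp`` consecutive bases
    contains more than ``max_variants`` of the positions.
    """
    removed = set()
    pos = sorted(positions)
    for start in pos:  # windows anchored at a variant dominate all others
        inside = [p for p in pos if start <= p <= start + window_bp - 1]
        if len(inside) > max_variants:
            removed.update(inside)
    return removed


# compact standard genetic code, written out independently of Biopython
_CODON_TABLE_RAW = """
TTT F TTC F TTA L TTG L CTT L CTC L CTA L CTG L ATT I ATC I ATA I ATG M
GTT V GTC V GTA V GTG V TCT S TCC S TCA S TCG S CCT P CCC P CCA P CCG P
ACT T ACC T ACA T ACG T GCT A GCC A GCA A GCG A TAT Y TAC Y TAA * TAG *
CAT H CAC H CAA Q CAG Q AAT N AAC N AAA K AAG K GAT D GAC D GAA E GAG E
TGT C TGC C TGA * TGG W CGT R CGC R CGA R CGG R AGT S AGC S AGA R AGG R
GGT G GGC G GGA G GGG G
"""
_parts = _CODON_TABLE_RAW.split()
CODON_TABLE = {c: aa for c, aa in zip(_parts[0::2], _parts[1::2])}


def consequence_oracle(ref_codon: str, alt_codon: str) -> str:
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        return "synonymous"
    if "*" in (ref_aa, alt_aa):
        return "stop"
    return "nonsynonymous"
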
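"""Naive reference implementations used for validation.

These deliberately avoid the optimised code paths of the main modules:
the Fisher test is computed by exhaustive enumeration in exact integer
arithmetic, and the brute-force DMR enumerator works in plain Python with
a right-to-left merge sweep.  They exist so that the fast implementations
can be checked against an independently written route; they are not meant
for production-size inputs.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Dict, List, Tuple

from .bscore import MethylomeTable

# relative tolerance on the "probability <= observed" comparison, applied
# in exact integer arithmetic: num_k * 10^7 <= num_obs * (10^7 + 1)
_TOL_NUM = 10**7 + 1
_TOL_DEN = 10**7


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive table enumeration.

    Exact integer arithmetic throughout: pmf numerators are
    C(r1, k) * C(r2, c1 - k) over the common denominator C(n, c1).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num_k = comb(r1, k) * comb(r2, c1 - k)
        if num_k * _TOL_DEN <= num_obs * _TOL_NUM:
            total += num_k
    return float(Fraction(total, comb(n, c1)))


def _sites(m: MethylomeTable, context: str, min_cov: int) -> Dict[str, list]:
    out: Dict[str, list] = {}
    for row in m.sites.itertuples(index=False):
        if row.context == context and row.mc + row.uc >= min_cov:
            out.setdefault(row.chrom, []).append((row.pos, row.strand, row.mc, row.uc))
    return out


def dmrs_bruteforce(
    m1: MethylomeTable,
    m2: MethylomeTable,
    context: str = "CpG",
    min_sites: int = 5,
    min_cov: int = 5,
    fold_min: float = 2.0,
    p_max: float = 0.05,
    hypo_threshold: float = 0.2,
    max_gap: int = 500,
) -> List[Tuple[str, int, int, int]]:
    """Brute-force DMR enumeration.

    Returns (chrom, start, end, n_sites) tuples: windows of exactly
    ``min_sites`` consecutive commonly covered sites are tested one by one
    with the enumeration Fisher test, overlapping passing windows are
    unioned into maximal site runs, and nearby runs are merged by repeated
    right-to-left sweeps while their pooled span passes every criterion.
    """
    s1 = _sites(m1, context, min_cov)
    s2 = _sites(m2, context, min_cov)

    def passes(counts) -> bool:
        mc1 = sum(x[0] for x in counts)
        uc1 = sum(x[1] for x in counts)
        mc2 = sum(x[2] for x in counts)
        uc2 = sum(x[3] for x in counts)
        l1 = mc1 / (mc1 + uc1)
        l2 = mc2 / (mc2 + uc2)
        lo, hi = min(l1, l2), max(l1, l2)
        if hi < hypo_threshold:
            return False
        if lo == 0.0:
            fold_ok = hi > 0
        else:
            fold_ok = hi / lo >= fold_min
        if not fold_ok:
            return False
        return fisher_two_sided_enumeration(mc1, uc1, mc2, uc2) < p_max

    results: List[Tuple[str, int, int, int]] = []
    for chrom in sorted(set(s1) & set(s2)):
        d2 = {(pos, strand): (mc, uc) for pos, strand, mc, uc in s2[chrom]}
        common = []
        for pos, strand, mc, uc in s1[chrom]:
            if (pos, strand) in d2:
                mc2_, uc2_ = d2[(pos, strand)]
                common.append((pos, mc, uc, mc2_, uc2_))
        common.sort()
        pos = [x[0] for x in common]
        cnt = [(x[1], x[2], x[3], x[4]) for x in common]
        n = len(common)

        # exact-size windows, tested independently
        passing_spans = []
        for i in range(n - min_sites + 1):
            j = i + min_sites - 1
            if passes(cnt[i : j + 1]):
                passing_spans.append((i, j))

        # union of overlapping passing windows into maximal runs
        runs: List[List[int]] = []
        for i, j in passing_spans:
            if runs and i <= runs[-1][1]:
                runs[-1][1] = max(runs[-1][1], j)
            else:
                runs.append([i, j])

        # iterative merging, right-to-left sweeps until stable
        changed = True
        while changed:
            changed = False
            k = len(runs) - 2
            while k >= 0:
                a, b = runs[k], runs[k + 1]
                gap = pos[b[0]] - (pos[a[1]] + 1)
                if gap <= max_gap and passes(cnt[a[0] : b[1] + 1]):
                    runs[k] = [a[0], b[1]]
                    del runs[k + 1]
                    changed = True
                k -= 1

        for a, b in runs:
            if passes(cnt[a : b + 1]):
                results.append((chrom, pos[a], pos[b] + 1, b - a + 1))
    return results
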
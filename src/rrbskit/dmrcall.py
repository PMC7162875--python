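"""Differentially methylated region (DMR) discovery.

Two single-sample methylomes are compared.  Sites of one context (CpG,
CHG or CHH) covered in both samples at a minimum depth are scanned with
sliding windows of exactly ``min_sites`` consecutive qualifying sites.  A
window is a putative DMR when, on coverage-pooled counts,

* the methylation-level fold change max(L1, L2) / min(L1, L2) is >= 2,
* the two-sided Fisher exact p value of the pooled 2x2 count table is
  < 0.05, and
* the two samples are not both hypomethylated (max(L1, L2) >= 0.2 by
  default; the stricter "neither hypomethylated" rule is available).

Overlapping passing windows are collapsed into maximal putative regions.
Two nearby regions are interdependent when the spanning region — all
qualifying sites from the start of the upstream region to the end of the
downstream one, pooled — again meets every criterion; interdependent
regions are merged iteratively until a fixpoint, and the final DMRs are
mutually independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bscore import MethylomeTable

logger = logging.getLogger(__name__)

_LOGFACT = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Cached log-factorial table 0..n."""
    global _LOGFACT
    if len(_LOGFACT) <= n:
        start = len(_LOGFACT)
        ext = np.log(np.arange(start, n + 1, dtype=float))
        _LOGFACT = np.concatenate([_LOGFACT, np.cumsum(ext) + _LOGFACT[-1]])
    return _LOGFACT


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums, in log space, the hypergeometric probabilities of every table
    with the observed margins whose probability does not exceed that of
    the observed table (relative tolerance 1e-7 on the comparison).  An
    all-zero table returns 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lf = _logfact(n)
    const = lf[r1] + lf[r2] + lf[c1] + lf[n - c1] - lf[n]
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    logp = const - (lf[ks] + lf[r1 - ks] + lf[c1 - ks] + lf[r2 - c1 + ks])
    lp_obs = logp[a - kmin]
    thresh = lp_obs + math.log1p(1e-7)
    sel = logp <= thresh
    # stable log-sum-exp then back to linear scale; clamp to the smallest
    # positive float so the contract p in (0, 1] survives extreme tables
    m = logp[sel].max()
    lse = m + math.log(float(np.exp(logp[sel] - m).sum()))
    p = math.exp(lse) if lse > -745.0 else 0.0
    return min(max(p, math.ulp(0.0)), 1.0)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass
class CandidateWindow:
    chrom: str
    start: int  # position of the first member site
    end: int  # last member site position + 1
    context: str
    first: int  # index of first member site in the qualifying-site arrays
    last: int  # index of last member site (inclusive)
    mc1: int
    uc1: int
    mc2: int
    uc2: int

    @property
    def n_sites(self) -> int:
        return self.last - self.first + 1

    @property
    def l1(self) -> float:
        return self.mc1 / (self.mc1 + self.uc1)

    @property
    def l2(self) -> float:
        return self.mc2 / (self.mc2 + self.uc2)


@dataclass
class WindowTest:
    passed: bool
    fold: float
    p: float
    l1: float
    l2: float


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    context: str
    n_sites: int
    l1: float
    l2: float
    fold: float
    p: float
    merged_from: List[int] = field(default_factory=list)


@dataclass
class DMRParams:
    context: str = "CpG"
    min_sites: int = 5
    min_cov: int = 5
    fold_min: float = 2.0
    p_max: float = 0.05
    hypo_threshold: float = 0.2
    hypo_rule: str = "not_both"  # or "neither"
    max_gap: int = 500


@dataclass
class _SiteArrays:
    """Qualifying sites of one chromosome, position-sorted."""

    chrom: str
    pos: np.ndarray
    mc1: np.ndarray
    uc1: np.ndarray
    mc2: np.ndarray
    uc2: np.ndarray


def _qualifying_sites(
    m1: MethylomeTable, m2: MethylomeTable, context: str, min_cov: int
) -> List[_SiteArrays]:
    a = m1.sites[m1.sites["context"] == context]
    b = m2.sites[m2.sites["context"] == context]
    j = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_1", "_2"))
    cov1 = j["mc_1"] + j["uc_1"]
    cov2 = j["mc_2"] + j["uc_2"]
    j = j[(cov1 >= min_cov) & (cov2 >= min_cov)]
    out = []
    for chrom, sub in j.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        out.append(
            _SiteArrays(
                str(chrom),
                sub["pos"].to_numpy(),
                sub["mc_1"].to_numpy(),
                sub["uc_1"].to_numpy(),
                sub["mc_2"].to_numpy(),
                sub["uc_2"].to_numpy(),
            )
        )
    return out


def _window_from_span(sa: _SiteArrays, context: str, first: int, last: int) -> CandidateWindow:
    sl = slice(first, last + 1)
    return CandidateWindow(
        sa.chrom,
        int(sa.pos[first]),
        int(sa.pos[last]) + 1,
        context,
        first,
        last,
        int(sa.mc1[sl].sum()),
        int(sa.uc1[sl].sum()),
        int(sa.mc2[sl].sum()),
        int(sa.uc2[sl].sum()),
    )


def scan_windows(
    m1: MethylomeTable,
    m2: MethylomeTable,
    context: str = "CpG",
    min_sites: int = 5,
    min_cov: int = 5,
) -> List[CandidateWindow]:
    """All windows of exactly ``min_sites`` consecutive qualifying sites.

    Qualifying sites are those of the requested context covered at least
    ``min_cov``-fold in BOTH samples; windows slide by one site and never
    span chromosomes.
    """
    windows: List[CandidateWindow] = []
    for sa in _qualifying_sites(m1, m2, context, min_cov):
        n = len(sa.pos)
        for i in range(n - min_sites + 1):
            windows.append(_window_from_span(sa, context, i, i + min_sites - 1))
    return windows


def test_window(
    w: CandidateWindow,
    fold_min: float = 2.0,
    p_max: float = 0.05,
    hypo_threshold: float = 0.2,
    hypo_rule: str = "not_both",
) -> WindowTest:
    """Apply the three DMR criteria to one pooled window."""
    l1, l2 = w.l1, w.l2
    lo, hi = min(l1, l2), max(l1, l2)
    if lo == 0.0:
        fold = math.inf if hi > 0 else 1.0
    else:
        fold = hi / lo
    if hypo_rule == "not_both":
        not_hypo = hi >= hypo_threshold
    elif hypo_rule == "neither":
        not_hypo = lo >= hypo_threshold
    else:
        raise ValueError(f"unknown hypo_rule {hypo_rule!r}")
    p = fisher_exact_two_sided(w.mc1, w.uc1, w.mc2, w.uc2)
    passed = fold >= fold_min and p < p_max and not_hypo
    return WindowTest(passed, fold, p, l1, l2)


# ---------------------------------------------------------------------------
# Collapse and iterative merging
# ---------------------------------------------------------------------------


def _collapse_passing(
    passing: Sequence[CandidateWindow], sa_by_chrom: Dict[str, _SiteArrays], context: str
) -> List[Tuple[CandidateWindow, List[int]]]:
    """Merge genomically overlapping passing windows into maximal regions.

    Returns each collapsed region (recomputed over all qualifying sites in
    its span) with the ids (input indices) of its member windows.
    """
    regions: List[Tuple[CandidateWindow, List[int]]] = []
    cur: Optional[List] = None  # [chrom, first, last, ids]
    for wid, w in enumerate(passing):
        if cur is not None and w.chrom == cur[0] and w.first <= cur[2]:
            cur[2] = max(cur[2], w.last)
            cur[3].append(wid)
        else:
            if cur is not None:
                regions.append(
                    (_window_from_span(sa_by_chrom[cur[0]], context, cur[1], cur[2]), cur[3])
                )
            cur = [w.chrom, w.first, w.last, [wid]]
    if cur is not None:
        regions.append(
            (_window_from_span(sa_by_chrom[cur[0]], context, cur[1], cur[2]), cur[3])
        )
    return regions


def merge_dmrs(
    putative: Sequence[Tuple[CandidateWindow, List[int]]],
    sa_by_chrom: Dict[str, _SiteArrays],
    params: DMRParams,
) -> List[Tuple[CandidateWindow, List[int]]]:
    """Iteratively merge interdependent neighbouring regions to a fixpoint.

    Two adjacent regions on one chromosome within ``max_gap`` bp are merged
    when the spanning region — every qualifying site from the upstream
    start to the downstream end, pooled — passes all DMR criteria.  Sweeps
    repeat until a full left-to-right pass makes no merge.
    """
    regions = [(w, list(ids)) for w, ids in putative]
    changed = True
    while changed:
        changed = False
        i = 0
        while i + 1 < len(regions):
            (w1, ids1), (w2, ids2) = regions[i], regions[i + 1]
            if w1.chrom == w2.chrom and w2.start - w1.end <= params.max_gap:
                span = _window_from_span(
                    sa_by_chrom[w1.chrom], params.context, w1.first, w2.last
                )
                t = test_window(
                    span, params.fold_min, params.p_max, params.hypo_threshold, params.hypo_rule
                )
                if t.passed:
                    regions[i] = (span, ids1 + ids2)
                    del regions[i + 1]
                    changed = True
                    continue
            i += 1
    return regions


@dataclass
class DMRResult:
    dmrs: List[DMR]
    n_qualifying_sites: int
    n_windows: int
    n_passing_windows: int
    params: DMRParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "context": d.context,
                    "n_sites": d.n_sites,
                    "level1": d.l1,
                    "level2": d.l2,
                    "fold_change": d.fold,
                    "fisher_p": d.p,
                    "n_merged_windows": len(d.merged_from),
                }
                for d in self.dmrs
            ],
            columns=[
                "chrom", "start", "end", "context", "n_sites", "level1",
                "level2", "fold_change", "fisher_p", "n_merged_windows",
            ],
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, d in enumerate(self.dmrs, 1):
                score = 100.0 if d.p <= 0 else min(100.0, -math.log10(d.p))
                fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR{i:04d}\t{score:.3f}\t.\n")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def call_dmrs(
    m1: MethylomeTable, m2: MethylomeTable, params: Optional[DMRParams] = None, **kw
) -> DMRResult:
    """Full DMR discovery: scan -> test -> collapse -> iterative merge.

    Keyword arguments override individual ``DMRParams`` fields.  The final
    regions are re-checked on their own pooled counts; a merged region that
    no longer passes (possible only in pathological collapses) is dropped
    with a warning.
    """
    params = replace(params or DMRParams(), **kw)
    sas = _qualifying_sites(m1, m2, params.context, params.min_cov)
    sa_by_chrom = {sa.chrom: sa for sa in sas}
    n_sites = sum(len(sa.pos) for sa in sas)
    if n_sites == 0:
        logger.warning("no commonly covered %s sites between samples", params.context)
        return DMRResult([], 0, 0, 0, params)

    windows: List[CandidateWindow] = []
    for sa in sas:
        n = len(sa.pos)
        for i in range(n - params.min_sites + 1):
            windows.append(_window_from_span(sa, params.context, i, i + params.min_sites - 1))

    passing = [
        w
        for w in windows
        if test_window(
            w, params.fold_min, params.p_max, params.hypo_threshold, params.hypo_rule
        ).passed
    ]
    putative = _collapse_passing(passing, sa_by_chrom, params.context)
    merged = merge_dmrs(putative, sa_by_chrom, params)

    dmrs: List[DMR] = []
    for w, ids in merged:
        t = test_window(w, params.fold_min, params.p_max, params.hypo_threshold, params.hypo_rule)
        if not t.passed:
            logger.warning(
                "collapsed region %s:%d-%d fails the criteria on its own counts; dropped",
                w.chrom, w.start, w.end,
            )
            continue
        dmrs.append(
            DMR(w.chrom, w.start, w.end, w.context, w.n_sites, t.l1, t.l2, t.fold, t.p, ids)
        )
    return DMRResult(dmrs, n_sites, len(windows), len(passing), params)
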
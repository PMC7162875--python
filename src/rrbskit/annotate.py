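"""DMR-to-gene assignment and local gene-set over-representation.

DMRs are associated with gene bodies and with strand-aware promoter
windows (TSS - 2000 / TSS + 500 by default) on >= 1 bp overlap.  The
enrichment step is a hypergeometric over-representation test of a query
gene list against GMT gene sets over an explicit background universe,
reported significant at raw p <= 0.05 (a Benjamini-Hochberg column is
emitted for information only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .dmrcall import DMR
from .synthio import Feature, ReferenceGenome


@dataclass(frozen=True)
class GeneAssignment:
    dmr_id: str
    gene_id: str
    relation: str  # gene_body or promoter
    overlap_bp: int


def promoter_interval(gene: Feature, promoter_up: int = 2000, promoter_down: int = 500):
    """Strand-aware promoter window [TSS - up, TSS + down)."""
    if gene.strand == "+":
        return max(0, gene.start - promoter_up), gene.start + promoter_down
    return max(0, gene.end - promoter_down), gene.end + promoter_up


def assign_regions(
    dmrs: Sequence[DMR],
    genome: ReferenceGenome,
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> List[GeneAssignment]:
    """Assign each DMR to overlapping gene bodies and promoters."""
    trees: Dict[str, IntervalTree] = {}
    for g in genome.features_of("gene"):
        t = trees.setdefault(g.chrom, IntervalTree())
        t[g.start : g.end] = ("gene_body", g.id)
        ps, pe = promoter_interval(g, promoter_up, promoter_down)
        if pe > ps:
            t[ps:pe] = ("promoter", g.id)

    out: List[GeneAssignment] = []
    for i, d in enumerate(dmrs, 1):
        did = f"DMR{i:04d}"
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(d.start, d.end)):
            relation, gid = iv.data
            ov = min(d.end, iv.end) - max(d.start, iv.begin)
            if ov >= 1:
                out.append(GeneAssignment(did, gid, relation, ov))
    return out


def assigned_genes(assignments: Iterable[GeneAssignment]) -> Set[str]:
    """Gene universe touched by DMRs, gene body and promoter both together."""
    return {a.gene_id for a in assignments}


@dataclass
class EnrichmentResult:
    term: str
    term_size: int
    overlap: int
    p: float
    significant: bool


def enrich(
    query_genes: Set[str],
    gene_sets: Mapping[str, Sequence[str]],
    background: Set[str],
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    p = P(X >= overlap) with population |background|, successes
    |term ∩ background| and draws |query|.  Terms with no background
    overlap are skipped.  Results are sorted by p; the significance flag
    uses raw p <= alpha.
    """
    if not query_genes:
        raise ValueError("empty query gene set")
    if not query_genes <= background:
        raise ValueError("query genes must be a subset of the background")
    M = len(background)
    N = len(query_genes)
    out: List[EnrichmentResult] = []
    for term, genes in gene_sets.items():
        in_bg = set(genes) & background
        if not in_bg:
            continue
        K = len(in_bg)
        k = len(in_bg & query_genes)
        p = float(hypergeom.sf(k - 1, M, K, N))
        p = min(p, 1.0)
        out.append(EnrichmentResult(term, K, k, p, p <= alpha))
    out.sort(key=lambda r: (r.p, r.term))
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results with an informational BH-adjusted column."""
    df = pd.DataFrame(
        [
            {
                "term": r.term,
                "term_size": r.term_size,
                "overlap": r.overlap,
                "p": r.p,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["term", "term_size", "overlap", "p", "significant"],
    )
    if len(df):
        m = len(df)
        ranked = df["p"].rank(method="first")
        bh = (df["p"] * m / ranked).clip(upper=1.0)
        # enforce monotonicity from the largest p downwards
        order = ranked.sort_values(ascending=False).index
        running = 1.0
        for idx in order:
            running = min(running, bh[idx])
            bh[idx] = running
        df["p_bh"] = bh
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df
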
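"""Read placement and per-cytosine methylation calling.

Reads from a directional bisulfite library are placed by exact
collapsed-alphabet search: the read is compared C->T-collapsed against the
forward strand (original-top, OT) and its reverse complement
G->A-collapsed against the forward strand (original-bottom, OB).  A unique
best placement with at most ``max_mismatches`` collapsed-space mismatches
is accepted; ambiguous or unplaced reads are discarded and counted.

At every reference cytosine covered on its informative strand, a read base
C increments the methylated count (mC) and T the unmethylated count (uC);
other bases are treated as sequencing error and ignored.  The methylation
level at a site is mC / (mC + uC).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .synthio import ReferenceGenome, ReadSet, revcomp

CONTEXTS = ("CpG", "CHG", "CHH")


def classify_context(genome: ReferenceGenome, chrom: str, pos: int, strand: str) -> str:
    """Sequence context of a cytosine: CpG, CHG or CHH (H = A, C or T).

    Strand-aware; a cytosine whose context is truncated by the chromosome
    end defaults to CHH.
    """
    seq = genome.chromosomes[chrom]
    n = len(seq)
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is not a cytosine")
        if pos + 1 < n and seq[pos + 1] == "G":
            return "CpG"
        if pos + 2 < n and seq[pos + 2] == "G":
            return "CHG"
        return "CHH"
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is not a cytosine")
        if pos - 1 >= 0 and seq[pos - 1] == "C":
            return "CpG"
        if pos - 2 >= 0 and seq[pos - 2] == "C":
            return "CHG"
        return "CHH"
    raise ValueError(f"bad strand {strand!r}")


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    read_id: str
    sequence: str  # as sequenced
    chrom: str
    start: int  # forward-strand coordinates of the aligned window
    library: str  # OT or OB
    mismatches: int


@dataclass
class GenomeIndex:
    """Collapsed-alphabet text of each chromosome for both library strands."""

    genome: ReferenceGenome
    ct: Dict[str, str] = field(default_factory=dict)  # C->T collapse (OT search)
    ga: Dict[str, str] = field(default_factory=dict)  # G->A collapse (OB search)

    def __post_init__(self):
        for chrom, seq in self.genome.chromosomes.items():
            self.ct[chrom] = seq.replace("C", "T")
            self.ga[chrom] = seq.replace("G", "A")


def _find_all(text: str, pattern: str) -> List[int]:
    out = []
    i = text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _candidates(text: str, query: str, k: int) -> Dict[int, int]:
    """Candidate start -> mismatch count for placements with <= k mismatches.

    Pigeonhole seeding: split the query into k+1 segments; any placement
    with <= k mismatches matches at least one segment exactly.
    """
    L = len(query)
    hits: Dict[int, int] = {}
    if L == 0 or L > len(text):
        return hits
    nseg = k + 1
    bounds = [round(i * L / nseg) for i in range(nseg + 1)]
    seen = set()
    for si in range(nseg):
        a, b = bounds[si], bounds[si + 1]
        if b <= a:
            continue
        for occ in _find_all(text, query[a:b]):
            start = occ - a
            if start < 0 or start + L > len(text) or start in seen:
                continue
            seen.add(start)
            m = _mismatches(text[start : start + L], query, k)
            if m <= k:
                hits[start] = m
    return hits


def place_read(
    read_id: str, sequence: str, index: GenomeIndex, max_mismatches: int = 2
) -> Optional[Placement]:
    """Unique-best collapsed-alphabet placement, or None when discarded."""
    q_ot = sequence.replace("C", "T")
    q_ob = revcomp(sequence).replace("G", "A")
    best: List[Tuple[str, int, str, int]] = []  # (chrom, start, lib, mismatches)
    best_m = max_mismatches + 1
    for chrom in index.genome.chromosomes:
        for lib, text, q in (("OT", index.ct[chrom], q_ot), ("OB", index.ga[chrom], q_ob)):
            for start, m in _candidates(text, q, max_mismatches).items():
                if m < best_m:
                    best = [(chrom, start, lib, m)]
                    best_m = m
                elif m == best_m:
                    best.append((chrom, start, lib, m))
    if len(best) != 1:
        return None  # unplaced or ambiguous
    chrom, start, lib, m = best[0]
    return Placement(read_id, sequence, chrom, start, lib, m)


def place_reads(
    reads: ReadSet, genome: ReferenceGenome, max_mismatches: int = 2
) -> Tuple[List[Placement], Dict[str, int]]:
    """Place every read; returns placements and discard statistics."""
    index = GenomeIndex(genome)
    placements: List[Placement] = []
    stats = {"placed": 0, "discarded": 0}
    for r in reads.reads:
        p = place_read(r.id, r.sequence, index, max_mismatches)
        if p is None:
            stats["discarded"] += 1
        else:
            stats["placed"] += 1
            placements.append(p)
    return placements, stats


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


@dataclass
class MethylomeTable:
    """Per-cytosine methylation calls for one sample.

    ``sites`` columns: chrom, pos, strand, context, mc, uc, level; unique
    (chrom, pos, strand) keys, sorted by chrom then pos.
    """

    sample: str
    sites: pd.DataFrame

    COLUMNS = ("chrom", "pos", "strand", "context", "mc", "uc", "level")

    def to_cx(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_cx(cls, path, sample: str = "") -> "MethylomeTable":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "pos": np.int64, "strand": str, "context": str,
                   "mc": np.int64, "uc": np.int64, "level": float},
        )
        # level is derived; recompute for exact round-trips
        df["level"] = df["mc"] / (df["mc"] + df["uc"])
        return cls(sample or str(path), df)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.sites.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.level:.6g}\n")


def call_cytosines(
    placements: Iterable[Placement],
    genome: ReferenceGenome,
    min_coverage: int = 1,
    sample: str = "sample",
) -> MethylomeTable:
    """Count C/T observations at reference cytosines, strand-resolved.

    OT placements report cytosines of the forward strand; OB placements
    (oriented to forward coordinates) report cytosines of the reverse
    strand, which appear as G/A in forward orientation.  Sites with
    mc + uc < min_coverage are omitted.
    """
    counts: Dict[Tuple[str, int, str], List[int]] = defaultdict(lambda: [0, 0])
    for p in placements:
        seq = genome.chromosomes[p.chrom]
        if p.library == "OT":
            oriented = p.sequence
            for i, base in enumerate(oriented):
                gpos = p.start + i
                if seq[gpos] == "C":
                    if base == "C":
                        counts[(p.chrom, gpos, "+")][0] += 1
                    elif base == "T":
                        counts[(p.chrom, gpos, "+")][1] += 1
        else:
            oriented = revcomp(p.sequence)
            for i, base in enumerate(oriented):
                gpos = p.start + i
                if seq[gpos] == "G":
                    if base == "G":
                        counts[(p.chrom, gpos, "-")][0] += 1
                    elif base == "A":
                        counts[(p.chrom, gpos, "-")][1] += 1

    rows = []
    for (chrom, pos, strand), (mc, uc) in counts.items():
        if mc + uc >= min_coverage and mc + uc > 0:
            rows.append(
                (
                    chrom,
                    pos,
                    strand,
                    classify_context(genome, chrom, pos, strand),
                    mc,
                    uc,
                    mc / (mc + uc),
                )
            )
    df = pd.DataFrame(rows, columns=list(MethylomeTable.COLUMNS))
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return MethylomeTable(sample, df)


def methylome_from_profile(
    profile,
    genome: ReferenceGenome,
    coverage: float = 30.0,
    seed: int = 0,
    sample: str = "",
    covered_positions: Optional[pd.DataFrame] = None,
) -> MethylomeTable:
    """Direct count simulation from a true profile (no reads).

    Each cytosine receives Poisson(coverage) observations and mc ~
    Binomial(n, true_level).  ``covered_positions`` (chrom, pos) optionally
    restricts the simulated sites (e.g. to size-selected fragments).
    """
    rng = np.random.default_rng(seed)
    df = profile.sites
    if covered_positions is not None:
        key = pd.MultiIndex.from_frame(covered_positions[["chrom", "pos"]])
        df = df[pd.MultiIndex.from_frame(df[["chrom", "pos"]]).isin(key)]
    n = rng.poisson(coverage, size=len(df))
    mc = rng.binomial(n, df["true_level"].to_numpy())
    out = df[["chrom", "pos", "strand", "context"]].copy()
    out["mc"] = mc
    out["uc"] = n - mc
    keep = n > 0
    out = out[keep].copy()
    out["level"] = out["mc"] / (out["mc"] + out["uc"])
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return MethylomeTable(sample or profile.condition, out)
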
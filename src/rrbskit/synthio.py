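"""Synthetic input generation with known ground truth.

Everything the downstream pipeline consumes is produced here: a small
reference genome with CCGG-rich sequence and feature annotation (genes,
promoters, CpG islands, implanted differential regions and one TSDR-like
locus), condition-specific per-cytosine methylation profiles for the four
culture arms (medium, pVC, TGF-beta, TGF-beta + pVC), directional bisulfite
reads from size-selected MspI fragments, targeted-amplicon per-CpG
methylation tables, and cytometry event tables for standard-cell-dilution
counting and CFSE dilution analysis.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CONDITIONS = ("medium", "pVC", "TGFb", "TGFb_pVC")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("gene", "promoter", "CGI", "truth_dmr", "tsdr")


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    kind: str
    id: str
    strand: str = "+"

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")


@dataclass
class ReferenceGenome:
    chromosomes: Dict[str, str]
    features: List[Feature] = field(default_factory=list)

    def validate(self) -> None:
        for name, seq in self.chromosomes.items():
            if re.search("[^ACGT]", seq):
                raise ValueError(f"chromosome {name} contains non-ACGT bases")
        for f in self.features:
            if f.chrom not in self.chromosomes:
                raise ValueError(f"feature {f.id} on unknown chromosome {f.chrom}")
            if f.end > len(self.chromosomes[f.chrom]):
                raise ValueError(f"feature {f.id} exceeds chromosome bounds")

    def features_of(self, kind: str) -> List[Feature]:
        return [f for f in self.features if f.kind == kind]

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def to_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, features: Optional[List[Feature]] = None) -> "ReferenceGenome":
        from Bio import SeqIO

        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(chroms, features or [])

    def features_to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.kind}:{f.id}\t0\t{f.strand}\n"
                )

    def genes_to_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.features_of("gene"):
                # GTF is 1-based inclusive
                fh.write(
                    f'{f.chrom}\trrbskit\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t'
                    f'gene_id "{f.id}";\n'
                )


def _cassette(n_cpgs: int, rng: np.random.Generator) -> str:
    """A designed locus: CCGG + CpG-dense middle + CCGG.

    MspI cuts after the first C of each CCGG, so the middle falls inside a
    single fragment of length 6*n_cpgs + 4 bp (within 40-220 bp for
    6 <= n_cpgs <= 36), guaranteeing RRBS coverage of the implanted CpGs.
    Spacer bases around each CpG are random A/T so that distinct cassettes
    stay unique and mappable; A/T spacers cannot create extra CpG, CCGG or
    CHG context inside the cassette.
    """
    at = np.array(list("AT"))
    units = []
    for _ in range(n_cpgs):
        s = rng.choice(at, size=4)
        units.append(s[0] + s[1] + "CG" + s[2] + s[3])
    return "CCGG" + "".join(units) + "CCGG"


def generate_genome(
    n_chrom: int,
    chrom_length: int,
    gc_fraction: float,
    ccgg_boost: float = 3.0,
    n_genes: int = 20,
    seed: int = 0,
    n_truth_dmrs: int = 0,
    truth_dmr_cpgs: int = 10,
    tsdr_cpgs: int = 7,
    n_cgi: Optional[int] = None,
) -> ReferenceGenome:
    """Generate a random genome with annotation and implanted loci.

    ``ccgg_boost`` multiplies the expected CCGG density relative to the
    random-sequence baseline by implanting extra motifs.  One ``tsdr``
    feature (>= ``tsdr_cpgs`` CpGs) is always present; ``n_truth_dmrs``
    additional CpG-dense differential cassettes are implanted inside gene
    bodies when genes are available.
    """
    if n_chrom < 1 or chrom_length < 10_000 or n_genes < 0:
        raise ValueError("n_chrom >= 1, chrom_length >= 10000, n_genes >= 0 required")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    if tsdr_cpgs < 7:
        raise ValueError("the TSDR-like locus needs at least 7 CpGs")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )

    chroms: Dict[str, str] = {}
    features: List[Feature] = []
    gene_counter = 0
    dmr_counter = 0
    cgi_counter = 0
    if n_cgi is None:
        n_cgi = max(1, n_genes // 2)

    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        seq = rng.choice(bases, size=chrom_length, p=p)

        # extra CCGG motifs on top of the random baseline
        base_rate = (gc_fraction / 2) ** 4
        n_extra = rng.poisson(max(ccgg_boost - 1.0, 0.0) * base_rate * chrom_length)
        for pos in rng.integers(0, chrom_length - 4, size=n_extra):
            seq[pos : pos + 4] = list("CCGG")

        occupied: List[Tuple[int, int]] = []

        def _reserve(length: int) -> int:
            for _ in range(1000):
                s = int(rng.integers(100, chrom_length - length - 100))
                if all(e <= s or s + length <= b for b, e in occupied):
                    occupied.append((s, s + length))
                    return s
            raise RuntimeError("could not place cassette; genome too small/crowded")

        # genes with promoters
        chrom_genes: List[Feature] = []
        for _ in range(n_genes if ci == 0 else max(n_genes // 2, 0)):
            gene_counter += 1
            glen = int(rng.integers(1000, 3000))
            gstart = int(rng.integers(0, chrom_length - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gene_counter:04d}"
            g = Feature(name, gstart, gstart + glen, "gene", gid, strand)
            chrom_genes.append(g)
            features.append(g)
            if strand == "+":
                ps, pe = max(0, gstart - 1000), min(chrom_length, gstart + 500)
            else:
                ps, pe = max(0, gstart + glen - 500), min(chrom_length, gstart + glen + 1000)
            features.append(Feature(name, ps, pe, "promoter", f"prom_{gid}", strand))

        # CpG islands: random intervals with CG-dinucleotide enrichment
        for _ in range(n_cgi if ci == 0 else 0):
            cgi_counter += 1
            clen = int(rng.integers(300, 800))
            cstart = int(rng.integers(0, chrom_length - clen))
            for pos in rng.integers(cstart, cstart + clen - 2, size=clen // 12):
                seq[pos : pos + 2] = list("CG")
            features.append(Feature(name, cstart, cstart + clen, "CGI", f"cgi{cgi_counter:03d}"))

        # implanted cassettes (overwrite last so nothing disturbs them)
        def _implant(n_cpgs: int, kind: str, fid: str) -> None:
            cas = _cassette(n_cpgs, rng)
            host_genes = [g for g in chrom_genes if g.end - g.start > len(cas) + 200]
            if host_genes:
                g = host_genes[int(rng.integers(len(host_genes)))]
                lo, hi = g.start + 50, g.end - len(cas) - 50
            else:
                lo, hi = 100, chrom_length - len(cas) - 100
            for _ in range(1000):
                s = int(rng.integers(lo, hi))
                if all(e <= s or s + len(cas) <= b for b, e in occupied):
                    occupied.append((s, s + len(cas)))
                    break
            else:
                s = _reserve(len(cas))
            seq[s : s + len(cas)] = list(cas)
            features.append(Feature(name, s + 4, s + 4 + 6 * n_cpgs, kind, fid))

        if ci == 0:
            _implant(tsdr_cpgs, "tsdr", "tsdr")
        n_here = n_truth_dmrs if ci == 0 else 0
        for _ in range(n_here):
            dmr_counter += 1
            _implant(truth_dmr_cpgs, "truth_dmr", f"dmr{dmr_counter:04d}")

        chroms[name] = "".join(seq)

    genome = ReferenceGenome(chroms, features)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# Methylation profiles
# ---------------------------------------------------------------------------


@dataclass
class MethylationProfile:
    """Per-cytosine true methylation probability for one condition arm."""

    condition: str
    sites: pd.DataFrame  # columns: chrom, pos, strand, context, true_level

    def level_arrays(self, genome: ReferenceGenome) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (plus, minus) level arrays indexed by position.

        Non-cytosine positions are NaN; used for fast read simulation.
        """
        out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, seq in genome.chromosomes.items():
            plus = np.full(len(seq), np.nan)
            minus = np.full(len(seq), np.nan)
            sub = self.sites[self.sites["chrom"] == chrom]
            fwd = sub[sub["strand"] == "+"]
            rev = sub[sub["strand"] == "-"]
            plus[fwd["pos"].to_numpy()] = fwd["true_level"].to_numpy()
            minus[rev["pos"].to_numpy()] = rev["true_level"].to_numpy()
            out[chrom] = (plus, minus)
        return out


def cytosine_sites(genome: ReferenceGenome) -> pd.DataFrame:
    """All cytosines on both strands with their sequence context.

    Context is strand-aware: CpG when the next base (5'->3') is G, CHG when
    the base after next is G, else CHH; truncated contexts at chromosome
    ends default to CHH.
    """
    frames = []
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        n = len(arr)

        # plus strand: look rightwards
        nxt_g = np.zeros(n, bool)
        nxt_g[:-1] = is_g[1:]
        nxt2_g = np.zeros(n, bool)
        nxt2_g[:-2] = is_g[2:]
        ctx_plus = np.where(nxt_g, "CpG", np.where(nxt2_g, "CHG", "CHH"))
        pos_p = np.nonzero(is_c)[0]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos_p, "strand": "+", "context": ctx_plus[pos_p]}
            )
        )

        # minus strand: genome G positions; look leftwards, complemented
        prv_c = np.zeros(n, bool)
        prv_c[1:] = is_c[:-1]
        prv2_c = np.zeros(n, bool)
        prv2_c[2:] = is_c[:-2]
        ctx_minus = np.where(prv_c, "CpG", np.where(prv2_c, "CHG", "CHH"))
        pos_m = np.nonzero(is_g)[0]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos_m, "strand": "-", "context": ctx_minus[pos_m]}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def assign_profile(
    genome: ReferenceGenome,
    condition: str,
    base_cg_level: float = 0.8,
    base_noncg_level: float = 0.02,
    dmr_spec: Sequence[Tuple[str, Mapping[str, float]]] = (),
    seed: int = 0,
    jitter_sd: float = 0.05,
) -> MethylationProfile:
    """Assign a true methylation level to every cytosine.

    Outside ``dmr_spec`` features, CpG sites get ``base_cg_level`` and
    non-CpG sites ``base_noncg_level``, plus normal jitter (SD
    ``jitter_sd``) clipped to [0, 1].  Inside a listed feature, CpG sites
    take the level that feature's mapping specifies for ``condition``
    (exactly, no jitter); a feature whose mapping omits the condition keeps
    base levels.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    for fid, _levels in dmr_spec:
        genome.feature_by_id(fid)  # KeyError for unknown ids

    rng = np.random.default_rng(seed)
    df = cytosine_sites(genome)
    is_cpg = (df["context"] == "CpG").to_numpy()
    level = np.where(is_cpg, base_cg_level, base_noncg_level)
    level = level + rng.normal(0.0, jitter_sd, size=len(df))
    level = np.clip(level, 0.0, 1.0)

    pos = df["pos"].to_numpy()
    for fid, levels in dmr_spec:
        if condition not in levels:
            continue
        f = genome.feature_by_id(fid)
        mask = (df["chrom"].to_numpy() == f.chrom) & (pos >= f.start) & (pos < f.end) & is_cpg
        level[mask] = float(levels[condition])

    out = df.copy()
    out["true_level"] = level
    return MethylationProfile(condition, out)


# ---------------------------------------------------------------------------
# MspI digestion and size selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def digest_mspi(genome: ReferenceGenome) -> List[Fragment]:
    """In-silico MspI digestion: cut after the first C of every CCGG (C^CGG).

    Overlapping motif occurrences each produce a cut; fragments partition
    each chromosome.
    """
    fragments: List[Fragment] = []
    for chrom, seq in genome.chromosomes.items():
        cuts = [m.start() + 1 for m in re.finditer("(?=CCGG)", seq)]
        bounds = [0] + cuts + [len(seq)]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                fragments.append(Fragment(chrom, a, b))
    return fragments


def size_select(
    fragments: Iterable[Fragment], min_bp: int = 40, max_bp: int = 220
) -> List[Fragment]:
    """Keep fragments with min_bp <= length <= max_bp (bounds inclusive)."""
    if min_bp > max_bp:
        raise ValueError("min_bp must not exceed max_bp")
    return [f for f in fragments if min_bp <= f.length <= max_bp]


# ---------------------------------------------------------------------------
# Bisulfite read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    chrom: str
    start: int  # genomic start of the aligned window (forward coordinates)
    library: str  # OT or OB


@dataclass
class ReadSet:
    reads: List[Read]
    read_length: int

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        from Bio import SeqIO

        reads = []
        maxlen = 0
        for rec in SeqIO.parse(str(path), "fastq"):
            parts = rec.id.split("|")
            if len(parts) == 4:
                _, chrom, start, lib = parts
                reads.append(Read(rec.id, str(rec.seq), chrom, int(start), lib))
            else:
                reads.append(Read(rec.id, str(rec.seq), "", -1, ""))
            maxlen = max(maxlen, len(rec.seq))
        return cls(reads, maxlen)


def simulate_reads(
    fragments: Sequence[Fragment],
    genome: ReferenceGenome,
    profile: MethylationProfile,
    read_length: int = 50,
    mean_depth: float = 30.0,
    conversion_rate: float = 0.995,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Directional single-end bisulfite reads from fragment 5' ends.

    Each fragment yields Poisson(mean_depth) reads from the original-top
    (OT) strand 5' end and the same from the original-bottom (OB) strand.
    A cytosine is read as C with probability
    ``level + (1 - level) * (1 - conversion_rate)`` and as T otherwise;
    independent substitution errors are applied at ``error_rate``.
    """
    if not 0.0 <= conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in [0, 1]")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if fragments and read_length > max(f.length for f in fragments):
        raise ValueError("read_length exceeds the longest fragment")

    rng = np.random.default_rng(seed)
    levels = profile.level_arrays(genome)
    other = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    reads: List[Read] = []
    serial = 0

    for frag in fragments:
        seq = genome.chromosomes[frag.chrom]
        plus, minus = levels[frag.chrom]
        L = min(read_length, frag.length)
        for lib in ("OT", "OB"):
            n = rng.poisson(mean_depth)
            if lib == "OT":
                gstart = frag.start
                template = seq[gstart : gstart + L]
                site_levels = plus[gstart : gstart + L]
                c_char = "C"
            else:
                gstart = frag.end - L
                template = revcomp(seq[gstart : gstart + L])
                # read base i corresponds to genome position gstart + L - 1 - i
                site_levels = minus[gstart : gstart + L][::-1]
                c_char = "C"  # cytosines of the bottom strand appear as C in template
            c_idx = [i for i, b in enumerate(template) if b == c_char]
            p_c = np.array(
                [
                    lv + (1.0 - lv) * (1.0 - conversion_rate)
                    for lv in (site_levels[i] for i in c_idx)
                ]
            )
            for _ in range(n):
                base_list = list(template)
                if c_idx:
                    draws = rng.random(len(c_idx))
                    for j, i in enumerate(c_idx):
                        base_list[i] = "C" if draws[j] < p_c[j] else "T"
                if error_rate > 0:
                    err = rng.random(L) < error_rate
                    for i in np.nonzero(err)[0]:
                        base_list[i] = other[base_list[i]][int(rng.integers(3))]
                serial += 1
                reads.append(
                    Read(
                        f"r{serial:07d}|{frag.chrom}|{gstart}|{lib}",
                        "".join(base_list),
                        frag.chrom,
                        gstart,
                        lib,
                    )
                )
    return ReadSet(reads, read_length)


# ---------------------------------------------------------------------------
# Targeted amplicon and cytometry simulation
# ---------------------------------------------------------------------------


def simulate_amplicon(
    true_levels: Sequence[float],
    n_reads: int,
    seed: int = 0,
    tsdr_cpg_count: Optional[int] = None,
) -> pd.DataFrame:
    """Pyrosequencing-style per-CpG table: binomial sampling of each CpG.

    Returns a DataFrame with columns cpg (1-based index), methylated,
    total, percent.
    """
    if tsdr_cpg_count is not None and len(true_levels) != tsdr_cpg_count:
        raise ValueError("true_levels length must equal tsdr_cpg_count")
    rng = np.random.default_rng(seed)
    lv = np.asarray(true_levels, float)
    if np.any((lv < 0) | (lv > 1)):
        raise ValueError("true levels must lie in [0, 1]")
    meth = rng.binomial(n_reads, lv)
    return pd.DataFrame(
        {
            "cpg": np.arange(1, len(lv) + 1),
            "methylated": meth,
            "total": n_reads,
            "percent": 100.0 * meth / n_reads,
        }
    )


def simulate_suppression_assay(
    true_counts: Mapping[str, int],
    n_standard_added: int,
    cfse_generations: Sequence[float] = (1.0,),
    seed: int = 0,
    cfse_base_intensity: float = 1e4,
    cfse_noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Event-level cytometry table for SCDA counting and CFSE analysis.

    One row per event with role in {gd, cd4, standard}, a viability flag,
    and (for cd4 events) a CFSE intensity that halves per division with
    lognormal measurement noise.  ``cfse_generations`` gives the generation
    distribution of cd4 responders (index 0 = undivided); exactly
    ``n_standard_added`` standard events are emitted.
    """
    for role, cnt in true_counts.items():
        if cnt < 0:
            raise ValueError(f"negative count for role {role!r}")
    if n_standard_added < 0:
        raise ValueError("n_standard_added must be >= 0")
    rng = np.random.default_rng(seed)
    gen_p = np.asarray(cfse_generations, float)
    gen_p = gen_p / gen_p.sum()

    rows = []
    for role in ("gd", "cd4"):
        for _ in range(int(true_counts.get(role, 0))):
            if role == "cd4":
                gen = int(rng.choice(len(gen_p), p=gen_p))
                inten = cfse_base_intensity * 2.0 ** (-gen) * float(
                    np.exp(rng.normal(0.0, cfse_noise_sd))
                )
                rows.append((role, True, inten, gen))
            else:
                rows.append((role, True, np.nan, -1))
    for _ in range(int(n_standard_added)):
        rows.append(("standard", True, np.nan, -1))
    return pd.DataFrame(rows, columns=["role", "viable", "cfse", "generation"])


# ---------------------------------------------------------------------------
# Gene sets and ground-truth manifest
# ---------------------------------------------------------------------------


def host_genes(genome: ReferenceGenome, kinds: Sequence[str] = ("truth_dmr", "tsdr")) -> List[str]:
    """Gene ids whose bodies contain an implanted feature of the given kinds."""
    out = []
    targets = [f for f in genome.features if f.kind in kinds]
    for g in genome.features_of("gene"):
        for t in targets:
            if t.chrom == g.chrom and t.start < g.end and g.start < t.end:
                out.append(g.id)
                break
    return out


def make_gene_sets(
    genome: ReferenceGenome,
    n_sets: int = 10,
    set_size: Tuple[int, int] = (5, 15),
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Synthetic GMT-style gene sets; the first set collects the genes
    hosting implanted differential loci (so that enrichment has signal)."""
    rng = np.random.default_rng(seed)
    genes = [g.id for g in genome.features_of("gene")]
    sets: Dict[str, List[str]] = {}
    hosts = host_genes(genome)
    if hosts:
        sets["implanted_locus_hosts"] = sorted(hosts)
    for i in range(n_sets):
        k = int(rng.integers(set_size[0], set_size[1] + 1))
        k = min(k, len(genes))
        sets[f"random_set_{i + 1:02d}"] = sorted(
            rng.choice(genes, size=k, replace=False).tolist()
        )
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def truth_manifest(
    genome: ReferenceGenome,
    dmr_spec: Sequence[Tuple[str, Mapping[str, float]]],
    seed: int,
    extra: Optional[Mapping] = None,
) -> dict:
    """JSON-serializable record of implanted truth: intervals, per-arm
    levels, and the master seed."""
    regions = []
    spec_map = {fid: dict(levels) for fid, levels in dmr_spec}
    for f in genome.features:
        if f.kind in ("truth_dmr", "tsdr"):
            regions.append(
                {
                    "id": f.id,
                    "kind": f.kind,
                    "chrom": f.chrom,
                    "start": f.start,
                    "end": f.end,
                    "levels": spec_map.get(f.id, {}),
                }
            )
    out = {"seed": seed, "regions": regions}
    if extra:
        out.update(extra)
    return out


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
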
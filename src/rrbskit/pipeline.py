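"""End-to-end reproducible pipeline runs.

A single flat config file (INI sections, no code execution) drives the
whole chain: synthesize genome and per-arm profiles -> simulate RRBS reads
-> place and call methylomes -> sample comparison -> DMR discovery for
[medium] vs [pVC] and [TGF-b] vs [TGF-b + pVC] -> gene annotation and
enrichment -> targeted amplicon and suppression-assay summaries.  A run
manifest records the config hash, seeds and a checksum of every output,
so identical config + seed gives identical manifests.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import annotate as ann
from . import bscore, cytoquant, dmrcall, sampstats, synthio, targeted

logger = logging.getLogger(__name__)

ARMS = list(synthio.CONDITIONS)
COMPARISONS = [("medium", "pVC"), ("TGFb", "TGFb_pVC")]


@dataclass
class RunConfig:
    # run
    seed: int = 1
    # genome
    n_chrom: int = 1
    chrom_length: int = 50_000
    gc_fraction: float = 0.5
    ccgg_boost: float = 3.0
    n_genes: int = 20
    n_truth_dmrs: int = 6
    truth_dmr_cpgs: int = 10
    tsdr_cpgs: int = 7
    # profiles
    base_cg_level: float = 0.8
    base_noncg_level: float = 0.02
    jitter_sd: float = 0.05
    high_level: float = 0.9
    low_level: float = 0.1
    tsdr_methylated_level: float = 0.85
    # reads
    read_length: int = 50
    mean_depth: float = 30.0
    conversion_rate: float = 0.995
    error_rate: float = 0.001
    size_min: int = 40
    size_max: int = 220
    # calling
    min_coverage: int = 1
    max_mismatches: int = 2
    # dmr
    context: str = "CpG"
    min_sites: int = 5
    dmr_min_cov: int = 5
    fold_min: float = 2.0
    p_max: float = 0.05
    hypo_threshold: float = 0.2
    max_gap: int = 500
    # sample comparison
    matrix_min_cov: int = 5
    # annotation
    promoter_up: int = 2000
    promoter_down: int = 500
    n_gene_sets: int = 10
    # amplicon
    amplicon_reads: int = 1000
    # cytometry
    n_standard_added: int = 10_000
    solo_cd4: int = 30_000
    gd_per_condition: int = 20_000
    quotient_gd: float = 0.6
    quotient_gd_pvc: float = 0.25
    divided_fraction_solo: float = 0.74
    divided_fraction_gd: float = 0.59
    divided_fraction_gd_pvc: float = 0.33

    _SECTIONS = {
        "run": ("seed",),
        "genome": ("n_chrom", "chrom_length", "gc_fraction", "ccgg_boost", "n_genes",
                   "n_truth_dmrs", "truth_dmr_cpgs", "tsdr_cpgs"),
        "profiles": ("base_cg_level", "base_noncg_level", "jitter_sd", "high_level",
                     "low_level", "tsdr_methylated_level"),
        "reads": ("read_length", "mean_depth", "conversion_rate", "error_rate",
                  "size_min", "size_max"),
        "calling": ("min_coverage", "max_mismatches"),
        "dmr": ("context", "min_sites", "dmr_min_cov", "fold_min", "p_max",
                "hypo_threshold", "max_gap"),
        "comparison": ("matrix_min_cov",),
        "annotation": ("promoter_up", "promoter_down", "n_gene_sets"),
        "amplicon": ("amplicon_reads",),
        "cytometry": ("n_standard_added", "solo_cd4", "gd_per_condition",
                      "quotient_gd", "quotient_gd_pvc", "divided_fraction_solo",
                      "divided_fraction_gd", "divided_fraction_gd_pvc"),
    }

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {k: repr(getattr(self, k)) for k in keys}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read_string(text)
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for section in cp.sections():
            for key, val in cp[section].items():
                if key not in types:
                    raise ValueError(f"unknown config key {key!r} in [{section}]")
                kind = types[key]
                if kind == "int":
                    kwargs[key] = int(val)
                elif kind == "float":
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val.strip("'\"")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_ini(Path(path).read_text())

    def to_file(self, path) -> None:
        Path(path).write_text(self.to_ini())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_ini().encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_dmr_spec(genome: synthio.ReferenceGenome, cfg: RunConfig):
    """Per-arm levels for implanted regions.

    The TSDR-like locus is methylated in every arm except [TGF-b + pVC];
    the remaining truth regions alternate between responding to pVC alone
    (differential in medium vs pVC) and to pVC under TGF-b (differential
    in TGF-b vs TGF-b + pVC).
    """
    hi, lo = cfg.high_level, cfg.low_level
    spec: List[Tuple[str, Dict[str, float]]] = [
        (
            "tsdr",
            {
                "medium": cfg.tsdr_methylated_level,
                "pVC": cfg.tsdr_methylated_level,
                "TGFb": cfg.tsdr_methylated_level,
                "TGFb_pVC": cfg.low_level,
            },
        )
    ]
    for i, f in enumerate(genome.features_of("truth_dmr")):
        if i % 2 == 0:
            levels = {"medium": hi, "pVC": lo, "TGFb": hi, "TGFb_pVC": hi}
        else:
            levels = {"medium": hi, "pVC": hi, "TGFb": hi, "TGFb_pVC": lo}
        spec.append((f.id, levels))
    return spec


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage, write all outputs under ``outdir``, return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    log_path = out / "run.log"
    t0 = time.time()

    def log(stage: str, msg: str) -> None:
        line = f"[{time.time() - t0:8.2f}s] {stage}: {msg}"
        logger.info(line)
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    outputs: Dict[str, Path] = {}
    stage = "genome"
    try:
        log(stage, f"seed={cfg.seed} parameters={asdict(cfg)}")
        genome = synthio.generate_genome(
            cfg.n_chrom, cfg.chrom_length, cfg.gc_fraction, cfg.ccgg_boost,
            cfg.n_genes, cfg.seed, n_truth_dmrs=cfg.n_truth_dmrs,
            truth_dmr_cpgs=cfg.truth_dmr_cpgs, tsdr_cpgs=cfg.tsdr_cpgs,
        )
        genome.to_fasta(out / "genome.fa")
        genome.features_to_bed(out / "features.bed")
        genome.genes_to_gtf(out / "genes.gtf")
        outputs["genome.fa"] = out / "genome.fa"
        outputs["features.bed"] = out / "features.bed"
        outputs["genes.gtf"] = out / "genes.gtf"

        dmr_spec = build_dmr_spec(genome, cfg)
        manifest_truth = synthio.truth_manifest(genome, dmr_spec, cfg.seed)
        synthio.write_manifest(manifest_truth, out / "truth.json")
        outputs["truth.json"] = out / "truth.json"

        stage = "profiles"
        profiles = {}
        for i, arm in enumerate(ARMS):
            profiles[arm] = synthio.assign_profile(
                genome, arm, cfg.base_cg_level, cfg.base_noncg_level, dmr_spec,
                seed=cfg.seed * 10 + i, jitter_sd=cfg.jitter_sd,
            )
        log(stage, f"{len(profiles['medium'].sites)} cytosines per arm")

        stage = "digestion"
        fragments = synthio.size_select(
            synthio.digest_mspi(genome), cfg.size_min, cfg.size_max
        )
        with open(out / "fragments.bed", "w") as fh:
            for f in fragments:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
        outputs["fragments.bed"] = out / "fragments.bed"
        log(stage, f"{len(fragments)} size-selected fragments")

        stage = "reads"
        tables = {}
        for i, arm in enumerate(ARMS):
            reads = synthio.simulate_reads(
                fragments, genome, profiles[arm], cfg.read_length, cfg.mean_depth,
                cfg.conversion_rate, cfg.error_rate, seed=cfg.seed * 100 + i,
            )
            fq = out / f"reads_{arm}.fastq"
            reads.to_fastq(fq)
            outputs[fq.name] = fq
            stage = f"calling[{arm}]"
            placements, pstats = bscore.place_reads(reads, genome, cfg.max_mismatches)
            table = bscore.call_cytosines(placements, genome, cfg.min_coverage, sample=arm)
            tables[arm] = table
            cx = out / f"methylome_{arm}.tsv"
            table.to_cx(cx)
            outputs[cx.name] = cx
            bg = out / f"levels_{arm}.bedGraph"
            table.to_bedgraph(bg)
            outputs[bg.name] = bg
            log(stage, f"{pstats['placed']} reads placed, {pstats['discarded']} discarded, "
                       f"{len(table.sites)} sites called")
            stage = "reads"

        stage = "comparison"
        matrix = sampstats.build_matrix(
            [tables[a] for a in ARMS], cfg.context, cfg.matrix_min_cov
        )
        matrix.to_tsv(out / "site_matrix.tsv")
        outputs["site_matrix.tsv"] = out / "site_matrix.tsv"
        pearson_matrix = sampstats.pearson_matrix(matrix)
        pearson_matrix.to_csv(out / "pearson.csv")
        outputs["pearson.csv"] = out / "pearson.csv"
        pca = sampstats.pca_samples(matrix)
        pca.to_csv(out / "pca.csv")
        outputs["pca.csv"] = out / "pca.csv"
        summaries = []
        for arm in ARMS:
            s = sampstats.context_feature_summary(tables[arm], genome)
            s.insert(0, "sample", arm)
            summaries.append(s)
        pd.concat(summaries, ignore_index=True).to_csv(
            out / "context_summary.tsv", sep="\t", index=False
        )
        outputs["context_summary.tsv"] = out / "context_summary.tsv"
        log(stage, f"{matrix.levels.shape[0]} shared {cfg.context} sites")

        stage = "dmr"
        params = dmrcall.DMRParams(
            context=cfg.context, min_sites=cfg.min_sites, min_cov=cfg.dmr_min_cov,
            fold_min=cfg.fold_min, p_max=cfg.p_max, hypo_threshold=cfg.hypo_threshold,
            max_gap=cfg.max_gap,
        )
        dmr_results = {}
        gene_sets = synthio.make_gene_sets(genome, cfg.n_gene_sets, seed=cfg.seed)
        synthio.write_gmt(gene_sets, out / "gene_sets.gmt")
        outputs["gene_sets.gmt"] = out / "gene_sets.gmt"
        background = {g.id for g in genome.features_of("gene")}
        for s1, s2 in COMPARISONS:
            name = f"{s1}_vs_{s2}"
            res = dmrcall.call_dmrs(tables[s1], tables[s2], params)
            dmr_results[name] = res
            res.to_bed(out / f"dmrs_{name}.bed")
            res.to_tsv(out / f"dmrs_{name}.tsv")
            outputs[f"dmrs_{name}.bed"] = out / f"dmrs_{name}.bed"
            outputs[f"dmrs_{name}.tsv"] = out / f"dmrs_{name}.tsv"
            log(stage, f"{name}: {len(res.dmrs)} DMRs from {res.n_windows} windows")

            stage = f"annotation[{name}]"
            assignments = ann.assign_regions(
                res.dmrs, genome, cfg.promoter_up, cfg.promoter_down
            )
            with open(out / f"assignments_{name}.tsv", "w") as fh:
                fh.write("dmr_id\tgene_id\trelation\toverlap_bp\n")
                for a in assignments:
                    fh.write(f"{a.dmr_id}\t{a.gene_id}\t{a.relation}\t{a.overlap_bp}\n")
            outputs[f"assignments_{name}.tsv"] = out / f"assignments_{name}.tsv"
            query = ann.assigned_genes(assignments) & background
            if query:
                results = ann.enrich(query, gene_sets, background)
                ann.enrichment_frame(results).to_csv(
                    out / f"enrichment_{name}.tsv", sep="\t", index=False
                )
                outputs[f"enrichment_{name}.tsv"] = out / f"enrichment_{name}.tsv"
            else:
                log(stage, "no DMR-associated genes; enrichment skipped")
            stage = "dmr"

        stage = "amplicon"
        tsdr = genome.feature_by_id("tsdr")
        amps = []
        for i, arm in enumerate(ARMS):
            sub = profiles[arm].sites
            sel = sub[
                (sub["chrom"] == tsdr.chrom) & (sub["pos"] >= tsdr.start)
                & (sub["pos"] < tsdr.end) & (sub["strand"] == "+")
                & (sub["context"] == "CpG")
            ]
            levels = sel["true_level"].to_numpy()[: cfg.tsdr_cpgs]
            tab = synthio.simulate_amplicon(levels, cfg.amplicon_reads, seed=cfg.seed * 7 + i)
            tab.to_csv(out / f"amplicon_{arm}.csv", index=False)
            outputs[f"amplicon_{arm}.csv"] = out / f"amplicon_{arm}.csv"
            amps.append(targeted.summarize_amplicon(tab, sample=arm))
        targeted.color_matrix(amps).to_csv(out / "amplicon_colors.csv")
        outputs["amplicon_colors.csv"] = out / "amplicon_colors.csv"
        with open(out / "amplicon_summary.tsv", "w") as fh:
            fh.write("sample\t" + "\t".join(f"CpG{i+1}" for i in range(cfg.tsdr_cpgs))
                     + "\taverage\n")
            for a in amps:
                fh.write(a.sample + "\t" + "\t".join(f"{p:.2f}" for p in a.percents)
                         + f"\t{a.average:.2f}\n")
        outputs["amplicon_summary.tsv"] = out / "amplicon_summary.tsv"

        stage = "cytometry"

        def gens(frac):
            # dividing cells spread over generations 1-4 with a decaying wave
            return [1 - frac, 0.4 * frac, 0.3 * frac, 0.2 * frac, 0.1 * frac]

        cultures = {
            "solo": (cfg.solo_cd4, cfg.divided_fraction_solo, 1.0),
            "with_gd": (int(round(cfg.solo_cd4 * cfg.quotient_gd)),
                        cfg.divided_fraction_gd, cfg.quotient_gd),
            "with_gd_pvc": (int(round(cfg.solo_cd4 * cfg.quotient_gd_pvc)),
                            cfg.divided_fraction_gd_pvc, cfg.quotient_gd_pvc),
        }
        rows = []
        solo_count = None
        for i, (label, (n_cd4, frac, _)) in enumerate(cultures.items()):
            counts = {"cd4": n_cd4, "gd": 0 if label == "solo" else cfg.gd_per_condition}
            ev = synthio.simulate_suppression_assay(
                counts, cfg.n_standard_added, gens(frac), seed=cfg.seed * 13 + i
            )
            ev.to_csv(out / f"cytometry_{label}.csv", index=False)
            outputs[f"cytometry_{label}.csv"] = out / f"cytometry_{label}.csv"
            count = cytoquant.scda_from_events(ev, "cd4", cfg.n_standard_added)
            if label == "solo":
                solo_count = count
            cfse = ev.loc[ev["role"] == "cd4", "cfse"].to_numpy()
            low = cytoquant.cfse_low_fraction(cfse)
            rows.append((label, count, cytoquant.relative_expansion(count, solo_count), low))
        with open(out / "suppression_summary.tsv", "w") as fh:
            fh.write("culture\tcd4_count\texpansion_quotient\tcfse_low_fraction\n")
            for label, count, quot, low in rows:
                fh.write(f"{label}\t{count:.1f}\t{quot:.4f}\t{low:.4f}\n")
        outputs["suppression_summary.tsv"] = out / "suppression_summary.tsv"
        log(stage, f"suppression summary: {rows}")
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage named
        log(stage, f"FAILED: {exc}")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log("done", f"manifest written with {len(outputs)} outputs")
    return manifest
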
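import numpy as np
import pandas as pd
import pytest

from rrbskit import bscore, synthio


@pytest.fixture(scope="session")
def genome():
    """Small genome with genes, CGIs, three implanted regions and a TSDR."""
    return synthio.generate_genome(
        1, 20_000, 0.5, ccgg_boost=3.0, n_genes=10, seed=7, n_truth_dmrs=3
    )


@pytest.fixture(scope="session")
def dmr_spec(genome):
    spec = [("tsdr", {c: 0.85 for c in synthio.CONDITIONS} | {"TGFb_pVC": 0.1})]
    for f in genome.features_of("truth_dmr"):
        spec.append((f.id, {"medium": 0.9, "pVC": 0.1, "TGFb": 0.9, "TGFb_pVC": 0.9}))
    return spec


@pytest.fixture(scope="session")
def profile_medium(genome, dmr_spec):
    return synthio.assign_profile(genome, "medium", dmr_spec=dmr_spec, seed=31)


@pytest.fixture(scope="session")
def profile_pvc(genome, dmr_spec):
    return synthio.assign_profile(genome, "pVC", dmr_spec=dmr_spec, seed=32)


@pytest.fixture(scope="session")
def fragments(genome):
    return synthio.size_select(synthio.digest_mspi(genome))


@pytest.fixture(scope="session")
def clean_readset(genome, fragments, profile_medium):
    """Error-free, fully converted reads: observed levels are exact binomials."""
    return synthio.simulate_reads(
        fragments, genome, profile_medium, read_length=50, mean_depth=12,
        conversion_rate=1.0, error_rate=0.0, seed=41,
    )


@pytest.fixture(scope="session")
def clean_placements(genome, clean_readset):
    placements, stats = bscore.place_reads(clean_readset, genome)
    return placements, stats


@pytest.fixture(scope="session")
def clean_table(genome, clean_placements):
    placements, _ = clean_placements
    return bscore.call_cytosines(placements, genome, sample="medium")


def make_table(sample, rows):
    """MethylomeTable from (chrom, pos, strand, context, mc, uc) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "mc", "uc"])
    df["level"] = df["mc"] / (df["mc"] + df["uc"])
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return bscore.MethylomeTable(sample, df)


def cpg_run(sample, counts, start=100, step=20, chrom="chr1"):
    """Evenly spaced CpG sites from (mc, uc) pairs."""
    rows = [
        (chrom, start + i * step, "+", "CpG", mc, uc) for i, (mc, uc) in enumerate(counts)
    ]
    return make_table(sample, rows)
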
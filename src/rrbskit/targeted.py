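"""Targeted-amplicon (TSDR-style) methylation summaries.

Pyrosequencing-like per-CpG tables are reduced to per-CpG percentages and
a per-sample average over the assay's CpGs (7 for the TSDR amplicon), and
percentages are rendered with the yellow (0%) -> green (50%) -> blue
(100%) colour code used for TSDR methylation heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

YELLOW = (255, 255, 0)
GREEN = (0, 128, 0)
BLUE = (0, 0, 255)


@dataclass
class AmpliconMethylation:
    sample: str
    percents: List[float]  # ordered per-CpG percentages; NaN = no observations

    @property
    def average(self) -> float:
        vals = [p for p in self.percents if not np.isnan(p)]
        return float(np.mean(vals)) if vals else float("nan")


def summarize_amplicon(table: pd.DataFrame, sample: str = "sample") -> AmpliconMethylation:
    """Per-CpG percent methylation from a counts table.

    Accepts either columns (cpg, methylated, total) or (cpg, percent).  A
    CpG with zero observations is reported as NaN and excluded from the
    average, with a warning.
    """
    df = table.sort_values("cpg")
    if {"methylated", "total"} <= set(df.columns):
        percents = []
        for row in df.itertuples(index=False):
            if row.total == 0:
                warnings.warn(f"CpG {row.cpg} has zero observations; excluded from average")
                percents.append(float("nan"))
            else:
                percents.append(100.0 * row.methylated / row.total)
    elif "percent" in df.columns:
        percents = [float(p) for p in df["percent"]]
    else:
        raise ValueError("table needs (cpg, methylated, total) or (cpg, percent) columns")
    return AmpliconMethylation(sample, percents)


def heatmap_color(percent: float) -> Tuple[int, int, int]:
    """Yellow -> green -> blue piecewise-linear colour code.

    0% maps to yellow (255, 255, 0), 50% to green (0, 128, 0) and 100% to
    blue (0, 0, 255); intermediate values interpolate linearly on each
    segment.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    if percent <= 50.0:
        t = percent / 50.0
        a, b = YELLOW, GREEN
    else:
        t = (percent - 50.0) / 50.0
        a, b = GREEN, BLUE
    return tuple(int(round(a[i] + t * (b[i] - a[i]))) for i in range(3))


def color_matrix(samples: Sequence[AmpliconMethylation]) -> pd.DataFrame:
    """RGB hex code per CpG (rows) and sample (columns)."""
    data = {}
    for s in samples:
        data[s.sample] = [
            "#{:02x}{:02x}{:02x}".format(*heatmap_color(p)) if not np.isnan(p) else ""
            for p in s.percents
        ]
    n = max(len(s.percents) for s in samples)
    return pd.DataFrame(data, index=[f"CpG{i + 1}" for i in range(n)])


def compare_groups(
    groups: Mapping[str, Sequence[AmpliconMethylation]]
) -> pd.DataFrame:
    """Mean +/- SD of the per-sample average percent for each group.

    SD uses n-1 degrees of freedom and is NaN (undefined) for single-sample
    groups; no inferential statistics are computed.
    """
    rows = []
    for label, samples in groups.items():
        if not samples:
            raise ValueError(f"group {label!r} has no samples")
        avgs = np.array([s.average for s in samples], float)
        sd = float(np.std(avgs, ddof=1)) if len(avgs) > 1 else float("nan")
        rows.append((label, len(avgs), float(np.mean(avgs)), sd))
    return pd.DataFrame(rows, columns=["group", "n", "mean_percent", "sd_percent"])


# alias matching the figure the comparison reproduces (sorted FOXP3+/- fractions)
compare_sorted_fractions = compare_groups


def plot_heatmap(samples: Sequence[AmpliconMethylation], path) -> None:
    """SVG heatmap of per-CpG percentages in the yellow/green/blue code."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_cpg = max(len(s.percents) for s in samples)
    img = np.ones((n_cpg, len(samples), 3))
    for j, s in enumerate(samples):
        for i, p in enumerate(s.percents):
            if not np.isnan(p):
                img[i, j] = [c / 255.0 for c in heatmap_color(p)]
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(samples), 1 + 0.4 * n_cpg))
    ax.imshow(img, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(len(samples)), [s.sample for s in samples], rotation=45, ha="right")
    ax.set_yticks(range(n_cpg), [f"CpG{i + 1}" for i in range(n_cpg)])
    ax.set_title("Amplicon methylation (%)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
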
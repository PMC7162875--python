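"""Suppression-assay quantification.

Absolute viable-cell counts via the standard cell dilution assay (SCDA) —
the ratio of target events to spiked-in standard-cell events times the
known number of standard cells added — relative expansion quotients
normalised to the solo-cultured responder condition, and the proliferating
(CFSE-low) fraction of responder T cells with an automatic
histogram-valley threshold.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd


def ug_per_ml_to_micromolar(ug_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration to micromolar.

    ug/mL equals mg/L, so concentration [uM] = 1000 * (mg/L) / (g/mol).
    Used for reagent bookkeeping, e.g. 50 ug/mL of phospho-ascorbate
    (289.54 g/mol anhydrous) ~= 173 uM.
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be positive")
    return 1000.0 * ug_per_ml / molar_mass_g_per_mol


def scda_count(events_target: int, events_standard: int, n_standard_added: int) -> float:
    """Absolute viable-cell count = (target / standard events) x standards added."""
    if events_standard <= 0:
        raise ValueError("no standard-cell events acquired; count undefined")
    if events_target < 0 or n_standard_added < 0:
        raise ValueError("counts must be non-negative")
    return events_target / events_standard * n_standard_added


def scda_from_events(
    events: pd.DataFrame,
    target_role: str,
    n_standard_added: int,
    viable_only: bool = True,
) -> float:
    """SCDA count from an event table with role and viability columns."""
    df = events
    if viable_only and "viable" in df.columns:
        df = df[df["viable"].astype(bool) | (df["role"] == "standard")]
    n_std = int((df["role"] == "standard").sum())
    n_tgt = int((df["role"] == target_role).sum())
    return scda_count(n_tgt, n_std, n_standard_added)


def relative_expansion(count_condition: float, count_solo: float) -> float:
    """Expansion quotient versus the solo-cultured responder (solo = 1.0)."""
    if count_solo <= 0:
        raise ValueError("solo-culture count must be positive")
    return count_condition / count_solo


def cfse_threshold(intensities: np.ndarray, min_mode_separation: float = 0.5) -> float:
    """Automatic CFSE-low threshold: smoothed-histogram valley.

    Works on log2 intensity (CFSE halves per division, i.e. modes sit one
    log2 unit apart).  Bin width follows Freedman-Diaconis; the histogram
    is smoothed with a short moving average and the threshold is placed at
    the minimum between the two largest modes.  The two modes must be at
    least ``min_mode_separation`` log2 units apart so that noise wiggles
    within one generation cluster are not mistaken for separate modes.
    """
    x = np.log2(intensities[intensities > 0])
    if len(x) < 10:
        raise ValueError("too few positive events for automatic thresholding")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    width = 2 * iqr / len(x) ** (1 / 3) if iqr > 0 else 0.1
    width = max(width, 1e-3)
    nbins = max(10, int(np.ceil((x.max() - x.min()) / width)))
    counts, edges = np.histogram(x, bins=nbins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts, kernel, mode="same")
    # local maxima of the smoothed histogram
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0
    ]
    if len(peaks) < 2:
        raise ValueError("could not locate two CFSE modes for automatic thresholding")
    p1 = max(peaks, key=lambda i: smooth[i])
    far = [i for i in peaks if abs(centres[i] - centres[p1]) >= min_mode_separation]
    if not far:
        raise ValueError("could not locate two separated CFSE modes")
    p2 = max(far, key=lambda i: smooth[i])
    lo, hi = sorted((p1, p2))
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    return float(2.0 ** centres[valley])


def cfse_low_fraction(
    intensities: Sequence[float], threshold: Optional[float] = None
) -> float:
    """Fraction of events below the CFSE threshold (proliferating cells).

    ``threshold=None`` selects the automatic histogram-valley threshold.
    """
    x = np.asarray(intensities, float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("no CFSE events")
    if threshold is None:
        threshold = cfse_threshold(x)
    return float((x < threshold).mean())
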
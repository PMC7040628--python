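"""Phenology metrics from fitted curves: onset, cessation, modality.

Onset and cessation of a differentiation phase are read from the fitted
count curve as threshold crossings (default half a cell: the first time the
smoothed mean supports at least one cell being present on average).  The
uni/bimodal character of a curve — the facultative second growth period of
Mediterranean conifers — is operationalized by peak prominence and
separation rather than by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .smoothing import FittedPhaseCurve

__all__ = [
    "PhenologyMetrics",
    "phase_window",
    "classify_modality",
    "phenology_metrics",
    "phenology_to_frame",
]


@dataclass(frozen=True)
class PhenologyMetrics:
    group: str
    phase: str
    onset_day: float  # NaN when the phase never becomes active
    cessation_day: float
    duration: float
    modality: str  # "unimodal" | "bimodal"
    peak_days: tuple = field(default_factory=tuple)


def phase_window(
    curve: FittedPhaseCurve, threshold: float = 0.5
) -> tuple[float, float]:
    """Onset (first up-crossing) and cessation (last down-crossing) of the
    threshold, linearly interpolated; NaN pair when the curve never reaches
    the threshold.  A curve already above threshold at the grid start (or
    still above at the end) uses the boundary day."""
    y = np.maximum(np.asarray(curve.mean, dtype=float), 0.0)
    t = np.asarray(curve.grid, dtype=float)
    above = y >= threshold
    if not above.any():
        return float("nan"), float("nan")
    first = int(np.argmax(above))
    last = int(len(above) - 1 - np.argmax(above[::-1]))
    if first == 0:
        onset = float(t[0])
    else:
        y0, y1 = y[first - 1], y[first]
        onset = float(t[first - 1] + (threshold - y0) / (y1 - y0) * (t[first] - t[first - 1]))
    if last == len(t) - 1:
        cessation = float(t[-1])
    else:
        y0, y1 = y[last], y[last + 1]
        cessation = float(t[last] + (y0 - threshold) / (y0 - y1) * (t[last + 1] - t[last]))
    return onset, cessation


def classify_modality(
    grid: np.ndarray,
    values: np.ndarray,
    min_prominence: float = 0.2,
    min_separation: float = 60.0,
) -> tuple[str, tuple]:
    """Unimodal/bimodal classification of a rate or count curve.

    Local maxima qualify as peaks when their prominence is at least
    ``min_prominence`` times the global maximum and they are at least
    ``min_separation`` grid units apart; two or more qualifying peaks make
    the curve bimodal.  At most the two highest peaks are reported.  A flat
    (all-zero) curve is unimodal with no peaks.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(grid, dtype=float)
    ymax = float(np.max(y)) if y.size else 0.0
    if ymax <= 0:
        return "unimodal", ()
    step = float(np.median(np.diff(t)))
    distance = max(1, int(round(min_separation / step)))
    # pad so boundary maxima (a season already rising at the grid edge)
    # register as peaks
    ypad = np.concatenate([[y[0] - 1e-12], y, [y[-1] - 1e-12]])
    idx, props = find_peaks(
        ypad, prominence=min_prominence * ymax, distance=distance
    )
    idx = idx - 1
    idx = idx[(idx >= 0) & (idx < y.size)]
    if idx.size == 0:
        peak_days = (float(t[np.argmax(y)]),)
        return "unimodal", peak_days
    order = np.argsort(y[idx])[::-1][:2]
    top = np.sort(idx[order])
    peak_days = tuple(float(t[i]) for i in top)
    modality = "bimodal" if idx.size >= 2 else "unimodal"
    return modality, peak_days


def phenology_metrics(
    curve: FittedPhaseCurve,
    threshold: float = 0.5,
    min_prominence: float = 0.2,
    min_separation: float = 60.0,
) -> PhenologyMetrics:
    """Full phenology record for one fitted group x phase curve."""
    onset, cess = phase_window(curve, threshold)
    modality, peaks = classify_modality(
        curve.grid, np.maximum(curve.mean, 0.0), min_prominence, min_separation
    )
    return PhenologyMetrics(
        group=curve.group,
        phase=curve.phase,
        onset_day=onset,
        cessation_day=cess,
        duration=cess - onset,
        modality=modality,
        peak_days=peaks,
    )


def phenology_to_frame(metrics: list[PhenologyMetrics]) -> pd.DataFrame:
    rows = [
        (
            m.group,
            m.phase,
            m.onset_day,
            m.cessation_day,
            m.duration,
            m.modality,
            ";".join(f"{d:.2f}" for d in m.peak_days),
        )
        for m in metrics
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "phase",
            "onset",
            "cessation",
            "duration",
            "modality",
            "peak_days",
        ],
    )
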
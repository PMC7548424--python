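"""P1 wave feature extraction and the mean-posterior-P1 (MPP1) biomarker.

Latency is measured per participant at the posterior electrode carrying the
highest P1 peak in 100-200 ms; amplitude features for classification use a
fixed 120-170 ms window so that participants with a numerically absent P1
still receive a feature vector. Per-electrode windowed means are
standardized across the full montage (topography-preserving amplitude
normalization, which cancels age-related gain), and MPP1 is the mean of the
13 posterior z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import VERP
from .montage import Montage

__all__ = [
    "PeakResult",
    "P1Features",
    "find_largest_peak",
    "individual_p1_latency",
    "windowed_mean",
    "has_p1",
    "group_mean_latency",
    "fixed_window_features",
    "normalize_topography",
    "compute_mpp1",
    "extract_features",
    "features_table",
]

PEAK_WINDOW_MS = (100.0, 200.0)
FIXED_WINDOW_MS = (120.0, 170.0)
WINDOW_HALFWIDTH_MS = 25.0


@dataclass(frozen=True)
class PeakResult:
    electrode: str
    latency_ms: Optional[float]
    amplitude_uv: Optional[float]
    found: bool


@dataclass
class P1Features:
    """Per-participant, per-condition feature bundle."""

    pid: str
    condition: str
    electrode_means_uv: np.ndarray  # (n_electrodes,) fixed-window means
    z_scores: np.ndarray  # (n_electrodes,) standardized across montage
    mpp1: float
    latency_ms: Optional[float] = None  # individual P1 latency, may be absent
    latency_electrode: Optional[str] = None


def find_largest_peak(
    verp: VERP, electrode: str, window_ms: tuple = PEAK_WINDOW_MS
) -> PeakResult:
    """Largest strict local maximum of one electrode's waveform in a window.

    Candidates are samples strictly inside the window that exceed both
    neighbouring samples; window endpoints are never eligible. Ties are
    broken in favour of the earlier latency. ``found=False`` when no
    interior local maximum exists (e.g. a monotone ramp).
    """
    lo, hi = window_ms
    if lo < verp.times[0] or hi > verp.times[-1]:
        raise ValueError("peak window lies outside the epoch")
    idx = verp.time_indices(lo, hi)
    if idx.size < 3:
        return PeakResult(electrode, None, None, False)
    x = verp.electrode(electrode)
    interior = idx[1:-1]
    is_peak = (x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])
    candidates = interior[is_peak]
    if candidates.size == 0:
        return PeakResult(electrode, None, None, False)
    amps = x[candidates]
    best = candidates[np.argmax(amps)]  # argmax takes first of equals: earliest
    return PeakResult(electrode, float(verp.times[best]), float(x[best]), True)


def individual_p1_latency(
    verp: VERP, montage: Montage, window_ms: tuple = PEAK_WINDOW_MS
) -> tuple[Optional[float], Optional[str]]:
    """Latency at the posterior electrode with the globally highest P1 peak.

    Returns ``(None, None)`` when no posterior electrode shows a peak.
    """
    best: Optional[PeakResult] = None
    for name in montage.posterior:
        peak = find_largest_peak(verp, name, window_ms)
        if not peak.found:
            continue
        if best is None or peak.amplitude_uv > best.amplitude_uv:
            best = peak
    if best is None:
        return None, None
    return best.latency_ms, best.electrode


def windowed_mean(
    verp: VERP, center_ms: float, halfwidth_ms: float = WINDOW_HALFWIDTH_MS
) -> np.ndarray:
    """Per-electrode mean over [center - halfwidth, center + halfwidth], inclusive."""
    lo, hi = center_ms - halfwidth_ms, center_ms + halfwidth_ms
    if lo < verp.times[0] or hi > verp.times[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] ms clipped by epoch "
            f"[{verp.times[0]}, {verp.times[-1]}] ms"
        )
    idx = verp.time_indices(lo, hi)
    return verp.data[:, idx].mean(axis=1)


def has_p1(
    verp_upper: VERP,
    verp_lower: VERP,
    latency_upper: Optional[float],
    latency_lower: Optional[float],
    montage: Montage,
    latency_electrode_upper: Optional[str] = None,
    latency_electrode_lower: Optional[str] = None,
) -> bool:
    """False when the individually-centred windowed mean is negative for BOTH fields.

    Participants without a P1 are excluded from latency statistics only;
    they always keep a (fixed-window) feature vector for classification. A
    condition with no detectable peak counts as a negative-amplitude
    condition.
    """

    def _mean_at(verp, latency, electrode) -> Optional[float]:
        if latency is None:
            return None
        if electrode is None:
            _, electrode = individual_p1_latency(verp, montage)
            if electrode is None:
                return None
        means = windowed_mean(verp, latency)
        return float(means[montage.index(electrode)])

    upper = _mean_at(verp_upper, latency_upper, latency_electrode_upper)
    lower = _mean_at(verp_lower, latency_lower, latency_electrode_lower)
    upper_negative = upper is None or upper < 0
    lower_negative = lower is None or lower < 0
    return not (upper_negative and lower_negative)


def group_mean_latency(table: pd.DataFrame) -> tuple[pd.Series, float]:
    """Mean P1 latency per (group, condition) cell plus the grand mean.

    Expects a tidy table with ``group``, ``condition`` and ``latency_ms``
    columns; rows with missing latency (absent P1) are ignored. Raises on
    an empty cell.
    """
    valid = table.dropna(subset=["latency_ms"])
    cells = valid.groupby(["group", "condition"])["latency_ms"].mean()
    expected = table.groupby(["group", "condition"]).ngroups
    if len(cells) < expected:
        raise ValueError("a group/condition cell has no measurable latency")
    return cells, float(cells.mean())


def fixed_window_features(
    verp: VERP, window_ms: tuple = FIXED_WINDOW_MS
) -> np.ndarray:
    """Per-electrode means in the fixed P1 window (used for all participants)."""
    lo, hi = window_ms
    center = (lo + hi) / 2.0
    return windowed_mean(verp, center, halfwidth_ms=(hi - lo) / 2.0)


def normalize_topography(means: np.ndarray) -> np.ndarray:
    """Standard scores across electrodes: z = (m - mean) / SD (ddof=1).

    Invariant under any positive affine transform of the input, which is
    exactly why it removes age-dependent amplitude scaling.
    """
    means = np.asarray(means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 electrodes to standardize")
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across electrodes: cannot standardize")
    return (means - means.mean()) / sd


def compute_mpp1(z_scores: np.ndarray, montage: Montage) -> float:
    """Mean of the 13 posterior z-scores (uniform 1/13 weighting)."""
    z_scores = np.asarray(z_scores, dtype=float)
    return float(z_scores[montage.posterior_indices].mean())


def extract_features(
    verp: VERP, montage: Montage, window_ms: tuple = FIXED_WINDOW_MS
) -> P1Features:
    """Fixed-window amplitude features, z-topography and MPP1 for one VERP."""
    means = fixed_window_features(verp, window_ms)
    z = normalize_topography(means)
    latency, electrode = individual_p1_latency(verp, montage)
    return P1Features(
        pid=verp.pid,
        condition=verp.condition,
        electrode_means_uv=means,
        z_scores=z,
        mpp1=compute_mpp1(z, montage),
        latency_ms=latency,
        latency_electrode=electrode,
    )


def features_table(
    features: Sequence[P1Features], groups: Sequence[str], montage: Montage
) -> pd.DataFrame:
    """Tidy per-participant table: id, group, condition, latency, MPP1, z columns."""
    rows = []
    for feat, group in zip(features, groups):
        row = {
            "pid": feat.pid,
            "group": group,
            "condition": feat.condition,
            "latency_ms": feat.latency_ms,
            "mpp1": feat.mpp1,
        }
        for name, z in zip(montage.names, feat.z_scores):
            row[f"z_{name}"] = z
        rows.append(row)
    return pd.DataFrame(rows)
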
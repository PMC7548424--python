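"""Epoch-level preprocessing: reference, filtering, rejection, mirroring, averaging.

The canonical order is: average reference -> low-pass (optionally notch) ->
ocular-component rejection -> response rejection -> left-field mirror swap ->
per-condition averaging. Every operation is pure: inputs are left untouched
and a new :class:`~verpmark.data.EpochSet` (or VERP) is returned.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import signal

from .data import EpochSet, OcularComponents, VERP
from .montage import Montage

logger = logging.getLogger(__name__)

__all__ = [
    "average_reference",
    "filter_epochs",
    "detect_ocular_rejections",
    "reject_response_epochs",
    "mirror_swap_left_field",
    "average_verp",
    "preprocess_epochs",
]


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean across electrodes.

    After the operation the electrode mean at every trial/time point is zero
    (to float precision). Idempotent.
    """
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference requires at least 2 electrodes")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(data)


def filter_epochs(
    epochs: EpochSet,
    lowpass_hz: float = 40.0,
    notch_hz: float = 50.0,
    apply_notch: bool = False,
    order: int = 4,
    notch_q: float = 12.0,
) -> EpochSet:
    """Zero-phase Butterworth low-pass, optional notch at line harmonics.

    Forward-backward filtering (``filtfilt``) keeps component latencies
    unshifted, which matters because peak latency is a downstream measurand.
    """
    nyquist = epochs.sfreq / 2.0
    if lowpass_hz >= nyquist:
        raise ValueError(
            f"low-pass cutoff {lowpass_hz} Hz is at/above Nyquist {nyquist} Hz"
        )
    data = epochs.data
    if apply_notch:
        for harmonic in np.arange(notch_hz, nyquist, notch_hz):
            b, a = signal.iirnotch(harmonic, Q=notch_q, fs=epochs.sfreq)
            data = signal.filtfilt(b, a, data, axis=-1)
    sos = signal.butter(order, lowpass_hz, btype="low", fs=epochs.sfreq,
                        output="sos")
    data = signal.sosfiltfilt(sos, data, axis=-1)
    return epochs.with_data(data)


def detect_ocular_rejections(
    ocular: OcularComponents,
    montage: Montage,
    window_ms: tuple = (-25.0, 175.0),
    blink_k: float = 5.0,
    eye_k: float = 3.0,
) -> np.ndarray:
    """Keep-mask from thresholded ocular component signals.

    For blinks the separated source is projected onto FP1/FP2, for eye
    movements onto F9/F10. The per-channel SD is taken over all trials and
    time points (trial-concatenated support); the rejection threshold is
    ``k`` times the larger of the two channel SDs. A trial is rejected when
    the projected signal's absolute value exceeds the threshold anywhere
    inside the window (bounds inclusive). Missing components yield an
    all-keep mask with a warning.
    """
    lo, hi = window_ms
    in_window = (ocular.times >= lo) & (ocular.times <= hi)

    def _mask_for(which: str, channels: tuple, k: float) -> Optional[np.ndarray]:
        source = getattr(ocular, which)
        topo = getattr(ocular, f"{which}_topo")
        if source is None or topo is None:
            logger.warning(
                "%s component missing: no trials rejected for it", which
            )
            return None
        projections = [topo[montage.index(ch)] * source for ch in channels]
        threshold = k * max(float(p.std()) for p in projections)
        if threshold == 0.0:
            return None
        exceeded = np.zeros(source.shape[0], dtype=bool)
        for proj in projections:
            exceeded |= (np.abs(proj[:, in_window]) > threshold).any(axis=1)
        return ~exceeded

    n_trials = None
    for which in ("blink", "saccade"):
        src = getattr(ocular, which)
        if src is not None:
            n_trials = src.shape[0]
            break
    if n_trials is None:
        logger.warning("no ocular components provided: keeping all trials")
        return np.ones(0, dtype=bool)

    keep = np.ones(n_trials, dtype=bool)
    blink_keep = _mask_for("blink", ("FP1", "FP2"), blink_k)
    eye_keep = _mask_for("saccade", ("F9", "F10"), eye_k)
    if blink_keep is not None:
        keep &= blink_keep
    if eye_keep is not None:
        keep &= eye_keep
    return keep


def reject_response_epochs(epochs: EpochSet, window_ms: float = 500.0,
                           responds_manually: bool = True) -> EpochSet:
    """Mask out trials with a button response within ``window_ms`` of onset.

    Applies only to participants who operated the response device
    themselves; passive observers pass through unchanged.
    """
    out = epochs.copy()
    if not responds_manually:
        return out
    rt = epochs.events["response_ms"].to_numpy(dtype=float)
    early = np.isfinite(rt) & (rt > 0) & (rt <= window_ms)
    out.keep = out.keep & ~early
    return out


def mirror_swap_left_field(epochs: EpochSet, montage: Montage) -> EpochSet:
    """Exchange mirror-electrode data for left-visual-field trials.

    Midline electrodes map to themselves; right-field trials are untouched.
    Applying the operation twice restores the original epochs.
    """
    perm = montage.mirror_permutation()
    out = epochs.copy()
    left = (epochs.events["side"] == "left").to_numpy()
    out.data[left] = out.data[left][:, perm, :]
    return out


def average_verp(epochs: EpochSet, condition: str) -> VERP:
    """Pointwise mean over kept trials of one visual-field condition."""
    if condition not in ("upper", "lower"):
        raise ValueError(f"unknown condition {condition!r}")
    sel = epochs.keep & (epochs.events["field"] == condition).to_numpy()
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"no kept trials for participant {epochs.pid!r}, "
            f"condition {condition!r}"
        )
    return VERP(
        data=epochs.data[sel].mean(axis=0),
        times=epochs.times,
        condition=condition,
        n_trials=n,
        montage=epochs.montage,
        pid=epochs.pid,
    )


def preprocess_epochs(
    epochs: EpochSet,
    ocular: Optional[OcularComponents] = None,
    responds_manually: bool = True,
    lowpass_hz: float = 40.0,
    apply_notch: bool = False,
    notch_hz: float = 50.0,
    ocular_window_ms: tuple = (-25.0, 175.0),
    blink_k: float = 5.0,
    eye_k: float = 3.0,
    response_window_ms: float = 500.0,
) -> tuple[VERP, VERP, dict]:
    """Run the full per-participant pipeline; returns (upper, lower, counts)."""
    montage = epochs.montage
    out = average_reference(epochs)
    out = filter_epochs(out, lowpass_hz=lowpass_hz, notch_hz=notch_hz,
                        apply_notch=apply_notch)
    counts = {"total": out.n_trials}
    if ocular is not None:
        keep = detect_ocular_rejections(
            ocular, montage, window_ms=ocular_window_ms,
            blink_k=blink_k, eye_k=eye_k,
        )
        out.keep = out.keep & keep
    counts["after_ocular"] = int(out.keep.sum())
    out = reject_response_epochs(out, window_ms=response_window_ms,
                                 responds_manually=responds_manually)
    counts["after_response"] = int(out.keep.sum())
    out = mirror_swap_left_field(out, montage)
    verp_upper = average_verp(out, "upper")
    verp_lower = average_verp(out, "lower")
    counts["kept_upper"] = verp_upper.n_trials
    counts["kept_lower"] = verp_lower.n_trials
    logger.info(
        "participant %s: %d/%d trials kept (upper %d, lower %d)",
        epochs.pid, counts["after_response"], counts["total"],
        counts["kept_upper"], counts["kept_lower"],
    )
    return verp_upper, verp_lower, counts
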
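"""Seeded synthetic EEG cohort generation.

Builds multi-trial epoched EEG for three participant groups (CC / DC /
Control) with the statistical structure the downstream biomarker pipeline
assumes: a posterior-positive P1 deflection (~145 ms) that is attenuated in
the CC group (including a subgroup with a numerically absent P1), an
earlier C1 whose polarity inverts between upper and lower visual field, a
later N1, age-dependent overall amplitude scaling, alpha oscillations, 1/f
background noise, and blink / saccade artifact projections whose
ground-truth source time courses are returned alongside the epochs.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning (one child per participant, one grandchild per noise source).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import EpochSet, OcularComponents, ParticipantMeta
from .montage import Montage, standard_montage

__all__ = [
    "ERPComponentSpec",
    "ArtifactSpec",
    "CohortDesign",
    "default_components",
    "default_artifacts",
    "simulate_participant",
    "simulate_cohort",
    "exp1_design",
    "exp2_design",
    "fast_design",
    "age_amplitude_scale",
]

#: Overall VERP amplitude multiplier as a function of age. Children show
#: considerably larger amplitudes than adults; only monotone decrease
#: matters downstream because topography normalization cancels any
#: participant-level gain. scale(7 y) ~ 1.58, scale(38 y) ~ 0.75.
AGE_SCALE_NUMERATOR_YEARS = 30.0


def age_amplitude_scale(age_years: float) -> float:
    return AGE_SCALE_NUMERATOR_YEARS / (age_years + 12.0)


def gaussian_topography(
    montage: Montage, center: Sequence[float], sigma: float
) -> np.ndarray:
    """Scalp weight map decaying with chord distance from ``center``."""
    center = np.asarray(center, dtype=float)
    center = center / np.linalg.norm(center)
    d = np.linalg.norm(montage.positions - center, axis=1)
    topo = np.exp(-(d**2) / (2.0 * sigma**2))
    return topo / topo.max()


@dataclass(frozen=True)
class ERPComponentSpec:
    """One evoked deflection: Gaussian pulse in time, fixed scalp map."""

    name: str
    latency_ms: float
    jitter_sd_ms: float
    amp_upper_uv: float
    amp_lower_uv: float
    width_ms: float  # temporal Gaussian SD
    topography: np.ndarray  # (n_electrodes,)
    group_scale: dict = field(default_factory=dict)  # multiplier per group
    attenuable: bool = False  # participant-level P1 attenuation applies
    polarity_flips_by_field: bool = False
    ipsilateral_bias: float = 0.0  # fractional boost ipsilateral to stimulus

    def __post_init__(self) -> None:
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter SD must be >= 0")
        if not np.all(np.isfinite(self.topography)):
            raise ValueError("topography must be finite")
        if any(v < 0 for v in self.group_scale.values()):
            raise ValueError("group attenuation factors must be >= 0")

    def amplitude(self, fld: str) -> float:
        return self.amp_upper_uv if fld == "upper" else self.amp_lower_uv


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates/amplitudes for ocular artifacts and background activity."""

    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 120.0
    saccade_rate_per_min: float = 8.0
    saccade_amplitude_uv: float = 35.0
    alpha_amplitude_uv: float = 3.0
    alpha_freq_hz: float = 10.0
    noise_scale_uv: float = 3.0  # per-channel 1/f RMS

    def __post_init__(self) -> None:
        for name in ("blink_rate_per_min", "saccade_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("blink_amplitude_uv", "saccade_amplitude_uv",
                     "alpha_amplitude_uv", "noise_scale_uv"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout plus acquisition and attenuation parameters.

    ``absent_p1_count`` CC participants receive near-zero P1 attenuation
    (the numerically-absent-P1 subgroup); the remaining CC draw their
    attenuation from a truncated normal with the stated mean/SD, clipped
    to [0.02, 0.95]. The defaults were calibrated by simulation so the
    cohort-level standardized CC deficit on MPP1 is ~= -1.46.
    """

    n_cc: int = 13
    n_dc: int = 13
    n_control: int = 26
    trials_per_condition: int = 145
    sfreq: float = 250.0
    tmin_ms: float = -1000.0
    tmax_ms: float = 1000.0
    age_range_years: tuple = (7.0, 38.0)
    absent_p1_count: int = 5
    attenuation_mean: float = 0.52
    attenuation_sd: float = 0.13
    target_rate: float = 0.2
    label: str = "cohort"

    def __post_init__(self) -> None:
        if min(self.n_cc, self.n_dc, self.n_control) < 0:
            raise ValueError("group counts must be >= 0")
        if self.trials_per_condition < 21:
            raise ValueError("trials per condition must be >= 21")
        if self.sfreq <= 80.0:
            raise ValueError("sampling rate must exceed 80 Hz")
        if not (self.tmin_ms <= 0.0 < self.tmax_ms):
            raise ValueError("epoch must span stimulus onset")

    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        lo = int(round(self.tmin_ms / step))
        hi = int(round(self.tmax_ms / step))
        return np.arange(lo, hi + 1) * step


def default_components(montage: Montage) -> list[ERPComponentSpec]:
    """C1 / P1 / N1 with qualitatively realistic posterior topographies."""
    occipital = gaussian_topography(montage, (0.0, -0.95, 0.1), 0.55)
    parieto_occipital = gaussian_topography(montage, (0.0, -0.80, 0.45), 0.85)
    parietal = gaussian_topography(montage, (0.0, -0.70, 0.55), 0.80)
    return [
        ERPComponentSpec(
            name="C1", latency_ms=80.0, jitter_sd_ms=4.0,
            amp_upper_uv=-1.5, amp_lower_uv=1.5, width_ms=12.0,
            topography=occipital, polarity_flips_by_field=True,
        ),
        ERPComponentSpec(
            name="P1", latency_ms=145.0, jitter_sd_ms=8.0,
            amp_upper_uv=6.0, amp_lower_uv=4.0, width_ms=20.0,
            topography=parieto_occipital, attenuable=True,
            ipsilateral_bias=0.25,
        ),
        ERPComponentSpec(
            name="N1", latency_ms=195.0, jitter_sd_ms=8.0,
            amp_upper_uv=-3.0, amp_lower_uv=-2.5, width_ms=22.0,
            topography=parietal,
        ),
    ]


def default_artifacts() -> ArtifactSpec:
    return ArtifactSpec()


def _pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float,
                scale_uv: float) -> np.ndarray:
    """1/f-amplitude noise along the last axis, per-channel RMS = scale."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n, axis=-1)
    rms = np.sqrt(np.mean(pink**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return pink / rms * scale_uv


def _event_pulses(rng: np.random.Generator, times: np.ndarray,
                  rate_per_min: float, width_ms: float,
                  signed: bool) -> np.ndarray:
    """Sum of Gaussian pulses at Poisson event times over one epoch."""
    duration_s = (times[-1] - times[0]) / 1000.0
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    source = np.zeros_like(times)
    for _ in range(n_events):
        center = rng.uniform(times[0], times[-1])
        sign = rng.choice([-1.0, 1.0]) if signed else 1.0
        source += sign * np.exp(-((times - center) ** 2) / (2 * width_ms**2))
    return source


def _blink_topography(montage: Montage) -> np.ndarray:
    return gaussian_topography(montage, (0.0, 1.0, 0.25), 0.7)


def _saccade_topography(montage: Montage) -> np.ndarray:
    frontal = gaussian_topography(montage, (0.0, 0.95, -0.1), 0.8)
    topo = frontal * np.sign(montage.positions[:, 0])
    # normalize so the F9 projection carries unit weight
    return topo / abs(topo[montage.index("F9")])


def simulate_participant(
    meta: ParticipantMeta,
    design: CohortDesign,
    components: Sequence[ERPComponentSpec],
    artifacts: ArtifactSpec,
    seed,
    p1_attenuation: float = 1.0,
    montage: Optional[Montage] = None,
    gain_sd: float = 0.12,
) -> tuple[EpochSet, OcularComponents]:
    """Generate one participant's epoched EEG plus ground-truth ocular sources.

    Per-trial signal is the latency-jittered component sum (field-, group-
    and attenuation-scaled) plus alpha, 1/f noise and artifact projections;
    everything is multiplied by a monotone age factor and a participant
    gain. Fully reproducible given ``seed``.
    """
    if montage is None:
        montage = standard_montage()
    if design.trials_per_condition <= 0:
        raise ValueError("trial count must be positive")
    if not any(c.attenuable for c in components):
        raise ValueError("component list must include an attenuable P1 spec")

    rng = np.random.default_rng(seed)
    times = design.times_ms()
    n_times = times.size
    n_trials = 2 * design.trials_per_condition

    fields = np.array(
        ["upper"] * design.trials_per_condition
        + ["lower"] * design.trials_per_condition
    )
    rng.shuffle(fields)
    sides = rng.choice(["left", "right"], size=n_trials)
    targets = rng.random(n_trials) < design.target_rate
    response_ms = np.full(n_trials, np.nan)
    if meta.responds_manually:
        rts = rng.lognormal(mean=np.log(430.0), sigma=0.35, size=n_trials)
        response_ms[targets] = rts[targets]

    data = np.zeros((n_trials, len(montage), n_times))

    # evoked components
    x_sign = np.sign(montage.positions[:, 0])
    for comp in components:
        amp_by_field = {
            "upper": comp.amp_upper_uv, "lower": comp.amp_lower_uv
        }
        scale = comp.group_scale.get(meta.group, 1.0)
        if comp.attenuable:
            scale *= p1_attenuation
        latencies = comp.latency_ms + rng.normal(
            0.0, comp.jitter_sd_ms, size=n_trials
        )
        pulses = np.exp(
            -((times[None, :] - latencies[:, None]) ** 2)
            / (2 * comp.width_ms**2)
        )  # (trials, times)
        amps = np.array([amp_by_field[f] for f in fields]) * scale
        topo = np.broadcast_to(comp.topography, (n_trials, len(montage)))
        if comp.ipsilateral_bias:
            side_sign = np.where(sides == "right", 1.0, -1.0)
            topo = comp.topography[None, :] * (
                1.0 + comp.ipsilateral_bias * x_sign[None, :]
                * side_sign[:, None]
            )
        data += amps[:, None, None] * topo[:, :, None] * pulses[:, None, :]

    # alpha oscillation with trial-random phase (averages toward zero)
    if artifacts.alpha_amplitude_uv > 0:
        alpha_topo = gaussian_topography(montage, (0.0, -0.85, 0.4), 0.9)
        phases = rng.uniform(0, 2 * np.pi, size=n_trials)
        osc = np.sin(
            2 * np.pi * artifacts.alpha_freq_hz * times[None, :] / 1000.0
            + phases[:, None]
        )
        data += (
            artifacts.alpha_amplitude_uv
            * alpha_topo[None, :, None]
            * osc[:, None, :]
        )

    # 1/f background
    if artifacts.noise_scale_uv > 0:
        data += _pink_noise(
            rng, (n_trials, len(montage), n_times), design.sfreq,
            artifacts.noise_scale_uv,
        )

    # ocular artifacts: Gaussian pulses at Poisson times
    blink = np.zeros((n_trials, n_times))
    saccade = np.zeros((n_trials, n_times))
    for i in range(n_trials):
        blink[i] = artifacts.blink_amplitude_uv * _event_pulses(
            rng, times, artifacts.blink_rate_per_min, 60.0, signed=False
        )
        saccade[i] = artifacts.saccade_amplitude_uv * _event_pulses(
            rng, times, artifacts.saccade_rate_per_min, 25.0, signed=True
        )
    blink_topo = _blink_topography(montage)
    saccade_topo = _saccade_topography(montage)
    data += blink_topo[None, :, None] * blink[:, None, :]
    data += saccade_topo[None, :, None] * saccade[:, None, :]

    # participant-level gain: age factor times idiosyncratic lognormal
    gain = age_amplitude_scale(meta.age_years) * rng.lognormal(0.0, gain_sd)
    data *= gain
    blink *= gain
    saccade *= gain

    events = pd.DataFrame(
        {
            "field": fields,
            "side": sides,
            "target": targets,
            "response_ms": response_ms,
        }
    )
    epochs = EpochSet(
        data=data, times=times, sfreq=design.sfreq, montage=montage,
        events=events, pid=meta.pid,
    )
    ocular = OcularComponents(
        blink=blink, blink_topo=blink_topo,
        saccade=saccade, saccade_topo=saccade_topo, times=times,
    )
    return epochs, ocular


def _draw_meta(rng: np.random.Generator, group: str, pid: str,
               design: CohortDesign) -> ParticipantMeta:
    age = rng.uniform(*design.age_range_years)
    if group == "Control":
        return ParticipantMeta(
            pid=pid, group=group, age_years=age, responds_manually=True
        )
    if group == "CC":
        age_at_surgery = float(
            np.clip(rng.lognormal(np.log(30.0), 1.0), 1.0, age * 12.0 - 13.0)
        )
    else:  # DC: later onset
        age_at_surgery = float(
            np.clip(rng.normal(110.0, 50.0), 20.0, age * 12.0 - 13.0)
        )
    time_since = age * 12.0 - age_at_surgery
    responds = rng.random() > 0.12
    return ParticipantMeta(
        pid=pid, group=group, age_years=age,
        age_at_surgery_months=age_at_surgery,
        time_since_surgery_months=time_since,
        responds_manually=responds,
    )


def _draw_attenuations(rng: np.random.Generator,
                       design: CohortDesign) -> np.ndarray:
    """Per-CC-participant P1 attenuation factors (documented distribution)."""
    n = design.n_cc
    k = min(design.absent_p1_count, n)
    atten = np.empty(n)
    atten[:k] = rng.uniform(0.0, 0.04, size=k)
    atten[k:] = np.clip(
        rng.normal(design.attenuation_mean, design.attenuation_sd,
                   size=n - k),
        0.02, 0.95,
    )
    return atten


def simulate_cohort(
    design: CohortDesign,
    components: Optional[Sequence[ERPComponentSpec]] = None,
    artifacts: Optional[ArtifactSpec] = None,
    seed: int = 0,
    montage: Optional[Montage] = None,
) -> list[tuple[ParticipantMeta, EpochSet, OcularComponents]]:
    """Simulate a full three-group cohort, one sub-seed per participant."""
    if montage is None:
        montage = standard_montage()
    if components is None:
        components = default_components(montage)
    if artifacts is None:
        artifacts = default_artifacts()

    root = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    groups = (
        ["CC"] * design.n_cc + ["DC"] * design.n_dc
        + ["Control"] * design.n_control
    )
    attenuations = _draw_attenuations(meta_rng, design)
    child_seeds = root.spawn(len(groups) + 1)[1:]

    cohort = []
    cc_index = 0
    for i, (group, child) in enumerate(zip(groups, child_seeds)):
        pid = f"{design.label}-{group}-{i:03d}"
        meta = _draw_meta(meta_rng, group, pid, design)
        attenuation = 1.0
        if group == "CC":
            attenuation = float(attenuations[cc_index])
            cc_index += 1
        epochs, ocular = simulate_participant(
            meta, design, components, artifacts, child,
            p1_attenuation=attenuation, montage=montage,
        )
        cohort.append((meta, epochs, ocular))
    return cohort


def exp1_design(**overrides) -> CohortDesign:
    """Development-cohort preset (13 / 13 / 26); trial count chosen so the
    mean artifact-free upper-field trial count lands near 128."""
    kwargs = dict(
        n_cc=13, n_dc=13, n_control=26, trials_per_condition=162,
        label="exp1",
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def exp2_design(**overrides) -> CohortDesign:
    """Validation-cohort preset: group sizes 14 / 15 / 29, fewer clean trials."""
    kwargs = dict(
        n_cc=14, n_dc=15, n_control=29, trials_per_condition=102,
        label="exp2",
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def fast_design(base: str = "exp1", **overrides) -> CohortDesign:
    """Scaled-down preset (short epochs, low rate) for tests and replicates."""
    maker = {"exp1": exp1_design, "exp2": exp2_design}[base]
    kwargs = dict(
        trials_per_condition=24, sfreq=125.0,
        tmin_ms=-296.0, tmax_ms=400.0, label=f"{base}-fast",
    )
    kwargs.update(overrides)
    return maker(**kwargs)
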
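"""Seeded synthetic accelerometer-magnitude datasets.

The generator is a harmonic-plus-impulse gait proxy, not a biomechanical
simulation: each 180-sample trace at 256 Hz is a baseline plus a stride-
frequency sinusoid, sharpened periodic impact pulses, Gaussian noise and a
linear drift. The two classes differ in waveform shape so that, after the
pipeline's per-segment min-max normalization, fatigue traces tend toward
LOWER segment means and HIGHER late-segment RMS than non-fatigue traces —
the direction of the package's domain-knowledge threshold rules.

Fatigued running is modeled as sharper, taller, more variable impact
pulses over a weak oscillation (spiky, asymmetric signal); non-fatigued
running as a smoother dominant oscillation with mild impacts. The
``overlap`` dial pulls both class parameter sets toward their common
midpoint: 0 gives well-separated classes, 1 makes them identical up to
noise, creating the overlapping-pattern regime that motivates
context-aware example selection.

Determinism: the dataset seed spawns one child seed per user index, so a
given user's traces are identical regardless of how many users are
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .preprocessing import FATIGUE, NON_FATIGUE, MagnitudeTrace

__all__ = [
    "ClassParams",
    "SyntheticSpec",
    "generate_trace",
    "generate_dataset",
    "dataset_to_wide_frame",
]


@dataclass(frozen=True)
class ClassParams:
    """Waveform parameters of one class (arbitrary acceleration units).

    Impact pulses are sharpened positive sinusoid lobes at the step
    frequency; ``spike_saturation`` < 1 clips them into flat-topped
    (square-ish) impacts, which is what pushes a class toward the bimodal
    high-RMS regime after per-segment min-max normalization. ``dip_amp``
    adds narrow unloading dips on the opposite half-cycle.
    """

    baseline_mean: float
    oscillation_amp: float
    spike_amp: float
    spike_sharpness: float  # exponent on the positive sinusoid lobe
    spike_saturation: float  # in (0, 1]; 1 = no clipping
    dip_amp: float
    dip_sharpness: float
    noise_sd: float
    drift: float  # fractional late-trace growth of the impact amplitude

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.baseline_mean,
                self.oscillation_amp,
                self.spike_amp,
                self.spike_sharpness,
                self.spike_saturation,
                self.dip_amp,
                self.dip_sharpness,
                self.noise_sd,
                self.drift,
            ]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ClassParams":
        return cls(*map(float, arr))


#: mid-level plateau with narrow two-sided excursions: higher normalized
#: segment mean, lower RMS
DEFAULT_NONFATIGUE = ClassParams(
    baseline_mean=9.8,
    oscillation_amp=0.3,
    spike_amp=2.5,
    spike_sharpness=12.0,
    spike_saturation=1.0,
    dip_amp=1.5,
    dip_sharpness=12.0,
    noise_sd=0.25,
    drift=0.0,
)

#: tall flat-topped impacts growing late in the trace: bimodal shape with
#: lower normalized mean and higher RMS
DEFAULT_FATIGUE = ClassParams(
    baseline_mean=9.5,
    oscillation_amp=0.3,
    spike_amp=6.0,
    spike_sharpness=4.0,
    spike_saturation=0.6,
    dip_amp=0.5,
    dip_sharpness=12.0,
    noise_sd=0.35,
    drift=0.6,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Dataset-level generation parameters."""

    n_users: int = 5
    instances_per_user: int = 40
    class_balance: float = 0.5  # probability an instance is fatigue
    stride_freq_hz: float = 2.5
    fatigue_params: ClassParams = DEFAULT_FATIGUE
    nonfatigue_params: ClassParams = DEFAULT_NONFATIGUE
    overlap: float = 0.0
    seed: int = 0
    fs: float = 256.0
    n_samples: int = 180

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.instances_per_user < 2:
            raise ValueError("need >= 1 user and >= 2 instances per user")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if self.stride_freq_hz <= 0 or self.fs <= 0 or self.n_samples < 4:
            raise ValueError("invalid physical parameters")

    def effective_params(self, label: str) -> ClassParams:
        """Class parameters after pulling both classes toward the midpoint."""
        own = self.fatigue_params if label == FATIGUE else self.nonfatigue_params
        other = self.nonfatigue_params if label == FATIGUE else self.fatigue_params
        mix = (1.0 - self.overlap / 2.0) * own.as_array() + (
            self.overlap / 2.0
        ) * other.as_array()
        return ClassParams.from_array(mix)


def _user_rng(spec: SyntheticSpec, user_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(user_index,))
    )


def generate_trace(
    spec: SyntheticSpec,
    label: str,
    user_rng: np.random.Generator,
    user_id: str = "u00",
    instance_id: str = "u00_i000",
    user_scale: float = 1.0,
) -> MagnitudeTrace:
    """One labeled magnitude trace drawn from the class's waveform model."""
    p = spec.effective_params(label)
    t = np.arange(spec.n_samples) / spec.fs
    phase = user_rng.uniform(0, 2 * np.pi)
    frac = t / t[-1]
    # impacts at the step frequency (two steps per stride), dips on the
    # opposite half-cycle, plus the stride-frequency oscillation
    step_hz = 2.0 * spec.stride_freq_hz
    lobe_up = np.maximum(0.0, np.sin(2 * np.pi * step_hz * t + phase))
    lobe_dn = np.maximum(0.0, np.sin(2 * np.pi * step_hz * t + phase + np.pi))
    pulses = np.minimum(1.0, (lobe_up / p.spike_saturation) ** p.spike_sharpness)
    dips = lobe_dn ** p.dip_sharpness
    amp_jitter = user_rng.lognormal(mean=0.0, sigma=0.08)
    x = (
        p.baseline_mean * user_scale
        + p.oscillation_amp * amp_jitter * np.sin(2 * np.pi * spec.stride_freq_hz * t + phase)
        + p.spike_amp * amp_jitter * (1.0 + p.drift * frac) * pulses
        - p.dip_amp * amp_jitter * dips
        + user_rng.normal(0.0, p.noise_sd, size=spec.n_samples)
    )
    return MagnitudeTrace(
        user_id=user_id,
        instance_id=instance_id,
        samples=x,
        fs=spec.fs,
        label=label,
    )


def generate_dataset(spec: SyntheticSpec) -> list[MagnitudeTrace]:
    """All users' labeled traces, deterministically from ``spec.seed``.

    Labels are Bernoulli(``class_balance``) per instance; if a user happens
    to draw a single class, the first instance's label is flipped so both
    classes are always present.
    """
    traces: list[MagnitudeTrace] = []
    for u in range(spec.n_users):
        rng = _user_rng(spec, u)
        user_id = f"u{u:02d}"
        user_scale = rng.lognormal(mean=0.0, sigma=0.05)
        labels = [
            FATIGUE if rng.random() < spec.class_balance else NON_FATIGUE
            for _ in range(spec.instances_per_user)
        ]
        if len(set(labels)) == 1:
            labels[0] = NON_FATIGUE if labels[0] == FATIGUE else FATIGUE
        for j, label in enumerate(labels):
            traces.append(
                generate_trace(
                    spec,
                    label,
                    rng,
                    user_id=user_id,
                    instance_id=f"{user_id}_i{j:03d}",
                    user_scale=user_scale,
                )
            )
    return traces


def dataset_to_wide_frame(traces: list[MagnitudeTrace]) -> pd.DataFrame:
    """Wide-format table: user_id, instance_id, label, s000..sNNN."""
    if not traces:
        raise ValueError("no traces to export")
    n = traces[0].n_samples
    cols = [f"s{i:03d}" for i in range(n)]
    rows = []
    for tr in traces:
        if tr.n_samples != n:
            raise ValueError("all traces must share one length")
        rows.append(
            {"user_id": tr.user_id, "instance_id": tr.instance_id, "label": tr.label}
            | dict(zip(cols, tr.samples))
        )
    return pd.DataFrame(rows, columns=["user_id", "instance_id", "label"] + cols)
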
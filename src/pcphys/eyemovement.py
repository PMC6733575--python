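"""Gain/phase extraction from sinusoidal compensatory eye movements.

Compensatory eye movements (optokinetic reflex, OKR; vestibulo-ocular
reflex, VOR; visually-enhanced VOR, VVOR) are probed with sinusoidal
stimulation of a visual surround ("drum") or the turntable.  Motor
performance is summarized per trial as gain (eye velocity / stimulus
velocity) and phase (eye relative to stimulus, degrees, positive = eye
leads).  The harmonic fit is a linear least-squares fit of
``A·sin(2πft) + B·cos(2πft) + C + D·t``; fitting amplitude and phase of
the *position* sinusoid gives exactly the same gain and phase as fitting
the analytically differentiated velocity, so position traces are fitted
directly.

Sign convention: for table-driven conditions (VOR, VVOR) the eye is
compared against the inverted stimulus, so a perfectly compensatory
response (eye exactly opposite the head) reports gain 1, phase 0.

Quick phases / saccades are removed by a velocity-threshold mask with a
guard margin before fitting (the harmonic fit handles the gaps
naturally).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ContractError, DataQualityError, InsufficientDataError

__all__ = [
    "EyeTrial",
    "GainPhase",
    "SineFit",
    "desaccade",
    "fit_sine",
    "gain_phase",
    "session_curve",
    "wrap_phase",
]

_TABLE_CONDITIONS = ("VOR", "VVOR")


@dataclass
class EyeTrial:
    """Paired stimulus/eye position traces for one stimulation block."""

    time: np.ndarray               # s
    stimulus_position: np.ndarray  # degrees
    eye_position: np.ndarray       # degrees
    stim_freq: float               # Hz
    stim_amplitude: float          # degrees
    condition: str = "OKR"         # OKR | VOR | VVOR
    mask: np.ndarray | None = None  # True = sample excluded from fits

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stimulus_position = np.asarray(self.stimulus_position, dtype=float)
        self.eye_position = np.asarray(self.eye_position, dtype=float)
        if not (self.time.size == self.stimulus_position.size
                == self.eye_position.size):
            raise ContractError("time/stimulus/eye must have equal length")
        if self.stim_freq <= 0:
            raise ContractError("stim_freq must be > 0")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ContractError("time must be strictly increasing")

    @property
    def stimulus_source(self) -> str:
        return "table" if self.condition in _TABLE_CONDITIONS else "drum"


@dataclass
class SineFit:
    amplitude: float
    phase_deg: float
    offset: float
    drift: float
    r_squared: float
    n_samples_used: int


@dataclass
class GainPhase:
    """Per-trial gain and phase (degrees, wrapped to (−180, 180])."""

    gain: float
    phase: float
    r_squared: float
    n_samples_used: int


def wrap_phase(deg: float) -> float:
    """Wrap a phase in degrees to (−180, 180]."""
    w = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else float(w)


def desaccade(trial: EyeTrial, velocity_threshold: float | None = None,
              margin: float = 50.0, max_masked_fraction: float = 0.5,
              smooth: float = 40.0) -> EyeTrial:
    """Mask saccade-contaminated samples of the eye trace.

    Samples where the numerical eye velocity exceeds ``velocity_threshold``
    (deg/s), plus ``margin`` ms on both sides, are masked.  The default
    threshold is the lower of 10× the stimulus peak velocity and
    50 deg/s.  The position trace is low-pass filtered (moving average,
    ``smooth`` ms) before differentiation — raw sample noise would
    otherwise dominate the velocity estimate — but the returned trial
    keeps the unfiltered samples for fitting.  The trial is rejected
    when more than half of the samples end up masked.
    """
    if velocity_threshold is None:
        peak_vel = 2 * np.pi * trial.stim_freq * trial.stim_amplitude
        velocity_threshold = min(10.0 * peak_vel, 50.0)
    if velocity_threshold <= 0:
        raise ContractError("velocity_threshold must be > 0")
    pos = trial.eye_position
    if smooth > 0:
        dt_med = float(np.median(np.diff(trial.time)))
        w = max(1, int(round(smooth / 1000.0 / dt_med)))
        if w > 1:
            kern = np.ones(w) / w
            pos = np.convolve(np.pad(pos, (w // 2, w - 1 - w // 2),
                                     mode="edge"), kern, mode="valid")
    vel = np.gradient(pos, trial.time)
    fast = np.abs(vel) > velocity_threshold
    if fast.any():
        dt = np.median(np.diff(trial.time))
        pad = max(1, int(round(margin / 1000.0 / dt)))
        kernel = np.ones(2 * pad + 1)
        fast = np.convolve(fast.astype(float), kernel, mode="same") > 0
    mask = fast if trial.mask is None else (fast | trial.mask)
    if mask.mean() > max_masked_fraction:
        raise DataQualityError(
            f"{mask.mean():.0%} of samples masked as saccade; trial rejected")
    return replace(trial, mask=mask)


def fit_sine(values: np.ndarray, time: np.ndarray, freq: float,
             mask: np.ndarray | None = None, drift: bool = True) -> SineFit:
    """Least-squares harmonic fit at a known frequency.

    Fits ``A·sin(2πft) + B·cos(2πft) + C (+ D·t)``; amplitude is
    √(A²+B²) and phase atan2(B, A) in degrees.  Requires at least two
    full stimulus cycles of (unmasked) data.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    if freq <= 0:
        raise ContractError("freq must be > 0")
    keep = np.ones(values.size, dtype=bool) if mask is None else ~np.asarray(mask)
    t, y = time[keep], values[keep]
    if t.size < 8 or (t.max() - t.min()) < 2.0 / freq:
        raise InsufficientDataError("need at least 2 full cycles of data")
    w = 2 * np.pi * freq
    cols = [np.sin(w * t), np.cos(w * t), np.ones_like(t)]
    if drift:
        cols.append(t - t.mean())
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    a, b = float(coef[0]), float(coef[1])
    return SineFit(amplitude=float(np.hypot(a, b)),
                   phase_deg=wrap_phase(np.degrees(np.arctan2(b, a))),
                   offset=float(coef[2]),
                   drift=float(coef[3]) if drift else 0.0,
                   r_squared=r2, n_samples_used=int(t.size))


def gain_phase(trial: EyeTrial) -> GainPhase:
    """Gain and phase of one (desaccaded) trial.

    Both traces are fitted at the stimulus frequency; gain is the ratio
    of fitted amplitudes and phase the fitted phase difference.  Since
    differentiating ``A·sin(ωt+φ)`` scales both amplitudes by ω, the
    position-amplitude ratio equals the velocity ratio exactly.
    """
    stim = trial.stimulus_position
    if trial.stimulus_source == "table":
        stim = -stim  # compensatory response -> phase 0
    f_eye = fit_sine(trial.eye_position, trial.time, trial.stim_freq,
                     mask=trial.mask)
    f_stim = fit_sine(stim, trial.time, trial.stim_freq, mask=trial.mask)
    if f_stim.amplitude <= 0:
        raise DataQualityError("stimulus has no component at stim_freq")
    return GainPhase(gain=f_eye.amplitude / f_stim.amplitude,
                     phase=wrap_phase(f_eye.phase_deg - f_stim.phase_deg),
                     r_squared=f_eye.r_squared,
                     n_samples_used=f_eye.n_samples_used)


def session_curve(points: list[tuple[int, GainPhase]],
                  paradigm: str = "gain_decrease") -> pd.DataFrame:
    """Order per-probe gain/phase into a learning-curve table.

    ``points`` are (session index, GainPhase) pairs, e.g. VOR probes
    before/between/after training blocks.  The returned frame carries
    per-probe gain and phase plus summary columns: ``gain_delta`` and
    ``phase_delta`` (last − first) and, for the phase-reversal paradigm,
    ``reversal_progress`` = |phase| / 180 at each probe.
    """
    if paradigm not in ("gain_decrease", "gain_increase", "phase_reversal",
                        "okr_increase"):
        raise ContractError(f"unknown paradigm '{paradigm}'")
    if len(points) < 2:
        raise InsufficientDataError("need at least 2 probe points")
    rows = sorted(points, key=lambda p: p[0])
    df = pd.DataFrame({
        "session": [s for s, _ in rows],
        "gain": [gp.gain for _, gp in rows],
        "phase": [gp.phase for _, gp in rows],
    })
    df["paradigm"] = paradigm
    df["gain_delta"] = df["gain"].iloc[-1] - df["gain"].iloc[0]
    df["phase_delta"] = df["phase"].iloc[-1] - df["phase"].iloc[0]
    if paradigm == "phase_reversal":
        df["reversal_progress"] = df["phase"].abs() / 180.0
    return df
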
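"""Synthetic data generators emulating the recorded modalities.

Every analysis stage in this package is exercised against data with
known ground truth.  This module generates:

* gamma-renewal simple-spike trains with an independent complex-spike
  process, an enforced climbing-fiber pause, and one of four post-CS
  modulation profiles (normal / facilitation / suppression /
  oscillation);
* sinusoidal compensatory eye-movement trials with known gain/phase,
  Gaussian noise and saccade-like artifacts;
* eyeblink-conditioning sessions (paired / CS-only / US-only trials)
  with parameterized conditioned-response probability and latencies,
  plus a fraction of invalid noisy-baseline trials;
* current-step intrinsic-excitability sweeps with a known input–output
  slope;
* labeled multi-cell cohorts for group comparisons.

All generators are pure functions of (spec, seed): repeated calls yield
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SpecificationError
from .spiketrain import SpikeTrain
from .eyemovement import EyeTrial
from .eyeblink import BlinkTrial
from .excitability import ExcitabilitySweep

__all__ = [
    "SpikeGenSpec",
    "EyeGenSpec",
    "BlinkGenSpec",
    "GroupSpec",
    "gen_spiketrain",
    "gen_eye_trial",
    "gen_blink_session",
    "gen_excitability_cell",
    "gen_group_dataset",
]


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise SpecificationError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# Spike trains


@dataclass(frozen=True)
class SpikeGenSpec:
    """Ground truth for one synthetic Purkinje-cell recording.

    ``target_rate``/``target_cv`` set the gamma renewal process of the
    simple spikes (shape k = 1/cv², so cv → 0 gives a metronome and
    cv = 1 a Poisson train).  Complex spikes are an independent Poisson
    process at ``cs_rate``; after each complex spike, simple spikes are
    silenced for ``cf_pause`` ms and then modulated according to
    ``modulation_type``.
    """

    target_rate: float = 60.0       # Hz
    target_cv: float = 0.5
    cs_rate: float = 1.0            # Hz
    cf_pause: float = 15.0          # ms
    modulation_type: str = "normal"
    modulation_amplitude: float = 0.5   # fractional rate change
    modulation_window: float = 100.0    # ms, facilitation/suppression support
    oscillation_freq: float = 10.0      # Hz
    oscillation_tau: float = 100.0      # ms, decay of the oscillation kernel
    duration: float = 60.0          # s
    seed: int = 0

    def validate(self) -> None:
        _require(self.target_rate > 0, "target_rate", "must be > 0")
        _require(self.target_cv > 0 and np.isfinite(1.0 / self.target_cv**2),
                 "target_cv", "must be > 0 with finite gamma shape")
        _require(self.cs_rate >= 0, "cs_rate", "must be >= 0")
        _require(self.cf_pause >= 0, "cf_pause", "must be >= 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.modulation_type in
                 ("normal", "facilitation", "suppression", "oscillation"),
                 "modulation_type", "unknown type")
        _require(self.modulation_window >= 0, "modulation_window", "must be >= 0")
        if self.modulation_type == "oscillation":
            _require(self.oscillation_freq > 0, "oscillation_freq",
                     "must be > 0 for oscillation")


def _renewal_times(rng: np.random.Generator, rate: float, shape: float,
                   t_start: float, t_stop: float) -> np.ndarray:
    """Event times of a gamma renewal process on [t_start, t_stop].

    Started ``t_start`` early relative to the observation window so the
    process is close to equilibrium at time 0.
    """
    mean_isi = 1.0 / rate
    span = t_stop - t_start
    n_guess = int(span * rate * 1.2) + 50
    times = []
    t = t_start
    while t < t_stop:
        isi = rng.gamma(shape, mean_isi / shape, size=n_guess)
        chunk = t + np.cumsum(isi)
        times.append(chunk)
        t = chunk[-1]
    all_t = np.concatenate(times)
    return all_t[(all_t >= 0.0) & (all_t <= t_stop)]


def _modulation_kernel(spec: SpikeGenSpec, t_after_pause: np.ndarray) -> np.ndarray:
    """Fractional rate multiplier minus one, as a function of time (s)
    after the end of the climbing-fiber pause."""
    amp = spec.modulation_amplitude
    if spec.modulation_type == "facilitation":
        return np.where(t_after_pause <= spec.modulation_window / 1000.0, amp, 0.0)
    if spec.modulation_type == "suppression":
        return np.where(t_after_pause <= spec.modulation_window / 1000.0, -amp, 0.0)
    if spec.modulation_type == "oscillation":
        return (amp * np.cos(2 * np.pi * spec.oscillation_freq * t_after_pause)
                * np.exp(-t_after_pause / (spec.oscillation_tau / 1000.0)))
    return np.zeros_like(t_after_pause)


def _kernel_support_s(spec: SpikeGenSpec) -> float:
    if spec.modulation_type in ("facilitation", "suppression"):
        return spec.modulation_window / 1000.0
    if spec.modulation_type == "oscillation":
        # 3 decay constants covers the visible part of the kernel
        return 3.0 * spec.oscillation_tau / 1000.0
    return 0.0


def gen_spiketrain(spec: SpikeGenSpec) -> SpikeTrain:
    """Generate one labeled spike train from a :class:`SpikeGenSpec`.

    Simple spikes are a gamma renewal process (shape 1/cv²) at the
    target rate; complex spikes an independent Poisson process.  After
    each complex spike, simple spikes within the pause are deleted, and
    the post-pause intensity is modulated by thinning (negative kernel
    lobes) and superposed Poisson insertion (positive lobes), which keeps
    the baseline ISI statistics interpretable.
    """
    spec.validate()
    if spec.modulation_amplitude > 1.0 and spec.modulation_type in (
            "suppression", "oscillation"):
        warnings.warn("modulation_amplitude > 1 would make the intensity "
                      "negative; thinning probability clipped at 1")
    rng = np.random.default_rng(spec.seed)
    shape = 1.0 / spec.target_cv**2
    burn = max(1.0, 20.0 / spec.target_rate)
    ss = _renewal_times(rng, spec.target_rate, shape, -burn, spec.duration)

    if spec.cs_rate > 0:
        cs = _renewal_times(rng, spec.cs_rate, 1.0, -1.0 / spec.cs_rate,
                            spec.duration)
    else:
        cs = np.empty(0)

    pause_s = spec.cf_pause / 1000.0
    if cs.size:
        # delete simple spikes inside (cs, cs + pause]
        keep = np.ones(ss.size, dtype=bool)
        for c in cs:
            i0 = np.searchsorted(ss, c, side="left")
            i1 = np.searchsorted(ss, c + pause_s, side="right")
            keep[i0:i1] = False
        ss = ss[keep]

        support = _kernel_support_s(spec)
        if support > 0 and spec.modulation_type != "normal":
            # thinning of negative lobes
            idx = np.searchsorted(cs, ss, side="right") - 1
            has_cs = idx >= 0
            dt = np.where(has_cs, ss - cs[np.clip(idx, 0, None)], np.inf) - pause_s
            in_support = has_cs & (dt >= 0) & (dt <= support)
            m = np.zeros(ss.size)
            m[in_support] = _modulation_kernel(spec, dt[in_support])
            thin_p = np.clip(-m, 0.0, 1.0)
            ss = ss[rng.random(ss.size) >= thin_p]

            # superposed insertion for positive lobes, per complex spike
            m_max = max(float(np.max(_modulation_kernel(
                spec, np.linspace(0, support, 512)))), 0.0)
            if m_max > 0:
                inserted = []
                lam = spec.target_rate * m_max
                for c in cs:
                    n_ins = rng.poisson(lam * support)
                    if n_ins == 0:
                        continue
                    u = rng.uniform(0.0, support, size=n_ins)
                    acc = rng.random(n_ins) < (
                        np.clip(_modulation_kernel(spec, u), 0.0, None) / m_max)
                    inserted.append(c + pause_s + u[acc])
                if inserted:
                    extra = np.concatenate(inserted)
                    extra = extra[(extra >= 0) & (extra <= spec.duration)]
                    ss = np.sort(np.concatenate([ss, extra]))

    ss = np.unique(ss)
    ss = ss[~np.isin(ss, cs)]  # event lists must be disjoint
    return SpikeTrain(simple_spike_times=ss, complex_spike_times=cs,
                      duration=spec.duration)


# ---------------------------------------------------------------------------
# Eye movements


@dataclass(frozen=True)
class EyeGenSpec:
    """Ground truth for one sinusoidal eye-movement trial.

    Defaults follow the recording protocol emulated here: drum/table
    oscillation of 5 degrees amplitude in the 0.1–1 Hz band (0.6 Hz
    default).  ``true_phase`` is in degrees, positive = eye leads; for
    table-driven conditions (VOR, VVOR) the eye trace is generated with
    the compensatory sign, so a perfect response is (gain 1, phase 0).
    """

    stim_freq: float = 0.6         # Hz
    stim_amplitude: float = 5.0    # degrees
    true_gain: float = 0.8
    true_phase: float = 0.0        # degrees
    condition: str = "OKR"         # OKR | VOR | VVOR
    noise_sd: float = 0.2          # degrees
    saccade_rate: float = 0.0      # events/s
    saccade_tau: float = 0.15      # s, exponential return
    duration: float = 20.0         # s
    sample_rate: float = 120.0     # Hz
    seed: int = 0

    def validate(self) -> None:
        _require(self.stim_freq > 0, "stim_freq", "must be > 0")
        _require(self.stim_amplitude > 0, "stim_amplitude", "must be > 0")
        _require(self.true_gain >= 0, "true_gain", "must be >= 0")
        _require(-180.0 < self.true_phase <= 180.0, "true_phase",
                 "must be in (-180, 180]")
        _require(self.condition in ("OKR", "VOR", "VVOR"), "condition",
                 "must be OKR, VOR or VVOR")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.saccade_rate >= 0, "saccade_rate", "must be >= 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.sample_rate > 0, "sample_rate", "must be > 0")


def gen_eye_trial(spec: EyeGenSpec) -> EyeTrial:
    """Generate one sinusoidal stimulation trial with known gain/phase."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    w = 2 * np.pi * spec.stim_freq
    stim = spec.stim_amplitude * np.sin(w * t)
    sign = -1.0 if spec.condition in ("VOR", "VVOR") else 1.0
    eye = (sign * spec.true_gain * spec.stim_amplitude
           * np.sin(w * t + np.deg2rad(spec.true_phase)))
    if spec.noise_sd > 0:
        eye = eye + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.saccade_rate > 0:
        n_sac = rng.poisson(spec.saccade_rate * spec.duration)
        for t0 in rng.uniform(0.0, spec.duration, size=n_sac):
            step = rng.uniform(2.0, 5.0) * rng.choice([-1.0, 1.0])
            after = t >= t0
            eye[after] += step * np.exp(-(t[after] - t0) / spec.saccade_tau)
    return EyeTrial(time=t, stimulus_position=stim, eye_position=eye,
                    stim_freq=spec.stim_freq, stim_amplitude=spec.stim_amplitude,
                    condition=spec.condition)


# ---------------------------------------------------------------------------
# Eyeblink sessions


@dataclass(frozen=True)
class BlinkGenSpec:
    """Ground truth for one eyeblink-conditioning session.

    Session composition defaults to the emulated protocol: 200 paired
    CS-US trials, 20 CS-only and 20 US-only trials per session, CS–US
    interval 250 ms, CS duration 280 ms co-terminating with a 30 ms US.
    ``cr_amplitude`` is a fraction of the full blink (the UR peak).
    """

    n_paired: int = 200
    n_cs_only: int = 20
    n_us_only: int = 20
    cs_duration: float = 280.0      # ms
    isi_cs_us: float = 250.0        # ms, CS onset to US onset
    cr_probability: float = 0.5
    cr_amplitude: float = 0.5       # fraction of full blink
    cr_onset_latency: float = 150.0  # ms after CS onset
    cr_peak_latency: float = 220.0   # ms after CS onset
    ur_amplitude: float = 1.0       # raw units; defines "full blink"
    baseline_noise_sd: float = 0.01  # raw units
    invalid_fraction: float = 0.0
    artifact_scale: float = 15.0    # pre-CS artifact size, × baseline_noise_sd
    sample_rate: float = 1000.0     # Hz
    trial_length: float = 2.0       # s
    cs_onset: float = 0.5           # s into the trace
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_paired", "n_cs_only", "n_us_only"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(self.isi_cs_us > 0, "isi_cs_us", "must be > 0")
        _require(0.0 <= self.cr_probability <= 1.0, "cr_probability",
                 "must be in [0, 1]")
        _require(0.0 <= self.invalid_fraction <= 1.0, "invalid_fraction",
                 "must be in [0, 1]")
        _require(self.ur_amplitude > 0, "ur_amplitude", "must be > 0")
        _require(self.baseline_noise_sd >= 0, "baseline_noise_sd", "must be >= 0")
        _require(self.artifact_scale >= 10.0, "artifact_scale",
                 "must be >= 10 x baseline noise")
        _require(self.cs_onset >= 0.5, "cs_onset",
                 "a full 500 ms pre-CS window must exist")
        _require(self.cr_onset_latency < self.cr_peak_latency, "cr_onset_latency",
                 "must precede cr_peak_latency")
        _require(self.sample_rate > 0, "sample_rate", "must be > 0")


def _sigmoid_ramp(t: np.ndarray, t_on: float, t_peak: float) -> np.ndarray:
    """Smooth 0→1 ramp starting near t_on, saturating near t_peak."""
    center = 0.5 * (t_on + t_peak)
    slope = 8.0 / max(t_peak - t_on, 1e-6)
    return 1.0 / (1.0 + np.exp(-slope * (t - center)))


def _blink_trial(spec: BlinkGenSpec, rng: np.random.Generator,
                 trial_type: str, invalid: bool) -> BlinkTrial:
    n = int(round(spec.trial_length * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    trace = rng.normal(0.0, spec.baseline_noise_sd, size=n)
    cs_on = spec.cs_onset
    us_on = cs_on + spec.isi_cs_us / 1000.0 if trial_type != "cs_only" else None

    if trial_type in ("paired", "us_only"):
        # unconditioned response: fast sigmoid rise to the full-blink
        # amplitude ~40 ms after US onset, then exponential relaxation
        rise = _sigmoid_ramp(t, us_on + 0.005, us_on + 0.040)
        decay = np.where(t > us_on + 0.040,
                         np.exp(-(t - us_on - 0.040) / 0.25), 1.0)
        trace += spec.ur_amplitude * rise * decay

    if trial_type in ("paired", "cs_only") and rng.random() < spec.cr_probability:
        on = cs_on + spec.cr_onset_latency / 1000.0
        pk = cs_on + spec.cr_peak_latency / 1000.0
        ramp = _sigmoid_ramp(t, on, pk)
        decay = np.where(t > pk, np.exp(-(t - pk) / 0.30), 1.0)
        trace += spec.cr_amplitude * spec.ur_amplitude * ramp * decay

    if invalid:
        # large square artifact confined to the pre-CS window
        t0 = rng.uniform(0.05, cs_on - 0.10)
        amp = spec.artifact_scale * spec.baseline_noise_sd
        trace[(t >= t0) & (t < t0 + 0.05)] += amp

    return BlinkTrial(trace=trace, sample_rate=spec.sample_rate,
                      cs_onset=cs_on, us_onset=us_on, trial_type=trial_type)


def gen_blink_session(spec: BlinkGenSpec) -> list[BlinkTrial]:
    """Generate one session of eyeblink trials in randomized order."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    types = (["paired"] * spec.n_paired + ["cs_only"] * spec.n_cs_only
             + ["us_only"] * spec.n_us_only)
    n_total = len(types)
    invalid_flags = rng.random(n_total) < spec.invalid_fraction
    order = rng.permutation(n_total)
    return [_blink_trial(spec, rng, types[i], bool(invalid_flags[i]))
            for i in order]


# ---------------------------------------------------------------------------
# Intrinsic excitability


def gen_excitability_cell(
    rheobase: float,
    slope: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    currents: np.ndarray | None = None,
    pulse_duration: float = 1.0,
) -> list[ExcitabilitySweep]:
    """Current-step sweeps of a cell with a known input–output slope.

    Currents default to the −100..1100 pA ladder in 100 pA steps; the
    mean rate over the 1 s pulse is ``max(0, slope·(I − rheobase)/100)``
    plus Gaussian noise, rounded to a non-negative integer spike count.
    ``slope`` is in Hz per 100 pA.
    """
    _require(slope >= 0, "slope", "must be >= 0")
    _require(noise_sd >= 0, "noise_sd", "must be >= 0")
    rng = np.random.default_rng(seed)
    if currents is None:
        currents = np.arange(-100.0, 1100.0 + 1, 100.0)
    sweeps = []
    for i_pa in currents:
        rate = max(0.0, slope * (i_pa - rheobase) / 100.0)
        if noise_sd > 0 and rate > 0:
            rate = rate + rng.normal(0.0, noise_sd)
        count = max(0, int(round(rate * pulse_duration)))
        sweeps.append(ExcitabilitySweep(injected_current=float(i_pa),
                                        spike_count=count,
                                        pulse_duration=pulse_duration))
    return sweeps


# ---------------------------------------------------------------------------
# Group cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Per-group recipe for a cohort of spike trains."""

    label: str
    mean_rate: float   # Hz, across-cell mean
    sd_rate: float     # Hz, across-cell SD
    n: int
    cv: float = 0.5
    cs_rate: float = 1.0
    cf_pause: float = 15.0
    duration: float = 60.0
    zebrin: str = "unknown"


def gen_group_dataset(group_specs: list[GroupSpec], seed: int = 0) -> list[SpikeTrain]:
    """Cohort of labeled spike trains with per-cell rates drawn from a
    truncated normal (> 1 Hz) around each group's mean ± SD."""
    trains: list[SpikeTrain] = []
    for g_idx, g in enumerate(group_specs):
        _require(g.n >= 2, "n", f"group '{g.label}' needs n >= 2")
        _require(g.sd_rate >= 0, "sd_rate", "must be >= 0")
        cell_seeds = np.random.SeedSequence((seed, g_idx)).generate_state(g.n)
        rate_rng = np.random.default_rng(np.random.SeedSequence((seed, g_idx, 977)))
        for c_idx in range(g.n):
            rate = rate_rng.normal(g.mean_rate, g.sd_rate)
            while rate <= 1.0:  # truncation avoids degenerate trains
                rate = rate_rng.normal(g.mean_rate, g.sd_rate)
            spec = SpikeGenSpec(target_rate=float(rate), target_cv=g.cv,
                                cs_rate=g.cs_rate, cf_pause=g.cf_pause,
                                duration=g.duration,
                                seed=int(cell_seeds[c_idx] % (2**31)))
            train = gen_spiketrain(spec)
            train.cell_id = f"{g.label}_{c_idx:03d}"
            train.group = g.label
            train.zebrin = g.zebrin
            trains.append(train)
    return trains
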
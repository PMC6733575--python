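"""Eyeblink-conditioning trial pipeline.

Delay eyeblink conditioning pairs a neutral conditioned stimulus (CS,
an LED) with a corneal air-puff unconditioned stimulus (US) 250 ms after
CS onset; over training the animal learns a preventative eyelid closure
(conditioned response, CR) timed before the US.  The per-trial pipeline:

1. *validity*: trials with significant activity in the 500 ms pre-CS
   window (> 7 × IQR of the session's pooled pre-CS samples, measured
   from the session pre-CS median) are discarded;
2. *normalization*: pre-CS baseline aligned to 0 and the trace scaled
   so a full blink (the mean US-only UR peak) equals 1;
3. *CR detection*: an eyelid movement counts as a CR when its
   normalized amplitude exceeds 0.1, its onset latency falls in
   50–250 ms and its peak latency in 100–250 ms after CS onset
   (probe/CS-only variant: peak in 100–500 ms);
4. *session metrics*: CR percentage and mean CR amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import CalibrationError, ContractError, InsufficientDataError

__all__ = [
    "BlinkTrial",
    "CRResult",
    "BlinkSessionResult",
    "session_baseline",
    "validate_trial",
    "normalize_trial",
    "full_blink_scale",
    "detect_cr",
    "session_metrics",
    "analyze_session",
]

PRE_CS_WINDOW = 0.5  # s; baseline window before CS onset


@dataclass
class BlinkTrial:
    """One eyelid trace with stimulus markers.

    ``trace`` is eyelid position in raw acquisition units until
    normalization (0 = open, 1 = full blink afterwards).  ``us_onset``
    is None for CS-only trials.
    """

    trace: np.ndarray
    sample_rate: float
    cs_onset: float                 # s; >= 0.5 so a full pre-CS window exists
    us_onset: float | None = None   # s
    trial_type: str = "paired"      # paired | cs_only | us_only
    valid: bool | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.sample_rate <= 0:
            raise ContractError("sample_rate must be > 0")
        if self.cs_onset < PRE_CS_WINDOW:
            raise ContractError("cs_onset must leave a full 500 ms pre-CS window")
        if self.trial_type not in ("paired", "cs_only", "us_only"):
            raise ContractError(f"unknown trial_type '{self.trial_type}'")
        if self.trial_type == "paired" and self.us_onset is None:
            raise ContractError("paired trial requires us_onset")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.trace.size) / self.sample_rate

    def pre_cs_samples(self) -> np.ndarray:
        i0 = int(round((self.cs_onset - PRE_CS_WINDOW) * self.sample_rate))
        i1 = int(round(self.cs_onset * self.sample_rate))
        if i1 > self.trace.size:
            raise ContractError("trace ends before CS onset")
        return self.trace[i0:i1]


@dataclass
class CRResult:
    is_cr: bool
    amplitude: float        # normalized units
    onset_latency: float    # ms after CS onset, NaN if never crossed
    peak_latency: float     # ms after CS onset


@dataclass
class BlinkSessionResult:
    n_trials: int
    n_valid: int
    n_cr: int
    cr_percentage: float
    cr_amplitude: float      # mean over CR-positive trials, NaN if none
    full_blink_scale: float  # raw units
    ur_peak_latency: float   # ms after US onset, NaN without US-only trials


# ---------------------------------------------------------------------------


def session_baseline(trials: list[BlinkTrial]) -> tuple[float, float]:
    """Session-level pre-CS (median, IQR) pooled over all trials.

    Pooling across trials makes the validity rule robust and
    session-stationary: a single contaminated trial cannot inflate its
    own threshold.
    """
    if not trials:
        raise InsufficientDataError("no trials")
    pooled = np.concatenate([t.pre_cs_samples() for t in trials])
    q25, q50, q75 = np.percentile(pooled, [25, 50, 75])
    return float(q50), float(q75 - q25)


def validate_trial(trial: BlinkTrial, baseline_median: float,
                   baseline_iqr: float, multiplier: float = 7.0) -> bool:
    """Trial validity: no significant pre-CS activity.

    Invalid iff any pre-CS sample deviates from the session pre-CS
    median by more than ``multiplier × baseline_iqr``.
    """
    if baseline_iqr <= 0:
        raise ContractError("baseline_iqr must be > 0")
    dev = np.max(np.abs(trial.pre_cs_samples() - baseline_median))
    return bool(dev <= multiplier * baseline_iqr)


def full_blink_scale(us_only_trials: list[BlinkTrial]) -> float:
    """Full-blink calibration constant, in raw units.

    Mean over valid US-only trials of (UR peak − pre-CS baseline mean).
    """
    usable = [t for t in us_only_trials
              if t.trial_type == "us_only" and t.valid is not False]
    if not usable:
        raise CalibrationError("no valid US-only trials to calibrate from")
    deflections = []
    for t in usable:
        if t.us_onset is None:
            raise ContractError("us_only trial lacks us_onset")
        i_us = int(round(t.us_onset * t.sample_rate))
        deflections.append(t.trace[i_us:].max() - t.pre_cs_samples().mean())
    return float(np.mean(deflections))


def normalize_trial(trial: BlinkTrial, scale: float) -> BlinkTrial:
    """Align the pre-CS baseline to 0 and scale a full blink to 1.

    ``trace' = (trace − mean(pre-CS)) / scale``; the normalized pre-CS
    mean is exactly 0.
    """
    if scale <= 0:
        raise CalibrationError("full-blink scale must be > 0")
    base = trial.pre_cs_samples().mean()
    return replace(trial, trace=(trial.trace - base) / scale, normalized=True)


def detect_cr(trial: BlinkTrial, probe: bool = False,
              amplitude_threshold: float = 0.1,
              onset_window: tuple[float, float] = (50.0, 250.0),
              peak_window: tuple[float, float] = (100.0, 250.0),
              probe_peak_window: tuple[float, float] = (100.0, 500.0),
              onset_level: float = 0.05,
              onset_sustain: float = 10.0) -> CRResult:
    """Conditioned-response detection on one normalized trial.

    The search window runs from CS onset to US onset for paired trials,
    or to CS onset + 500 ms for the probe (CS-only) variant.  Amplitude
    is the maximum normalized closure in the window; the onset is the
    first crossing of ``onset_level`` (half the amplitude criterion)
    sustained for at least ``onset_sustain`` ms.  A CR requires
    amplitude > ``amplitude_threshold`` with onset and peak latencies
    inside their windows.
    """
    if not trial.normalized:
        raise ContractError("detect_cr requires a normalized trial")
    fs = trial.sample_rate
    if probe or trial.us_onset is None:
        end = trial.cs_onset + 0.5
        pk_win = probe_peak_window
    else:
        end = trial.us_onset
        pk_win = peak_window
    i0 = int(round(trial.cs_onset * fs))
    i1 = min(int(round(end * fs)), trial.trace.size)
    seg = trial.trace[i0:i1]
    if seg.size == 0:
        raise ContractError("empty CR search window")
    amplitude = float(seg.max())
    i_max = int(np.argmax(seg))
    peak_latency = float(i_max / fs * 1000.0)
    if (i_max == seg.size - 1 and i1 < trial.trace.size
            and trial.trace[i1] > seg[i_max]):
        # eyelid still closing at the window edge: the true peak falls
        # beyond the window, so the peak-latency criterion cannot hold
        peak_latency = np.inf

    sustain_n = max(1, int(round(onset_sustain / 1000.0 * fs)))
    above = seg >= onset_level
    onset_latency = np.nan
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain_n:
            onset_latency = (i - sustain_n + 1) / fs * 1000.0
            break
    is_cr = (amplitude > amplitude_threshold
             and np.isfinite(onset_latency)
             and onset_window[0] <= onset_latency <= onset_window[1]
             and pk_win[0] <= peak_latency <= pk_win[1])
    return CRResult(is_cr=bool(is_cr), amplitude=amplitude,
                    onset_latency=float(onset_latency),
                    peak_latency=peak_latency)


def _ur_peak_latency_ms(trial: BlinkTrial) -> float:
    i_us = int(round(trial.us_onset * trial.sample_rate))
    seg = trial.trace[i_us:]
    return float(np.argmax(seg) / trial.sample_rate * 1000.0)


def session_metrics(trials: list[BlinkTrial], scale: float,
                    cr_trial_class: str = "cs_only",
                    probe: bool = True) -> BlinkSessionResult:
    """Per-session CR percentage and amplitude.

    ``trials`` must already carry validity flags and be normalized (the
    convenience wrapper :func:`analyze_session` does the full pipeline).
    CR percentage is computed over the designated trial class (CS-only
    by default, with the probe peak window, since CS-only trials are
    uncontaminated by the UR; ``cr_trial_class="paired"`` switches to
    paired trials with the standard window).
    """
    valid = [t for t in trials if t.valid]
    if not valid:
        raise InsufficientDataError("no valid trials in session")
    pool = [t for t in valid if t.trial_type == cr_trial_class]
    if not pool:
        raise InsufficientDataError(
            f"no valid '{cr_trial_class}' trials in session")
    results = [detect_cr(t, probe=probe) for t in pool]
    n_cr = sum(r.is_cr for r in results)
    cr_amps = [r.amplitude for r in results if r.is_cr]
    us_lat = [_ur_peak_latency_ms(t) for t in valid if t.trial_type == "us_only"]
    return BlinkSessionResult(
        n_trials=len(trials), n_valid=len(valid), n_cr=int(n_cr),
        cr_percentage=100.0 * n_cr / len(pool),
        cr_amplitude=float(np.mean(cr_amps)) if cr_amps else np.nan,
        full_blink_scale=scale,
        ur_peak_latency=float(np.mean(us_lat)) if us_lat else np.nan)


def analyze_session(trials: list[BlinkTrial],
                    multiplier: float = 7.0,
                    cr_trial_class: str = "cs_only",
                    probe: bool = True) -> BlinkSessionResult:
    """Full session pipeline: validity → calibration → normalization →
    CR detection → session metrics."""
    median, iqr = session_baseline(trials)
    flagged = [replace(t, valid=validate_trial(t, median, iqr, multiplier))
               for t in trials]
    scale = full_blink_scale([t for t in flagged if t.trial_type == "us_only"
                              and t.valid])
    processed = [normalize_trial(t, scale) if t.valid else t for t in flagged]
    return session_metrics(processed, scale, cr_trial_class=cr_trial_class,
                           probe=probe)
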
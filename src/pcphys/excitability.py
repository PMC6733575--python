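"""In vitro intrinsic-excitability metrics.

Whole-cell current-clamp protocol: 1 s depolarizing current pulses from
−100 to 1100 pA in 100 pA increments; the average spiking rate over the
pulse builds the current–frequency (input–output, I–O) curve, and
intrinsic excitability is quantified as the slope of that curve in
Hz per 100 pA.  Action-potential features (peak amplitude, AHP,
half-width) are measured on the first spike of a sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, InsufficientDataError

__all__ = [
    "ExcitabilitySweep",
    "IOCurve",
    "APFeatures",
    "io_curve",
    "io_slope",
    "ap_features",
]


@dataclass
class ExcitabilitySweep:
    """One current step: injected current (pA) and resulting spike count."""

    injected_current: float
    spike_count: int
    pulse_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.spike_count < 0:
            raise ContractError("spike_count must be >= 0")
        if self.pulse_duration <= 0:
            raise ContractError("pulse_duration must be > 0")

    @property
    def rate(self) -> float:
        return self.spike_count / self.pulse_duration


@dataclass
class IOCurve:
    """Current–frequency curve with its fitted excitability slope."""

    currents: np.ndarray          # pA
    rates: np.ndarray             # Hz
    slope: float                  # Hz per 100 pA
    fit_intercept: float          # Hz, at 0 pA
    fit_range: tuple[float, float]  # pA


@dataclass
class APFeatures:
    """First-action-potential waveform features.

    ``peak_amplitude`` is measured from the resting potential; ``ahp``
    is the undershoot magnitude below resting (0 when the waveform never
    dips below it); ``half_width`` is the width at 50 % of the peak
    amplitude above resting, linearly interpolated between samples.
    """

    peak_amplitude: float   # mV
    ahp: float              # mV, magnitude >= 0
    half_width: float       # ms
    resting_potential: float  # mV


def _ols_slope_per_100pa(currents: np.ndarray, rates: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([currents / 100.0, np.ones_like(currents)])
    coef, *_ = np.linalg.lstsq(A, rates, rcond=None)
    return float(coef[0]), float(coef[1])


def io_curve(sweeps: list[ExcitabilitySweep],
             fit_range: tuple[float, float] | None = None) -> IOCurve:
    """Build the I–O curve and fit its slope by ordinary least squares.

    The default fit range runs from the first suprathreshold current
    (first sweep with a non-zero rate) to the largest current, so
    sub-threshold (zero-rate) sweeps do not drag the slope down.  When
    every sweep is silent the slope is 0 and a warning is issued.
    """
    if len(sweeps) < 3:
        raise InsufficientDataError("need at least 3 sweeps")
    order = np.argsort([s.injected_current for s in sweeps])
    currents = np.array([sweeps[i].injected_current for i in order])
    if np.unique(currents).size < 3:
        raise InsufficientDataError("need at least 3 distinct currents")
    rates = np.array([sweeps[i].rate for i in order])

    if fit_range is None:
        nonzero = np.nonzero(rates > 0)[0]
        if nonzero.size == 0:
            warnings.warn("all sweeps sub-threshold; slope set to 0")
            return IOCurve(currents=currents, rates=rates, slope=0.0,
                           fit_intercept=0.0,
                           fit_range=(float(currents[0]), float(currents[-1])))
        fit_range = (float(currents[nonzero[0]]), float(currents[-1]))

    sel = (currents >= fit_range[0]) & (currents <= fit_range[1])
    if sel.sum() < 3:
        raise InsufficientDataError("fewer than 3 points in the fit range")
    slope, intercept = _ols_slope_per_100pa(currents[sel], rates[sel])
    return IOCurve(currents=currents, rates=rates, slope=slope,
                   fit_intercept=intercept, fit_range=fit_range)


def io_slope(curve: IOCurve, fit_range: tuple[float, float] | None = None) -> float:
    """Excitability slope (Hz per 100 pA) over ``fit_range``.

    With no range given, returns the slope already fitted on the curve.
    """
    if fit_range is None:
        return curve.slope
    sel = (curve.currents >= fit_range[0]) & (curve.currents <= fit_range[1])
    if sel.sum() < 3:
        raise InsufficientDataError("fewer than 3 points in the fit range")
    slope, _ = _ols_slope_per_100pa(curve.currents[sel], curve.rates[sel])
    return slope


def _interp_crossing(t: np.ndarray, v: np.ndarray, i: int, level: float) -> float:
    """Time where v crosses `level` between samples i and i+1."""
    v0, v1 = v[i], v[i + 1]
    if v1 == v0:
        return float(t[i])
    return float(t[i] + (level - v0) / (v1 - v0) * (t[i + 1] - t[i]))


def ap_features(waveform: np.ndarray, sample_rate: float,
                resting_potential: float) -> APFeatures:
    """Measure the first action potential of a membrane-potential trace.

    The caller isolates a segment containing exactly one spike whose
    peak rises above 0 mV.  The half-width threshold is referenced to
    the resting potential (matching the AHP convention): width at
    ``resting + peak_amplitude / 2``.
    """
    v = np.asarray(waveform, dtype=float)
    if v.size < 3:
        raise InsufficientDataError("waveform too short")
    if v.max() <= 0.0:
        raise InsufficientDataError("no suprathreshold deflection (peak <= 0 mV)")
    t = np.arange(v.size) / sample_rate * 1000.0  # ms
    i_peak = int(np.argmax(v))
    peak_amplitude = float(v[i_peak] - resting_potential)
    after = v[i_peak:]
    ahp = float(max(0.0, resting_potential - after.min()))

    half_level = resting_potential + peak_amplitude / 2.0
    above = v > half_level
    # last up-crossing before the peak
    i_up = i_peak
    while i_up > 0 and above[i_up - 1]:
        i_up -= 1
    if i_up == 0 and above[0]:
        t_up = float(t[0])
    else:
        t_up = _interp_crossing(t, v, i_up - 1, half_level)
    # first down-crossing after the peak
    i_dn = i_peak
    while i_dn < v.size - 1 and above[i_dn + 1]:
        i_dn += 1
    if i_dn == v.size - 1 and above[-1]:
        t_dn = float(t[-1])
    else:
        t_dn = _interp_crossing(t, v, i_dn, half_level)
    return APFeatures(peak_amplitude=peak_amplitude, ahp=ahp,
                      half_width=float(t_dn - t_up),
                      resting_potential=resting_potential)
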
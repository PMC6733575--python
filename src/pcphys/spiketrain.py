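"""Spike-train statistics for Purkinje-cell recordings.

A Purkinje cell fires two kinds of action potentials: high-frequency
*simple spikes* (intrinsic and parallel-fiber driven, tens of Hz) and
*complex spikes* (climbing-fiber evoked, ~1 Hz).  This module computes the
standard descriptive statistics of labeled event-time trains — firing
rate, ISI coefficient of variation (CV), the local regularity measure
CV2, and the climbing-fiber pause — and classifies the simple-spike
response that follows each complex spike into one of four qualitative
types (normal / facilitation / suppression / oscillation).

Definitions
-----------
CV   = SD(ISI) / mean(ISI)                       (whole-recording regularity)
CV2  = mean over adjacent pairs of 2|ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i)
       (short-timescale regularity; each term is bounded by 2)
CF pause = latency from a complex spike to the first following simple
       spike; its consistent presence marks a single-unit recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, InsufficientDataError

__all__ = [
    "SpikeTrain",
    "ISIStats",
    "CFPauseResult",
    "PeriCSProfile",
    "SingleUnitReport",
    "isi_stats",
    "cs_stats",
    "cf_pause",
    "validate_single_unit",
    "peri_cs_profile",
    "classify_response",
    "RESPONSE_LABELS",
]

RESPONSE_LABELS = ("normal", "facilitation", "suppression", "oscillation")


@dataclass
class SpikeTrain:
    """Labeled simple/complex spike event times for one cell.

    Times are in seconds from recording onset; both lists are strictly
    increasing, disjoint, and confined to ``[0, duration]``.
    """

    simple_spike_times: np.ndarray
    complex_spike_times: np.ndarray
    duration: float
    cell_id: str = ""
    group: str = ""
    zebrin: str = "unknown"  # "Z+", "Z-" or "unknown"

    def __post_init__(self) -> None:
        self.simple_spike_times = np.asarray(self.simple_spike_times, dtype=float)
        self.complex_spike_times = np.asarray(self.complex_spike_times, dtype=float)
        if self.duration <= 0:
            raise ContractError("duration must be positive")
        for name, t in (
            ("simple_spike_times", self.simple_spike_times),
            ("complex_spike_times", self.complex_spike_times),
        ):
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ContractError(f"{name} outside [0, duration]")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ContractError(f"{name} must be strictly increasing")


@dataclass
class ISIStats:
    """Rate and ISI regularity of one event train.

    ``cv`` and ``mean_cv2`` are NaN when fewer than 3 spikes are available.
    """

    rate: float
    cv: float
    mean_cv2: float
    n_spikes: int
    n_isi: int


@dataclass
class CFPauseResult:
    """Climbing-fiber pause: per-CS first-following-SS latency, in ms."""

    mean_pause: float
    per_cs_pauses: np.ndarray
    n_cs_used: int


@dataclass
class SingleUnitReport:
    """Outcome of the single-unit check.

    ``status`` is True/False, or None (indeterminate) when the train has
    no complex spikes to test against.
    """

    status: bool | None
    violating_cs_times: np.ndarray
    n_cs_checked: int


@dataclass
class PeriCSProfile:
    """Simple-spike counts time-locked to complex spikes.

    ``bin_edges`` are in ms relative to each complex spike (default −100
    to +300).  ``counts`` sums spikes over all CS-aligned windows; spikes
    falling in overlapping windows are counted once per window.
    ``coverage`` gives, per bin, the number of windows that fully cover
    that bin inside the recording (truncated edge windows are handled by
    normalizing rates per-bin).  ``z_per_bin`` compares each bin count to
    the pre-CS baseline under a Poisson assumption.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    coverage: np.ndarray
    n_cs: int
    baseline_rate: float
    z_per_bin: np.ndarray
    rate_per_bin: np.ndarray
    pause_ms: float
    label: str | None = None
    bin_width: float = field(default=5.0)


# ---------------------------------------------------------------------------
# ISI statistics


def isi_stats(spike_times: np.ndarray, duration: float, ddof: int = 1) -> ISIStats:
    """Firing rate, CV and mean CV2 of one event train.

    Parameters
    ----------
    spike_times
        Sorted event times in seconds.
    duration
        Recording length in seconds; the rate denominator.
    ddof
        Delta degrees of freedom for the SD in CV (1 = sample SD,
        the default; 0 = population SD).

    With fewer than 3 spikes the rate is still returned but ``cv`` and
    ``mean_cv2`` are NaN (undefined).
    """
    t = np.asarray(spike_times, dtype=float)
    if duration <= 0:
        raise ContractError("duration must be positive")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ContractError("spike_times must be sorted")
    n = int(t.size)
    rate = n / duration
    if n < 3:
        return ISIStats(rate=rate, cv=np.nan, mean_cv2=np.nan, n_spikes=n,
                        n_isi=max(n - 1, 0))
    isi = np.diff(t)
    mean_isi = isi.mean()
    cv = float(isi.std(ddof=ddof) / mean_isi) if mean_isi > 0 else np.nan
    pair_sum = isi[1:] + isi[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2_terms = 2.0 * np.abs(np.diff(isi)) / pair_sum
    mean_cv2 = float(np.nanmean(cv2_terms))
    return ISIStats(rate=rate, cv=cv, mean_cv2=mean_cv2, n_spikes=n, n_isi=n - 1)


def cs_stats(train: SpikeTrain, ddof: int = 1) -> ISIStats:
    """`isi_stats` applied to the complex-spike train."""
    return isi_stats(train.complex_spike_times, train.duration, ddof=ddof)


# ---------------------------------------------------------------------------
# Climbing-fiber pause and single-unit check


def _first_following_latencies(train: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Latency (s) from each CS to the first following SS.

    Returns (cs_times_used, latencies); CSs with no later simple spike
    are dropped.
    """
    ss = train.simple_spike_times
    cs = train.complex_spike_times
    idx = np.searchsorted(ss, cs, side="right")
    ok = idx < ss.size
    return cs[ok], ss[idx[ok]] - cs[ok]


def cf_pause(train: SpikeTrain) -> CFPauseResult:
    """Mean climbing-fiber pause of a train, in ms.

    The pause is the duration between a complex spike and the first
    following simple spike; a trailing CS with no later SS is excluded.
    """
    cs_used, lat = _first_following_latencies(train)
    if lat.size == 0:
        raise InsufficientDataError(
            "no complex spike with a following simple spike")
    pauses_ms = lat * 1000.0
    return CFPauseResult(mean_pause=float(pauses_ms.mean()),
                         per_cs_pauses=pauses_ms, n_cs_used=int(lat.size))


def validate_single_unit(train: SpikeTrain, min_pause: float = 8.0) -> SingleUnitReport:
    """Check the single-unit criterion: every CS is followed by a pause.

    A recording is accepted as single-unit when, for every complex spike
    (except possibly a trailing one with no subsequent simple spike), the
    first following simple spike occurs at least ``min_pause`` ms later.

    Returns an indeterminate report (``status=None``) when the train has
    no complex spikes.
    """
    if min_pause <= 0:
        raise ContractError("min_pause must be positive")
    if train.complex_spike_times.size == 0:
        return SingleUnitReport(status=None,
                                violating_cs_times=np.empty(0), n_cs_checked=0)
    cs_used, lat = _first_following_latencies(train)
    violations = cs_used[lat * 1000.0 < min_pause]
    return SingleUnitReport(status=bool(violations.size == 0),
                            violating_cs_times=violations,
                            n_cs_checked=int(lat.size))


# ---------------------------------------------------------------------------
# Peri-complex-spike histogram and its four-way classification


def peri_cs_profile(
    train: SpikeTrain,
    window: tuple[float, float] = (-100.0, 300.0),
    bin_width: float = 5.0,
    min_cs: int = 10,
    baseline_window: tuple[float, float] = (-100.0, -10.0),
) -> PeriCSProfile:
    """Histogram of simple-spike activity time-locked to complex spikes.

    Parameters are in ms relative to each complex spike.  ``bin_width``
    must divide the window length.  The baseline rate is estimated from
    the pre-CS bins (default −100..−10 ms) and each bin is given a z
    score against the Poisson expectation ``baseline_rate × bin_width ×
    coverage``.  Complex spikes near the recording edges contribute
    truncated windows; per-bin rates are normalized by the number of
    windows fully covering each bin.
    """
    lo, hi = window
    if bin_width <= 0 or not np.isclose((hi - lo) / bin_width,
                                        round((hi - lo) / bin_width)):
        raise ContractError("bin_width must divide the window length")
    cs = train.complex_spike_times
    if cs.size < min_cs:
        raise InsufficientDataError(
            f"need at least {min_cs} complex spikes, got {cs.size}")
    ss = train.simple_spike_times
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)

    counts = np.zeros(n_bins, dtype=int)
    lo_s, hi_s = lo / 1000.0, hi / 1000.0
    for c in cs:
        rel = (ss[np.searchsorted(ss, c + lo_s):np.searchsorted(ss, c + hi_s)]
               - c) * 1000.0
        counts += np.histogram(rel, bins=edges)[0]

    # windows fully covering each bin inside [0, duration]
    cover_lo = cs[:, None] + edges[None, :-1] / 1000.0 >= 0.0
    cover_hi = cs[:, None] + edges[None, 1:] / 1000.0 <= train.duration
    coverage = (cover_lo & cover_hi).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        rate_per_bin = np.where(coverage > 0,
                                counts / (coverage * bin_width / 1000.0), np.nan)

    b0, b1 = baseline_window
    base_mask = (edges[:-1] >= b0) & (edges[1:] <= b1)
    base_cov = coverage[base_mask].sum()
    baseline_rate = (counts[base_mask].sum() / (base_cov * bin_width / 1000.0)
                     if base_cov > 0 else np.nan)

    expected = baseline_rate * (bin_width / 1000.0) * coverage
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(expected > 0, (counts - expected) / np.sqrt(expected), np.nan)

    try:
        pause_ms = float(np.percentile(cf_pause(train).per_cs_pauses, 5.0))
    except InsufficientDataError:
        pause_ms = 0.0

    return PeriCSProfile(bin_edges=edges, counts=counts, coverage=coverage,
                         n_cs=int(cs.size), baseline_rate=float(baseline_rate),
                         z_per_bin=z, rate_per_bin=rate_per_bin,
                         pause_ms=pause_ms, bin_width=bin_width)


def _has_run(mask: np.ndarray, length: int) -> bool:
    run = 0
    for m in mask:
        run = run + 1 if m else 0
        if run >= length:
            return True
    return False


def _oscillation_score(profile: PeriCSProfile, start_ms: float,
                       lag_range: tuple[float, float],
                       structure_guard: float = 0.2) -> float:
    """Largest qualifying secondary autocorrelation peak of the post-pause
    profile, or 0 when none qualifies.

    The mean-subtracted per-bin rate over ``start_ms``..+300 ms is
    autocorrelated with a shot-noise-corrected normalization: the
    expected Poisson counting variance of each bin rate is subtracted
    from the lag-0 denominator, so the correlation refers to the
    underlying rate modulation rather than being attenuated by counting
    noise.  When less than ``structure_guard`` of the raw variance
    survives the correction the profile carries no rate structure at
    all and the score is 0 (this rejects flat/normal profiles whose
    corrected normalization would otherwise divide by ~0).

    A secondary peak only qualifies if it is a local maximum at a lag
    inside ``lag_range`` *and* the autocorrelation dips below zero at
    some shorter lag; the dip requirement rejects the slowly decaying
    (box-like) autocorrelation of plain facilitation or suppression
    profiles.
    """
    edges = profile.bin_edges
    sel = (edges[:-1] >= start_ms) & np.isfinite(profile.rate_per_bin)
    x = profile.rate_per_bin[sel]
    if x.size < 10:
        return 0.0
    counts = profile.counts[sel]
    cov = profile.coverage[sel]
    x = x - x.mean()
    raw_var = float(np.sum(x * x))
    bw_s = profile.bin_width / 1000.0
    noise_var = float(np.sum(counts / (cov * bw_s) ** 2))
    denom = raw_var - noise_var
    if raw_var <= 0 or denom < structure_guard * raw_var:
        return 0.0
    n = x.size
    ac = np.array([np.sum(x[:n - l] * x[l:]) / denom for l in range(n)])
    bw = profile.bin_width
    lag_lo = max(1, int(np.floor(lag_range[0] / bw)))
    lag_hi = min(n - 2, int(np.ceil(lag_range[1] / bw)))
    best = 0.0
    for l in range(lag_lo, lag_hi + 1):
        if ac[l] > ac[l - 1] and ac[l] >= ac[l + 1] and np.min(ac[1:l]) < 0:
            best = max(best, float(ac[l]))
    return best


def classify_response(
    profile: PeriCSProfile,
    z_threshold: float = 2.0,
    n_consecutive: int = 3,
    mod_window: tuple[float, float] = (10.0, 100.0),
    osc_lag_range: tuple[float, float] = (30.0, 200.0),
    osc_threshold: float = 0.3,
) -> str:
    """Four-way classification of the post-CS simple-spike response.

    Decision rule (deterministic, reimplemented here — the qualitative
    taxonomy is established in the field but no published formula exists
    for it, so thresholds are explicit and configurable):

    * the climbing-fiber pause region (0..pause) is excluded; the
      effective start is ``max(mod_window[0], pause)`` rounded up to a
      bin edge;
    * **facilitation**: ≥ ``n_consecutive`` consecutive bins with
      z > +``z_threshold`` inside ``mod_window``;
    * **suppression**: same with z < −``z_threshold``;
    * **oscillation**: the autocorrelation of the mean-subtracted
      post-pause profile (start..300 ms) has a qualifying secondary peak
      > ``osc_threshold`` at a lag in ``osc_lag_range``;
    * precedence: oscillation > suppression > facilitation > normal.
    """
    if not np.isfinite(profile.baseline_rate) or profile.baseline_rate <= 0:
        raise InsufficientDataError("baseline rate undefined; cannot classify")
    bw = profile.bin_width
    start = max(mod_window[0], np.ceil(profile.pause_ms / bw) * bw)
    edges = profile.bin_edges
    in_mod = (edges[:-1] >= start) & (edges[1:] <= mod_window[1])
    z = profile.z_per_bin
    if np.any(~np.isfinite(z[in_mod])):
        warnings.warn("undefined z values inside the modulation window")

    if _oscillation_score(profile, start, osc_lag_range) > osc_threshold:
        return "oscillation"
    zm = np.where(np.isfinite(z[in_mod]), z[in_mod], 0.0)
    if _has_run(zm < -z_threshold, n_consecutive):
        return "suppression"
    if _has_run(zm > z_threshold, n_consecutive):
        return "facilitation"
    return "normal"
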
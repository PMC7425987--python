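"""Peak-based intercycle period stability and phase of entrainment.

The precision of a cellular circadian rhythm is quantified as the SD of
consecutive peak-to-peak intervals of the detrended trace, restricted to the
first three to four cycles so short- and long-period clones contribute
comparable cycle counts.  Under an imposed temperature (zeitgeber) cycle of
period T, the phase of entrainment is the stable timing of the daily peak
relative to the preceding warm-phase onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rhythm import TimeSeries


class InsufficientPeaksError(ValueError):
    """Fewer peaks than the analysis requires."""


def detect_peaks(
    detrended: TimeSeries,
    neighborhood: float = 8.0,
    min_separation: float = 16.0,
) -> np.ndarray:
    """Times of local maxima strictly dominating a +/- ``neighborhood`` window.

    A sample is a peak if it is strictly greater than every other sample
    within ``neighborhood`` hours on both sides (ties suppress both, except
    that on an exact tie between two candidate peaks the earlier survives the
    separation rule).  Surviving peaks closer than ``min_separation`` hours
    are resolved by keeping the higher (earlier on exact tie).
    """
    t = detrended.time
    y = detrended.values
    step = detrended.step
    k = max(int(round(neighborhood / step)), 1)
    n = len(y)
    candidates = []
    # only samples with a full +/- neighborhood qualify: edge-truncated
    # windows otherwise promote boundary samples to spurious peaks
    for i in range(k, n - k):
        lo, hi = i - k, i + k + 1
        window = y[lo:hi]
        # dominant within the neighbourhood; exact ties resolve to the
        # earliest sample (argmax returns the first maximum); flat windows
        # contain no peak
        if lo + int(np.argmax(window)) == i and window.max() > window.min():
            candidates.append(i)

    # enforce min_separation greedily by height (earlier wins exact ties)
    order = sorted(candidates, key=lambda i: (-y[i], t[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(t[i] - t[j]) >= min_separation for j in kept):
            kept.append(i)
    return t[np.array(sorted(kept), dtype=int)] if kept else np.array([])


@dataclass
class StabilityReport:
    """Intercycle period variability of one well."""

    well_id: str
    peak_times: np.ndarray
    intercycle_periods: np.ndarray
    intercycle_sd: float
    n_cycles_used: int

    def to_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "n_peaks": len(self.peak_times),
            "n_cycles_used": self.n_cycles_used,
            "mean_period_h": float(np.mean(self.intercycle_periods)),
            "intercycle_sd_h": self.intercycle_sd,
        }


def intercycle_sd(
    peaks: np.ndarray, max_cycles: int = 4, well_id: str = ""
) -> StabilityReport:
    """Sample SD of the first ``min(max_cycles, available)`` peak intervals.

    Requires at least four peaks (three cycles); uses at most four cycles so
    clones of different period contribute comparable cycle counts.
    """
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 4:
        raise InsufficientPeaksError(
            f"need >= 4 peaks (3 cycles); got {len(peaks)}"
        )
    intervals = np.diff(peaks)[: min(max_cycles, len(peaks) - 1)]
    return StabilityReport(
        well_id=well_id,
        peak_times=peaks,
        intercycle_periods=intervals,
        intercycle_sd=float(np.std(intervals, ddof=1)),
        n_cycles_used=len(intervals),
    )


def stability_report(
    detrended: TimeSeries,
    neighborhood: float = 8.0,
    min_separation: float = 16.0,
    max_cycles: int = 4,
) -> StabilityReport:
    """detect_peaks + intercycle_sd on one detrended trace."""
    peaks = detect_peaks(detrended, neighborhood, min_separation)
    return intercycle_sd(peaks, max_cycles=max_cycles, well_id=detrended.well_id)


@dataclass
class EntrainmentPhase:
    """Peak phases relative to warm-phase onsets under a zeitgeber T-cycle."""

    well_id: str
    zeitgeber_period: float
    warm_onset_times: np.ndarray
    daily_phases: np.ndarray  # hours in [0, T)
    mean_phase: float
    phase_sd: float

    def to_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "zeitgeber_period_h": self.zeitgeber_period,
            "n_cycles": len(self.daily_phases),
            "mean_phase_h": self.mean_phase,
            "phase_sd_h": self.phase_sd,
        }


def phase_of_entrainment(
    ts: TimeSeries,
    T: float,
    warm_onset0: float = 0.0,
    neighborhood: float = 8.0,
) -> EntrainmentPhase:
    """Per-cycle peak phase relative to warm onsets; cycle 1 is a transient.

    Warm onsets occur at ``warm_onset0 + k*T``.  For every zeitgeber cycle
    after the first, the phase is (peak time − preceding warm onset) mod T;
    cycles without a detected peak are skipped with a warning.
    """
    span = ts.time[-1] - warm_onset0
    if span < 3 * T:
        raise InsufficientPeaksError("recording must span >= 3 zeitgeber cycles")
    peaks = detect_peaks(ts, neighborhood=neighborhood, min_separation=T / 2.0)
    n_cycles = int(span // T)
    onsets = warm_onset0 + T * np.arange(n_cycles)
    phases = []
    used_onsets = []
    for k in range(1, n_cycles):  # discard the first (entrainment transient)
        lo, hi = onsets[k], onsets[k] + T
        inside = peaks[(peaks >= lo) & (peaks < hi)]
        if len(inside) == 0:
            warnings.warn(
                f"no peak inside zeitgeber cycle {k} [{lo:g}, {hi:g}) h",
                stacklevel=2,
            )
            continue
        phases.append(float((inside[0] - lo) % T))
        used_onsets.append(lo)
    if not phases:
        raise InsufficientPeaksError("no zeitgeber cycle contained a peak")
    phases_arr = np.array(phases)
    return EntrainmentPhase(
        well_id=ts.well_id,
        zeitgeber_period=T,
        warm_onset_times=np.array(used_onsets),
        daily_phases=phases_arr,
        mean_phase=float(phases_arr.mean()),
        phase_sd=float(phases_arr.std(ddof=1)) if len(phases_arr) > 1 else 0.0,
    )
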
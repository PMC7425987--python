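"""Detrending and damped-oscillator fitting of bioluminescence rhythms.

A raw plate-luminometer trace is detrended by a centred 24-h moving average
(ratio detrend: value/trend − 1), which truncates half a window at each end
of the recording.  The dimensionless residual is fitted by nonlinear least
squares to a damped cosine

    y(t) = A exp(-gamma t) cos(2 pi f t + phi)

with t rebased to zero at the start of the detrended window.  The fit is
multi-started over a grid of candidate periods plus a periodogram peak, since
the residual-sum-of-squares surface is multimodal in frequency.  Reported
parameters: relative amplitude A (detrended scale at window start), damping
gamma (1/h), period tau = 1/f (h), phase phi in [−pi, pi), and the MESOR
(mean of the raw trace over the full recording).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

PERIOD_BOUNDS = (16.0, 40.0)
DEFAULT_START_PERIODS = (20.0, 22.0, 24.0, 26.0, 28.0)


class InputTooShortError(ValueError):
    """Recording too short for the requested operation."""


class DegenerateTraceError(ValueError):
    """Trace unusable (zero/negative trend, mixed grids, ...)."""


@dataclass
class TimeSeries:
    """A uniformly sampled single-well trace (time in hours)."""

    time: np.ndarray
    values: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.values.shape:
            raise ValueError("time and values must be 1-D and equal length")
        if len(self.time) >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(steps) > 1e-9:
                raise ValueError("time grid must be uniform (within 1e-9 h)")

    @property
    def step(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])


def detrend(ts: TimeSeries, window: float = 24.0) -> TimeSeries:
    """Ratio-detrend by a centred moving average of width ``window`` hours.

    Output value = raw/trend − 1; the first and last window/2 hours (where the
    full window does not fit) are truncated, so a 168-h recording detrended
    with the default window spans [12, 156] h.
    """
    if ts.span <= window:
        raise InputTooShortError(
            f"recording span {ts.span:g} h must exceed window {window:g} h"
        )
    step = ts.step
    half = int(round(window / 2.0 / step))
    if half < 1:
        raise InputTooShortError("window must cover at least two samples")
    n = len(ts.time)
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    trend = np.convolve(ts.values, kernel, mode="valid")  # length n - 2*half
    if np.any(trend == 0):
        raise DegenerateTraceError("zero trend value in moving average")
    sl = slice(half, n - half)
    return TimeSeries(
        time=ts.time[sl],
        values=ts.values[sl] / trend - 1.0,
        well_id=ts.well_id,
    )


@dataclass
class RhythmFit:
    """Best-fit damped-cosine parameters for one well."""

    amplitude: float
    damping: float
    period: float
    phase: float
    mesor: float
    fit_rmse: float
    converged: bool
    at_boundary: bool = False
    well_id: str = ""
    n_points: int = 0
    message: str = ""

    @property
    def frequency(self) -> float:
        return 1.0 / self.period if self.period else math.nan

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Model curve on the rebased time axis used in fitting."""
        return self.amplitude * np.exp(-self.damping * t) * np.cos(
            2 * math.pi * self.frequency * t + self.phase
        )

    def summary(self) -> str:
        lines = [
            f"Damped-oscillator fit: well {self.well_id or '<unnamed>'}",
            "-" * 48,
            f"period tau        {self.period:10.3f} h",
            f"rel. amplitude A  {self.amplitude:10.4f}",
            f"damping gamma     {self.damping:10.5f} /h",
            f"phase phi         {self.phase:10.4f} rad",
            f"MESOR             {self.mesor:10.2f} counts/s",
            f"fit RMSE          {self.fit_rmse:10.5f}",
            f"converged         {self.converged!s:>10}"
            + ("  (period at search bound)" if self.at_boundary else ""),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "period_h": self.period,
            "relative_amplitude": self.amplitude,
            "damping_per_h": self.damping,
            "phase_rad": self.phase,
            "mesor": self.mesor,
            "fit_rmse": self.fit_rmse,
            "converged": self.converged,
            "at_boundary": self.at_boundary,
        }


def _wrap_phase(phi: float) -> float:
    return (phi + math.pi) % (2 * math.pi) - math.pi


def _fold_sign(a: float, phi: float) -> tuple[float, float]:
    """Fold a negative amplitude into a pi phase shift (A >= 0 convention)."""
    if a < 0:
        return -a, _wrap_phase(phi + math.pi)
    return a, _wrap_phase(phi)


def _spectral_period_guess(t: np.ndarray, y: np.ndarray) -> float | None:
    """Periodogram argmax restricted to the circadian search band."""
    n = len(y)
    dt = t[1] - t[0]
    freqs = np.fft.rfftfreq(n, d=dt)
    power = np.abs(np.fft.rfft(y - y.mean())) ** 2
    band = (freqs >= 1.0 / PERIOD_BOUNDS[1]) & (freqs <= 1.0 / PERIOD_BOUNDS[0])
    if not band.any():
        return None
    f = freqs[band][np.argmax(power[band])]
    return 1.0 / f if f > 0 else None


class DampedOscillator:
    """Damped-cosine model of a detrended bioluminescence rhythm.

    Parameters
    ----------
    detrended : TimeSeries
        Output of :func:`detrend` (dimensionless, centred near 0).
    mesor : float, optional
        Mean of the raw trace over the full recording; stored on the results
        object for reporting (the fit itself is on the detrended scale).
    min_cycles : float, optional
        Minimum number of oscillation cycles (at the shortest searchable
        period) the span must contain; windowed amplitude fits relax this.
    """

    def __init__(
        self,
        detrended: TimeSeries,
        mesor: float = math.nan,
        min_cycles: float = 2.0,
    ):
        if len(detrended.time) < 8:
            raise InputTooShortError("too few samples to fit")
        if detrended.span < min_cycles * PERIOD_BOUNDS[0]:
            raise InputTooShortError(
                f"need at least {min_cycles:g} oscillation cycles in the span"
            )
        self.data = detrended
        self.mesor = mesor
        # rebase time to 0 at window start: A is amplitude at window start
        self._t = detrended.time - detrended.time[0]
        self._y = detrended.values

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        a, gamma, f, phi = theta
        return a * np.exp(-gamma * self._t) * np.cos(
            2 * math.pi * f * self._t + phi
        ) - self._y

    def fit(
        self,
        start_periods: tuple[float, ...] = DEFAULT_START_PERIODS,
        fix_damping: float | None = None,
    ) -> RhythmFit:
        """Multi-start nonlinear least squares; lowest-RMSE converged fit wins.

        ``fix_damping`` pins gamma (used for windowed amplitude estimates with
        gamma = 0).
        """
        t, y = self._t, self._y
        n = len(y)
        guesses = list(start_periods)
        spec = _spectral_period_guess(t, y)
        if spec is not None:
            guesses.append(spec)

        a0 = max(float(np.sqrt(2.0) * y.std()), 1e-6)
        best: RhythmFit | None = None
        flo, fhi = 1.0 / PERIOD_BOUNDS[1], 1.0 / PERIOD_BOUNDS[0]
        for tau0 in guesses:
            tau0 = min(max(tau0, PERIOD_BOUNDS[0] * 1.01), PERIOD_BOUNDS[1] * 0.99)
            if fix_damping is None:
                x0 = [a0, 0.01, 1.0 / tau0, 0.0]
                lb = [0.0, -0.05, flo, -2 * math.pi]
                ub = [np.inf, 0.5, fhi, 2 * math.pi]

                def fun(th):
                    return self._residuals(th)
            else:
                x0 = [a0, 1.0 / tau0, 0.0]
                lb = [0.0, flo, -2 * math.pi]
                ub = [np.inf, fhi, 2 * math.pi]

                def fun(th):
                    return self._residuals(
                        np.array([th[0], fix_damping, th[1], th[2]])
                    )

            try:
                res = least_squares(fun, x0, bounds=(lb, ub), max_nfev=2000)
            except Exception:  # pragma: no cover - scipy failure path
                continue
            if not res.success:
                continue
            rmse = float(np.sqrt(np.mean(res.fun**2)))
            if fix_damping is None:
                a, gamma, f, phi = res.x
            else:
                a, (gamma, f, phi) = res.x[0], (fix_damping, res.x[1], res.x[2])
            a, phi = _fold_sign(float(a), float(phi))
            fit = RhythmFit(
                amplitude=a,
                damping=float(gamma),
                period=1.0 / float(f),
                phase=phi,
                mesor=self.mesor,
                fit_rmse=rmse,
                converged=True,
                well_id=self.data.well_id,
                n_points=n,
            )
            if best is None or rmse < best.fit_rmse:
                best = fit

        if best is None:
            return RhythmFit(
                amplitude=math.nan,
                damping=math.nan,
                period=math.nan,
                phase=math.nan,
                mesor=self.mesor,
                fit_rmse=math.nan,
                converged=False,
                well_id=self.data.well_id,
                n_points=n,
                message="no start converged",
            )
        rel = 1e-4
        if (
            best.period <= PERIOD_BOUNDS[0] * (1 + rel)
            or best.period >= PERIOD_BOUNDS[1] * (1 - rel)
        ):
            best.at_boundary = True
        return best


def fit_damped_oscillator(
    detrended: TimeSeries, mesor: float = math.nan
) -> RhythmFit:
    """Convenience wrapper: ``DampedOscillator(detrended, mesor).fit()``."""
    return DampedOscillator(detrended, mesor=mesor).fit()


def window_amplitude(
    detrended: TimeSeries, window_start: float, window_len: float = 24.0
) -> float:
    """Relative amplitude within a sub-window, from an undamped cosine fit.

    Used to compare early- vs late-recording rhythm amplitude (for example,
    day 1 vs day 6 of a week-long recording); gamma is fixed to 0 so A is the
    window's stationary amplitude.
    """
    t0, t1 = window_start, window_start + window_len
    if t0 < detrended.time[0] - 1e-9 or t1 > detrended.time[-1] + 1e-9:
        raise ValueError(
            f"window [{t0:g}, {t1:g}] h outside detrended span "
            f"[{detrended.time[0]:g}, {detrended.time[-1]:g}] h"
        )
    mask = (detrended.time >= t0 - 1e-9) & (detrended.time <= t1 + 1e-9)
    sub = TimeSeries(
        time=detrended.time[mask],
        values=detrended.values[mask],
        well_id=detrended.well_id,
    )
    fit = DampedOscillator(sub, min_cycles=0.0).fit(fix_damping=0.0)
    if not fit.converged:
        raise DegenerateTraceError("window fit did not converge")
    return fit.amplitude


def amplitude_percent_reduction(early: float, late: float) -> float:
    """Percent collapse of rhythm amplitude: 100 * (1 - late/early)."""
    if early == 0:
        raise ZeroDivisionError("early amplitude is zero")
    return 100.0 * (1.0 - late / early)


def summarize_plate(
    plate: list[TimeSeries], window: float = 24.0
) -> pd.DataFrame:
    """Detrend + fit every well of a plate sharing one time grid.

    Non-converged wells are retained with ``converged = False``.
    """
    if not plate:
        return pd.DataFrame(
            columns=[
                "well_id", "period_h", "relative_amplitude", "damping_per_h",
                "phase_rad", "mesor", "fit_rmse", "converged", "at_boundary",
            ]
        )
    ref = plate[0].time
    rows = []
    for ts in plate:
        if len(ts.time) != len(ref) or np.max(np.abs(ts.time - ref)) > 1e-9:
            raise DegenerateTraceError(
                f"well {ts.well_id!r} is not on the shared time grid"
            )
        mesor = float(ts.values.mean())
        try:
            fit = DampedOscillator(detrend(ts, window=window), mesor=mesor).fit()
        except (InputTooShortError, DegenerateTraceError) as exc:
            fit = RhythmFit(
                amplitude=math.nan, damping=math.nan, period=math.nan,
                phase=math.nan, mesor=mesor, fit_rmse=math.nan,
                converged=False, well_id=ts.well_id, message=str(exc),
            )
        rows.append(fit.to_dict())
    return pd.DataFrame(rows)
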
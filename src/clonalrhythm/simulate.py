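"""Synthetic clonal pedigrees, bioluminescence traces, and expression panels.

The generators emulate a laboratory-selection study of clonal circadian-period
heterogeneity in cultured reporter cells: a founding culture is single-cell
cloned, each clone's bioluminescence rhythm is recorded for about a week, and
clones are re-cloned over several assay generations.  A clone's period is
modelled as

    tau = g + e,        g ~ heritable value,  e ~ N(0, sigma_NH^2)

where the heritable value g is transmitted from parent to progeny with a small
truncated-Gaussian drift (sigma_m) confined to ``period_bounds``.  The variance
of g across clones (V_H = sigma_H^2) and of e (V_NH = sigma_NH^2) are the
quantities the downstream variance partition estimates.

Bioluminescence traces follow a damped cosine riding on a slowly decaying
baseline whose level increases with period (long-period clones are brighter),
with multiplicative lognormal photon noise.  Expression panels mimic a digital
probe-count platform: endogenous genes whose mean log2 count depends on the
clone period linearly or as an inverted U, plus positive, negative, and
housekeeping control probes and a per-sample technical scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the clonal-period and trace generators.

    Periods are in hours.  ``heritable_sd`` (sigma_H) is the SD of heritable
    values among founders, ``nonheritable_sd`` (sigma_NH) the SD of the
    per-measurement stochastic component, and ``lineage_jitter_sd`` (sigma_m)
    the SD of the heritable drift applied at each subcloning.  Heritable
    values are confined to ``period_bounds`` by truncated-normal sampling.
    """

    founding_mean_period: float = 24.6
    heritable_sd: float = 0.8
    nonheritable_sd: float = 0.66
    lineage_jitter_sd: float = 0.2
    period_bounds: tuple[float, float] = (22.0, 28.0)
    sampling_interval: float = 0.5
    recording_span: float = 168.0
    amplitude0: float = 0.5
    damping0: float = 0.025
    mesor0: float = 1000.0
    mesor_period_slope: float = 120.0
    noise_cv: float = 0.05
    trend_decay: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.period_bounds
        if not lo < self.founding_mean_period < hi:
            raise ConfigurationError(
                f"founding_mean_period {self.founding_mean_period} outside "
                f"period_bounds {self.period_bounds}"
            )
        for name in ("heritable_sd", "nonheritable_sd", "lineage_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be > 0")
        if self.recording_span < 72.0:
            raise ConfigurationError("recording_span must be >= 72 h")

    def mesor(self, period: float) -> float:
        """Baseline level for a clone of the given period (counts/s)."""
        m = self.mesor0 + self.mesor_period_slope * (
            period - self.founding_mean_period
        )
        if m <= 0:
            raise ConfigurationError(
                f"mesor {m:.3g} <= 0 for period {period} h; adjust mesor0 or "
                "mesor_period_slope"
            )
        return m


@dataclass(frozen=True)
class CloneRecord:
    """One clonal line: pedigree position and its period decomposition."""

    clone_id: str
    generation: int
    parent_id: str | None
    heritable_period: float  # g, hours
    realized_period: float  # tau = g + e, hours
    group_label: str = "unselected"

    def __post_init__(self) -> None:
        if self.realized_period <= 0:
            raise ConfigurationError("realized_period must be > 0")
        if (self.parent_id is None) != (self.generation == 0):
            raise ConfigurationError(
                "parent_id must be None exactly for generation-0 founders"
            )


def _truncnorm(
    rng: np.random.Generator,
    mean: np.ndarray | float,
    sd: float,
    bounds: tuple[float, float],
    size: int | None = None,
) -> np.ndarray:
    """Truncated-normal draws confined to ``bounds``; degenerate sd clips."""
    lo, hi = bounds
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return np.clip(mean, lo, hi) if size is None else np.clip(
            np.broadcast_to(mean, (size,)), lo, hi
        )
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    u = rng.random(size if size is not None else mean.shape)
    # inverse-CDF sampling keeps the draw fully determined by rng
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_pedigree(
    config: SimConfig,
    n_founders: int,
    progeny_per_parent: int,
    n_generations: int,
    rng: np.random.Generator | None = None,
) -> list[CloneRecord]:
    """Simulate a clonal pedigree of ``n_generations`` rounds of subcloning.

    Founders draw heritable values from a truncated N(founding_mean_period,
    sigma_H^2); each subcloning adds truncated-Gaussian drift with SD sigma_m.
    Realized periods add fresh N(0, sigma_NH^2) noise.  ``n_generations = 0``
    returns founders only.
    """
    if n_founders < 1 or progeny_per_parent < 1 or n_generations < 0:
        raise ConfigurationError("counts must be >= 1 (n_generations >= 0)")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    records: list[CloneRecord] = []
    g0 = _truncnorm(
        rng,
        config.founding_mean_period,
        config.heritable_sd,
        config.period_bounds,
        size=n_founders,
    )
    e0 = rng.normal(0.0, config.nonheritable_sd, size=n_founders)
    current = [
        CloneRecord(f"G0-{i:03d}", 0, None, float(g0[i]), float(g0[i] + e0[i]))
        for i in range(n_founders)
    ]
    records.extend(current)

    for gen in range(1, n_generations + 1):
        nxt: list[CloneRecord] = []
        for parent in current:
            g = _truncnorm(
                rng,
                parent.heritable_period,
                config.lineage_jitter_sd,
                config.period_bounds,
                size=progeny_per_parent,
            )
            e = rng.normal(0.0, config.nonheritable_sd, size=progeny_per_parent)
            for j in range(progeny_per_parent):
                nxt.append(
                    CloneRecord(
                        f"G{gen}-{parent.clone_id}-{j:03d}",
                        gen,
                        parent.clone_id,
                        float(g[j]),
                        float(g[j] + e[j]),
                    )
                )
        records.extend(nxt)
        current = nxt
    return records


def pedigree_to_frame(records: list[CloneRecord]) -> pd.DataFrame:
    """Tidy pedigree table (one row per clone)."""
    return pd.DataFrame(
        {
            "clone_id": [r.clone_id for r in records],
            "generation": [r.generation for r in records],
            "parent_id": [r.parent_id if r.parent_id is not None else "" for r in records],
            "group_label": [r.group_label for r in records],
            "heritable_period": [r.heritable_period for r in records],
            "realized_period": [r.realized_period for r in records],
        }
    )


def generate_trace(
    clone: CloneRecord,
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Simulate one well's bioluminescence recording.

    values = trend(t) * [1 + A exp(-gamma t) cos(2 pi t / tau + phi)] * noise,
    trend(t) = mesor(tau) * exp(-trend_decay * t), noise lognormal with unit
    mean and CV ``noise_cv``.  Phase is drawn uniformly unless noise_cv is 0,
    in which case phi = 0 so the noiseless trace is an exact oracle.
    """
    from .rhythm import TimeSeries  # local import to avoid a cycle

    tau = clone.realized_period
    if not 16.0 < tau < 40.0:
        raise ConfigurationError(f"realized period {tau:.2f} h outside (16, 40)")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = int(round(config.recording_span / config.sampling_interval)) + 1
    t = np.arange(n) * config.sampling_interval
    mesor = config.mesor(tau)
    trend = mesor * np.exp(-config.trend_decay * t)
    phi = 0.0 if config.noise_cv == 0 else float(rng.uniform(-math.pi, math.pi))
    osc = 1.0 + config.amplitude0 * np.exp(-config.damping0 * t) * np.cos(
        2 * math.pi * t / tau + phi
    )
    values = trend * osc
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        values = values * rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    return TimeSeries(time=t, values=values, well_id=clone.clone_id)


def generate_plate(
    clones: list[CloneRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """One trace per clone on a shared time grid."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [generate_trace(c, config, rng) for c in clones]


# --- expression panel -------------------------------------------------------

ARCHETYPES = ("linear_pos", "linear_neg", "inverted_U", "flat")

#: 19-gene circadian panel: genes whose mean expression tracks the clone
#: period linearly (either sign), peaks at intermediate periods (inverted U),
#: or is period-independent.
DEFAULT_GENE_ARCHETYPES: dict[str, str] = {
    "ARNTL2": "linear_pos",
    "BHLHE40": "linear_pos",
    "DBP": "linear_neg",
    "NR1D2": "linear_neg",
    "PER2": "linear_neg",
    "NR1D1": "inverted_U",
    "CLOCK": "inverted_U",
    "CSNK1D": "inverted_U",
    "CIPC": "inverted_U",
    "NFIL3": "inverted_U",
    "PER1": "flat",
    "PER3": "flat",
    "CRY1": "flat",
    "CRY2": "flat",
    "ARNTL": "flat",
    "NPAS2": "flat",
    "RORA": "flat",
    "TEF": "flat",
    "HLF": "flat",
}


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the probe-count panel generator.

    ``slope`` is in log2 counts per hour of period deviation from 24.6 h for
    linear archetypes; inverted-U genes fall off quadratically from
    ``peak_period``.  A lognormal per-sample technical scale (SD
    ``sample_scale_sd`` on the log scale) multiplies endogenous, positive
    control and housekeeping counts — the quantity normalization must remove.
    """

    gene_archetypes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GENE_ARCHETYPES)
    )
    slope: float = 0.35
    peak_period: float = 25.0
    inverted_u_curvature: float = 0.25  # log2 counts per h^2
    base_log2: float = 9.0
    dispersion: float = 0.15
    housekeeping_dispersion: float = 0.05  # stable reference genes
    positive_control_levels: tuple[float, ...] = (
        128.0, 512.0, 2048.0, 8192.0, 32768.0, 131072.0,
    )
    negative_mean: float = 20.0
    housekeeping_base: float = 4096.0
    n_housekeeping: int = 4
    n_negative: int = 8
    sample_scale_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.dispersion < 0 or self.sample_scale_sd < 0:
            raise ConfigurationError("dispersions must be >= 0")
        if self.negative_mean <= 0 or self.housekeeping_base <= 0:
            raise ConfigurationError("count parameters must be > 0")
        if len(self.positive_control_levels) < 2:
            raise ConfigurationError(">= 2 positive-control probes required")
        if self.n_negative < 2 or self.n_housekeeping < 2:
            raise ConfigurationError(">= 2 negative and housekeeping probes required")
        bad = set(self.gene_archetypes.values()) - set(ARCHETYPES)
        if bad:
            raise ConfigurationError(f"unknown archetypes: {sorted(bad)}")
        if len(self.gene_archetypes) < 1:
            raise ConfigurationError(">= 1 endogenous gene required")


@dataclass
class CountMatrix:
    """Samples x probes nonnegative integer counts with probe annotation."""

    counts: pd.DataFrame  # samples x probes
    probe_class: pd.Series  # probe -> {endogenous, positive, negative, housekeeping}
    periods: pd.Series | None = None  # sample -> clone period, hours

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.probe_class.index):
            self.probe_class = self.probe_class.reindex(self.counts.columns)
        if self.probe_class.isna().any():
            raise ConfigurationError("every probe needs a class annotation")
        if (self.counts.values < 0).any():
            raise ConfigurationError("counts must be nonnegative")
        for cls in ("positive", "negative", "housekeeping"):
            if (self.probe_class == cls).sum() < 2:
                raise ConfigurationError(f"need >= 2 probes of class {cls!r}")

    def probes_of(self, cls: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])


def expected_log2_expression(
    archetype: str, period: float, config: ExpressionSimConfig
) -> float:
    """Noise-free mean log2 count of a gene for a clone of the given period."""
    d = period - 24.6
    if archetype == "linear_pos":
        return config.base_log2 + config.slope * d
    if archetype == "linear_neg":
        return config.base_log2 - config.slope * d
    if archetype == "inverted_U":
        return config.base_log2 - config.inverted_u_curvature * (
            period - config.peak_period
        ) ** 2
    if archetype == "flat":
        return config.base_log2
    raise ConfigurationError(f"unknown archetype {archetype!r}")


def generate_expression_panel(
    clones: list[CloneRecord],
    config: ExpressionSimConfig,
    seed: int,
) -> CountMatrix:
    """Simulate a probe-count panel across a clone panel.

    Endogenous and control probes share a per-sample lognormal technical scale
    (except negative controls, which are scale-independent background).
    """
    if len(clones) < 2:
        raise ConfigurationError(">= 2 clones required")
    rng = np.random.default_rng(seed)
    genes = list(config.gene_archetypes)
    pos = [f"POS_{chr(65 + i)}" for i in range(len(config.positive_control_levels))]
    neg = [f"NEG_{chr(65 + i)}" for i in range(config.n_negative)]
    hk = [f"HK_{i + 1}" for i in range(config.n_housekeeping)]
    probes = genes + pos + neg + hk
    classes = pd.Series(
        ["endogenous"] * len(genes)
        + ["positive"] * len(pos)
        + ["negative"] * len(neg)
        + ["housekeeping"] * len(hk),
        index=probes,
    )

    rows = []
    periods = []
    for clone in clones:
        tau = clone.realized_period
        periods.append(tau)
        scale = float(rng.lognormal(0.0, config.sample_scale_sd))
        row = {}
        for gene in genes:
            mu = expected_log2_expression(config.gene_archetypes[gene], tau, config)
            noisy = mu + rng.normal(0.0, config.dispersion)
            row[gene] = scale * 2.0**noisy
        for p, level in zip(pos, config.positive_control_levels):
            row[p] = scale * level * float(
                rng.lognormal(-0.5 * 0.05**2, 0.05)
            )
        for p in neg:
            row[p] = rng.poisson(config.negative_mean)
        for p in hk:
            noisy = math.log2(config.housekeeping_base) + rng.normal(
                0.0, config.housekeeping_dispersion
            )
            row[p] = scale * 2.0**noisy
        rows.append(row)

    counts = pd.DataFrame(rows, index=[c.clone_id for c in clones], columns=probes)
    counts = counts.round().clip(lower=0).astype(int)
    return CountMatrix(
        counts=counts,
        probe_class=classes,
        periods=pd.Series(periods, index=counts.index, name="period_h"),
    )


def spread_clone_panel(
    n_clones: int = 25,
    period_range: tuple[float, float] = (22.0, 28.0),
) -> list[CloneRecord]:
    """Deterministic clone panel with periods evenly spanning a range.

    Convenience for expression-analysis demonstrations where the clone panel's
    period spread (not its pedigree) is what matters.
    """
    taus = np.linspace(period_range[0], period_range[1], n_clones)
    return [
        CloneRecord(f"CL{i + 1:02d}", 0, None, float(tau), float(tau))
        for i, tau in enumerate(taus)
    ]
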
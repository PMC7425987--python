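"""Broad-sense heritability from one-way variance partitioning.

For a set of parental clones each assayed through n progeny subclones, the
one-way ANOVA mean squares decompose the phenotypic variance V_P = V_H + V_NH
into a heritable (between-parent) and a nonheritable (within-parent)
component:

    MS_b = V_NH + n * V_H        =>  V_H = (MS_b - MS_w) / n
    MS_w = V_NH

and broad-sense heritability H^2 = V_H / (V_H + V_NH).  Subclones of a parent
are genetically identical, so within-parent spread estimates the nonheritable
component.  Unbalanced designs replace n by the Sokal-Rohlf effective group
size n0 = (N - sum(n_i^2)/N) / (a - 1).  A negative method-of-moments V_H is
truncated to 0 so H^2 stays in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """Invalid parent-progeny design (too few groups or progeny)."""


@dataclass
class VarianceComponents:
    """Results of a one-way parent-progeny variance partition."""

    a: int  # number of parental clones
    n: float  # progeny per parent (n0 if unbalanced)
    balanced: bool
    MS_b: float
    MS_w: float
    V_H: float
    V_NH: float
    H2: float
    trait_name: str = "period_h"
    SS_b: float = math.nan
    SS_w: float = math.nan
    N: int = 0

    @classmethod
    def from_components(
        cls, V_H: float, V_NH: float, trait_name: str = "period_h"
    ) -> "VarianceComponents":
        """Heritability arithmetic from already-estimated variance components."""
        if V_H < 0 or V_NH < 0:
            raise ValueError("variance components must be >= 0")
        vp = V_H + V_NH
        return cls(
            a=0, n=math.nan, balanced=True, MS_b=math.nan, MS_w=V_NH,
            V_H=V_H, V_NH=V_NH, H2=(V_H / vp) if vp > 0 else 0.0,
            trait_name=trait_name,
        )

    def summary(self) -> str:
        design = "balanced" if self.balanced else "unbalanced (n0)"
        return "\n".join(
            [
                f"Variance partition: trait {self.trait_name!r}",
                "-" * 48,
                f"parents a            {self.a:>8d}   design: {design}",
                f"progeny per parent n {self.n:>8.3f}",
                f"MS_between           {self.MS_b:>8.4f}",
                f"MS_within            {self.MS_w:>8.4f}",
                f"V_H (heritable)      {self.V_H:>8.4f}",
                f"V_NH (nonheritable)  {self.V_NH:>8.4f}",
                f"H2 = V_H/(V_H+V_NH)  {self.H2:>8.3f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "trait_name": self.trait_name,
            "a": self.a,
            "n": self.n,
            "balanced": self.balanced,
            "MS_b": self.MS_b,
            "MS_w": self.MS_w,
            "V_H": self.V_H,
            "V_NH": self.V_NH,
            "H2": self.H2,
        }


def variance_partition(
    table: pd.DataFrame,
    parent_col: str = "parent_id",
    value_col: str = "value",
    trait_name: str | None = None,
) -> VarianceComponents:
    """One-way ANOVA variance partition of a parent-progeny trait table.

    ``table`` has one row per progeny with its parent's id and trait value.
    Every parent needs >= 2 progeny and at least two parents are required.
    """
    if not np.isfinite(table[value_col].to_numpy(dtype=float)).all():
        raise DesignError("trait values must be finite")
    groups = {
        pid: sub[value_col].to_numpy(dtype=float)
        for pid, sub in table.groupby(parent_col, sort=True)
    }
    a = len(groups)
    if a < 2:
        raise DesignError(f"need >= 2 parental clones, got {a}")
    for pid, vals in groups.items():
        if len(vals) < 2:
            raise DesignError(f"parent {pid!r} has only {len(vals)} progeny (need >= 2)")

    sizes = np.array([len(v) for v in groups.values()], dtype=float)
    N = int(sizes.sum())
    grand = np.concatenate(list(groups.values())).mean()
    ss_b = float(sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values()))
    ss_w = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    ms_b = ss_b / (a - 1)
    ms_w = ss_w / (N - a)

    balanced = bool(np.all(sizes == sizes[0]))
    n_eff = float(sizes[0]) if balanced else float(
        (N - (sizes**2).sum() / N) / (a - 1)
    )
    v_h = max((ms_b - ms_w) / n_eff, 0.0)
    v_nh = ms_w
    vp = v_h + v_nh
    return VarianceComponents(
        a=a,
        n=n_eff,
        balanced=balanced,
        MS_b=ms_b,
        MS_w=ms_w,
        V_H=v_h,
        V_NH=v_nh,
        H2=(v_h / vp) if vp > 0 else 0.0,
        trait_name=trait_name or value_col,
        SS_b=ss_b,
        SS_w=ss_w,
        N=N,
    )


def heritability_by_generation(
    pedigree: pd.DataFrame,
    trait_col: str = "realized_period",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Variance partition per (generation, group) cell of a pedigree table.

    For each generation g >= 1, progeny of generation g are grouped by their
    parent and partitioned.  Cells that cannot be partitioned (a single
    parent, or a parent with one progeny) are reported with a reason instead
    of a result.
    """
    required = {"clone_id", "parent_id", "generation", trait_col}
    missing = required - set(pedigree.columns)
    if missing:
        raise DesignError(f"pedigree table missing columns: {sorted(missing)}")
    known = set(pedigree["clone_id"])
    nonfounders = pedigree[pedigree["generation"] > 0]
    bad = set(nonfounders["parent_id"]) - known
    if bad:
        raise DesignError(f"unresolvable parent links: {sorted(bad)[:5]}")

    rows = []
    group_iter = (
        nonfounders.groupby(["generation", group_col], sort=True)
        if group_col
        else ((gen, sub) for gen, sub in nonfounders.groupby("generation", sort=True))
    )
    for key, sub in group_iter:
        gen, grp = key if group_col else (key, "")
        tab = sub.rename(columns={trait_col: "value"})[["parent_id", "value"]]
        row = {"generation": gen, "group": grp, "n_progeny": len(tab)}
        try:
            vc = variance_partition(tab, trait_name=trait_col)
            row.update(vc.to_dict())
            row["reason"] = ""
        except DesignError as exc:
            row.update({k: math.nan for k in ("MS_b", "MS_w", "V_H", "V_NH", "H2")})
            row["reason"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AssociationReport:
    """Association between two clone traits (rank and linear)."""

    trait_x: str
    trait_y: str
    n_pairs: int
    spearman_rho: float = math.nan
    spearman_p: float = math.nan
    slope: float = math.nan
    intercept: float = math.nan
    r_squared: float = math.nan
    constant_input: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def parent_progeny_regression(
    table: pd.DataFrame,
    parent_col: str = "parent_id",
    parent_value_col: str = "parent_value",
    value_col: str = "value",
    trait_name: str = "trait",
) -> AssociationReport:
    """OLS of progeny-mean trait on the parental trait value.

    A slope near 1 with high R^2 means the parental value predicts the mean
    progeny value — the regression analogue of the variance-partition result.
    """
    per_parent = table.groupby(parent_col).agg(
        parent_value=(parent_value_col, "first"),
        progeny_mean=(value_col, "mean"),
    )
    if len(per_parent) < 3:
        raise DesignError("need >= 3 parents for regression")
    x = per_parent["parent_value"].to_numpy(dtype=float)
    y = per_parent["progeny_mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DesignError("zero variance in parent trait: slope undefined")
    res = stats.linregress(x, y)
    return AssociationReport(
        trait_x=f"parent {trait_name}",
        trait_y=f"progeny-mean {trait_name}",
        n_pairs=len(per_parent),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def trait_correlations(
    params_table: pd.DataFrame,
    traits: list[str],
    against: str = "period_h",
) -> pd.DataFrame:
    """Spearman rank correlation of each trait against the reference trait.

    Ties get average ranks.  P-values come from the large-sample t
    approximation and are descriptive only.  Constant traits are flagged
    rather than raised.
    """
    if len(params_table) < 5:
        raise DesignError("need >= 5 clones for trait correlations")
    ref = params_table[against].to_numpy(dtype=float)
    rows = []
    for trait in traits:
        y = params_table[trait].to_numpy(dtype=float)
        rep = AssociationReport(trait_x=against, trait_y=trait, n_pairs=len(y))
        if np.ptp(y) == 0 or np.ptp(ref) == 0:
            rep.constant_input = True
        else:
            rho, p = stats.spearmanr(ref, y)
            rep.spearman_rho = float(rho)
            rep.spearman_p = float(p)
        rows.append(rep.to_dict())
    return pd.DataFrame(rows)
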
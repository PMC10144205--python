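"""Partial cohort life tables and reproductive parameters.

Built from daily cage observations, a :class:`LifeTable` carries, per cohort
age ``x`` in days:

* ``lx`` — survivorship, the fraction of the original adult-female cohort
  alive at age ``x``;
* ``Mx`` — age-specific fecundity, eggs laid per living female per day;
* ``hx`` — hatch fraction of the eggs laid at age ``x``;
* ``lx*Mx*hx`` — net maternity, hatched eggs per original female.

From the table the classical cohort reproductive parameters follow: gross
fecundity and fertility rates, fecundity-weighted gross hatch rate, mean age
of net fertility ``T``, and the intrinsic rate of increase ``r`` solving the
Euler-Lotka renewal equation ``sum_x exp(-r x) lx Mx hx = 1``.  Maternity is
counted in hatched eggs of both sexes by default; the textbook
daughters-only convention is available via ``daughters_only=True`` (which
halves maternity at an even sex ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cage import CageObservations

__all__ = [
    "LifeTable",
    "ReproductiveParameters",
    "build_life_table",
    "daily_net_fertility",
    "reproductive_parameters",
    "intrinsic_rate_of_increase",
]


@dataclass
class LifeTable:
    """Age-indexed survivorship / fecundity / hatch schedule.

    ``data`` has columns ``age_day, lx, Mx, hx`` with strictly increasing
    integer ages, ``l0 = 1``, ``lx`` non-increasing, ``0 <= lx, hx <= 1``
    and ``Mx >= 0``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        required = {"age_day", "lx", "Mx", "hx"}
        missing = required - set(d.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        ages = d["age_day"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        lx = d["lx"].to_numpy(dtype=float)
        if np.any((lx < 0) | (lx > 1)) or np.any(np.diff(lx) > 1e-12):
            raise ValueError("lx must be non-increasing within [0, 1]")
        if abs(lx[0] - 1.0) > 1e-12 and ages[0] == 0:
            raise ValueError("l0 must equal 1")
        hx = d["hx"].to_numpy(dtype=float)
        if np.any((hx < 0) | (hx > 1)):
            raise ValueError("hx must lie in [0, 1]")
        if np.any(d["Mx"].to_numpy(dtype=float) < 0):
            raise ValueError("Mx must be nonnegative")

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_day"].to_numpy()

    @property
    def net_maternity(self) -> np.ndarray:
        """Per-age ``lx * Mx * hx`` (hatched eggs per original female)."""
        d = self.data
        return (d["lx"] * d["Mx"] * d["hx"]).to_numpy(dtype=float)

    def to_csv(self, path: "str | Path") -> None:
        out = self.data.copy()
        out["net_maternity"] = self.net_maternity
        out.to_csv(Path(path), index=False)


@dataclass
class ReproductiveParameters:
    """Cohort reproductive parameters of one treatment arm.

    ``intrinsic_rate`` is the Euler-Lotka root; ``intrinsic_rate_approx``
    the one-generation approximation ``ln(gross_fertility_rate) /
    mean_age_net_fertility``.  When the table has no reproduction the rate
    fields are None and ``defined`` is False rather than silently NaN.
    """

    gross_fecundity_rate: float
    gross_fertility_rate: float
    gross_hatch_rate: float
    eggs_per_female_per_day: float
    mean_age_net_fertility: "float | None"
    intrinsic_rate: "float | None"
    intrinsic_rate_approx: "float | None"
    net_fertility_total: float  # sum of lx*Mx*hx, an R0-style total
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "gross_fecundity_rate": self.gross_fecundity_rate,
            "gross_fertility_rate": self.gross_fertility_rate,
            "gross_hatch_rate": self.gross_hatch_rate,
            "eggs_per_female_per_day": self.eggs_per_female_per_day,
            "mean_age_net_fertility": self.mean_age_net_fertility,
            "intrinsic_rate": self.intrinsic_rate,
            "intrinsic_rate_approx": self.intrinsic_rate_approx,
            "net_fertility_total": self.net_fertility_total,
            "defined": self.defined,
        }


def build_life_table(
    obs: CageObservations, horizon: "int | None" = None
) -> LifeTable:
    """Construct the partial life table (ages 0..horizon) from daily cage
    observations.

    The original cohort is the female count on the first observation day;
    ages before the first record carry ``lx = 1`` and ``Mx = 0`` (the
    immature stages, over which the table tracks no mortality), gap days
    carry the last ``lx`` forward with ``Mx = hx = 0``, and the table is
    truncated at ``horizon`` (default: the last observed age).
    """
    d = obs.daily.sort_values("age_day").reset_index(drop=True)
    cohort = int(d["n_alive_females"].iloc[0])
    if cohort <= 0:
        raise ValueError("original cohort size must be positive")
    bad = d.index[(d["eggs_collected"] > 0) & (d["n_alive_females"] == 0)]
    if len(bad):
        raise ValueError(
            f"eggs recorded with no females alive at age {d['age_day'].iloc[bad[0]]}"
        )
    if horizon is None:
        horizon = int(d["age_day"].iloc[-1])

    ages = np.arange(0, horizon + 1)
    lx = np.ones(len(ages))
    Mx = np.zeros(len(ages))
    hx = np.zeros(len(ages))
    recorded = dict(zip(d["age_day"].astype(int), d.index))
    last_l = 1.0
    for i, age in enumerate(ages):
        if age in recorded:
            row = d.loc[recorded[age]]
            last_l = row["n_alive_females"] / cohort
            if row["n_alive_females"] > 0:
                Mx[i] = row["eggs_collected"] / row["n_alive_females"]
            if row["eggs_collected"] > 0:
                hx[i] = row["eggs_hatched"] / row["eggs_collected"]
        lx[i] = last_l
    return LifeTable(pd.DataFrame({"age_day": ages, "lx": lx, "Mx": Mx, "hx": hx}))


def daily_net_fertility(table: LifeTable) -> pd.DataFrame:
    """Per-age net fertility series.

    Returns both conventions: ``net_fertility_pct`` — the literal
    survival-times-hatch product ``lx * hx`` expressed as a percentage, the
    field-report style — and ``net_maternity`` — the demographic
    ``lx * Mx * hx`` in hatched eggs per original female.
    """
    d = table.data
    return pd.DataFrame(
        {
            "age_day": d["age_day"],
            "net_fertility_pct": 100.0 * d["lx"] * d["hx"],
            "net_maternity": table.net_maternity,
        }
    )


def intrinsic_rate_of_increase(
    table: LifeTable,
    daughters_only: bool = False,
    male_frac: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Intrinsic rate of increase ``r``: the Euler-Lotka root of
    ``sum_x exp(-r x) lx Mx hx = 1``.

    Solved by bisection on a bracket auto-expanded from [-1, 2]; the
    residual at the returned root is below 1e-10.  ``daughters_only=True``
    multiplies maternity by ``1 - male_frac``.
    """
    phi = table.net_maternity.astype(float)
    if daughters_only:
        phi = phi * (1.0 - male_frac)
    x = table.ages.astype(float)
    total = phi.sum()
    if total <= 0:
        raise ValueError("intrinsic rate undefined: zero net maternity")

    def residual(r: float) -> float:
        return float(np.sum(np.exp(-r * x) * phi) - 1.0)

    lo, hi = -1.0, 2.0
    # residual is strictly decreasing in r (x > 0 wherever phi > 0)
    for _ in range(200):
        if residual(lo) > 0:
            break
        lo *= 2.0
    else:
        raise ArithmeticError(
            f"could not bracket Euler-Lotka root: residual({lo})={residual(lo)}"
        )
    for _ in range(200):
        if residual(hi) < 0:
            break
        hi *= 2.0
    else:
        raise ArithmeticError(
            f"could not bracket Euler-Lotka root: residual({hi})={residual(hi)}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    r = 0.5 * (lo + hi)
    res = residual(r)
    if abs(res) > 1e-10:
        raise ArithmeticError(
            f"Euler-Lotka bisection did not converge: residual {res:.3e} at r={r}"
        )
    return r


def reproductive_parameters(
    table: LifeTable,
    window: "tuple[int, int] | None" = None,
    daughters_only: bool = False,
) -> ReproductiveParameters:
    """All cohort reproductive parameters of a life table.

    ``window`` restricts the ages considered (inclusive, default: the whole
    table); its length in days is the denominator of
    ``eggs_per_female_per_day`` (52 for the standard 0-51 d window).
    """
    d = table.data
    if window is not None:
        lo, hi = window
        d = d[(d["age_day"] >= lo) & (d["age_day"] <= hi)]
        if len(d) == 0:
            raise ValueError(f"window {window} selects no ages")
        window_days = hi - lo + 1
    else:
        window_days = int(d["age_day"].iloc[-1] - d["age_day"].iloc[0]) + 1

    Mx = d["Mx"].to_numpy(dtype=float)
    hx = d["hx"].to_numpy(dtype=float)
    lx = d["lx"].to_numpy(dtype=float)
    x = d["age_day"].to_numpy(dtype=float)

    gross_fecundity = float(Mx.sum())
    gross_fertility = float((Mx * hx).sum())
    phi = lx * Mx * hx
    net_total = float(phi.sum())
    eggs_per_day = net_total / window_days

    if gross_fecundity <= 0 or net_total <= 0:
        return ReproductiveParameters(
            gross_fecundity_rate=gross_fecundity,
            gross_fertility_rate=gross_fertility,
            gross_hatch_rate=0.0,
            eggs_per_female_per_day=eggs_per_day,
            mean_age_net_fertility=None,
            intrinsic_rate=None,
            intrinsic_rate_approx=None,
            net_fertility_total=net_total,
            defined=False,
        )

    gross_hatch = 100.0 * gross_fertility / gross_fecundity
    T = float((x * phi).sum() / net_total)
    sub = LifeTable(
        pd.DataFrame({"age_day": d["age_day"], "lx": lx, "Mx": Mx, "hx": hx})
    )
    r = intrinsic_rate_of_increase(sub, daughters_only=daughters_only)
    r_approx = (
        math.log(gross_fertility) / T if gross_fertility > 0 and T > 0 else None
    )
    return ReproductiveParameters(
        gross_fecundity_rate=gross_fecundity,
        gross_fertility_rate=gross_fertility,
        gross_hatch_rate=gross_hatch,
        eggs_per_female_per_day=eggs_per_day,
        mean_age_net_fertility=T,
        intrinsic_rate=r,
        intrinsic_rate_approx=r_approx,
        net_fertility_total=net_total,
        defined=True,
    )
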
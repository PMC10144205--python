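"""Stochastic simulator of field-cage SIT x parasitoid trials.

One trial confines a founder cohort of fly larvae in a field cage.
Depending on the treatment arm, parasitoids attack the immatures
(removing a binomial fraction before adult emergence) and/or sterile males
are released at a target sterile:fertile ratio sized from a sentinel-cage
emergence estimate.  Emerged females are then followed daily: egg output on
the oviposition ages, egg hatch under mating competition, and survival.

All counts are binomial or Poisson draws from a single seeded RNG stream, so
a trial is exactly reproducible from its configuration.

Timeline convention (cohort age = days since egg deposition): larvae are
placed at age 14 d, adults emerge around age 29 d, and oviposition is scored
at adult ages 12-22 d, i.e. cohort ages 41-51 d, so the daily table ends at
the 51-day observation horizon.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .suppression import ControlScenario, effective_hatch, release_size

__all__ = [
    "Treatment",
    "CageTrialConfig",
    "CageObservations",
    "simulate_trial",
    "expected_life_table",
    "write_observations",
    "read_observations",
]

SENTINEL_LARVAE = 100  # larvae per sentinel emergence cage


class Treatment(str, enum.Enum):
    """Treatment arm of a field-cage trial."""

    CONTROL = "CONTROL"
    SIT = "SIT"
    ABC = "ABC"
    ABC_SIT = "ABC_SIT"

    @property
    def has_parasitoids(self) -> bool:
        return self in (Treatment.ABC, Treatment.ABC_SIT)

    @property
    def has_sterile_males(self) -> bool:
        return self in (Treatment.SIT, Treatment.ABC_SIT)


@dataclass(frozen=True)
class CageTrialConfig:
    """Generator parameters of one simulated cage trial.

    Defaults reproduce the study conditions: 500-larva founder cohorts,
    ~80% emergence, a 10:1 target sterile:fertile ratio sized from the
    sentinel cage, 80% fertile-cross hatch, oviposition at adult ages
    12-22 d and observation truncated at cohort age 51 d.
    """

    n_founder_larvae: int = 500
    emergence_prob: float = 0.80
    male_frac: float = 0.5
    parasitism_prob: float = 0.0
    treatment: Treatment = Treatment.CONTROL
    target_ratio: float = 10.0
    competitiveness_c: float = 1.0
    control_hatch: float = 0.80
    sterile_cross_hatch: float = 0.0
    daily_adult_mortality: float = 0.02
    eggs_per_female_per_day: float = 50.0
    oviposition_adult_ages: tuple[int, int] = (12, 22)
    age_at_larval_placement: int = 14
    age_at_emergence: int = 29
    horizon: int = 51
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.treatment, str) and not isinstance(
            self.treatment, Treatment
        ):
            object.__setattr__(self, "treatment", Treatment(self.treatment))
        if self.n_founder_larvae <= 0:
            raise ValueError("n_founder_larvae must be positive")
        if int(self.n_founder_larvae) != self.n_founder_larvae:
            raise ValueError("n_founder_larvae must be an integer count")
        for name in (
            "emergence_prob",
            "male_frac",
            "parasitism_prob",
            "control_hatch",
            "sterile_cross_hatch",
            "daily_adult_mortality",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.target_ratio < 0:
            raise ValueError("target_ratio must be nonnegative")
        if self.competitiveness_c <= 0:
            raise ValueError("competitiveness_c must be positive")
        if self.eggs_per_female_per_day < 0:
            raise ValueError("eggs_per_female_per_day must be nonnegative")
        lo, hi = self.oviposition_adult_ages
        if lo > hi or lo < 0:
            raise ValueError("oviposition_adult_ages must be a valid day range")

    @property
    def oviposition_cohort_ages(self) -> tuple[int, int]:
        lo, hi = self.oviposition_adult_ages
        return (self.age_at_emergence + lo, self.age_at_emergence + hi)


@dataclass
class CageObservations:
    """Raw observation tables of one (simulated or imported) cage trial.

    ``daily`` is keyed by cohort age in days since egg deposition with
    integer columns ``n_alive_females``, ``eggs_collected``,
    ``eggs_hatched``.
    """

    sentinel_emergence: dict  # {"n_larvae": int, "n_emerged": int}
    field_emergence: dict  # {"n_males": int, "n_females": int, "n_parasitoids": int}
    sterile_released: int
    daily: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"age_day", "n_alive_females", "eggs_collected", "eggs_hatched"}
        if self.daily is None or len(self.daily) == 0:
            raise ValueError("daily observation table is empty")
        missing = required - set(self.daily.columns)
        if missing:
            raise ValueError(f"daily table missing columns: {sorted(missing)}")
        d = self.daily
        for col in ("n_alive_females", "eggs_collected", "eggs_hatched"):
            bad = d.index[d[col] < 0]
            if len(bad):
                raise ValueError(
                    f"negative {col} at row {bad[0]} (age {d.loc[bad[0], 'age_day']})"
                )
        bad = d.index[d["eggs_hatched"] > d["eggs_collected"]]
        if len(bad):
            raise ValueError(
                f"eggs_hatched exceeds eggs_collected at row {bad[0]} "
                f"(age {d.loc[bad[0], 'age_day']})"
            )
        alive = d["n_alive_females"].to_numpy()
        if np.any(np.diff(alive) > 0):
            i = int(np.argmax(np.diff(alive) > 0)) + 1
            raise ValueError(
                f"n_alive_females increases at age {d['age_day'].iloc[i]}"
            )
        if self.sterile_released < 0:
            raise ValueError("sterile_released must be nonnegative")

    @property
    def parasitism_fraction(self) -> float:
        """Adult parasitoids over all adults emerged (flies + parasitoids)."""
        f = self.field_emergence
        n_flies = f["n_males"] + f["n_females"]
        total = n_flies + f["n_parasitoids"]
        if total == 0:
            raise ValueError("no adult emergence: parasitism undefined")
        return f["n_parasitoids"] / total

    @property
    def hatch_fraction(self) -> float:
        """Pooled egg-hatch fraction over the whole trial."""
        collected = int(self.daily["eggs_collected"].sum())
        if collected == 0:
            return 0.0
        return int(self.daily["eggs_hatched"].sum()) / collected


def _hatch_probability(config: CageTrialConfig, fertile_males: int,
                       sterile_released: int) -> float:
    """Per-egg hatch probability under the trial's mating competition."""
    if sterile_released == 0:
        return config.control_hatch
    return effective_hatch(
        ControlScenario(
            sterile_S=sterile_released,
            fertile_F=fertile_males,
            competitiveness_c=config.competitiveness_c,
            control_hatch_h0=config.control_hatch,
            sterile_cross_hatch_hs=config.sterile_cross_hatch,
        )
    )


def simulate_trial(config: CageTrialConfig) -> CageObservations:
    """Simulate one field-cage trial.

    Stages: sentinel emergence, parasitism of immatures (ABC arms),
    adult emergence and sex split, sterile-male release sizing (SIT arms),
    then the daily oviposition / hatch / survival table up to the horizon.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    # 1. sentinel cage: emergence estimate used to size the sterile release
    sentinel_emerged = int(rng.binomial(SENTINEL_LARVAE, config.emergence_prob))
    emergence_est = sentinel_emerged / SENTINEL_LARVAE

    # 2. parasitism of immatures (before adult emergence)
    if config.treatment.has_parasitoids:
        n_parasitized = int(
            rng.binomial(config.n_founder_larvae, config.parasitism_prob)
        )
    else:
        n_parasitized = 0
    n_unparasitized = config.n_founder_larvae - n_parasitized

    # 3. adult emergence; parasitoid adults emerge from parasitized hosts at
    # the same rate, so the recovered parasitism percentage is unbiased
    n_adult_flies = int(rng.binomial(n_unparasitized, config.emergence_prob))
    n_parasitoid_adults = int(rng.binomial(n_parasitized, config.emergence_prob))
    n_males = int(rng.binomial(n_adult_flies, config.male_frac))
    n_females = n_adult_flies - n_males

    # 4. sterile release sized from the sentinel estimate and the full
    # founder cohort (before parasitism losses), as in release protocols
    if config.treatment.has_sterile_males:
        sterile_released = release_size(
            config.n_founder_larvae,
            emergence_est,
            config.male_frac,
            config.target_ratio,
        )
    else:
        sterile_released = 0

    hatch_p = _hatch_probability(config, n_males, sterile_released)

    # 5-6. daily table from emergence to the horizon
    ovi_lo, ovi_hi = config.oviposition_cohort_ages
    ages = np.arange(config.age_at_emergence, config.horizon + 1)
    alive = np.empty(len(ages), dtype=int)
    eggs = np.zeros(len(ages), dtype=int)
    hatched = np.zeros(len(ages), dtype=int)
    n_alive = n_females
    for i, age in enumerate(ages):
        alive[i] = n_alive
        if ovi_lo <= age <= ovi_hi and n_alive > 0:
            e = int(rng.poisson(config.eggs_per_female_per_day * n_alive))
            eggs[i] = e
            hatched[i] = int(rng.binomial(e, hatch_p))
        deaths = int(rng.binomial(n_alive, config.daily_adult_mortality))
        n_alive -= deaths

    daily = pd.DataFrame(
        {
            "age_day": ages,
            "n_alive_females": alive,
            "eggs_collected": eggs,
            "eggs_hatched": hatched,
        }
    )
    return CageObservations(
        sentinel_emergence={"n_larvae": SENTINEL_LARVAE, "n_emerged": sentinel_emerged},
        field_emergence={
            "n_males": n_males,
            "n_females": n_females,
            "n_parasitoids": n_parasitoid_adults,
        },
        sterile_released=sterile_released,
        daily=daily,
    )


def expected_life_table(config: CageTrialConfig) -> pd.DataFrame:
    """Deterministic expectation of the life-table schedule implied by a
    configuration: columns ``age_day, lx, Mx, hx``.

    ``lx`` is relative to the emerged adult-female cohort (1 at emergence,
    geometric decline at the daily mortality), ``Mx`` the mean egg output
    per living female, and ``hx`` the model hatch probability, in which
    parasitism shrinks the fertile-male pool and thereby inflates the
    achieved sterile:fertile ratio.  Used as ground truth when checking
    parameter recovery of the stochastic simulator.
    """
    ages = np.arange(0, config.horizon + 1)
    lx = np.ones(len(ages))
    adult = ages >= config.age_at_emergence
    lx[adult] = (1.0 - config.daily_adult_mortality) ** (
        ages[adult] - config.age_at_emergence
    )
    ovi_lo, ovi_hi = config.oviposition_cohort_ages
    Mx = np.where(
        (ages >= ovi_lo) & (ages <= ovi_hi), config.eggs_per_female_per_day, 0.0
    )
    p = config.parasitism_prob if config.treatment.has_parasitoids else 0.0
    expected_fertile = (
        config.n_founder_larvae * (1.0 - p) * config.emergence_prob * config.male_frac
    )
    if config.treatment.has_sterile_males:
        expected_release = (
            config.target_ratio
            * config.n_founder_larvae
            * config.emergence_prob
            * config.male_frac
        )
    else:
        expected_release = 0.0
    h = _hatch_probability(
        config, fertile_males=expected_fertile, sterile_released=expected_release
    )
    hx = np.where(Mx > 0, h, 0.0)
    return pd.DataFrame({"age_day": ages, "lx": lx, "Mx": Mx, "hx": hx})


# ---------------------------------------------------------------------------
# persistence

_DAILY_COLUMNS = ["age_day", "n_alive_females", "eggs_collected", "eggs_hatched"]


def write_observations(obs: CageObservations, path: "str | Path") -> None:
    """Write a trial to ``<path>.csv`` (daily table) + ``<path>.json``
    (summary counts); ``path`` is a stem without extension."""
    path = Path(path)
    obs.daily[_DAILY_COLUMNS].to_csv(path.with_suffix(".csv"), index=False)
    meta = {
        "sentinel_emergence": obs.sentinel_emergence,
        "field_emergence": obs.field_emergence,
        "sterile_released": int(obs.sterile_released),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_observations(path: "str | Path") -> CageObservations:
    """Read a trial written by :func:`write_observations`; the CSV/JSON
    round trip is lossless.

    Malformed tables (negative counts, hatched > collected, increasing
    alive counts) are rejected with a row-indexed message.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    if not csv_path.exists():
        raise FileNotFoundError(f"missing daily observation table {csv_path}")
    daily = pd.read_csv(csv_path)
    if len(daily) == 0:
        raise ValueError(f"daily observation table {csv_path} is empty")
    missing = set(_DAILY_COLUMNS) - set(daily.columns)
    if missing:
        raise ValueError(f"{csv_path} missing columns: {sorted(missing)}")
    for col in _DAILY_COLUMNS:
        if not np.issubdtype(daily[col].dtype, np.integer):
            try:
                as_int = daily[col].astype(int)
            except (ValueError, TypeError) as err:
                raise ValueError(f"{csv_path}: non-integer counts in {col}") from err
            if not np.allclose(as_int, daily[col]):
                raise ValueError(f"{csv_path}: non-integer counts in {col}")
            daily[col] = as_int
    if json_path.exists():
        meta = json.loads(json_path.read_text())
    else:
        meta = {
            "sentinel_emergence": {"n_larvae": 0, "n_emerged": 0},
            "field_emergence": {"n_males": 0, "n_females": 0, "n_parasitoids": 0},
            "sterile_released": 0,
        }
    return CageObservations(
        sentinel_emergence=meta["sentinel_emergence"],
        field_emergence=meta["field_emergence"],
        sterile_released=meta["sterile_released"],
        daily=daily[_DAILY_COLUMNS],
    )
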
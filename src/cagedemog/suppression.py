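"""Sterile-male mating competition, parasitism, and their joint effect.

The model combines two mechanisms acting on different life stages:

* parasitism removes a fraction ``p`` of immatures before adult emergence;
* released sterile males compete with the ``F`` surviving fertile males for
  matings, so a wild female mates fertile with probability ``F / (F + c S)``
  where ``S`` is the sterile release size and ``c`` the Fried
  competitiveness index.

Egg hatch under competition is the mating-probability-weighted mixture of the
fertile-cross hatch ``h0`` and the residual sterile-cross hatch ``hs``.  The
fraction of the population left to breed in the next generation is the
product ``(1 - p) * h`` of the two marginal survivals, which makes the two
techniques multiplicative ("additive on a log scale"); any extra suppression
beyond that product — e.g. because parasitism shrinks ``F`` and thereby
inflates the achieved sterile:fertile ratio — is the synergistic component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControlScenario",
    "GenerationTrajectory",
    "fertile_mating_probability",
    "effective_hatch",
    "fried_competitiveness",
    "remaining_reproductive_fraction",
    "release_size",
    "achieved_ratio",
    "project_generations",
    "additivity_gap",
]


@dataclass(frozen=True)
class ControlScenario:
    """Parameters of one combined-control scenario.

    Parameters
    ----------
    parasitism_p:
        Fraction of immatures removed by parasitoids before emergence.
    sterile_S, fertile_F:
        Sterile and fertile male numbers (or a ratio with ``fertile_F=1``).
    competitiveness_c:
        Fried competitiveness index of the sterile males (1 = fully
        competitive).
    control_hatch_h0:
        Egg hatch fraction of a fertile (wild x wild) cross.
    sterile_cross_hatch_hs:
        Residual hatch of a sterile x wild cross (0 for full sterility).
    per_generation_R:
        Net replacement multiplier of an untreated population per
        generation.
    immigration:
        Additive per-generation influx of wild flies (default 0).
    """

    parasitism_p: float = 0.0
    sterile_S: float = 0.0
    fertile_F: float = 1.0
    competitiveness_c: float = 1.0
    control_hatch_h0: float = 0.80
    sterile_cross_hatch_hs: float = 0.0
    per_generation_R: float = 1.0
    immigration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("parasitism_p", "control_hatch_h0", "sterile_cross_hatch_hs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sterile_cross_hatch_hs > self.control_hatch_h0:
            raise ValueError("sterile_cross_hatch_hs exceeds control_hatch_h0")
        if self.competitiveness_c <= 0:
            raise ValueError("competitiveness_c must be positive")
        if self.sterile_S < 0 or self.fertile_F < 0:
            raise ValueError("sterile_S and fertile_F must be nonnegative")


@dataclass
class GenerationTrajectory:
    """Per-generation population sizes and effective sterile:fertile ratios."""

    sizes: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if np.any(self.sizes < 0):
            raise ValueError("population sizes must be nonnegative")

    def __len__(self) -> int:
        return len(self.sizes)


def fertile_mating_probability(F: float, S: float, c: float) -> float:
    """Probability that a wild female mates with a fertile male.

    Standard mating-competition form ``F / (F + c*S)``.
    """
    if F < 0 or S < 0:
        raise ValueError("F and S must be nonnegative")
    if c <= 0:
        raise ValueError("competitiveness c must be positive")
    denom = F + c * S
    if denom == 0:
        raise ValueError("fertile mating probability undefined: F = S = 0")
    return F / denom


def effective_hatch(scenario: ControlScenario) -> float:
    """Population egg-hatch fraction under sterile-male competition.

    ``h = h0 * F/(F + cS) + hs * cS/(F + cS)``; reduces to ``h0`` when no
    sterile males are present and tends to ``hs`` as the ratio or the
    competitiveness grows.
    """
    pf = fertile_mating_probability(
        scenario.fertile_F, scenario.sterile_S, scenario.competitiveness_c
    )
    return scenario.control_hatch_h0 * pf + scenario.sterile_cross_hatch_hs * (1.0 - pf)


def fried_competitiveness(
    Ha: float, Ho: float, Hs: float, S_over_F: float
) -> float:
    """Fried (1971) competitiveness index from observed hatch percentages.

    ``c = ((Ha - Ho) / (Ho - Hs)) / (S/F)`` where ``Ha`` is the hatch of the
    untreated (all-fertile) cross, ``Ho`` the observed hatch under the
    release, and ``Hs`` the sterile-cross hatch, all on the same
    (percentage or fraction) scale.  The returned ``c`` inverts
    :func:`effective_hatch` exactly: plugging it back with the same ratio
    reproduces ``Ho``.
    """
    if S_over_F <= 0:
        raise ValueError("sterile:fertile ratio must be positive")
    if Ho <= Hs:
        raise ValueError(
            f"observed hatch Ho={Ho} must exceed sterile-cross hatch Hs={Hs}"
        )
    c = ((Ha - Ho) / (Ho - Hs)) / S_over_F
    if c < 0:
        # observed hatch above the fertile baseline: no measurable competition
        import warnings

        warnings.warn(
            f"observed hatch {Ho} exceeds fertile-cross hatch {Ha}; "
            "competitiveness clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return c


def remaining_reproductive_fraction(p: float, h: float) -> float:
    """Fraction of the population left to breed: ``(1 - p) * h``.

    Multiplicative in its two factors — parasitism and induced sterility act
    on different stages and combine independently in a single generation.
    """
    if not 0.0 <= p <= 1.0 or not 0.0 <= h <= 1.0:
        raise ValueError("p and h must lie in [0, 1]")
    return (1.0 - p) * h


def release_size(
    n_founder: int,
    emergence_frac: float,
    male_frac: float,
    target_ratio: float,
) -> int:
    """Number of sterile males to release for a target sterile:fertile ratio.

    The expected number of fertile males is ``n_founder * emergence_frac *
    male_frac`` (sized from the sentinel-cage emergence before any
    parasitism), and the release is that number times the target ratio,
    rounded to the nearest whole insect.
    """
    if target_ratio < 0:
        raise ValueError("target_ratio must be nonnegative")
    if n_founder < 0:
        raise ValueError("n_founder must be nonnegative")
    if not 0.0 <= emergence_frac <= 1.0 or not 0.0 <= male_frac <= 1.0:
        raise ValueError("emergence_frac and male_frac must lie in [0, 1]")
    return round(target_ratio * n_founder * emergence_frac * male_frac)


def achieved_ratio(sterile_released: float, males_emerged: float) -> float:
    """Achieved sterile:fertile ratio, rounded to the nearest integer N (as
    in an "N:1" report).

    Returns ``math.inf`` when sterile males were released into a cage with
    no fertile males.
    """
    if sterile_released < 0 or males_emerged < 0:
        raise ValueError("counts must be nonnegative")
    if males_emerged == 0:
        if sterile_released == 0:
            return 0
        return math.inf
    return round(sterile_released / males_emerged)


def project_generations(
    scenario: ControlScenario,
    N0: float,
    n_gen: int,
    releases: "float | list[float] | np.ndarray | None" = None,
) -> GenerationTrajectory:
    """Project the fly population over generations of repeated releases.

    Each generation the population is multiplied by the untreated
    replacement ``per_generation_R``, the parasitism survival ``(1 - p)``
    and the relative hatch ``h_t / h0``, where ``h_t`` uses the ratio of the
    (fixed) sterile release to the current fertile population.  Constant
    absolute releases therefore yield a growing effective ratio as the
    population falls — the mechanism behind eventual eradication.

    Parameters
    ----------
    releases:
        Sterile males released each generation: a scalar (repeated), a
        sequence of length ``n_gen``, or None to repeat
        ``scenario.sterile_S``.
    """
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    if n_gen < 0:
        raise ValueError("n_gen must be nonnegative")
    if releases is None:
        rel = np.full(n_gen, float(scenario.sterile_S))
    else:
        rel = np.asarray(releases, dtype=float)
        if rel.ndim == 0:
            rel = np.full(n_gen, float(rel))
    if len(rel) != n_gen:
        raise ValueError(f"need {n_gen} release sizes, got {len(rel)}")

    sizes = np.empty(n_gen + 1)
    sizes[0] = N0
    N = N0
    for t in range(n_gen):
        if N <= 0:
            sizes[t + 1] = 0.0
            N = 0.0
            continue
        h_t = effective_hatch(
            ControlScenario(
                parasitism_p=scenario.parasitism_p,
                sterile_S=rel[t],
                fertile_F=N,
                competitiveness_c=scenario.competitiveness_c,
                control_hatch_h0=scenario.control_hatch_h0,
                sterile_cross_hatch_hs=scenario.sterile_cross_hatch_hs,
            )
        )
        f = remaining_reproductive_fraction(scenario.parasitism_p, h_t)
        # hatch normalized by h0 so an untreated population grows exactly by R
        N = N * scenario.per_generation_R * f / scenario.control_hatch_h0
        N += scenario.immigration
        sizes[t + 1] = max(N, 0.0)
        N = sizes[t + 1]
    # effective ratio at each generation: that generation's release over the
    # standing population (the final entry repeats the last release size)
    rel_ext = np.concatenate([rel, rel[-1:]]) if n_gen > 0 else np.array(
        [float(scenario.sterile_S)]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(
            sizes > 0, rel_ext / np.where(sizes > 0, sizes, 1.0),
            np.where(rel_ext > 0, math.inf, 0.0),
        )
    return GenerationTrajectory(sizes=sizes, ratios=ratios)


def additivity_gap(
    p: float,
    ratio: float,
    c: float,
    h0: float,
    hs: float = 0.0,
    combined_hatch: "float | None" = None,
) -> float:
    """Signed departure of the combined treatment from the product of its
    marginal effects.

    The product-of-marginals expectation for the remaining reproductive
    fraction is ``(1 - p) * h_SIT / h0`` with ``h_SIT`` the hatch at the
    nominal sterile:fertile ``ratio``.  The observed combined fraction uses
    either a measured ``combined_hatch`` or, by default, the model
    prediction in which parasitism removes fertile males and thereby
    inflates the achieved ratio to ``ratio / (1 - p)``.  A negative gap
    means the combination suppresses more than independence predicts
    (synergy); zero means the two mechanisms acted independently.
    """
    h_sit = effective_hatch(
        ControlScenario(
            sterile_S=ratio, fertile_F=1.0, competitiveness_c=c,
            control_hatch_h0=h0, sterile_cross_hatch_hs=hs,
        )
    )
    if combined_hatch is None:
        if p >= 1.0:
            h_comb = hs
        else:
            h_comb = effective_hatch(
                ControlScenario(
                    sterile_S=ratio, fertile_F=1.0 - p, competitiveness_c=c,
                    control_hatch_h0=h0, sterile_cross_hatch_hs=hs,
                )
            )
    else:
        h_comb = combined_hatch
    expected = remaining_reproductive_fraction(p, h_sit / h0)
    observed = remaining_reproductive_fraction(p, h_comb / h0)
    return observed - expected
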
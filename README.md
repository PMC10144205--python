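# cagedemog

Cohort life-table demography and suppression modelling for field-cage
trials that combine the **sterile insect technique (SIT)** with
**augmentative biological control (ABC, parasitoid releases)** against
tephritid fruit flies such as *Anastrepha ludens*.

The package is for entomologists and pest-management modellers who want to
analyse (or simulate) replicated field-cage assays in which a founder
cohort of fly larvae is exposed to parasitoids, surviving adults face
released sterile males, and daily egg output, egg hatch and female survival
are recorded. It answers the quantitative questions such trials pose: how
much does each technique — and their combination — reduce the population's
reproductive parameters, and is the combined effect additive or
synergistic?

## The model

For a cohort observed at ages `x` (days since egg deposition), the partial
life table carries survivorship `lx`, fecundity `Mx` (eggs per living
female per day) and hatch `hx`. The reproductive parameters are

* gross fertility rate `GFR = Σ Mx·hx` (hatched eggs/female),
* gross hatch rate `GHR = 100·Σ Mx·hx / Σ Mx` (%),
* mean age of net fertility `T = Σ x·lx·Mx·hx / Σ lx·Mx·hx` (days),
* intrinsic rate of increase `r` solving Euler–Lotka
  `Σ exp(−r·x)·lx·Mx·hx = 1` (with `ln(GFR)/T` as the standard
  approximation).

Suppression combines two stages: parasitism removes a fraction `p` of
immatures, and sterile males at ratio `S:F` with Fried competitiveness `c`
dilute egg hatch to `h = h0·F/(F+cS) + hs·cS/(F+cS)`. The fraction of the
population left to breed in one generation is `(1−p)·h`. Because releases
are sized against an unparasitized emergence sample, parasitism inflates
the achieved ratio (10:1 nominal → ~29:1 at 65% parasitism) — the
mechanism that makes the combination synergistic rather than merely
additive, quantified by `additivity_gap`.

A seeded stochastic simulator (`synthetic_cage`) generates full trials with
the binomial/Poisson structure the analysis assumes, so the whole pipeline
is testable without any field data.

## Worked example

Simulate one combined-treatment cage (500 founder larvae, 65% parasitism,
10:1 target ratio, competitiveness 0.1625) and analyse it:

```python
import cagedemog as cd
from cagedemog import suppression as sup

cfg = cd.CageTrialConfig(treatment="ABC_SIT", parasitism_prob=0.65,
                         competitiveness_c=0.1625, seed=1)
obs = cd.simulate_trial(cfg)
table = cd.build_life_table(obs)
params = cd.reproductive_parameters(table, window=(0, 51))
print(round(100 * obs.parasitism_fraction, 2))      # 65.38
print(obs.sterile_released,                          # 2000
      obs.field_emergence["n_males"],                # 63
      sup.achieved_ratio(obs.sterile_released,
                         obs.field_emergence["n_males"]))  # 32
print(round(params.gross_fertility_rate, 2))         # 72.12
print(round(params.gross_hatch_rate, 2))             # 13.07
print(round(params.mean_age_net_fertility, 2))       # 45.77
print(round(params.intrinsic_rate, 4))               # 0.0858
```

Reading: parasitoids removed ~65% of immatures, so only 63 fertile males
emerged against 2000 released sterile males — an achieved ratio of 32:1
instead of the nominal 10:1. Egg hatch collapsed to 13% (vs ~80% in an
untreated cage), cutting the intrinsic rate of increase from ~0.13/day to
0.086/day. The remaining reproductive fraction
`(1−p)·h ≈ 0.35 × 0.13 ≈ 4.5%` means fewer than one in twenty flies'
reproductive potential survives one generation of the combined treatment.

The same analysis runs from the shell:

```bash
cagedemog simulate --seed 1 --out trial/
cagedemog lifetable --in trial/observations --window 0:51 \
    --out trial/lt.csv --params trial/params.json
cagedemog run --seed 7 --out full_run/     # 4 arms x 5 replicate cages
```

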
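# Methods

`cagedemog` models the joint suppression of a *Anastrepha ludens* (Mexican
fruit fly) population by augmentative parasitoid releases (ABC) and the
sterile insect technique (SIT), at the scale of a replicated field-cage
trial. This note documents the model, its assumptions, the defaults, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Cohort timeline and life table

Ages are counted in days since egg deposition. Third-instar larvae are
placed in the cage at age 14 d, adults emerge around age 29 d, and females
oviposit at adult ages 12–22 d, i.e. cohort ages 41–51 d. Observation stops
at the 51-day horizon, which makes the life table *partial*: it covers the
full oviposition window but not post-reproductive survival. This timeline
puts the mean age of net fertility at ≈ 46 d, the scale reported for all
treatment arms of this kind of trial.

The life table is built from three daily series — females alive, eggs
collected, eggs hatched — as

* `lx` = females alive at age x / females in the original (first-day) adult
  cohort; ages before the first record carry `lx = 1` (no immature
  mortality is tracked), gap days carry the last value forward;
* `Mx` = eggs collected / females alive (0 when no females are alive);
* `hx` = eggs hatched / eggs collected (0 when no eggs);
* net maternity = `lx·Mx·hx`, hatched eggs per original female per day.

Eggs recorded on a day with zero live females is a data error, not a
division by zero.

## Reproductive parameters

From a table restricted to an age window (default the whole 0–51 d table):

* gross fecundity rate `Σ Mx` (eggs/female), gross fertility rate
  `Σ Mx·hx` (hatched eggs/female), and gross hatch rate
  `100·Σ Mx·hx / Σ Mx` (%), which satisfy GFR = GF × GHR/100 exactly;
* eggs per female per day = `Σ lx·Mx·hx` / window length (52 d for 0–51);
* mean age of net fertility `T = Σ x·lx·Mx·hx / Σ lx·Mx·hx` (d);
* the intrinsic rate of increase `r` solving Euler–Lotka,
  `Σ exp(−r·x)·lx·Mx·hx = 1`, plus the approximation `ln(GFR)/T`.

Two conventions deserve a note. First, maternity is counted in hatched eggs
of **both sexes** by default, because the `ln(GFR)/T` approximation under
that convention reproduces the published per-arm rates of this assay class
to ±0.002; the textbook daughters-only variant is available via
`daughters_only=True` (it lowers r by `ln 2 / T` at a 1:1 sex ratio at a
point mass). Second, "eggs per female per day" divides by the *window
length*, not the reproductive span — it is a per-calendar-day average. A
published value of −0.29 for this quantity in one combined-treatment arm is
arithmetically impossible for any nonnegative schedule and is not emulated.

Numerics: the Euler–Lotka root is found by bisection on a bracket
auto-expanded from [−1, 2] (the left residual grows without bound as
r → −∞, the right one falls to −1, and the residual is strictly decreasing,
so the root is unique). Tolerance 1e−12 on r, ≤ 200 iterations, and the
residual at the accepted root must be < 1e−10; `sign(r) = sign(Σ lx·Mx·hx − 1)`
by construction. Zero net maternity raises rather than returning NaN, and
`reproductive_parameters` returns an explicit `defined=False` record for
all-zero fecundity tables.

## Suppression model

Mating competition follows the standard form: a wild female mates fertile
with probability `F/(F + c·S)` for `F` fertile and `S` sterile males with
Fried competitiveness `c`. Egg hatch is the mixture
`h = h0·F/(F+cS) + hs·cS/(F+cS)` with `h0` the fertile-cross hatch and `hs`
the residual sterile-cross hatch (default 0; full sterility at the
operational irradiation dose is an assumption). The Fried index
`c = ((Ha−Ho)/(Ho−Hs))/(S/F)` inverts this mixture exactly, which is tested
as a round-trip property.

Parasitism removes a fraction `p` of immatures before emergence, so in a
single generation the fraction left to breed is `(1−p)·h` — multiplicative,
because the two mechanisms act on different life stages. The synergy of the
combined treatment enters through release sizing: sterile numbers are sized
from the sentinel-cage emergence of an *unparasitized* sample, so parasitism
shrinks `F` but not `S` and the achieved ratio inflates from the nominal
10:1 to `10/(1−p)` — ≈ 29:1 at 65% parasitism, matching what combined-arm
trials actually report. `additivity_gap` quantifies the departure of the
combined remaining fraction from the product of marginal effects; it is
negative (synergistic) exactly when the combined hatch falls below the
SIT-only hatch.

The generation projection multiplies the population each generation by
`R · (1−p) · h_t/h0`, with `h_t` computed at that generation's ratio of the
(fixed) release to the standing fertile population, plus an optional
immigration influx. The untreated replacement `R` defaults to `exp(r·T)` of
the control arm. Note that at laboratory-scale fecundity this is ≈ 330 per
generation, so a fixed 10:1 release cannot outpace growth; eradication
trajectories require either the field-realistic `R` of order 1–5 (exposed
as `per_generation_R`) or releases that keep `R·(1−p)·h/h0 < 1`. This is a
consequence of cage fecundity being density-free, not a model defect.

## Synthetic-data generator

One simulated trial draws, from a single seeded `numpy` RNG stream:
sentinel emergence ~ Binomial(100, e); parasitized immatures ~
Binomial(500, p) in ABC arms; adult flies ~ Binomial(survivors, e) split
Binomial(·, 0.5) into sexes, and parasitoid adults ~ Binomial(parasitized,
e) (same emergence rate, which makes the recovered parasitism percentage
unbiased); the sterile release from the sentinel estimate; then, per day,
eggs ~ Poisson(females·fecundity) on oviposition ages, hatches ~
Binomial(eggs, h), deaths ~ Binomial(females, m).

Defaults are the study conditions: 500 founder larvae, emergence 0.80,
control hatch 0.80, target ratio 10:1, daily adult mortality 0.02, 50
eggs/female/day (chosen to put the control gross fertility rate at the
reported ≈ 420–440 hatched eggs/female), parasitism 0.65 for the larval
parasitoid (*Diachasmimorpha longicaudata*-like) and 0.35 for the pupal
parasitoid (*Coptera haywardi*-like).

What the generator does **not** emulate, hence what passing tests do not
show about real data: immature mortality before emergence (lx = 1 until
adulthood), age-varying fecundity and mortality within the oviposition
window, sphere-level oviposition structure, parasitoid foraging behaviour,
weather, and overdispersion beyond binomial/Poisson. One known divergence
from published grids: because `Mx` is per *living* female, a
parasitoids-only arm has control-level per-female rates (parasitism reduces
the population, not individual fecundity), whereas published
parasitoids-only gross fertility rates are ≈ 5× below control, implying a
different normalization of egg totals there. No downstream computation in
this package depends on that normalization.

`expected_life_table` returns the deterministic schedule implied by a
configuration (geometric adult survival, flat fecundity, model hatch with
the parasitism-inflated ratio) and serves as ground truth for parameter
recovery: at study scale, 100 simulated combined-treatment cages recover
parasitism within 3 points, hatch within 0.03 and r within 0.01 of that
truth.

## Treatment statistics

Parasitism percentage is adult parasitoids × 100 / (flies + parasitoids).
Comparisons use parametric tests on untransformed percentages, as is usual
for these trial summaries: one-way ANOVA (scipy), Welch's heteroscedastic
ANOVA (closed-form implementation, Welch–Satterthwaite denominator df),
Welch's t (scipy), the k-sample log-rank test with right-censoring
(lifelines), and a mixed between-treatment × within-day ANOVA for daily net
reproduction (pingouin), which requires a balanced replicate × day layout.
Degenerate all-equal inputs return F = 0, p = 1 rather than erroring. Under
identical-treatment nulls simulated with the generator, the Welch t and the
ANOVA reject at 4.8–5.0% at α = 0.05 (2000 replicates).

## Pipeline

`run_pipeline` simulates every treatment arm (replicate seeds derived via
`SeedSequence(global_seed, spawn_key=(arm, replicate))`, so any cage can be
re-run alone), builds life tables and parameters, runs the applicable
comparisons, fits the Fried index from the simulated control/treated
hatches, projects generations, and writes CSV/JSON artifacts plus a text
summary. Identical config + seed give an identical bundle. Problem sizes
throughout (5 replicates × 4 arms, 500 larvae, 100-cage recovery runs,
2000-replicate null calibrations) are the package's chosen study scale.
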
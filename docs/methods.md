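# Methods

`splxann` implements, as a reusable pipeline, a simulation-plus-classifier
procedure for asking whether two small experimental groups differ: train
consensus ensembles of multilayer perceptrons (MLPs) on artificial
populations simulated from per-cell parameter estimators of the observed
cohort, and read group separability off the ensembles' per-class
prediction accuracy — alongside the frequentist battery (t tests, ANOVA,
repeated-measures ANOVA, Kruskal–Wallis, Dunnett) such a study would
normally run.  The concrete design it models is a splenectomy-MCAO mouse
experiment: 13 splenectomized (SPLX) and 14 sham-operated (SPL-sham)
animals observed on post-stroke days 2, 4, 7 and 28 for body mass, Garcia
neurological score (NS), MRI ipsi-/contralateral hemisphere volumes and
two bioluminescence (BLI) readouts.

## Synthetic cohort generator

No raw animal data are available, so a generator stands in for the study
cohort.  For each variable `v`, animal `i` in group `g`, day `d`:

```
x_ivd = mu_v + tau_v(d) + beta_g(v, d) * sigma_v + sigma_v * (sqrt(rho) * a_iv + sqrt(1 - rho) * e_ivd)
```

* `mu_v`, `sigma_v` — baseline location and scale (defaults: mass 24 ± 1.6 g,
  NS 18 ± 1.2, MR IL 228 ± 11 mm³, MR CL 225 ± 9 mm³, BLI flux
  1.2e7 ± 6e6 photons/s, BLI radiance 2.4e5 ± 1.2e5 photons/s/cm²/sr);
* `tau_v(d)` — the stroke trajectory shared by both groups: mass dips ~3 g
  at days 2–7 and mostly recovers by day 28; NS drops to ~10 acutely and
  recovers toward 15; the ipsilateral hemisphere swells early (edema,
  +30 mm³ at day 2) and shrinks slightly below baseline at day 28; BLI
  surges ×6–9 acutely and decays.  For the log-normal BLI variables the
  trajectory is multiplicative and the whole model lives on the log scale;
* `beta_g(v, d)` — the standardized SPLX-minus-sham effect in units of
  `sigma_v` (defaults ≤ 0.3 SD: slightly better NS, smaller ipsilateral
  volume, lower BLI under splenectomy; a null configuration sets all to 0);
* `a_iv` — a per-animal random intercept and `e_ivd` independent day noise,
  giving every pair of days within an animal correlation `rho`
  (default 0.5) while keeping the cross-sectional SD equal to `sigma_v`.

NS values are rounded half-away-from-zero and clamped to the Garcia range
[3, 18]; strictly positive variables are floored at 5% of their baseline
mean.  Mass, NS and the MRI volumes are Gaussian on the raw scale; the BLI
variables are log-normal (photon counts are positive and right-skewed).

All default magnitudes are plausibility stand-ins for a C57BL/6 MCAO
cohort, chosen once so that per-day t tests at n = 13/14 are typically
non-significant for sub-0.5-SD group effects while the day (time) effects
are overwhelming.  What the generator does **not** emulate: attrition,
missing visits, floor/ceiling clustering of NS in severely impaired
animals, measurement-linked correlation between the two BLI readouts
beyond what `mv-normal` simulation reintroduces, and any non-exchangeable
longitudinal structure (e.g. AR(1) decay of within-animal correlation).
Passing tests therefore certify the pipeline's behaviour under this
idealised data-generating process, not under real cohort pathologies.

## Estimators and artificial populations

`fit_estimators` reduces a cohort to per-(group × day × variable) cells:
n, sample mean, (n−1)-denominator SD, SEM, and a central-t 95% CI;
optionally a per-(group × day) correlation matrix across the six measured
variables, estimated on the modelling scale (log for BLI) and shrunk
toward the identity (initial weight 0.1, doubled until positive definite)
— 13 animals cannot support an unregularised 6×6 correlation.

`simulate_population` expands the estimators into an artificial population
(default 500 animals per group, each with one row per day):

* **plugin** mode draws each cell from its estimated mean and SD;
* **ci-perturbed** mode (the default) first draws the cell's population
  mean uniformly from the cell's 95% CI, then draws values around it with
  the estimated SD — propagating small-sample parameter uncertainty into
  the population.

Marginals mirror the generator (Gaussian; moment-matched log-normal for
BLI; NS rounding and clamping).  `mv-normal` correlation draws the per-day
variable vector through a Gaussian copula with the shrunken correlation
matrix.  The population size of 500/group is a package choice: large
enough that ensemble training is stable, small enough for desk-scale runs.

## Consensus-MLP evaluation

The classifier is a seven-hidden-layer MLP — widths (72, 96, 72, 48, 32,
16, 8), ReLU on hidden layers 1–6, logistic sigmoid on hidden layer 7 and
on the single output unit (P(SPLX)) — with inverted dropout (rate 0.2)
after every hidden layer, trained with Adam (initial learning rate 1e-3)
on binary cross-entropy in mini-batches of 32.  With a 7-feature input
this is 20,313 trainable parameters.  The implementation is plain numpy
(float32, flat parameter vector, stacked matmuls when several members
train jointly), bit-reproducible for a fixed seed, with an exhaustive
finite-difference gradient check in the test suite.

One evaluation replicate: split the animals 70/30, stratified by class,
all rows of an animal staying on one side (row-level splits would leak
animal identity across partitions); train each of 15 ensemble members
(5 in the scaled-down setting) on an animal-level bootstrap resample of
the training partition; stop early when the validation-partition loss has
not improved by 1e-4 for 20 epochs and restore the best weights; classify
every validation record by majority vote of the members' thresholded
P(SPLX) ≥ 0.5, exact ties going to a fixed class (SPL-sham).  Per-class
accuracy is the class-conditional recall — the only reading under which
the two classes can score differently for one classifier.  A condition's
result is the mean ± SD of these recalls over independent replicates
(default 20; replicates must be ≥ 2 so the SD exists).

## Ablation grid

The seven model inputs are day, MR IL, MR CL, mass, NS, BLI flux and BLI
radiance.  The grid crosses a day filter (all days / without day 2 /
without days 2 and 4) with the baseline plus every non-empty proper
subset of the inputs as an exclusion: 2^7 − 1 = 127 conditions per day
filter, canonically ordered by subset size then variable order.  `day` is
fed as a numeric covariate when retained and simply dropped as a column
when excluded (rows stay).  Per-condition seeds derive from the master
seed keyed on the condition id, so results are independent of execution
order and of which conditions run; finished conditions checkpoint to JSON
and a corrupt checkpoint raises instead of being silently recomputed.
One population is simulated per day filter and shared across its 127
conditions (re-simulation per condition is available through the
simulation seed, but sharing keeps conditions comparable).

## Statistical battery

`stats` wraps scipy (Shapiro–Wilk, Student/Welch/paired t, one-way ANOVA,
Kruskal–Wallis with tie correction, Dunnett via the multivariate-t
distribution) and pingouin (mixed between × within ANOVA).  Sphericity of
the repeated-measures within factor is handled by Greenhouse–Geisser
epsilon-scaling of both degrees of freedom, reported alongside the
uncorrected test; Huynh–Feldt is available behind a flag; with two within
levels epsilon is exactly 1.  Degenerate inputs are contracts, not
surprises: zero-variance t comparisons raise, an all-constant
Kruskal–Wallis returns H = 0 with p = 1, and all-constant Dunnett input
yields no significant comparison.  Normality gating (ANOVA vs
Kruskal–Wallis) is reported, never silently applied.

The grid summary compares, per day filter: each exclusion condition's
per-class replicate accuracies against the baseline condition with
Dunnett's test (126 many-to-one comparisons, replicates as the unit of
analysis), and each condition's SPLX vs SPL-sham accuracies with a Welch
t test (127 comparisons; the two accuracy samples come from common splits
but the unpaired test is the generic reading of a two-sample comparison
here).  It reports counts, fractions and the largest signed class-accuracy
differences with the conditions achieving them.

## Scale profiles and problem sizes

Full-scale settings (15 members × 20 replicates × 200 epochs × 3 × 127
conditions) are for real studies.  The package's own measurements — the
test suite and `scripts/acceptance.py` — use the desk-scale profiles:
*scaled-down* (5 members, 5 replicates, 50 epochs, one day filter; the
null-calibration check uses 20 replicates) and *smoke* (3 members, 3
replicates, 20 epochs, two variables, 60 animals/group) for end-to-end
determinism.  These sizes are the package's chosen trade-off between
Monte-Carlo error and a desk-scale run.

## Calibration findings and limitations

The package's own calibration measurements (reproducible via
`scripts/acceptance.py`) show a property users must understand before
interpreting ensemble accuracies:

**The procedure is anticonservative under a true null.**  With all group
effects set to zero, the consensus accuracy on a ci-perturbed population
simulated from the n = 13/14 cohort is far above chance (≈ 0.75–0.80 per
class at desk scale), not ≈ 0.5.  The mechanism is structural: populations
are simulated per group from group-specific cell estimators, so every
cell mean carries sampling noise of roughly `sigma * sqrt(1/13 + 1/14)`
≈ 0.38 SD, plus uniform CI-perturbation jitter (≈ 0.47 SD); across six
variables that is a per-record Mahalanobis separation near 1.5 SD between
the two simulated classes — and because training and validation partitions
are split from the *same* population, that noise is genuine, learnable
signal within it (expected Bayes accuracy ≈ Φ(0.73) ≈ 0.77, matching the
measurement).  Plugin mode lowers but does not remove the elevation.
Consequently an above-chance ensemble accuracy alone is **not** evidence
of a group effect; only the *contrast* between conditions (e.g. accuracy
dropping toward the measured null floor when the carrying variable is
excluded, or rising monotonically with the injected effect size — both of
which the acceptance checks verify) carries information.  The test suite
states the idealised chance-band expectations explicitly and documents
that the measured floor sits above them.

Other limitations: the monitoring set for early stopping is the
validation partition itself (a deliberate, documented choice matching the
single-split design; it mildly optimises members toward that partition);
accuracies are evaluated per record, not per animal, so an animal's four
days contribute four votes; Dunnett p-values come from numerical
multivariate-t integration (agreement with a 10^6-draw Monte-Carlo
critical value is verified to 0.01); and the generator defaults are
stand-ins, not fitted to any real cohort.
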
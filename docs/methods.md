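# Methods

## The estimation problem

An automated head chamber system (AHCS) measures instantaneous gas flux —
CO₂ and CH₄ emission and O₂ consumption, all in g/d — each time an animal
voluntarily visits a bait station.  An animal's daily flux is estimated as
an average over its spot samples.  Short visits are suspect: the analyzer
may not capture a full breathing cycle, so flux from sub-minute visits
reads far low (published pooled data put the shortfall near −70% for CH₄
below 1 min, shrinking to roughly −5% at 2–3 min, and ≈ +2% at 3–4 min).
The package quantifies the two design consequences: how the minimum-visit-
duration rule shifts the estimates, and how it changes the number of visits
each animal must contribute before the estimate agrees excellently with the
gold standard.

**Gold standard.** Per animal, the arithmetic mean over all QC-passed
visits ≥ 3 min long.  All candidate estimators are compared to it.

## QC

Two sequential screens: airflow < 26 L/s (incomplete breath-cloud capture),
then any present gas value strictly above its ceiling (CO₂ 20,000 / O₂
15,000 / CH₄ 500 g/d).  Boundary values are kept (the exclusion rules are
strict inequalities); a record failing both screens is charged to the
airflow stage; missing channels never trigger removal; negative fluxes are
retained with a logged warning (there is no lower QC bound).  The report's
identity `n_output = n_input − n_airflow − n_flux` is enforced by
construction, and re-running QC on filtered output removes nothing.

## Averaging methods

*Arithmetic*: plain mean over qualifying visits.  *Time-bin*: visits are
grouped by start-time clock hour into eight 3-h bins, within-bin means are
averaged across **occupied** bins (empty bins are excluded, not imputed;
per-animal occupied-bin counts are exposed because thinly occupied bins
inflate the weight of a handful of visits).  Bin membership uses the visit
start time only — visits are minutes long against 3-h bins, so splitting
boundary-spanning visits would add complexity without information.  With a
programmed inter-visit lockout forcing visits to spread over the day, the
two methods differ little; the package reports their signed mean difference
(and as a percent of the time-bin mean) so users can check this on their
own data.

## Agreement statistics

Lin's concordance correlation coefficient with **population (1/n)
moments**:

    CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²),   C_b = CCC / r.

The moment convention matters here: with the squared mean difference in the
denominator, 1/n and 1/(n−1) give different values, so it is pinned to the
original estimator (and verified in the tests against an independent
closed-form evaluation to 1e-12).  When r is numerically zero C_b is
undefined and reported as NaN rather than divided out.  RMSE is expressed
as a percent of the gold-standard mean.  No confidence intervals are
computed — the downstream decisions use point statistics with a fixed
excellent-agreement cut (CCC ≥ 0.90, configurable).

## Subsampling experiment

For thresholds ≥3 / ≥2 / ≥1 min and n ∈ {5, 10, …, 60}: draw n qualifying
visits per animal uniformly **without replacement** (distinct visits is the
natural reading of randomly selecting from an animal's record), average
them, and compare across animals with the gold standard, which is never
subsampled — so even the ≥3-min candidate at small n is a proper subset
comparison.  Default 100 replicates per cell; the decision statistic is the
replicate-mean CCC with a first-crossing rule (smallest n at or above the
cut; non-monotone curves are flagged).  A `single_draw` mode reproduces the
one-draw-per-cell variant.

Design choices that matter:

* **Eligibility** — animals must support the largest n in the grid (60), so
  the animal set is constant across the grid.  By default the same set is
  also used for **every threshold** (the qualifying sets are nested, so
  this is the strictest threshold's eligible set).  Without this, the
  ≥3-min cells can use a substantially smaller, lower-variance subset of
  animals than ≥1-min cells, and the cross-threshold comparison confounds
  the duration rule with cohort composition.  `common_animals=False`
  restores per-threshold sets.
* **Implementation** — per replicate, each animal's qualifying visits are
  permuted once (streams spawned from the design seed per threshold) and
  prefix means give the estimates for all n at once.  Each cell is still an
  exact uniform simple random sample; subsets are nested across n within a
  replicate, which acts as common random numbers across the n-grid and
  smooths the CCC-vs-n curves.  Agreement statistics for all cells are
  evaluated with a vectorised batch routine proven equal to the scalar one
  in the tests.  Results are bit-reproducible from the design seed.

## Synthetic cohort generator

The generator emulates the data-generating setting the pipeline assumes,
with defaults describing a feedlot-style cohort:

| parameter | default | rationale |
|---|---|---|
| animals / study days | 53 / 42 d | feedlot-cohort sizing |
| true flux, between-animal | CO₂ 9860.5 ± 835.81, O₂ 6706.4 ± 631.08, CH₄ 149.9 ± 33.0 g/d | published finishing-steer summaries; normal truncated 3 SD below the mean |
| candidate visit rate | 3.4 /d | before lockout thinning; realized rate (~2.0 /d) reported in provenance |
| diurnal peaks (hour, spread, weight) | (7.5, 1.5, 0.45), (15.5, 1.5, 0.40), (1.0, 2.0, 0.15) | morning and afternoon peaks with a smaller overnight one |
| min inter-visit gap | 4 h | programmed lockout |
| duration | log-normal(μ=1.75, σ=0.75 log-min), truncated [0.2, 12] min | right-skewed, empirical mode ≈ 3.8 min, ~77% of visits ≥ 3 min |
| bias curve | per-gas, per-range multiplicative (see `DEFAULT_BIAS_CURVE`) | published pooled per-range shortfalls vs the ≥3-min mean |
| visit noise | CV 0.15, correlations CO₂–O₂ 0.8, each–CH₄ 0.5 | one breath-cloud capture drives all three channels; CV is a free parameter (no published visit-level CV), properties hold across 0.10–0.25 |
| planted violations | 2% low airflow (uniform 20–26 L/s), 0.5% flux spikes | known rates, disjoint sets; clean records are drawn above the screens so QC removals are exactly the planted records |

Visit times: per day a Poisson(rate) number of candidates, each assigned to
a peak by weight and timed as a wrapped normal; candidates are swept in
time order and any within the lockout gap of the last accepted visit are
discarded.  The gap constraint is therefore hard, and with a 4-h gap at
most 6 visits fit per day.

The measurement model is multiplicative,
`observed = true × (1 + bias(duration)) × (1 + ε)`: fluxes are positive and
the published shortfalls are percentages, so a multiplicative form
reproduces the per-range pattern across animals of different magnitude.
The bias curve is piecewise-constant over the seven standard ranges
(matching how the calibration values are published); optional linear
interpolation at range midpoints is available but off by default.

**What the generator does not emulate**: day-level or seasonal drift in
true flux, diet/treatment effects, animal-specific visit-rate or duration
preferences, within-day flux cycles (diurnal variation enters only through
visitation timing), and mechanistic rumen fermentation.  Passing tests
therefore show the *pipeline* recovers known structure under the assumed
data-generating model — not that real AHCS data satisfy those assumptions.
In particular the default visit-level CV (0.15) is milder than typical
field data, so the minimum-visits decisions on synthetic cohorts
(≈ 5–20 visits) sit below published field recommendations (25–40); the
qualitative structure — CCC rising with n, stricter thresholds needing no
more visits than relaxed ones, relaxed-threshold estimates biased low — is
the transferable finding.

## Numerical and degenerate-input conventions

* Duration rules are half-open `[lower, upper)`; the seven ranges partition
  the visit multiset exactly.
* Thresholds keep the boundary (≥); QC keeps boundary values (strict
  exclusion); time bins are half-open on the clock.
* Agreement requires ≥ 3 pairs and nonzero variance on both sides; cells
  that fail are omitted with a note, never silently.
* A single-visit animal reports SD as missing; per-animal observation days
  use the inclusive calendar span (last − first + 1), a documented choice
  since the source summaries do not define their denominator.
* Float tolerance: round-trip I/O to 1e-9; CCC oracle equivalence to 1e-12;
  "exact" generator checks to 1e-12 relative (mean-of-identical-values
  floating error).
* Acceptance-scale runs use 20 seeded default cohorts with 100 replicates
  per subsampling cell; the vectorised grid keeps this under a minute.

## Known limitations

* The published-summary module carries printed values verbatim, including
  one implausible SD (O₂, ≥6-min range) that no computation uses.
* Two printed CO₂ percentages for long-duration ranges are inconsistent
  with the published table means they summarise; the bias-curve defaults
  follow the printed percentage series, which is near zero there and has
  negligible effect above 4 min.
* Time-bin estimates exclude animals' empty bins rather than modelling
  them; users screening for day coverage should use the reported
  occupied-bin counts.
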
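# Methods

`hipdd` implements a quasi-experimental evaluation pipeline for
community-level injury prevention: registry-based hip-fracture incidence
construction, difference-in-differences (DD) with nearest-neighbour
matching on pre-intervention trends, four effect measures with Poisson and
design-effect-adjusted inference, and a fixed-effects meta-analysis of
municipality-specific effects. This note records the models, the defaults,
and the design choices made where more than one reasonable construction
exists.

## The estimand and the design

Municipality-level panels of annual hip-fracture incidence (cases per
100,000 person-years among residents aged 65+) are compared between a small
treated group and matched controls. Writing `T_t` for the treated aggregate
rate, `C_t` for the matched control series and
`g = mean_pre(T − C)` for the pre-intervention mean gap:

* **DD** `= mean_post(T − C) − g`, an additive rate change per 100,000
  person-years, causal under the common-trends assumption;
* **dynamic effects** `(T_t − C_t) − g` per post year, which display the
  time profile of the response;
* **IRR** `= (T̄_post/T̄_pre) / (C̄_post/C̄_pre)`, a relative ratio-of-ratios
  whose pre-normalisation removes level differences between arms. A
  post-only ratio would confound any residual level gap with the effect,
  which is why the ratio-of-ratios form is the default and the only one
  implemented;
* **CE** `= Σ_post (T_t − C_t − g) · P_t / 1e5`, the cumulative number of
  cases prevented, with `P_t` the treated person-years.

## Case definition

An admission qualifies as a hip fracture when it carries a femoral-fracture
diagnosis in the hip range (ICD-10 S72.0–S72.2) *and* a NOMESCO procedure
code for femoral-fracture surgery (NFJxy, x = 0–9, y = 0–2) or hip
replacement (NFBxy, x = 0–4, y = 0–2; plus NFB62). The conjunction is the
validated registry definition for Nordic discharge data; diagnosis-only or
procedure-only admissions are rejected.

Normalisation: codes are uppercased and periods/whitespace stripped before
matching, because registry dialects differ ("S72.0" ≡ "S720"). Diagnoses
match on the stem prefix, so national fifth characters ("S7201") qualify;
procedure codes must match the five-character patterns exactly, since the
patterns constrain both trailing digits. One admission is at most one case;
a `dedup` flag collapses to one qualifying admission per patient-year but
is off by default because the registry measure counts admissions.
Municipalities lacking any study year (typically through administrative
mergers) are removed by `completeness_filter`, since every estimator
requires complete series.

## Matching

Controls are selected by nearest-neighbour matching on the
pre-intervention outcome series. The distance is the mean squared
discrepancy over pre-years; the default compares raw levels
(`level-mse`) because level differences between arms propagate into the
count-scale inference even when trends agree; demeaned and
first-difference variants are provided for trend-only matching. The
matched control series is the **unweighted mean** of the k nearest donors —
a transparent average of real municipalities, deliberately not a
re-weighted synthetic composite, which tends to chase sampling noise in
small-area incidence series.

The donor count k is chosen by cross-validation: donors are ranked on the
training pre-years only, and each k in 1..k_max is scored by the mean
squared prediction error of the k-donor average against the treated series
on held-out validation years (default: the last three pre-intervention
years, a forward-looking holdout mimicking the forecasting task the match
must perform; a different holdout can be configured). Ties in the CV curve
resolve toward smaller k (parsimony); distance ties resolve toward the
smaller municipality id (determinism). The final donor set re-ranks
candidates on **all** pre-years, since the training-only ranking exists
only to keep the CV score honest; ranking on training years alone is
available as an option. `k_max` defaults to 50 and is clipped with a
warning when it exceeds the candidate count.

For group-level analyses the treated units are pooled into one
population-weighted aggregate series (sum of cases over sum of
person-years) — the group's actual incidence rate; municipality-specific
analyses match each treated unit separately against the untreated pool.

## Inference

Counts are treated as Poisson. Each aggregate cell contributes a rate
variance `1e10 · cases / person-years²`; delta methods propagate to each
measure's scale, and the IRR interval is computed on the log scale
(`var(log rate) ≈ 1/cases` per aggregated period cell). Zero period cells
receive a Haldane–Anscombe 0.5 continuity correction with a warning.

**Matched-control variance.** The default is the exact delta-method
variance of the unweighted donor mean, `(1/n²) Σ_i 1e10·cases_i/pop_i²`.
Two alternatives are provided: `pooled` (the variance of the donors'
aggregate rate — identical to the default when donor populations are
equal) and `donor-mean`, which treats the donor average as a single
Poisson count of mean magnitude. The last convention discards the 1/n
averaging gain and therefore overstates the control variance roughly
n-fold; it is kept as a deliberately conservative option, not the default,
because it makes the nominal 95% interval cover far above its level in
calibration simulations.

**The pre-period gap.** The DD, dynamic and CE intervals treat `g` as a
fixed offset (`gap_variance="fixed"`), propagating Poisson variance from
the post-period cells only. Nearest-neighbour selection pins the matched
series to the treated series over the pre-period, so the realised pre gap
is strongly anti-correlated with the pre-period sampling noise; adding the
pre cells' variance as if independent double-counts noise the selection
already absorbed and pushes null coverage toward 1. The conservative
four-cell convention is available as `gap_variance="propagated"`. The IRR
retains the four-period-cell log-scale variance, which is the standard
count-ratio formula.

**Cluster adjustment.** Standard errors are inflated by `√DEFF` with
`DEFF = 1 + (m̄ − 1)·ICC`, where the intra-cluster correlation is the
one-way ANOVA estimator on the municipality-year rates of the matched
sample (treated plus donors, all study years; unbalanced clusters use the
standard `m0` coefficient), floored at 0 and capped at 1. With
heterogeneous municipality levels this ICC absorbs persistent
between-municipality variance, which cancels in the within-municipality DD
contrast — the adjustment is therefore conservative by construction in
that regime, which is the intended behaviour of a design-effect
correction. P-values are two-sided normal on the adjusted SE.

## Meta-analysis

Municipality-specific relative effects are pooled on the log-IRR scale
(standard for ratio measures; the pooled IRR back-transforms to a percent
change, e.g. 0.89 ↔ −11%) with inverse-variance fixed-effects weights
`w_i = 1/se_i²`. Cochran's Q with k−1 degrees of freedom tests
homogeneity. No random-effects model is offered: the pipeline's estimand
is the fixed-effects summary of the observed treated municipalities.

## The synthetic registry

The generator emulates a national admission registry aggregated to an
annual municipality panel, with known ground truth so that every
downstream stage is testable without confidential data. Counts are Poisson
(optionally gamma-Poisson overdispersed) around
`pop · max(m_c·(b_i + s_i·t + δ·D_it), 0)/1e5`: municipality baselines
`b_i` and linear slopes `s_i` are normal across municipalities, the
additive effect δ applies to treated units from the intervention year, and
stratum multipliers `m_c` (age 65–79/80+ × sex) are normalised so δ is
exactly the additive effect on the aggregate 65+ rate. Linear trends are
the simplest structure under which matching on pre-intervention trends is
well-defined and recoverable. Populations are fixed over time, isolating
rate dynamics. Seeding uses one master seed with per-municipality
substreams (prefix-stable, so enlarging the panel never perturbs existing
units), and the record-level generator shares the count substream with the
panel generator, making the case-definition round trip exact.

Defaults are the study conditions the pipeline targets: 420 municipalities
with 15 treated, calendar 1999–2014 with the intervention in 2007, a
baseline 65+ rate of 1,200 per 100,000 with SD 450 across municipalities,
a secular trend of −12 per 100,000 per year (≈ −1%/year, the documented
decline in Norwegian hip-fracture incidence over this period) with SD 8,
mean 65+ population 1,800 (SD 1,500, floored at 150), 28% of the 65+
population aged 80+, 55% female, a 2.25× rate ratio at 80+ and 1.86×
women/men. These choices reproduce the observed cross-municipality spread
of annual rates (≈550 per 100,000 at 65+) once Poisson noise is added to
the between-municipality SD in quadrature. The record generator emits
qualifying code pairs for every true case plus configurable decoy
admissions (femoral-shaft S72.3, diagnosis-only, procedure-only, NFB50,
NFJ93 and non-S72 patterns) at 0.2 decoys per expected case by default.

What the generator does **not** emulate: seasonality, migration,
mortality competing risks, population dynamics, municipality mergers, and
— by default — serial correlation within municipalities (an AR(1)
log-rate option exists but independence is the default, since the
within-municipality error structure of real registry data is not
identified here). Passing tests therefore demonstrate correctness of the
estimators under Poisson sampling with linear heterogeneous trends, not
robustness to every feature of real registry data.

## Numerical choices and degenerate inputs

* Ties: CV ties → smallest k; distance ties → smallest municipality id;
  `np.argmin` takes the first minimum, matching both rules.
* Zero cells: IRR continuity correction (+0.5 per aggregate period cell,
  warned); all-zero rate intervals warn of infinite relative width.
* Single cluster or single year per cluster: DEFF = 1 with a warning.
* Truncation: expected rates are floored at 0, so large negative injected
  effects on low-rate municipalities attenuate slightly; with the default
  conditions this shifts the recovered mean effect by a few per 100,000 at
  most.
* Determinism: identical configuration and seed reproduce every output
  byte for byte (CSV written with fixed float formatting, JSON with sorted
  keys).

## Known limitations

* Nearest-neighbour selection on noisy pre-periods induces a small
  regression-to-the-mean bias in the matched DD under heterogeneous
  trends (of the order of −10 per 100,000, below one Monte-Carlo standard
  error of a single replicate, in the default conditions). It is a
  property of matching on observed series, shared with synthetic-control
  methods, and is documented rather than corrected.
* The design-effect adjustment is conservative when municipality levels
  are heterogeneous but serially independent; it is calibrated in the
  homogeneous regime the correction is meant to protect (see the
  calibration tests).
* Problem sizes in the test suite: the statistical acceptance checks use
  200 replicates per recovery arm, 500 for interval coverage and 1,000
  for Q-test calibration, at the full 420-municipality panel size.
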
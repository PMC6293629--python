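# hipdd

Registry-based hip-fracture incidence panels and trend-matched
difference-in-differences evaluation of community prevention programs.

## The problem

Hip fractures among older adults are frequent, costly and often
preventable, and municipalities run community-level prevention programs
(exercise, education, home-safety modification). Whether such programs
shift *population-level* incidence is hard to establish: programs are not
randomised, only a handful of communities are treated, and small-area
incidence series are noisy. `hipdd` implements the quasi-experimental
pipeline an analyst needs to evaluate such a program from hospital
registry data:

1. **Case definition** — classify admissions as hip fractures by the
   validated conjunction of an ICD-10 hip-range diagnosis (S72.0–S72.2)
   and a NOMESCO surgical procedure code (NFJxy x=0–9 y=0–2;
   NFBxy x=0–4 y=0–2; NFB62), and build municipality × year × stratum
   incidence panels (65+/80+ × both/men/women, rates per 100,000
   person-years).
2. **Trend matching** — select control municipalities by nearest-neighbour
   matching on pre-intervention outcome series, with the donor count *n*
   chosen by cross-validation on held-out pre-years so the match tracks
   the trend signal rather than sampling noise.
3. **Effect measures** — on the matched panel, with treated series `T_t`,
   matched control series `C_t` and pre-period gap `g = mean_pre(T − C)`:
   the difference-in-differences `DD = mean_post(T − C) − g` (per 100,000
   person-years), per-year dynamic effects `(T_t − C_t) − g`, the incidence
   rate ratio `IRR = (T̄_post/T̄_pre)/(C̄_post/C̄_pre)` and the cumulative
   cases prevented `CE = Σ_post (T_t − C_t − g)·P_t/1e5`. Confidence
   intervals assume Poisson counts, with standard errors inflated by a
   design effect `1 + (m̄−1)·ICC` from the intra-cluster correlation of the
   matched sample.
4. **Meta-analysis** — municipality-specific log-IRRs pooled by
   inverse-variance fixed effects, with Cochran's Q testing homogeneity.
5. **Synthetic registry** — a generator of admission records and incidence
   panels with known ground truth (heterogeneous baselines and linear
   trends, injectable effects, age/sex strata, decoy codings), so the
   whole pipeline is testable without access to confidential registry
   data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a 420-municipality registry (15 treated, 1999–2014, intervention
in 2007) with an injected effect of −274.7 per 100,000, then match and
estimate on the primary stratum:

```python
from hipdd import synth, matching, effects

cfg = synth.SimulationConfig(effect=-274.7, seed=42)
panel, truth = synth.simulate_panel(cfg)
sl = panel[(panel.age_group == "65+") & (panel.sex == "both")]

spec = matching.MatchSpec(pre_years=tuple(range(1999, 2007)))
result = matching.match(sl, truth.treated_ids, spec)
print(f"cross-validated donor count: n = {result.n}")

est = effects.estimate_effects(sl, result,
                               list(range(1999, 2007)), list(range(2007, 2015)))
print(f"DD  = {est.dd:7.1f}  (95% CI {est.dd_ci[0]:.1f} to {est.dd_ci[1]:.1f}) per 100,000")
print(f"IRR = {est.irr:7.3f}  (95% CI {est.irr_ci[0]:.3f} to {est.irr_ci[1]:.3f})")
print(f"CE  = {est.ce:7.1f}  cases prevented (95% CI {est.ce_ci[0]:.1f} to {est.ce_ci[1]:.1f})")
print(f"ICC = {est.icc:.3f}, design effect = {est.deff:.2f}, p = {est.p_value:.4f}")
```

prints

```
cross-validated donor count: n = 4
DD  =  -165.4  (95% CI -426.7 to 95.9) per 100,000
IRR =   0.841  (95% CI 0.587 to 1.206)
CE  =  -386.8  cases prevented (95% CI -997.8 to 224.2)
ICC = 0.644, design effect = 10.66, p = 0.2147
```

Cross-validation kept 4 donor municipalities. The DD point estimate
(−165 per 100,000) carries the injected reduction plus one replicate's
sampling noise — across many replicates the estimator centres on the
injected −274.7 (the test suite checks this). The IRR of 0.84 reads as a
16% relative reduction, and the CE as ≈ 387 fractures prevented over the
eight post years; the wide, zero-crossing intervals show how hard such
effects are to pin down in a single 15-community panel once the design
effect (here 10.7, from the level heterogeneity of the matched sample) is
applied — the precision problem that motivates pooling and meta-analysis.

The same analysis runs from the shell:

```bash
hipdd simulate --out data --seed 42          # admission + population CSVs
hipdd build-panel --records data/admissions.csv --population data/population.csv \
    --treated data/treated.txt --out panel.csv
hipdd match --panel panel.csv --treated data/treated.txt --pre-end 2006 --out match/
hipdd estimate --panel panel.csv --post-start 2007 --out effects.csv
hipdd run --config scenario.yaml --out results/   # everything end to end
```

`hipdd run` writes the panel, the six-stratum effects table, the
municipality-specific forest table with its fixed-effects summary, a
machine-readable `summary.json` and a run log; re-running with the same
configuration and seed reproduces every file byte for byte.

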
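# Methods

This note documents the model implemented by `childimpact`: its
assumptions, parameter conventions, numerical choices, and the design
decisions taken where the calculus is genuinely open. Nothing here
states an empirical result the test suite or `scripts/acceptance.py`
does not itself compute.

## Model structure

The model is a partial cohort model over five age bands partitioning
[0, 60) months: 0m, 1–5m, 6–11m, 12–23m, 24–59m. Neonatal causes of
death (birth asphyxia, prematurity, sepsis/pneumonia, congenital
anomalies, tetanus, diarrhoea, residual) act only in the 0m band;
post-neonatal causes (diarrhoea, pneumonia, meningitis, measles,
malaria, pertussis, injury, residual) act in the four bands covering
1–59 months. AIDS is enumerated so cause-of-death profiles remain
consistent with published distributions, but flagged inactive: its
mortality depends on adult prevalence and belongs to a separate
epidemic model. A residual "all other causes" bucket is explicit so
cause fractions always sum to 1 exactly and all-cause aggregation is a
clean weighted sum; the residual can never be targeted by an
intervention.

No secular mortality trend is assumed: only coverage change moves
mortality. A scenario with flat coverage everywhere reproduces its
baseline indefinitely, and the test suite enforces this end to end.

All coverages, effectivenesses, affected fractions and prevalences are
dimensionless proportions in [0, 1] throughout the library; percent
appears only in I/O and report formatting (1 decimal place in printed
reports, full precision internally). This removes the percent/proportion
ambiguity that mixed conventions invite.

## Direct effects and attribution

The isolated reduction R = I·(Cₜ−C₀)/(1−I·C₀)·AF treats the
denominator's effectiveness as the same constant as the numerator's:
effectiveness does not vary over time, only coverage does. A coverage
decline produces a negative R (mortality increase), which propagates
through composition; attribution, however, is computed only over
positive reductions (with a warning), because crediting interventions
for a mortality *increase* has no defined semantics in this calculus.
If effectiveness × baseline coverage reaches 1 the susceptible burden
is already fully removed and the reduction is undefined; this raises a
saturated-baseline error rather than returning a limit value.

Attribution by timing tier generalises the proportional split. With T
the combined reduction of all (positive) isolated reductions and U_g
the combined reduction of tiers up to and including g, tier g's block
of credit is (U_g − U_{g−1})/T — the fraction of the total contributed
when that tier acts on the mortality remaining after earlier tiers —
split within the tier proportionally to isolated reductions. The blocks
telescope, so shares always sum to 1 for any number of tiers, and with
a single tier the scheme reduces exactly to Rᵢ/ΣRᵢ. Ties within a tier
need no tie-breaking: the proportional split is symmetric.

## Herd effects

Herd protection is phenomenological, not transmission-dynamic: a
piecewise-linear curve in population coverage with a lower threshold
(no herd protection), an upper threshold, and a maximum effect. The
default curve (0 below 90%, 1.0 above 95%, linear between) is the
established measles curve and is attached to herd-capable vaccines
unless the scenario supplies its own; bednet herd parameters are
scenario configuration. The herd increment is normalised by the
protection headroom at baseline, and the herd-adjusted reduction
hR = R + H(1−R) replaces R in composition and attribution — hR is
algebraically the residual composition of R and H, and a test pins this
equivalence. Whether the herd term protects only the unvaccinated or
the whole population when AF < 1 is not distinguishable at this level
of description; the formula is applied literally to the remaining
mortality.

## Risk-factor routes

**Two-status odds decomposition.** Solving the odds relation together
with the mixture relation reduces to a quadratic in the non-risky
prevalence; the closed-form root inside (0, 1) is taken (the system is
linear when everyone is risky or the odds ratio is 1). Residuals of
both relations are below 1e-10 across randomized parameter grids, and a
bisection oracle agrees to 1e-8 (enforced by property tests). The
odds-ratio formulation guarantees projected prevalences never leave
(0, 1), which is the reason it is used instead of relative risks.

**Four-status complementary feeding.** The four statuses are food
secure/insecure crossed with promotion, with three odds ratios relative
to the least risky status (food secure with promotion). The mixture
relation, after substituting the odds relations, is a single strictly
increasing function of the reference-status prevalence, so the root is
unique and bracketed on (0, 1). It is found with Brent's method at
xtol 1e-15 rather than by solving the equivalent quartic analytically:
same root, no quartic branch selection, and the residual checks (1e-10)
enforce correctness. The population split over the four statuses is
driven by the food-secure fraction (share above the poverty line) and
promotion coverage.

**Diarrhoea incidence.** The population-average stunting odds ratio is
the per-episode odds ratio raised to the mean episodes/year. Incidence
declines are recast as moving a proportion of children from "i
episodes" to "none": risky fraction 1 at baseline, target/baseline
afterwards. Incidence increases are not representable in this mapping
and raise an error. Water-and-sanitation interventions reduce incidence
with the same machinery as direct mortality effects (effectiveness ×
coverage change on residual incidence).

**Stunting cohort progression.** Five determinants move a band's
stunting: the carried risk (IUGR for the neonatal band, previous-band
stunting for later bands), complementary feeding, diarrhoea episodes,
and zinc-style supplementation. Bands are swept youngest to oldest each
year so the carried determinant uses the already-updated upstream
value; all bookkeeping is at the prevalence level (no individual-level
microsimulation). Each determinant contributes an isolated proportional
prevalence reduction, and determinants compose on the stunting
remaining after the others — the same residual product as mortality
composition, hence order-free. Per-band baseline stunting is an input;
the carry-over odds ratios (previous band → next band, IUGR →
neonatal stunting) are required configuration with no package defaults,
because the literature pins down only the supplementation odds ratio
(1.18); the fixture generators supply explicit synthetic values.

**Proportional declines.** The prevalence decline is defined as
(P₀ − Pₜ)/P₀, positive for declines — the sign convention that makes
"a 2.7 percent decline" a positive number.

**Breastfeeding.** Practice is modelled as four categories (exclusive,
predominant, partial, none) per band. Promotion shifts the
improved-vs-not dichotomy through the two-status solve (the promotion
odds ratio is the odds of improved practice for promoted vs un-promoted
mothers); the non-exclusive remainder is redistributed over the other
three categories in proportion to their baseline fractions, a design
choice taken because the calculus specifies the dichotomy but not the
within-remainder dynamics. Mortality effects come from category
relative risks with exclusive breastfeeding as the reference.
Breastfeeding is deliberately *not* routed through diarrhoea incidence:
its effectiveness values are combined estimates in which the direct
nutritional effect and the incidence-mediated effect are entangled, so
routing it through incidence as well would double-count.

## Anthropometry

Height-for-age (and weight-for-height) is taken as normal with unit SD
on the international standard's scale. A stunting prevalence *p* fixes
the shift m = −2 − Φ⁻¹(p), so the mass below the −2 SD cut reproduces
*p* exactly (to 1e-12, enforced); band occupancies are successive CDF
differences at the −3, −2, −1 cuts. Severe wasting anchors at the −3 SD
cut instead, since the input datum is the severe-wasting prevalence.
Prevalences of exactly 0 or 1 are degenerate (infinite shift) and
rejected. Band edges are half-open, with "stunted" = strictly below
−2 SD cumulative.

The average relative risk is the occupancy-weighted mean of band RRs
with the reference band (≥ −1 SD) fixed at exactly 1; RR ladders are
data, and no monotonicity toward the reference is assumed. Mortality
reduction between two years is 1 − ARRₜ/ARR₀, negative when the
profile worsens. Supplemental feeding moves a configured split of newly
covered severely wasted children into the three better bands (with a
"stays" fraction for whom feeding is ineffective); the split is
scenario configuration, and mass conservation is enforced to 1e-12.

IUGR uses the same ARR logic with two statuses (IUGR / not) and
neonatal cause-specific RRs.

## Pseudo-intervention attribution

For each (cause, band, year) cell, the composition includes the direct
interventions plus pseudo-interventions for the active indirect routes:
stunting, wasting, and breastfeeding at the preventive tier, IUGR at
the pregnancy tier. Pseudo-units participate in tiered attribution like
any intervention; their credited share is then expanded recursively onto
the real interventions that moved the underlying risk factor,
proportionally to each one's isolated contribution. Carried
determinants inherit the upstream factor's weights (the IUGR route's
weights feed neonatal stunting; a band's stunting weights feed the next
band), so credit flows through the cohort chain back to the
interventions that started it. Credit that cannot be traced to any
intervention retains the pseudo label in the output rather than being
silently dropped, preserving the per-cell invariant that attributed
deaths averted sum exactly to the cell's total.

## Cohort projection

The demographic stand-in is deliberately simple. Births within a year
are uniform, so a cohort born in year t enters band b at calendar time
t + (entry age); entrants split between the two calendar years the
entry window overlaps, proportionally to overlap. Band mortality risks
are per-child probabilities over the band's duration (not hazard
rates), applied at entry with the reductions of the entry year(s).
Five warm-up cohorts (born up to five years before the first reported
year, under baseline conditions, with the birth series clamped at its
endpoints) populate all bands so reported years start in steady state.
Fertility feedback, maternal age structure, migration, and stillbirth/
maternal outputs are out of scope; births are an exogenous annual
series.

Deaths averted are baseline minus scenario deaths per cell, attributed
by the expanded shares and summed across causes per intervention.
Survivor spillover is explicit and visible in the outputs: averting
deaths in one band increases entrants — and hence deaths — downstream,
so the *net* deaths averted can be slightly below the sum of attributed
deaths averted across cells. Summary rates (neonatal, infant,
under-five per 1000 births) are cumulative cohort death risks over the
constituent bands, 1 − ∏(1 − risk_b), from each year's period band
risks.

## Synthetic data

`make_worked_examples` encodes the classic parameter set of the
calculus (ORS 0.93/0.95 scaling 25→50%, zinc treatment at an isolated
0.25, rotavirus at 0.306, measles 0.85 with the 90/95 herd curve,
preventive zinc with stunting OR 1.18 scaling 25→50%, incidence falling
3→2 episodes/year) embedded in an otherwise plausible profile: 30/1000
neonatal risk, post-neonatal band risks 1.2–2%, 35% stunting, 12% IUGR,
10,000 births/year, five-year linear scale-ups. `make_random_country`
draws an internally consistent profile from a single seeded generator
(neonatal risk 2–4%, post-band risks 0.6–2%, stunting 20–45%, severe
wasting 2–8%, odds ratios 1.05–3, monotone coverage trajectories);
identical seeds give byte-identical bundles and every bundle passes
validation by construction.

What the generators emulate is the *structure* of real country
profiles, not any country's values: no real coverage data, no measured
RR ladders, no empirical cause-of-death distribution. Passing tests on
these bundles demonstrates the calculus (conservation, monotonicity,
determinism, the worked-value chains), not predictive accuracy for any
real setting — which additionally depends on the quality of the
effectiveness, odds-ratio, and relative-risk inputs.

## Numerical conventions

Closed forms are preferred (two-status quadratic, normal CDF via
scipy); the only iterative step is the bracketed Brent solve for the
four-status system. Tolerances: odds-system residuals 1e-10, band-mass
and prevalence recovery 1e-12, share and cause-fraction conservation
1e-9. Scenario serialization (JSON and CSV) uses shortest-round-trip
float formatting so serialize → parse → serialize is the identity, and
the CLI's outputs are byte-identical across reruns. Default problem
sizes (a ten-intervention, six-year worked scenario; a twenty-
intervention, fifteen-year synthetic country) run in well under a
second on one CPU.

## Known limitations

- Attribution of mortality increases (coverage scale-down) is
  undefined and reported as zero shares with a warning.
- The herd curve is phenomenological; no transmission dynamics, age
  mixing, or waning.
- Cohort bookkeeping is at the prevalence level; correlations between
  risk factors within children (e.g. the same child stunted *and*
  wasted) are not represented, consistent with the calculus.
- The stand-in demography has no fertility feedback; birth series are
  exogenous and clamped outside their range.
- Default odds ratios for carry-over, feeding states, and breastfeeding
  promotion are not shipped; scenarios must supply them.
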
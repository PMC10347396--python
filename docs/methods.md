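# Methods

## Model

The economic model is a partitioned-survival model (PSM), not a
state-transition model: state occupancy at each cycle is read directly
off the two survival curves rather than derived from transition
probabilities. With S_OS and S_PFS the overall-survival and
progression-free-survival functions,

    PFS(t)   = min(S_PFS(t), S_OS(t))
    PD(t)    = S_OS(t) − PFS(t)
    death(t) = 1 − S_OS(t)

The min-clamp handles the structural weakness of PSMs — nothing forces
independently estimated curves to satisfy S_PFS ≤ S_OS, particularly in
extrapolated tails. Clamp events are counted on the trace
(`StateTrace.n_clamped`) so a crossing pair of curves is visible rather
than silent.

Cycles are 1 month; the horizon is 60 cycles (5 years, chosen because
median OS in this population is well under 2 years). Costs and QALYs
discount at 5%/year via (1+r)^(−cycle/12); 0 and 8% are scenario bounds.
Membership is evaluated at cycle start with no half-cycle correction
(the convention the base case was built with); a half-cycle option
exists behind `EconomicSettings.half_cycle_correction` for sensitivity.
Willingness to pay is $35,796.83/QALY — three times 2021 Chinese
per-capita GDP — with all computation in 2022 USD at ¥6.7863/$.

### Costing

While progression-free, a cohort member accrues drug acquisition plus
hospitalization ($57.43/cycle) and follow-up ($48.00/cycle); after
progression, a flat best-supportive-care cost ($1,886.67/cycle) — no
subsequent active therapy, since this population has exhausted standard
lines. Treatment runs to progression: the model does not separate
time-on-treatment from PFS because the underlying trial readout does
not. Expected adverse-event management cost (incidence × unit cost over
the ten grade ≥3 events, per arm) is charged once at model entry, the
convention of the cost sources; the hormone-receptor-positive cohort
reuses the all-patient incidences.

Dosing is body-size based on a 55 kg / 1.72 m² reference patient. T-DXd
is 5.4 mg/kg every 3 weeks → 297 mg → 3 × 100 mg vials under the default
whole-vial wastage policy ($7,294.11/administration; an exact-mg policy
is selectable). A 3-week administration converts to a monthly cycle by
(365.25/12)/21 ≈ 1.4494; this factor is stated explicitly because the
published table cannot pin it down. The comparator is a usage-weighted
mix of five single agents (capecitabine 20.1%, eribulin 51.1%,
gemcitabine 10.3%, paclitaxel 8.2%, nab-paclitaxel 10.3%); each agent
carries a per-m² dose, administrations per 3-week cycle, package size
and wastage rule. Weights that sum to within 1% of unity are
renormalized (published percentages round); larger deviations are
rejected. **Assumed inputs:** the published cost table omits eribulin
and gemcitabine unit prices and leaves the paclitaxel unit ambiguous;
the demo configuration ships assumed values ($360 per 0.88 mg eribulin
vial, $8 per 1 g gemcitabine vial, paclitaxel read as per 30 mg) marked
as such. The comparator arm's absolute costs therefore cannot be
regenerated exactly, only to within the plausibility of these
assumptions.

## Pseudo-IPD reconstruction

The Guyot interval algorithm: within each risk-table interval, censoring
is assumed uniformly spread; candidate censor times are placed evenly,
event counts at each digitized coordinate follow from successive
survival ratios against a running product-limit estimate (rounded to
integers), and the interval's censoring count is iterated until the
implied number at risk at the next published time matches the printed
value. Ties between an event and a censoring at the same time resolve
event-first. Subjects still at risk after the last coordinate are
censored there. When coarsened coordinates over-assign events by a
subject or two, the published at-risk count can be unreachable with zero
censoring; the algorithm then accepts the closest match, as the original
does on real digitized figures. A published count that exceeds
n₀·S(t−) — structurally impossible, since each product-limit interval
bounds the at-risk process by the survival ratio — raises a named error
with the interval index. Calibration against a reported total event
count is supported (a final pass trades late events against censoring)
but off by default, matching how the inputs here were used.

## Survival fitting and extrapolation

The censored log likelihood Σ_events ln f + Σ_censored ln S is maximized
per family. The exponential uses its closed form (rate = events /
exposure, exact). Other families use multi-start L-BFGS-B on
log-transformed positive parameters (gradient tolerance 1e−8), starting
from method-of-moments and exponential-equivalent seeds; the converged
flag reports the optimizer's own status and unconverged fits are never
ranked. The generalized gamma uses the Prentice (μ, σ, Q)
parameterization for stability, evaluated through the regularized
incomplete gamma function with the Q→0 log-normal limit handled
explicitly; Stacy-form conversion helpers are provided. The Gompertz
shape may be negative, giving a bounded cure fraction exp(b/a) — kept,
and exercised in tests.

Selection is minimal AIC (BIC available), ties broken toward fewer
parameters then name. Because the published analysis twice chose a
family by visual inspection over the printed AIC minimum, the pipeline
records both the criterion winner and an explicit per-endpoint override
(`selection.overrides`), never guessing intent.

Extrapolation uses hybrid curves: the KM estimate inside follow-up,
spliced at its last time to the fitted parametric tail rescaled by
KM(t_max)/S_param(t_max) so the curve is continuous — the sequencing is
as published, the continuity treatment is this package's choice.
Medians are solved by bisection to 1e−6 months.

## Sensitivity analysis

One-way: each parameter is set to its low/high bound with the rest at
base; entries sort by |ICER span|. Default ranges are ±20%, the discount
rate 0–8%, and the T-DXd price lower bound a 50% decrement
(anticipating reimbursement-negotiation cuts). Spans are reported on the
ICER scale to match the tornado figure convention.

Probabilistic: unit costs draw from Gamma and utilities from Beta
distributions, moment-matched to (μ, σ) with σ = 20% of the mean —
mirroring the one-way ranges, since the distribution families were
stated without variances. Varied parameters are all unit costs and both
utilities; the discount rate and structural settings stay fixed
(standard practice). Each parameter owns an independent substream keyed
by (root seed, CRC32 of its name), so adding a parameter does not
perturb the others' draws. Independent utility draws can cross; the
state ordering u_PD ≤ u_PFS is enforced by clamping u_PD at evaluation.
The CEAC reports P(λ·ΔQALY − Δcost > 0) with ties counted as not
cost-effective.

## Synthetic-data generator

The generator emulates the published inputs, not the disease: each
arm/endpoint draws event times from a known family, applies independent
exponential drop-out (0.01/month in the demo — mild, trial-like) plus an
administrative cutoff (32 months, the end of follow-up of the source
trial's figures), estimates the KM curve, reads it off a monthly grid
(optionally with truncated-Gaussian vertical jitter, re-monotonized, as
manual digitization would) and tabulates numbers at risk every 3 months.
Demo arms use the trial's sizes (373 vs 184) and Weibull event times
calibrated so the median matches the printed all-patient medians
(shape 1.3 for OS, 1.1 for PFS — mildly increasing hazard, typical of
advanced-cancer OS curves; scale = median/(ln 2)^(1/shape)).

What it does **not** emulate: joint OS/PFS dependence within subjects
(the two endpoints are generated independently at the curve level and
the PSM clamp absorbs any crossing), informative censoring, recruitment
curves, or digitization error correlated along the curve. Passing tests
therefore demonstrate that the reconstruction–fitting–model chain is
faithful to its inputs, not that any particular real-world curve shape
is recovered.

## Numerical choices and problem sizes

- Reconstruction round-trip fidelity is asserted at ≤0.02 sup-norm on a
  300-subject arm with monthly digitization; observed deviations are
  ~0.002–0.006.
- Parameter recovery is asserted at 10% relative error for every family
  refitting its own data at n = 5,000 with ~20% censoring.
- State-occupancy conservation holds to 1e−9 by construction; hybrid
  splice continuity to 1e−12.
- The demo study and tests run the PSA at 1,000 iterations; the unit
  suite uses smaller draws where only mechanics are under test.
- Degenerate inputs: zero-variance PSA draws are exact point masses; a
  zero ΔQALY never divides — ICERs fall back to
  dominant/dominated/indeterminate labels; an all-censored sample yields
  an honest `converged=False` fit.

## Known limitations

- Absolute base-case costs/QALYs of the source analysis are not
  reproducible: they require the original digitized curves and fitted
  parameters, which were not published. The package reproduces the
  arithmetic identities of the published results table exactly and the
  qualitative structure (ICER ≫ WTP, P(CE) ≈ 0, tornado ordering) on the
  synthetic study.
- The PSM has no explicit progression-to-death pathway; anything not on
  the two curves (e.g., treatment waning) is out of scope.
- No spline or cure-fraction extrapolation, no covariate-adjusted
  models, no EVPI, no correlated PSA draws.
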
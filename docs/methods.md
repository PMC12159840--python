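# Methods

## Scope and model

`pritdose` estimates absorbed doses for pretargeted radioimmunotherapy from
*ex vivo* biodistribution data and projects multicycle regimens against
organ dose limits, alongside the survival statistics used to read out a
therapy study.  The dose model is deliberately first-order preclinical beta
dosimetry: each tissue's kinetics are reduced to a one-phase exponential
decay, the time-integrated activity coefficient (TIAC) is computed in closed
form, and the mean absorbed dose assumes local deposition of all
non-penetrating (electron) energy.  There is no photon cross-dose, no mouse
phantom or S-value set, and no voxel/Monte-Carlo transport; coefficients
produced this way are expected to agree with full schemes only to within a
few tens of percent, which is why regimen arithmetic (cumulative doses,
therapeutic indices) operates on the packaged reference coefficient table
rather than on the forward model.

### Kinetic model

Tissue activity concentration (decay-corrected %ID/g) follows

    A(t) = (A0 − P) · exp(−λ_b t) + P,     λ_b = ln 2 / T½_bio

with `A0` the back-extrapolated concentration at injection time, `P ≥ 0` the
plateau (sustained specific binding; 0 for normal-tissue washout), and
`T½_bio` the biological half-life in hours.  Values are stored
decay-corrected to injection time (`decay_corrected = True` on the dataset),
so the fitted kinetics are purely biological and physical decay enters only
analytically in the TIAC.  The study design the package defaults to samples
{2, 24, 48, 120} h with 5 animals per timepoint, destructively (each animal
contributes one timepoint).

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
`xtol = 1e-10`) on per-timepoint means, unweighted — matching how group
curves are usually fit — with a raw-points option.  Initialisation is a
deterministic multi-start schedule: `A0` from the first observation, plateau
candidates {0, last observation}, and `T½` from a log-linear regression of
the plateau-subtracted values; the best of the starts by SSE wins.  With
four timepoints and three parameters this is robust and reproducible; a
dense grid-search oracle in the tests confirms the optimum.  Constant data
are handled before optimisation (span 0, plateau at the common value,
R² = 1 by the zero-SStot convention below).

Numerical conventions: R² = 1 − SSres/SStot; when SStot = 0 the statistic is
1 if the residuals are also (numerically) zero, otherwise it is undefined
and raised as such rather than returned as a number.  `predict` rejects
negative times.  Median survival (below) uses a 1e-9 absolute tolerance on
S(t) ≤ 0.5 so that survival probabilities that are exactly one half up to
float rounding are honored.

### Dosimetry

With λ_p the physical decay constant of the nuclide, the TIAC per unit
administered activity is

    Ã = ∫₀^∞ [A(t)/100] e^(−λ_p t) dt
      = [ (A0 − P)/(λ_b + λ_p) + P/λ_p ] / 100     (MBq·h/g per MBq)

Integration starts at t = 0 using the fitted A0 (back-extrapolation from the
first 2 h sample).  A hybrid `trapezoid-plus-tail` estimator is also
provided for data-driven use: the activity is taken piecewise-linear between
observed means and integrated against the exact exponential decay weight per
segment (closed form, which removes the decay-weighting part of the
discretisation error), plus the analytic tail of the fitted curve beyond the
last sample.  On data lying exactly on the fitted curve it agrees with the
closed form to ~2% on the default 4-point design.

Nuclide defaults (Lu-177): T½_phys = 159.6 h (6.65 d) and a mean
non-penetrating energy of 0.1335 MeV per decay (beta mean), giving
Δ = 3.6e9 · E · 1.60218e-13 · 1000 = 0.0770 Gy·g/(MBq·h); an alternative
constant including conversion/Auger electrons (0.1473 MeV) is packaged as
`LU177_TOTAL_NP`.  Dose coefficient: D = Ã · Δ · 100 (cGy/MBq).

Presentation conventions follow the field's reporting style: therapeutic
indices round to the nearest integer (halves away from zero), cumulative
doses to two significant figures, coefficients to two decimals.  Regimen
cycles are treated as dosimetrically identical and additive.  The organ-limit
report distinguishes hard limits (kidney 23 Gy, the lower edge of the
accepted 23–26 Gy range) from thresholds (marrow 2.5 Gy, ovary 4 Gy follicle
LD50, uterus 4 Gy pregnancy function): a threshold is "reached" at equality
or above, a hard limit is "exceeded" only above.

The packaged reference table carries the published mean absorbed dose
coefficients for mono- and bivalent radiohaptens in the SW1222-luc
orthotopic liver model at 24 h/48 h pretargeting intervals, together with
the published integer TIs.  Because those coefficients are printed to two
decimals, reconstructing an integer TI from them can land one integer away
from the published value whenever the achievable ratio interval (over the
coefficients' half-ulp rounding ranges) straddles a rounding boundary; the
acceptance test therefore asserts interval-consistency rather than blind
equality, and exact equality for the headline blood/kidney TIs.

### Endpoint statistics

Kaplan–Meier estimation and the log-rank (Mantel–Cox) test are delegated to
`lifelines` behind the package's own record/curve types; exact loop-oracle
and permutation tests in the suite validate that delegation independently.
Euthanasia at a humane endpoint is coded as an event; censoring is reserved
for animals alive at study termination.  Mann–Whitney U uses exact
enumeration when the pooled sample is tie-free with n ≤ 12 and the
tie-corrected midrank normal approximation otherwise (`scipy`).  The
two-stage Benjamini–Krieger–Yekutieli FDR step-up is implemented directly
from its definition — stage 1 at q′ = q/(1+q); if 0 < r₁ < m, stage 2 at
q′·m/(m − r₁) — and cross-checked against `statsmodels` in the tests.

A known small-sample fact documented by the suite: for balanced 5+5
uncensored data the χ²(1) log-rank p can differ from the exact permutation p
by up to 0.058 (computed exhaustively over all C(10,5) rank
configurations), so agreement is asserted at 0.06, not tighter.

## Synthetic data

Generators are pure functions of (spec, seed).  Biodistribution arms draw
multiplicative lognormal noise with mean 1 and coefficient of variation
`noise_cv` (σ² = ln(1 + cv²), μ = −σ²/2), default 0.10 — consistent with the
inter-animal spread implied by reported SEMs at n = 5 — under the
destructive one-timepoint-per-animal design.  Default kinetic truths: the
bivalent tumor curve uses the published plateau 4.5 %ID/g and T½ 25.4 h with
A0 = 14.53 %ID/g anchored so the curve passes through the published 2 h mean
of 14.0 %ID/g; the monovalent curve uses plateau 1.3 %ID/g and T½ 13.4 h
with A0 = 8.46 %ID/g anchored so the forward local-deposition model
reproduces the published monovalent tumor coefficient (32.88 cGy/MBq), since
no early-timepoint mean is published for that arm.  Normal-tissue washouts
(blood, kidneys, liver) are plausible mono-exponentials of matching
magnitude, not calibrated quantities.

Survival cohorts are either fixed lists (the packaged fixture lists are
shaped so the product-limit medians equal the reported 18/71/81 days, with
all control animals dead by day 18) or lognormal event-time draws with a
stated median and log-sd 0.25, censored at a 128-day follow-up horizon.
Bioluminescence fluxes are lognormal with the realized geometric means
centered exactly on the requested baseline and fold-decrease.

What passing on synthetic data does *not* show: the generators have no
mechanistic pretargeting model (no bispecific/clearing-agent/hapten
compartments), no inter-animal correlation across tissues beyond the shared
noise draw, no tumor-size dependence, and survival times are not linked to
simulated dose.  Agreement on these data validates the estimators and
arithmetic, not the biology.

## Problem sizes

The suite fits 4-point group means (the study design); parameter-recovery
statements use 200 seeded replicates; oracle sweeps are exhaustive where the
space is small (all tie-free Mann–Whitney datasets with n ≤ 10, all balanced
5+5 log-rank configurations) and seeded samples of 30–100 elsewhere.  These
sizes make the full suite run in well under a minute while keeping every
claim exhaustive or replicated.

## Known limitations

* Local-deposition-only dosimetry: organs receiving substantial photon or
  neighbor-organ dose are underestimated; tumor self-dose from a
  back-extrapolated A0 is sensitive to the 0–2 h assumption.
* The reference coefficients are taken as given; the package cannot
  reproduce their generating scheme and checks its own forward model against
  them only within a 20% plausibility band.
* Survival analysis is two-group nonparametric only — no Cox regression, no
  repeated-measures modelling of weights or hematology.
* The reader accepts any tissue vocabulary (warning, not error), so typos in
  tissue names surface only in the warning log.
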
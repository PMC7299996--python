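# Methods

This note documents the models implemented in `srstream`, their assumptions,
the tunable parameters, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Long-term decline model

The baseline dissolved ⁹⁰Sr concentration is modelled as

    C_ref(t) = α exp[−(λ + k₁) t/365.25] + β exp[−(λ + k₂) t/365.25],

with *t* in days since the deposition event (1986-04-26 = day 0, Gregorian
calendar) and rates in 1/yr. λ is the physical decay rate of ⁹⁰Sr,
ln 2 / 28.79 yr ≈ 0.024 1/yr, treated as a known constant and never fitted.
The two environmental attenuation rates separate a faster component (soil
fixation and redistribution of the deposit, k₁) from a slow, near-equilibrium
one (k₂); components are reported in canonical order k₁ ≥ k₂, resolving the
label-swap symmetry of the sum. Published estimates for this kind of record
disagree at the second digit (e.g. 0.254 vs 0.27 1/yr for k₁ depending on
where in the source they are quoted); this package uses α = 9357 Bq/m³,
β = 2500 Bq/m³, k₁ = 0.254 1/yr, k₂ = 0.002 1/yr as its reference parameter
set throughout.

**Fitting.** `fit_trend` minimises the RMSE between C_ref evaluated at each
year's mean sampling time and the annual mean concentration. Annual
(calendar-year) arithmetic means are used to suppress the strong within-year
fluctuation; years with a single sample are retained because early monitoring
was sparse, and no weighting for sub-annual sampling irregularity is applied
(the representative time t_repr is the plain mean of the year's sample
times). The search runs a Nelder–Mead simplex in log-parameter space
(positivity enforced smoothly) from six deterministic starts that bracket
plausible rate scales, and each simplex optimum is polished by a trust-region
least-squares step in the same space: the RMSE surface has a nearly flat
valley in the slow rate k₂, where the simplex alone stalls several digits
short. Convergence: relative objective change below 1e−10 or 10 000
evaluations; the reported RMSE is always recomputed from the returned
parameters. At least four annual means are required (four free parameters).

Note that when concentrations are generated by the full concentration-
formation model, the *observed* annual means also carry the
discharge-dependent factor, so the fitted (α, k₁) describe the observed
decline rather than the latent C_ref — with a record starting four years
post-accident the fast component is only loosely identified, while the fitted
curve itself is tight.

## Concentration-formation model

Assumptions: (i) the soil-water ⁹⁰Sr concentration profile is
c(z, t) = C_ref(t)·exp(d·z/t), steepest just after deposition and flattening
as 1/t (z in metres, ≤ 0 below the surface); (ii) lateral flow into the
stream is distributed over depth as q(z) = a·exp(b·z); (iii) at discharge Q
the contributing zone is (−∞, z_w] with the water-table depth z_w solving
∫ q = Q, i.e. z_w = ln(bQ/a)/b — positive z_w (saturation excess) is allowed
and the model applied unchanged; (iv) the stream concentration is the
flux-weighted mean of c over the contributing zone. The integral evaluates in
closed form to

    C(Q, t) = C_ref(t) · bt/(bt + d) · (bQ/a)^{d/(bt)}.

The exponential flow profile is the reconstruction for which this closed form
follows exactly; the quadrature round-trip test (flow integrated to z_w
returns Q) pins it. Time is in **days**: with d ≈ 2117 m·day and b ≈ 1.37 1/m
the predicted log–log slopes d/(b·t) run from ≈ 0.44 (mid-1996) to ≈ 0.16
(mid-2013), which is dimensionally sensible, whereas a year-based t would
give absurd slopes.

Parameters: a (mm/day per metre, lateral-flow scale at the surface),
b (1/m, flow-profile decay with depth), d (m·day, profile steepness).
d = 0 is admitted as the uniform-profile limit, for which C ≡ C_ref.

**Scale invariance.** The map (a, b, d) → (κa, κb, κd) is a pure
reparametrisation of depth (z → z/κ): C(Q, t) is exactly unchanged. Only b/a
(which fixes where the water table sits for a given Q) and d/b (which fixes
the slope scale) are identified by concentration–discharge data; the overall
scale κ is set by prior information. This is pinned by a property test and
drives the calibration design below.

**Numerical oracle.** `concentration_numeric` evaluates both depth integrals
by adaptive quadrature (scipy QUADPACK), truncating the semi-infinite tail at
z_w − 40/min(b, b + d/t), i.e. where the slower of the two increasing
exponential integrands has decayed to e⁻⁴⁰ of its value at z_w. The requested
relative tolerance (default 1e−9) is enforced against the propagated
quadrature error estimate; the oracle agrees with the closed form to better
than 1e−6 relative error across randomised parameter draws.

## Bayesian calibration

Observation model: measured concentrations scatter multiplicatively around
the model (a relative measurement error of ~10.9 % motivates this), so the
likelihood is Gaussian on log residuals, log C_obs ~ N(log C(Q, t), σ²). σ is
a free parameter by default (`sigma_mode="estimated"`); it can be fixed at
0.109. Invalid parameter states return −∞ rather than raising, as sampler
rejections.

Priors are log-uniform. Because of the exact scale invariance the marginal
posteriors of a, b, d along the κ-direction are *prior-determined*, so the
support must be anchored on the physically plausible scale rather than made
arbitrarily wide: the defaults take previously reported 95 % credible ranges
for this model (a: 0.14–1.09, b: 0.74–3.05, d: 1032–2989) widened by one full
decade on each side — a: [0.014, 10.9], b: [0.074, 30.5], d: [103.2, 29890],
σ: [1e−3, 2]. Reported intervals on a, b and d are therefore wide and almost
perfectly correlated, while the identifiable ratios b/a and d/b are pinned
tightly; users needing scale-free conclusions should read the posterior
through those ratios.

Sampling uses the affine-invariant ensemble sampler (emcee) in log-parameter
space — well suited to the straight degenerate ridge — with walkers started
in a 1e−3 log-space ball around a posterior mode located by a deterministic
simplex search. Burn-in is discarded, no thinning. Diagnostics: mean
acceptance fraction and the split-chain R-hat (arviz); R-hat > 1.05 warns.
"Best fit" is the posterior median (2.5/97.5 % interval bounds alongside);
the maximum-a-posteriori draw is also recorded. Percentiles use linear
interpolation between order statistics throughout. Model agreement is
summarised as R² = 1 − SS_res/SS_tot of log-space point predictions at the
posterior median (a linear-space option exists); posterior-predictive bands
resample lognormal observation noise per retained draw.

## Empirical C–Q regression

Power laws y = p·Qᑫ are fitted per multi-year period by OLS of log y on
log Q on the raw (unbinned) points; equal-count binning in log Q (default 10
classes, counts differing by at most one) is provided for display only —
equal-count classes avoid empty bins at the sparse high-discharge tail.
Periods are calendar-year inclusive on both ends; records outside every
period are reported as unassigned, never dropped. Decay correction divides
each concentration by C_ref(t) (a flag on the returned series guards against
double correction). For comparing a period's fitted exponent with the model
slope d/(b·t), the period's **harmonic-mean** sample time is used, since the
exponent is proportional to 1/t; the comparison is exact at a single instant
and an effective-time approximation over a period (within ~3 % on noise-free
model output over decade-long periods).

## Wash-off accounting

The areal export rate is C·Q·10⁻³ (Bq/m³ × mm/day × 10⁻³ m/mm = Bq/m²/day);
`washoff_integral` integrates it over the actual sampling dates with the
trapezoid rule and reports kBq/m². Sampling gaps longer than 60 days are
logged as warnings (linear interpolation across them is doubtful). Decay in
transit is ignored (instantaneous export). Dividing by the initial areal
inventory (470.7 kBq/m² for the reference catchment) gives the exported
fraction; at field scale a cumulative export of ~5 kBq/m² over 1993–2016 is
~1 % of the deposit.

## Synthetic monitoring series

The generator emulates a biweekly 1990–2016 record. Discharge is
*phenomenological*: Q = clip(baseflow · s(doy) · ε, 0.004, 4.2) mm/day, where
s combines a Gaussian snowmelt bump (peak day-of-year 100, width 22 d,
amplitude 1.2 mm/day over a 0.12 mm/day baseflow) with a late-summer trough
(factor 0.3 at day 225, width 55 d), and ε is mean-one lognormal noise with
CV 0.5. Defaults keep the series inside the observed 0.004–4.2 mm/day
envelope with March–May maxima and July–September minima. Concentrations are
the closed-form model at (Q, t) times mean-one lognormal noise with CV 0.109
(the stated measurement error); CV = 0 returns the exact model curve. All
randomness derives from a single seed via spawned generators, and every
dataset carries a ground-truth sidecar sufficient to regenerate it exactly.

What the generator does **not** emulate: rainfall–runoff dynamics, storm
events and flow autocorrelation beyond the seasonal shape, the sparser
pre-1992 sampling cadence (available via configuration but not default),
laboratory detection limits, or data gaps. Passing recovery tests therefore
demonstrates the internal consistency of the estimators under the assumed
error structure, not robustness to real-world hydrological complexity.

## Degenerate inputs and tie-breaks

Records with nonpositive or missing Q or C are excluded before any log-space
computation and counted in a load report. Component order in the trend model
is canonicalised to k₁ ≥ k₂. Constant data with λ forced to 0 admit the flat
solution k₁ = k₂ = 0, α + β = mean. Zero-variance regressors and observation
vectors raise. The e-folding truncation, tolerance and percentile conventions
above are asserted by tests as stated.

## Problem sizes

The test suite and the reproduction script run the calibration study at 16
walkers × 800 draws (300 burn-in) over 20 replicate datasets of ~705 records,
and a single reference calibration at 16 × 2000 (600 burn-in) — sizes chosen
so the full coverage study completes in about a minute while split-chain
R-hat stays near 1.1 on the slowest (ridge) direction. Longer chains sharpen
the diagnostics but do not move the medians appreciably.

## Known limitations

- The scale non-identifiability means absolute values of a, b, d are
  prior-dependent by construction; only b/a and d/b are data-driven.
- The closed form assumes the exponential flow and profile shapes exactly;
  no shape uncertainty is propagated.
- The trend fit reports point estimates only (no uncertainty on α, β, k₁,
  k₂).
- Wash-off between samples relies on linear interpolation of C·Q; event-scale
  export between biweekly samples is invisible to it.
- No gap-filling or imputation is attempted for missing monitoring periods.
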
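# srstream

Parametric hydrochemical modelling of dissolved strontium-90 in small
catchment streams.

Decades after a major radionuclide release, dissolved ⁹⁰Sr is still carried
from contaminated catchments into river systems that supply downstream
populations. Long-term monitoring of such streams shows two robust patterns:
a slow multi-decadal decline of the concentration, and a power-law coupling
between concentration and discharge whose log–log slope *weakens* over the
years — even after the secular decline is divided out. `srstream` implements
a compact parametric model of both patterns, plus the machinery to calibrate
it and to account for the cumulative wash-off, for researchers in
radioecology and catchment hydrochemistry.

## The models

**Long-term decline.** The baseline concentration (Bq/m³) at *t* days after
the deposition event is a double exponential,

    C_ref(t) = α exp[−(λ + k₁) t/365.25] + β exp[−(λ + k₂) t/365.25]

with λ = ln 2 / 28.79 yr ≈ 0.024 1/yr the physical decay rate of ⁹⁰Sr and
(α, β, k₁, k₂) catchment-specific constants fitted by least-RMSE against
annual means (`fit_trend`).

**Concentration formation.** Stream water is fed by lateral flow through a
soil column whose ⁹⁰Sr concentration profile c(z, t) = C_ref(t) exp(d·z/t)
flattens with time (z ≤ 0 in metres below the surface). With an
exponential-with-depth lateral flow profile q(z) = a·exp(b·z), the
flux-weighted mean concentration over the contributing depths has the closed
form

    C(Q, t) = C_ref(t) · b·t/(b·t + d) · (b·Q/a)^{d/(b·t)}

— a power law in discharge Q whose exponent d/(b·t) decays like 1/t
(`concentration_closed_form`, with `concentration_numeric` as an independent
quadrature oracle). The model is exactly invariant under
(a, b, d) → (κa, κb, κd); only b/a and d/b are identified by data.

**Calibration and accounting.** `run_mcmc` samples the posterior of
(a, b, d, σ) with the affine-invariant ensemble sampler under a Gaussian
likelihood on log-concentration residuals; `fit_periods`/`slope_trend` fit
the empirical power law y = p·Qᑫ per multi-year period, optionally after
decay correction (C/C_ref); `washoff_integral` integrates C·Q over the
record to give the cumulative areal export in kBq/m². A synthetic-data
module generates biweekly 1990–2016 monitoring series with snowmelt-peaked
discharge and 10.9 % lognormal measurement noise for end-to-end validation.

## Worked example

```sh
python examples/03_cq_model_and_slopes.py
```

```
C(Q=1.0 mm/day, t=7000 d): closed form 1819.40 Bq/m^3, depth integral 1819.40 (rel diff 3.7e-16)
model C-Q slope mid-1996: 0.437
model C-Q slope mid-2013: 0.156

period       q_fit   d/(b*t_h)   p_raw     p_corrected
1991-2000   0.497   0.483          4109   1.489
2001-2010   0.219   0.220          1799   1.155
2011-2016   0.157   0.153          1363   1.106
exponent strictly decreasing: True
```

The closed form agrees with the defining depth integral to machine
precision. On noise-free model output the fitted period exponents fall from
0.50 to 0.16 and track d/(b·t) at each period's harmonic-mean time; decay
correction stabilises the prefactor *p* (the secular decline moves into
C_ref) while the declining exponent survives — the weakening C–Q coupling is
a change in the concentration-formation process, not radioactive decay. The
other examples (`examples/01…05`) cover simulation, trend fitting, MCMC
calibration and wash-off accounting; each prints the numbers it computes and
a line on what they mean.

A thin CLI wraps the same functions:

```sh
srstream simulate --seed 1 -o series.csv
srstream fit-trend series.csv -o trend.json
srstream calibrate series.csv --trend trend.json --draws 1500 --walkers 16 --seed 0 -o posterior.json
srstream cq-fit series.csv --periods 1991-2000,2001-2010,2011-2016 -o cq.json
srstream washoff series.csv --inventory-kbq-m2 470.7 -o flux.json
```

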
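"""The concentration-formation model and the weakening C-Q power law.

Evaluates the closed-form C(Q, t), verifies it against the defining depth
integral, and shows the model's central prediction: the log(C)-log(Q) slope
d/(b*t) decays like 1/t, so the concentration-discharge coupling weakens as
the soil profile flattens. Period-wise power-law fits on noise-free model
output reproduce it, before and after decay correction.
"""

from srstream import (
    DEFAULT_CQ,
    DEFAULT_TREND,
    SyntheticConfig,
    concentration_closed_form,
    concentration_numeric,
    decay_correct,
    fit_periods,
    generate_dataset,
    model_exponent,
    slope_trend,
)

q, t = 1.0, 7000.0
closed = concentration_closed_form(q, t, DEFAULT_CQ, DEFAULT_TREND)
numeric = concentration_numeric(q, t, DEFAULT_CQ, DEFAULT_TREND)
print(f"C(Q={q} mm/day, t={t:.0f} d): closed form {closed:.2f} Bq/m^3, "
      f"depth integral {numeric.value:.2f} (rel diff {abs(closed-numeric.value)/closed:.1e})")

for year, t_mid in [(1996, 3537.0), (2013, 9935.0)]:
    print(f"model C-Q slope mid-{year}: {model_exponent(t_mid, DEFAULT_CQ):.3f}")

records, _ = generate_dataset(SyntheticConfig(noise_cv=0.0, err_pct=None, seed=11))
periods = [(1991, 2000), (2001, 2010), (2011, 2016)]
fits = fit_periods(records, periods)
report = slope_trend(fits, DEFAULT_CQ)
corrected = fit_periods(decay_correct(records, DEFAULT_TREND), periods)
print("\nperiod       q_fit   d/(b*t_h)   p_raw     p_corrected")
for f, fc, m in zip(fits, corrected, report.model_exponents):
    print(f"{f.period[0]}-{f.period[1]}   {f.q:.3f}   {m:.3f}       {f.p:7.0f}   {fc.p:.3f}")
print(f"exponent strictly decreasing: {report.strictly_decreasing}")
# The exponent falls across the periods and tracks d/(b*t); decay correction
# stabilises the prefactor p (the secular decline moves into C_ref) while the
# declining exponent survives — the time dependence is not radioactive decay.
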
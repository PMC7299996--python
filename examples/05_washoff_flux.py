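"""Cumulative dissolved 90Sr wash-off and its share of the initial inventory.

Integrates C*Q over the sampling dates (trapezoid rule) to get the areal
export in kBq/m^2, then expresses it as a percentage of the 470.7 kBq/m^2
initial deposit.
"""

import datetime as dt

from srstream import SyntheticConfig, generate_dataset, washoff_integral

records, _ = generate_dataset(SyntheticConfig(seed=1))
since_1993 = [r for r in records if r.date.year >= 1993]
result = washoff_integral(since_1993, inventory_kbq_m2=470.7)

print(f"period: {result.period[0]} .. {result.period[1]} ({result.n} samples)")
print(f"cumulative wash-off: {result.total_kbq_m2:.2f} kBq/m^2")
print(f"fraction of the initial inventory: {result.fraction_pct:.2f}%")
# Only about one percent of the deposit leaves the catchment through the
# stream in 24 years — the watershed retains nearly all of its 90Sr.
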
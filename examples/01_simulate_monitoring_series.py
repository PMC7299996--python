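"""Generate a synthetic biweekly 1990-2016 stream-monitoring series.

Builds the default study-condition dataset — seasonal snowmelt discharge plus
dissolved 90Sr concentrations from the concentration-formation model with
10.9% measurement noise — and writes it to CSV with its ground-truth sidecar.
"""

import numpy as np

from srstream import SyntheticConfig, generate_dataset, write_timeseries
from srstream.synthetic import write_sidecar

cfg = SyntheticConfig(seed=1)
records, sidecar = generate_dataset(cfg)
write_timeseries(records, "series.csv")
write_sidecar(sidecar, "series.truth.json")

q = np.array([r.q for r in records])
c = np.array([r.c for r in records])
print(f"records: {len(records)} ({records[0].date} .. {records[-1].date})")
print(f"discharge range: {q.min():.4f} .. {q.max():.3f} mm/day")
print(f"concentration range: {c.min():.0f} .. {c.max():.0f} Bq/m^3")
early = c[[r.date.year <= 1995 for r in records]].mean()
late = c[[r.date.year >= 2012 for r in records]].mean()
print(f"mean 90Sr 1990-1995: {early:.0f} Bq/m^3 vs 2012-2016: {late:.0f} Bq/m^3")
# The discharge stays inside the observed 0.004-4.2 mm/day envelope and the
# concentration declines several-fold across the record, as in the field.
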
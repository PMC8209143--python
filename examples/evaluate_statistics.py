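"""Model-evaluation statistics on synthetic paired data, and the first-cut
shift-per-degree analysis on a phenology-network-like fixture.
"""

import numpy as np

from dynagrass.fixtures import generate_fixtures
from dynagrass.stats import (
    PairedSeries,
    error_metrics,
    first_cut_shift_per_degC,
    paired_t_and_correlation,
)

rng = np.random.default_rng(3)
observed = rng.uniform(1500, 4000, 22)
simulated = observed + rng.normal(0, 400, 22)
pairs = PairedSeries(observed, simulated)
m = error_metrics(pairs)
t = paired_t_and_correlation(pairs)
print(f"RMSE {m.rmse:6.1f} kg, NRMSE {m.nrmse:5.1%}, r2 {m.r2:.3f}, "
      f"CCC {m.ccc:.3f}")
print(f"paired t = {t.t_statistic:.2f} (p = {t.t_pvalue:.2f}), "
      f"{t.method} r = {t.correlation:.3f}")

# shift of the first cut per degree of warming between two 13-year periods
phen = generate_fixtures("dwd_like_phenology", seed=3)
a, b = phen[phen.year <= 2003], phen[phen.year > 2003]
q25, q75 = first_cut_shift_per_degC(a["first_cut_doy"], b["first_cut_doy"],
                                    a["mat_degc"], b["mat_degc"])
print(f"first cut moves {q25:.1f} (q25) to {q75:.1f} (q75) days earlier "
      "per +1 degC")
# Positive values mean earlier cutting with warming, the fixture's built-in
# response of ~10 days per degree.
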
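"""Which factors explain benchmark performance?

Builds benchmark summaries over several seeds and decomposes the variance of
mean |R| into cancer-type, regulon-source and method contributions via
sequential adjusted R^2.
"""

import pandas as pd

from grnbench import (SyntheticConfig, benchmark_cohort, simulate_cohort,
                      variance_decomposition)

rows = []
for seed in range(3):
    cfg = SyntheticConfig(n_cancer_types=4, n_samples=30, n_genes=600,
                          n_regulators=20, targets_min=10, targets_max=20,
                          driver="expression", alpha=0.6, seed=seed)
    expr, sens, truth = simulate_cohort(cfg)
    summary, *_ = benchmark_cohort(expr, sens, truth.regulons, compute_cles=False)
    rows.append(summary[summary["predictor"] != "expression"])

df = pd.concat(rows, ignore_index=True)
df["method"] = df["predictor"].str.replace("activity:", "", regex=False)

shares = variance_decomposition(df, "mean_abs_r", ["cancer_type", "method"])
print(shares.to_string(index=False))
print(f"\nfull-model adjusted R^2: {shares.attrs['full_model_adj_r2']:.3f}")
print("each share is the adjusted-R^2 gained when that term enters the model;")
print("the activity method explains almost nothing because all six methods")
print("track the same planted signal.")
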
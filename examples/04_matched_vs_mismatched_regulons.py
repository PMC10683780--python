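"""Are cancer-type-matched regulons better than mismatched ones?

Simulates a cohort whose per-type networks are 80% rewired, evaluates every
cancer type with every type's regulon, ranks regulons within each type and
tests matched vs mismatched ranks.
"""

from grnbench import (SyntheticConfig, cross_regulon_matrix,
                      matched_vs_mismatched, simulate_cohort)

cfg = SyntheticConfig(n_cancer_types=4, n_samples=30, n_genes=800,
                      n_regulators=25, targets_min=15, targets_max=25,
                      driver="activity", alpha=0.0, rewiring_fraction=0.8,
                      seed=5)
expr, sens, truth = simulate_cohort(cfg)

table = cross_regulon_matrix(expr, sens, truth.regulons, method="ulm")
print("mean |R| for each (cohort cancer type x regulon source):")
print(table.round(3).to_string())

ranks, p = matched_vs_mismatched(table)
print("\nwithin-type ranks (1 = most predictive regulon):")
print(ranks.astype(int).to_string())
print(f"\nrank-sum test, matched vs mismatched ranks: p = {p:.4g}")
print("diagonal cells are the matched combinations; with heavily rewired")
print("type-specific networks the matched regulon ranks first in its own type.")
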
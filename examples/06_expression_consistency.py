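"""Find genes differentially expressed in the same direction in every
tissue, and test whether DE status is independent across organs.

DE calls use |log2FC| >= 1 and adjusted p < 0.05. The independence test
permutes each tissue's indicator column and compares the observed count
of all-tissue-consistent genes against that null.
"""

from hadalcomp import (
    SimulationConfig,
    call_de,
    cross_tissue_consistent_genes,
    independence_permutation_test,
)
from hadalcomp.expression_consistency import indicator_matrix
from hadalcomp.simulate import simulate_expression_tables

cfg = SimulationConfig(
    n_genes=500,
    planted_consistent_up=frozenset({"g0010", "g0200", "g0404"}),
    background_de_rate=0.2,
    rng_seed=17,
)
_, de_tables, truth = simulate_expression_tables(cfg)

indicators = {tissue: call_de(table) for tissue, table in de_tables.items()}
consistent = cross_tissue_consistent_genes(indicators, direction="up")
print(f"tissues: {sorted(indicators)}")
print(f"consistently up-regulated in all tissues: {consistent}")
print(f"planted truth: {sorted(truth)}")

matrix = indicator_matrix(indicators)
result = independence_permutation_test(matrix, "up", n_permutations=1000, seed=17)
print(
    f"observed all-tissue count: {result.statistic}; "
    f"permutation p-value: {result.p_value:.4f}"
)
# With 3 planted genes against a ~0.1 per-tissue background up-rate, the
# observed count far exceeds the column-permutation null (p near 1/1001).
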
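"""Alpha diversity, Bray-Curtis dissimilarity and PCoA on one kingdom.

Simulates the inducible-virus (IV) compartment, summarises each sample by
richness / Fisher-alpha / Simpson dominance, then ordinates the
Bray-Curtis matrix. The first principal coordinate's explained-variance
share tells you how one-dimensional the community differences are; the
per-sample PC1 scores are the raw material of the stability statistic.
"""

from gutstab import (
    CohortConfig,
    alpha_diversity_table,
    bray_curtis_matrix,
    make_cohort,
    pcoa,
    simulate_feature_table,
)

config = CohortConfig(seed=2)
metadata = make_cohort(config)
iv = simulate_feature_table(metadata, config, "IV")

alpha = alpha_diversity_table(iv)
print("per-sample alpha diversity (first 5 samples):")
print(alpha.head().round(3))

D = bray_curtis_matrix(iv, on="proportions")
res = pcoa(D)
print(f"\nPCoA: {res.scores.shape[1]} positive axes; "
      f"PC1 explains {100 * res.proportion_explained[0]:.1f}% of positive-eigenvalue variance")
print("PC1 scores (first 5 samples):")
print(res.pc1().head().round(4))
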
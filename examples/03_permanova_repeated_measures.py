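"""PERMANOVA of time point with subject as a repeated-measures stratum.

Within one diet arm, asks whether community composition shifts across the
pre/mid/post time points. Because the same subjects are measured three
times, permutations shuffle time labels only *within* each subject —
the repeated-measures restriction. The R-squared is the share of
dissimilarity explained by time; the p-value comes from 999 restricted
permutations (its floor is 1/1000).
"""

from gutstab import (
    CohortConfig,
    bray_curtis_matrix,
    make_cohort,
    permanova,
    simulate_feature_table,
)

config = CohortConfig(seed=3)
metadata = make_cohort(config)
fvp = simulate_feature_table(metadata, config, "FVP")

arm = "HPD"
arm_samples = [s for s in fvp.sample_ids if metadata.frame.loc[s, "arm"] == arm]
D = bray_curtis_matrix(fvp.subset_samples(arm_samples), on="proportions")

res = permanova(
    D,
    {s: metadata.frame.loc[s, "time_point"] for s in arm_samples},
    strata={s: metadata.frame.loc[s, "subject"] for s in arm_samples},
    n_perm=999,
    seed=3,
)
print(f"{arm} FVP community vs time point (subject-stratified PERMANOVA):")
print(f"  pseudo-F = {res.pseudo_f:.3f}")
print(f"  R^2      = {res.r_squared:.3f}  (fraction of dissimilarity explained by time)")
print(f"  p        = {res.p_value:.4f}  ({res.n_permutations} restricted permutations)")
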
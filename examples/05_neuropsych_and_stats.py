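"""Neuropsychological battery handling and cohort contingency statistics.

Compares class-mean filling with list-wise deletion for
missing-at-random battery scores, builds the combined
imaging-plus-battery feature matrix, and reproduces the
subtype-by-outcome contingency analysis.
"""

import numpy as np

import mcisvm as m

y = np.array([1] * 41 + [-1] * 14)
npsych = m.simulate_neuropsych(y, group_shift=-0.5, n_incomplete=27, seed=4)
n_missing = int(npsych.missing_mask.sum())
print(f"battery: 55 x 6, {n_missing} missing cells across "
      f"{int(npsych.missing_mask.any(axis=1).sum())} subjects")

# strategy 1: class-mean filling (training rows; held-out rows get the
# overall training mean since their class is unknown at test time)
filled = m.class_mean_impute(npsych, y, train_rows=np.arange(55))
print(f"class-mean filling: 0 missing cells remain "
      f"({np.isnan(filled.values).sum()} NaNs)")

# strategy 2: list-wise deletion with rebalanced class costs
idx, survivors, costs = m.listwise_delete(npsych, list(y))
print(f"list-wise deletion: {idx.size} complete subjects survive; "
      f"class costs -> stable {costs[1]:.3f}, decline {costs[-1]:.3f}")

# combined model: imaging features + the 6 filled battery columns
atlas = m.make_atlas((12, 12, 12), n_parcels=16, n_networks=4, seed=4)
cohort = m.simulate_cohort(atlas, 41, 14, T=60, effects=m.EffectSpec(seed=4))
imaging = m.assemble_features(cohort, atlas, {"t1", "conn"})
combined = m.combined_feature_model(imaging, filled)
print(f"combined feature matrix: {imaging.n_features} imaging + 6 battery "
      f"= {combined.n_features} columns")

# subtype-by-outcome association, reconstructed from the group sizes and
# single-domain percentages
table = m.subtype_outcome_table()
out = m.chi_square_2x2(table)
print(f"\nsubtype x outcome table (rows stable/decline, cols single/multi):")
print(table.as_array().astype(int))
print(f"chi-square = {out['chi_square']:.2f}, p = {out['p_value']:.3f}, "
      f"odds ratio = {out['odds_ratio']:.1f}")
print("multi-domain aMCI at baseline is associated with decline at follow-up")
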
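"""From scans to the analysis feature space.

Vectorizes in-mask T1 voxels, computes Fisher-z connectivity for all
R(R-1)/2 parcel pairs, and shows the fold-internal t-test filter and
z-score standardization that precede every SVM fit.
"""

import numpy as np

import mcisvm as m

atlas = m.make_atlas((20, 20, 20), n_parcels=51, n_networks=7, seed=1)
effects = m.EffectSpec(t1_effect_parcels=(5,), t1_effect_size=3.0, seed=1)
cohort = m.simulate_cohort(atlas, 41, 14, T=150, effects=effects)

features = m.assemble_features(cohort, atlas, {"t1", "conn"})
n_vox = (features.modality == "t1").sum()
n_conn = (features.modality == "conn").sum()
print(f"feature matrix: {features.n_subjects} x {features.n_features} "
      f"({n_vox} voxels + {n_conn} connections)")
print(f"51 parcels -> {m.connection_count(51)} unique connections "
      f"(n(n-1)/2; a 160-region atlas would give {m.connection_count(160)})")

# Fold-internal selection: t-test between classes on training rows only,
# keep p < 0.01, no multiple-testing correction.
y = np.array([s.label for s in cohort])
train = np.arange(54)  # leave subject 55 out
mask = m.ttest_filter(features.values, y, train, alpha=0.01)
print(f"selected {mask.n_selected} of {features.n_features} features at p < 0.01 "
      f"(chance would keep ~{features.n_features // 100})")

# Standardization is fitted on the same training rows, after selection.
X_sel = features.values[:, mask.keep]
std = m.fit_standardizer(X_sel, train)
Z = m.apply_standardizer(std, X_sel[train])
print(f"standardized training block: col means ~{np.abs(Z.mean(0)).max():.1e}, "
      f"col SDs ~{Z.std(0, ddof=1).mean():.3f}")
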
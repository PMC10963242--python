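"""Rank features for SBP with both selectors on a synthetic cohort.

Extracts features from a 60-subject cohort and compares the CFS greedy
forward search with ReliefF weighting: the top-ranked features per
method, and how much the two subsets overlap.
"""

import warnings

from ppg2bp.features import FEATURE_NAMES, build_feature_matrix
from ppg2bp.preprocess import preprocess_record
from ppg2bp.selection import cfs_select, relieff_select, relieff_weights
from ppg2bp.synthetic import generate_cohort

records, table, _ = generate_cohort(60, 3, seed=11)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    matrix, _ = build_feature_matrix([preprocess_record(r) for r in records], table)

X = matrix[list(FEATURE_NAMES)]
y = matrix["sbp"].to_numpy()

cfs = cfs_select(X, y, target_size=15, target="sbp")
weights = relieff_weights(X, y, seed=0)
rel = relieff_select(weights, 15, feature_names=list(X.columns), target="sbp")

print(f"{'rank':>4s}  {'CFS':<16s} {'ReliefF':<16s}")
for i in range(15):
    print(f"{i + 1:>4d}  {cfs.selected[i]:<16s} {rel.selected[i]:<16s}")

overlap = set(cfs.selected) & set(rel.selected)
print(f"\nCFS subset fitness R_cfs = {cfs.scores[-1]:.3f}; "
      f"subset overlap: {len(overlap)}/15 features shared.")
print("Both selectors should surface the morphology features the generator "
      "drives with SBP (pulse interval, augmentation-index family, systolic "
      "timing) ahead of uninformative slots.")
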
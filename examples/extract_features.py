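"""Extract time-windowed features for one prediction point.

Builds instances six hours before each record's event (ICU transfer for
cases, floor departure for controls) using the 24 h vitals / 72 h other
lookback windows, and shows the sparse named-feature vector of one case.
"""

import icuward as iw
import icuward.features as F

cfg = iw.GeneratorConfig(n_case_encounters=20, n_control_encounters=100,
                         seed=3)
encounters, events, _ = iw.generate(cfg)
cohort = iw.build_cohort(encounters, events, ratio=5.0, seed=3)

instances = iw.build_instances(cohort, events, horizon_hours=6.0)
vocab = iw.FeatureVocabulary.fit(instances)
X = vocab.transform(instances)
y = F.labels(instances)

print(f"instances: {len(instances)}  (cases {int(y.sum())}), "
      f"vocabulary {len(vocab)} features, "
      f"density {X.nnz / (X.shape[0] * X.shape[1]):.3f}")

case = next(i for i in instances if i.y == 1)
print(f"\ncase {case.encounter_id}, prediction at {case.prediction_time} "
      f"(horizon {case.horizon_hours:.0f} h); sample of its "
      f"{len(case.features)} features:")
for name in sorted(case.features)[:12]:
    print(f"  {name:48s} {case.features[name]:+.3f}")
# Indicators (binned categories, attribute-value pairs, threshold bins) are
# 0/1; slopes and histogram entries are real-valued. Elements never charted
# in the window simply contribute nothing - there is no imputation.
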
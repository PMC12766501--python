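"""From raw event rows to per-patient temporal organ-interaction graphs.

Events are averaged into 4-h bins over 48 h (12 steps), filtered by
missingness, outlier-censored with Tukey fences, forward/backward filled,
and z-scored with training-split statistics; the binned features then
attach to the 13-node star-of-stars graph (patient -> 6 systems -> 6
feature nodes).
"""

from odtgc.graphs import build_sequences, encode_diagnoses, schema_from_feature_ids
from odtgc.preprocess import preprocess_events
from odtgc.synthcohort import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_patients=300, seed=1))
tensor, stats, (train, val, test) = preprocess_events(
    cohort.events, window_h=48, bin_h=4, seed=1
)
print(f"feature tensor: {tensor.values.shape}  (patients x 12 bins x features)")
print(f"splits: {len(train)}/{len(val)}/{len(test)}  (6:2:2, train stats only)")
print(f"dropped features: {stats.dropped_features or 'none'}; "
      f"dropped patients: {len(stats.dropped_patients)}")

schema = schema_from_feature_ids(tensor.feature_ids, cohort.config.systems)
print(f"graph schema: {len(schema.node_names)} nodes, {len(schema.edges)} edges")

_, dx_vectors = encode_diagnoses(cohort.diagnoses, min_count=25)
data = build_sequences(tensor, cohort.demographics, dx_vectors, schema)
print(f"graph dataset X: {data.X.shape}  (patients x time x nodes x attrs)")
print("adjacency is shared across patients; only node attributes vary in time")
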
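"""Cluster a synthetic two-class cohort under two representations.

Generates a small ischemic-like vs hemorrhagic-like cohort, represents each
patient as (a) the mean of its concept embedding vectors and (b) a multi-hot
binary vector, clusters with the matching distance (cosine / Jaccard),
selects k by silhouette, and scores the clusters against the planted
classes. Scaled down (n=400, d=32, 5 shuffles) to run in about a minute.
"""

from dataclasses import replace

from emr2vec import RunConfig, TrainConfig, default_cohort_spec, generate_cohort, run_pipeline, schema_for

spec = default_cohort_spec(n_patients=400, seed=7)
records, truth, _ = generate_cohort(spec)
schema = schema_for(spec)

cfg = RunConfig(
    scheme="embedding-shuffled", seed=7, k_range=(2, 6), n_init=4,
    train=TrainConfig(dim=32, window=5, epochs=3, seed=7, n_shuffles=5),
)

for scheme in ("embedding-shuffled", "multi-hot"):
    res = run_pipeline(replace(cfg, scheme=scheme), records, schema, truth)
    f1 = res.report.per_class["IS"]["f1"]
    print(f"{scheme:20s} k*={res.k_star}  Hopkins={res.report.hopkins:.3f}  "
          f"SI={res.report.silhouette:.3f}  DBI={res.report.dbi:.3f}  F1(IS)={f1:.3f}")

# The embedding representation recovers the planted k=2 and clusters far
# more cohesively (higher silhouette, lower Davies-Bouldin): averaging
# learned concept vectors places related admissions nearby even when they
# share few exact codes, which the set-overlap (Jaccard) view cannot see.
# At this small scale the multi-hot SI is nearly flat in k, so its selected
# k is unstable; at cohort scale both settle at k*=2.
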
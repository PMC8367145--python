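"""Score a published two-cluster confusion table.

Given per-cluster diagnosis counts — cluster 1 holding 6495 ischemic (IS)
and 427 hemorrhagic (HS) stroke patients, cluster 2 holding 340 IS and 970
HS — map each cluster to its majority diagnosis and compute precision,
recall and F1 per diagnosis.
"""

from emr2vec import score_from_counts

counts = {1: {"IS": 6495, "HS": 427}, 2: {"IS": 340, "HS": 970}}
report = score_from_counts(counts)

print("cluster -> label:", report.cluster_label_map)
for label, s in report.per_class.items():
    print(f"{label}: precision={s['precision']:.3f} recall={s['recall']:.3f} f1={s['f1']:.3f}")

# F1 of 0.944 for the IS-majority cluster and 0.717 for the HS-majority one:
# the large class is recovered almost perfectly, while a third of HS patients
# are absorbed by the IS cluster (many of those carry IS as a second code).
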
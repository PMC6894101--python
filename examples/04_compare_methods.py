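"""Compare bag-of-words against knowledge-fusion methods per rarity bin.

Runs a small version of the benchmark experiment (30 classes, 4,000
documents, 3 train/test splits) and prints mean macro-F1 per prevalence
bin. The interesting rows are the rare bins (<= 0.1%): that is where
the knowledge graph compensates for scarce training data.
"""

import kgfuse as kf

spec = kf.SyntheticSpec(
    n_classes=30, n_docs=4000, background_vocab=800, kg_coverage=0.9, seed=6
)
corpus, store, _ = kf.generate_benchmark(spec)

report = kf.run_experiment(
    corpus, store,
    ["bow", "kg1", "early_fusion_kg1", "pseudo_count_kg1"],
    runs=3, base_seed=0, rand_rounds=500,
)

print(f"{'method':<18} {'bin':<16} {'F1':>7} {'MRR':>7}  p(F1) vs bow")
for row in report.rows:
    if row.mean_f1 is None:
        continue
    p = "" if row.p_f1 is None else f"{row.p_f1:.3f}"
    print(f"{row.method:<18} {row.bin_name:<16} "
          f"{row.mean_f1:7.2f} {row.mean_mrr:7.2f}  {p}")
# Metrics are on the 0-100 scale, averaged over the 3 splits; p-values
# come from a paired randomization test on pooled per-document outcomes.
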
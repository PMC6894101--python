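"""Generate the default synthetic benchmark and inspect its shape.

Builds a Zipf-skewed 60-class corpus of 8,000 short documents plus an
imperfect companion knowledge graph, then prints how the classes fall
into the prevalence bins used for reporting.
"""

from collections import Counter

import kgfuse as kf

spec = kf.SyntheticSpec()
corpus, store, ground_truth = kf.generate_benchmark(spec)

counts = corpus.class_counts
ordered = counts.most_common()
print(f"documents: {len(corpus)}, classes: {len(corpus.labels)}, "
      f"KG entities: {len(store)}")
print(f"largest class: {ordered[0][0]} ({ordered[0][1]} docs); "
      f"smallest: {ordered[-1][0]} ({ordered[-1][1]} doc)")

binning = kf.compute_rarity_bins(corpus)
per_bin = Counter(binning.assignment.values())
for b in range(binning.n_bins):
    print(f"bin {binning.bin_name(b):>16}: {per_bin.get(b, 0):3d} classes")
print(f"{'above 1%':>20}: {per_bin.get(None, 0):3d} classes")
print(f"rare classes (<=0.1%): {len(binning.rare_labels())}")
# A long tail is the whole point: most classes are rare, but they hold
# only a small share of the documents.
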
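"""Build log-binned purchase plans and merge them.

Scores the observed non-binders of a noisy library with both metrics,
then applies the five-step picker: keep available compounds, buy all
score = 1 compounds, rank the rest, split the ranking into 25 bins
whose widths grow geometrically away from the top (densest sampling at
high scores), and buy the cheapest compound per bin.  The per-metric
plans are merged into one deduplicated purchase list.
"""

import numpy as np

from xsar import (
    categorize_bits, default_spec, fingerprint, generate,
    merge_ensembles, score, select_retrospective,
)

spec = default_spec(false_negative_rate=0.3, seed=7)
dataset, truth = generate(spec)
fps = fingerprint(dataset)
model = categorize_bits(fps, dataset)
records = {r.id: r for r in score(model, fps)}

candidates = [records[i] for i in sorted(dataset.nonbinder_ids)]
rng = np.random.default_rng(0)
price = {r.id: float(p) for r, p in zip(candidates, rng.uniform(1, 100, len(candidates)))}
availability = {r.id: True for r in candidates}

plans = [
    select_retrospective(candidates, which, availability, price, n_bins=25)
    for which in ("pbs", "nbs")
]
for plan in plans:
    print(f"{plan.ensemble}: {len(plan.score_one_ids)} score-1 buys + "
          f"{len(plan.bin_pick_ids)} bin picks")
merged = merge_ensembles(plans)
print(f"merged purchase list: {len(merged)} unique compounds "
      f"(overlap between ensembles collapses the union)")
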
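"""Fit a bit-conservation model on a synthetic elaboration library and score it.

Generates the default 432-compound congeneric library, fits the
CBB/CNB/UCB/USB bit categorisation on the binder/non-binder partition,
and scores a few compounds.  PBS is the fraction of conserved binding
bits a compound activates (1 = predicted binder); NBS is one minus the
fraction of conserved non-binding bits it activates (< 1 = predicted
non-binder).
"""

from xsar import categorize_bits, classify, default_spec, fingerprint, generate, score

spec = default_spec()
dataset, truth = generate(spec)
fps = fingerprint(dataset)
model = categorize_bits(fps, dataset)

print(f"library: {len(dataset)} compounds, "
      f"{dataset.n_binders} binders / {dataset.n_nonbinders} non-binders")
print(f"bit model: |CBB|={len(model.cbb)} |CNB|={len(model.cnb)} "
      f"|UCB|={len(model.ucb)} |USB|={len(model.usb)} "
      f"(sum = {model.params.length} = fingerprint length)")

records = score(model, fps)
print("\nid            PBS    NBS    verdict")
for rec in records[:3] + records[-3:]:
    verdict = classify(rec)
    tags = []
    if verdict.predicted_binder_by_pbs:
        tags.append("binder-by-PBS")
    if verdict.predicted_nonbinder_by_nbs:
        tags.append("non-binder-by-NBS")
    tag = " + ".join(tags) or "ambiguous"
    print(f"{rec.id:12s} {rec.pbs:6.3f} {rec.nbs:6.3f}  {tag}")
print("\nPBS = 1 means every conserved binding feature is present; "
      "NBS < 1 means at least one feature only ever seen in non-binders.")
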
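"""Recover false negatives planted by label-flip noise.

30% of the true binders are observed as non-binders, emulating the
false-negative rate of a crude-reaction-mixture crystallographic
readout.  Among the observed non-binders, the PBS = 1 stratum — the
compounds that nevertheless carry every conserved binding feature — is
enriched in true binders, which is exactly the set a retrospective
re-screen should buy.
"""

from xsar import categorize_bits, default_spec, fingerprint, generate, recovery_report

spec = default_spec(false_negative_rate=0.3, seed=7)
dataset, truth = generate(spec)
fps = fingerprint(dataset)
model = categorize_bits(fps, dataset)
report = recovery_report(model, fps, dataset, truth, spec)

n_flipped = int((truth.true_binder & ~truth.observed_binder).sum())
print(f"true binders: {int(truth.true_binder.sum())}, "
      f"observed binders: {dataset.n_binders} ({n_flipped} flipped to non-binder)")
print(f"observed non-binders: {report.n_observed_nonbinders}, "
      f"of which true binders: {report.baseline_true_binder_fraction:.1%}")
print(f"PBS = 1 stratum: {report.n_stratum} compounds, "
      f"of which true binders: {report.stratum_true_binder_fraction:.1%}")
print(f"enrichment over baseline: {report.enrichment:.2f}x")
print("\nRe-screening the PBS = 1 stratum in pure form recovers the planted "
      "false negatives at a rate well above picking non-binders at random.")
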
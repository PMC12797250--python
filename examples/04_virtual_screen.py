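"""Run the ligand-based virtual-screening cascade over a catalogue.

The funnel: Rule-of-Five exclusion, top-K by PBS, NBS-mean filter,
cheapest-N, MaxMin diversity, external-energy top fraction, final
diversity pick.  Price and energy are supplied columns (here seeded
stand-ins for a vendor price list and an external pose-scoring tool).
"""

import numpy as np

from xsar import (
    CascadeConfig, Compound, LabelledDataset,
    categorize_bits, default_spec, fingerprint, generate, run_cascade,
)

dataset, _ = generate(default_spec())
fps = fingerprint(dataset)
model = categorize_bits(fps, dataset)
catalogue = LabelledDataset([Compound(c.id, c.smiles) for c in dataset.compounds])

rng = np.random.default_rng(1)
price = {c.id: float(p) for c, p in zip(catalogue.compounds,
                                        rng.uniform(1, 100, len(catalogue)))}
energy = {c.id: float(e) for c, e in zip(catalogue.compounds,
                                         rng.normal(size=len(catalogue)))}

config = CascadeConfig(top_by_pbs=200, n_cheapest=100, n_diverse=50,
                       energy_top_fraction=0.2, final_n=10, seed=1,
                       nbs_filter_direction="remove_below_mean")
final, reports = run_cascade(catalogue, model, config, price=price, energy=energy)

print("stage                 in   ->  out")
for r in reports:
    print(f"{r.stage:20s} {r.n_in:5d} -> {r.n_out:5d}  {r.note}")
print(f"\nfinal selection ({len(final)}): {final}")
print("Counts shrink monotonically; the survivors are cheap, lead-like, "
      "high-PBS, structurally diverse and well ranked by the external energy.")
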
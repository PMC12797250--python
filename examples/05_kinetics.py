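"""Post-process binding-kinetics readouts.

For each compound: K_D = k_d / k_a with root-sum-square propagated
error, a stringent hit call (both rate errors < 25% and R_max > 10),
ligand efficiency −RT·ln(K_D)/N, and the theoretical R_max an ideal 1:1
interaction would reach on the immobilised surface.
"""

from xsar.kinetics import KineticRecord, process_records

records = [
    KineticRecord("hit_fast", ka=2.1e5, kd=8.0e-3, delta_ka=0.08, delta_kd=0.12,
                  rmax=22.0, smiles="Cc1ccc(o1)C(=O)N1CCN(C)CC1"),
    KineticRecord("weak", ka=9.0e3, kd=4.0e-1, delta_ka=0.18, delta_kd=0.22,
                  rmax=12.0, smiles="O=C(c1ccco1)N1CCNCC1"),
    KineticRecord("noisy_fit", ka=5.0e4, kd=2.0e-2, delta_ka=0.40, delta_kd=0.10,
                  rmax=18.0, smiles="c1ccc(cc1)C(=O)N1CCNCC1"),
]

frame = process_records(records, immobilised_mass=6554, mw_protein=17600)
print(frame.to_string(
    index=False,
    float_format=lambda v: f"{v:.3g}",
))
print("\nK_D in molar with its propagated error; `hit` applies the strict "
      "error/signal criteria; ligand efficiency is kcal/(mol × heavy atom); "
      "occupancy compares the fitted R_max to the 1:1 theoretical ceiling.")
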
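# Methods

## Model and assumptions

The package models crystallographic binding as a deterministic function
of local chemical environments. A compound is a set of hashed circular
fingerprint bits (binary presence, never counts); the fitted model is a
partition of all M bit positions into four categories driven by the
per-bit conservation score S_m = (binders with the bit active)/|B|:
bits conserved across every binder (CBB), bits never seen in a binder
but present in at least one non-binder (CNB), partially conserved bits
(UCB), and bits inactive everywhere (USB). CBB membership is decided
regardless of non-binder activation — a bit every binder carries is a
binding-conserved feature even if some non-binders also carry it.

The scores PBS = hits/|CBB| and NBS = 1 − hits/|CNB| are exact
rationals, and the classification rules are exact equalities (PBS = 1
predicts binder; NBS < 1 predicts non-binder). Score arithmetic
therefore uses integer bit counts and `fractions.Fraction`; floating
representations are derived views. Category membership likewise uses
exact integer counts (count == |B|, count == 0), never a tolerance:
S_m is rational and the boundary cases *are* the categories.

Assumptions worth stating: (i) binding outcome is attributable to
2-D substructure, so stereochemistry, conformation, protonation and
solubility are invisible; (ii) the training labels may be noisy, and
the method's value is precisely that conserved-feature statistics are
robust to moderate label noise while per-compound labels are not;
(iii) hashed-bit collisions are accepted — with M = 2048 and a
congeneric series they are rare, and the optional bit→exemplar
provenance map makes individual bits inspectable.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| fingerprint length M | 2048 | bit-collision rate vs. memory |
| radius | 6 | large radius: whole-substituent environments, good for congeneric series |
| invariants | `feature` | pharmacophoric (FCFP-like) atom classes; `connectivity` (ECFP-like) available and sharper for ring-type distinctions |
| pose split | `all` | `lateral`/`diving` re-label the other pose's binders as non-binders |
| t-SNE | Jaccard metric, perplexity 30 | diagnostic only; no decision consumes coordinates |
| selection bins | 25 | geometric rank cut-points, densest at high scores |
| cascade quotas | 45 000 / 15 000 / 10 000 / 3% | the reference campaign's sizes; scale to the catalogue |
| hit calling | δka < 25%, δkd < 25%, R_max > 10 | strict inequalities |
| constants | R = 1.987×10⁻³ kcal/(mol K), T = 298 K | overridable |

## Numerical and procedural choices

- **Tanimoto of two all-zero fingerprints is 1** (identical objects);
  this avoids 0/0 while preserving identity semantics, and is logged.
- **Rule-of-Five "violates" means ≥ 1 criterion failed** by default
  (`min_failures=2` gives the classic reading).
- **Mann–Whitney U**: scipy's implementation switches to the asymptotic
  approximation under ties, so for combined n ≤ 16 the p-value is
  computed by exhaustive enumeration of all label assignments of the
  pooled values (exact even with ties); larger samples use the
  tie-corrected normal approximation. The U statistic counts ties as ½.
- **PR-AUC** uses the step-function (average-precision) convention with
  equal scores grouped into one operating point; conventions differ, so
  the tests pin it against a brute-force threshold sweep.
- **Log-binned selection**: "denser sampling at higher scores" is
  realised by ranking descending and placing bin edges at geometrically
  spaced rank cut-points (`geomspace` over ranks, rounded, forced
  strictly increasing so no bin is empty when candidates ≥ bins); with
  fewer candidates than bins each candidate is its own bin. Price ties
  break by score closest to the bin mean, then lexicographic id. The
  score = 1 purchases are reported separately from the bin picks rather
  than forced into a fixed total.
- **NBS-mean filter direction**: the procedure as printed removes
  compounds with NBS ≥ mean, which (since high NBS means *few*
  non-binding features) removes the compounds its stated purpose should
  keep. The default is the as-printed rule; `remove_below_mean`
  implements the semantic reading. The discrepancy is surfaced as a
  documented flag, not silently resolved.
- **MaxMin diversity picking** is an in-package greedy farthest-point
  search under Tanimoto distance: seeded uniform start (recorded in the
  stage report), ties broken by lexicographic id, so runs are exactly
  reproducible and the picker can be verified against an exhaustive
  greedy oracle.
- **External energies** (pose-placement ΔΔG, ligand-energy ratios) are
  consumed as numeric columns; the package implements only the
  selection rules (lowest-ΔΔG top fraction, ratio cut-off). The ratio
  cut-off has no default — it is campaign-specific.
- **Degenerate inputs**: zero binders is an undefined-model error
  (division by zero in S_m); an empty CBB or CNB makes the respective
  score undefined and scoring refuses; a cascade stage that empties the
  pool halts with the report so far; a stage quota exceeding the pool
  passes all survivors with a note.
- **Model serialisation** is a versioned JSON document (parameters,
  counts, four bit-index lists) so scoring is reproducible without the
  training table; a `bit_weights` field is reserved but unused.

## The synthetic library

`default_spec()` enumerates a 3 × 12 × 12 = 432-compound library on a
benzamide–piperazine scaffold: R1 on the distal piperazine nitrogen
(H/methyl/ethyl; the N-methyl choice toggles the `diving` pose,
mirroring how a methylpiperazine reorients a core), R2 an aryl/alkyl
panel whose six furan-bearing options carry the essential five-membered
oxygen heteroaromatic, and R3 a decoration panel including two
sulfonamide extensions planted as binding-forbidden. A compound is a
true binder iff it has all essential features and no forbidden one
(180 of 432). False negatives are emulated by flipping true binders to
observed non-binders with a per-compound probability; each compound's
flip draws from an RNG keyed by (seed, structure hash) so growing the
library never reshuffles the noise of existing compounds.

What it emulates: a congeneric elaboration series, feature-determined
outcomes, pose toggling by a single substituent, and label noise. What
it does not: activity cliffs that 2-D features cannot express,
synthesis failures, solubility artefacts, hash collisions specific to
any real series, and continuous affinity. Passing tests therefore show
the machinery is correct and that conserved-feature recovery survives
label noise — not that crystallographic outcomes of any real system are
feature-determined.

One deliberate subtlety: with the default `feature` invariants,
aromatic rings of different elements share pharmacophoric atom classes,
so some furan signature bits are also activated by other aryl R2
choices. The false-negative enrichment of the PBS = 1 stratum is
consequently modest (≈1.5× at 30% noise) rather than dramatic — a
realistic picture of what feature-class fingerprints resolve on a
congeneric series; `connectivity` invariants sharpen it.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
the 432-compound library (noise-free and 30%-noise variants), cascade
quotas 200/100/50/20%/10, 25-bin purchase plans, and brute-force
oracles at M ≤ 16, n ≤ 10. These sizes exercise every code path of the
full-scale procedure; the quotas scale linearly to catalogue-sized
inputs.

## Known limitations

- CBB shrinks as binders accumulate and can collapse to generic bits
  (aromatic/aliphatic carbon environments) on diverse binder sets; the
  method is designed for scaffold-conserved series.
- NBS discriminates weakly when non-binders vastly outnumber binders:
  |CNB| grows, each compound activates few CNB bits, and the score
  compresses towards 1.
- PBS = 1 is a necessary-feature criterion, not a sufficiency claim;
  it cannot rank within the PBS = 1 stratum.
- t-SNE coordinates are not comparable across runs; they are plotted,
  never consumed.
- Bit weighting (e.g. down-weighting ubiquitous bits) is deliberately
  out of scope; the model format reserves a field for it.
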
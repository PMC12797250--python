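"""Prospective ligand-based virtual-screening cascade.

The funnel over a candidate catalogue, applied strictly in order:

1. Rule-of-Five exclusion (lead-likeness);
2. top-K compounds by PBS;
3. removal of compounds whose NBS is at or above the incoming mean
   (the as-printed direction — see ``nbs_filter_direction``);
4. the N cheapest (price is a supplied column or provider);
5. MaxMin diversity pick of the N most diverse under Tanimoto distance;
6. optional external-energy filters: a ligand-energy-ratio cut-off and
   a lowest-ΔΔG top-fraction cut, both consuming externally computed
   numeric columns;
7. a final MaxMin diversity pick of the purchase set.

Each stage emits a :class:`StageReport`; when a stage's quota exceeds
the surviving pool every survivor passes, with a note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .bitmodel import BitCategorization
from .dataio import DataError, LabelledDataset
from .fingerprints import FingerprintMatrix, fingerprint, rule_of_five, tanimoto_matrix
from .scoring import ScoreRecord, score

log = logging.getLogger(__name__)

NBS_DIRECTIONS = ("remove_at_or_above_mean", "remove_below_mean")


@dataclass(frozen=True)
class CascadeConfig:
    """Stage quotas; defaults are the reference screening campaign's sizes."""

    top_by_pbs: int = 45_000
    n_cheapest: int = 15_000
    n_diverse: int = 10_000
    energy_top_fraction: float = 0.03
    energy_ratio_cutoff: float | None = None  # no default; campaign-specific
    nbs_filter_direction: str = "remove_at_or_above_mean"
    final_n: int = 50
    ro5_min_failures: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("top_by_pbs", "n_cheapest", "n_diverse", "final_n"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")
        if not 0 < self.energy_top_fraction <= 1:
            raise DataError("energy_top_fraction must be in (0, 1]")
        if self.nbs_filter_direction not in NBS_DIRECTIONS:
            raise DataError(
                f"nbs_filter_direction must be one of {NBS_DIRECTIONS}"
            )


@dataclass(frozen=True)
class StageReport:
    stage: str
    n_in: int
    n_out: int
    parameters: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self):
        if self.n_out > self.n_in:
            raise DataError(f"stage {self.stage}: survivors exceed input")


def maxmin_pick(fps: FingerprintMatrix, k: int, seed: int) -> list[str]:
    """Greedy farthest-point (MaxMin) diversity selection under Tanimoto distance.

    Starts from a seeded uniform draw, then repeatedly adds the compound
    whose minimum distance to the picked set is largest; distance ties
    are broken by lexicographic id.  Deterministic for a fixed seed.
    """
    n = len(fps)
    if k > n:
        raise DataError(f"cannot pick {k} compounds from {n}")
    if k == 0:
        return []
    order = np.argsort(np.array(fps.ids, dtype=object))  # id rank for tie-breaks
    id_rank = np.empty(n, dtype=np.int64)
    id_rank[order] = np.arange(n)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    picked = [start]
    X = fps.bits.astype(np.int32)
    pops = X.sum(axis=1)

    def dist_to(i: int) -> np.ndarray:
        inter = X @ X[i]
        union = pops + pops[i] - inter
        sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
        return 1.0 - sim

    min_dist = dist_to(start)
    for _ in range(1, k):
        min_dist[picked] = -np.inf
        best = np.max(min_dist)
        candidates = np.flatnonzero(min_dist == best)
        nxt = int(candidates[np.argmin(id_rank[candidates])])
        picked.append(nxt)
        min_dist = np.minimum(min_dist, dist_to(nxt))
    return [fps.ids[i] for i in picked]


def nbs_mean_filter(
    records: Sequence[ScoreRecord],
    direction: str = "remove_at_or_above_mean",
) -> list[str]:
    """Filter compounds by NBS relative to the incoming mean.

    The default reproduces the procedure as printed (remove NBS ≥ mean).
    Read literally this removes the compounds its stated purpose —
    excluding non-binding features — should keep, since high NBS means
    *few* non-binding features; the alternate direction
    (``remove_below_mean``) implements that semantic reading.  The
    discrepancy is surfaced here rather than silently resolved.
    """
    if not records:
        raise DataError("nbs_mean_filter needs at least one record")
    if direction not in NBS_DIRECTIONS:
        raise DataError(f"direction must be one of {NBS_DIRECTIONS}")
    mean_nbs = sum(r.nbs_fraction for r in records) / len(records)
    if direction == "remove_at_or_above_mean":
        survivors = [r.id for r in records if r.nbs_fraction < mean_nbs]
    else:
        survivors = [r.id for r in records if r.nbs_fraction >= mean_nbs]
    if not survivors:
        log.warning(
            "nbs_mean_filter (%s) removed every compound (all NBS equal?)",
            direction,
        )
    return survivors


def run_cascade(
    catalogue: LabelledDataset,
    model: BitCategorization,
    config: CascadeConfig,
    price: Mapping[str, float] | None = None,
    energy: Mapping[str, float] | None = None,
    energy_ratio: Mapping[str, float] | None = None,
) -> tuple[list[str], list[StageReport]]:
    """Run the full funnel; returns the final id list and per-stage reports.

    ``energy`` (ΔΔG-like, lower is better) and ``energy_ratio`` are
    externally computed columns; their stages are skipped when the
    mapping is absent.  A cascade that empties at any stage halts and
    returns the reports accumulated so far.
    """
    reports: list[StageReport] = []
    records_by_id: dict[str, ScoreRecord] = {}

    def report(stage, n_in, survivors, params=None, note=""):
        reports.append(StageReport(stage, n_in, len(survivors), params or {}, note))
        log.info("cascade stage %-18s %6d -> %6d %s", stage, n_in, len(survivors), note)

    def need(mapping, ids, what):
        missing = [i for i in ids if mapping is None or i not in mapping]
        if missing:
            raise DataError(
                f"{what} missing for {len(missing)} compound(s), e.g. {missing[:5]}"
            )

    # stage 1: Rule of Five
    pool = [c.id for c in catalogue.compounds]
    survivors = [
        c.id
        for c in catalogue.compounds
        if not rule_of_five(c.smiles, config.ro5_min_failures).violates
    ]
    report("rule_of_five", len(pool), survivors,
           {"min_failures": config.ro5_min_failures})
    if not survivors:
        return [], reports

    # fingerprints + scores for the Ro5 survivors
    smiles = {c.id: c.smiles for c in catalogue.compounds}
    fps = fingerprint([smiles[i] for i in survivors], model.params, ids=survivors)
    for r in score(model, fps):
        records_by_id[r.id] = r

    # stage 2: top-K by PBS (ties by id, descending score)
    ranked = sorted(survivors,
                    key=lambda i: (-records_by_id[i].pbs_fraction, i))
    quota = config.top_by_pbs
    note = "" if quota <= len(ranked) else "quota exceeds pool; all pass"
    prev, survivors = survivors, ranked[:quota]
    report("top_by_pbs", len(prev), survivors, {"k": quota}, note)

    # stage 3: NBS-mean filter
    prev = survivors
    survivors = nbs_mean_filter(
        [records_by_id[i] for i in prev], config.nbs_filter_direction
    )
    report("nbs_mean_filter", len(prev), survivors,
           {"direction": config.nbs_filter_direction})
    if not survivors:
        return [], reports

    # stage 4: cheapest N
    need(price, survivors, "price")
    ranked = sorted(survivors, key=lambda i: (price[i], i))
    quota = config.n_cheapest
    note = "" if quota <= len(ranked) else "quota exceeds pool; all pass"
    prev, survivors = survivors, ranked[:quota]
    report("cheapest", len(prev), survivors, {"n": quota}, note)

    # stage 5: MaxMin diversity
    prev = survivors
    sub = fps.subset(sorted(prev))
    quota = min(config.n_diverse, len(prev))
    note = "" if config.n_diverse <= len(prev) else "quota exceeds pool; all pass"
    survivors = maxmin_pick(sub, quota, config.seed)
    start_id = survivors[0] if survivors else None
    report("maxmin_diversity", len(prev), survivors,
           {"n": config.n_diverse, "seed": config.seed, "start": start_id}, note)

    # stage 6a: ligand-energy-ratio cut (external column, optional)
    if energy_ratio is not None and config.energy_ratio_cutoff is not None:
        need(energy_ratio, survivors, "energy ratio")
        prev = survivors
        survivors = [i for i in prev
                     if energy_ratio[i] <= config.energy_ratio_cutoff]
        report("energy_ratio", len(prev), survivors,
               {"cutoff": config.energy_ratio_cutoff})
        if not survivors:
            return [], reports

    # stage 6b: lowest-energy top fraction (external column, optional)
    if energy is not None:
        need(energy, survivors, "energy")
        prev = survivors
        quota = max(1, int(len(prev) * config.energy_top_fraction))
        survivors = sorted(prev, key=lambda i: (energy[i], i))[:quota]
        report("energy_top_fraction", len(prev), survivors,
               {"fraction": config.energy_top_fraction})

    # stage 7: final diversity pick
    prev = survivors
    sub = fps.subset(sorted(prev))
    quota = min(config.final_n, len(prev))
    note = "" if config.final_n <= len(prev) else "quota exceeds pool; all pass"
    survivors = maxmin_pick(sub, quota, config.seed)
    report("final_diversity", len(prev), survivors,
           {"n": config.final_n, "seed": config.seed}, note)
    return survivors, reports
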
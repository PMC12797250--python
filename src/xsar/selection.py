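"""Retrospective re-screen selection: log-binned sampling of score gradients.

The picker mirrors a purchase workflow for re-testing compounds in pure
form: (1) drop unavailable compounds; (2) buy everything with a perfect
score (exactly 1); (3) rank the rest by score; (4) split the ranking
into bins whose widths grow geometrically away from the top, so that
sampling is densest at high scores; (5) buy the cheapest compound per
bin, breaking price ties by the score closest to the bin's average and
remaining ties lexicographically by id.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .dataio import DataError
from .scoring import ScoreRecord

WHICH_SCORES = ("pbs", "nbs")


@dataclass(frozen=True)
class Pick:
    id: str
    reason: str  # "score_one" | "bin_pick"
    bin_index: int | None = None
    score: float = float("nan")
    price: float = float("nan")


@dataclass(frozen=True)
class SelectionPlan:
    ensemble: str  # e.g. "lateral:pbs"
    n_bins: int
    picks: tuple[Pick, ...]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.picks]

    @property
    def score_one_ids(self) -> list[str]:
        return [p.id for p in self.picks if p.reason == "score_one"]

    @property
    def bin_pick_ids(self) -> list[str]:
        return [p.id for p in self.picks if p.reason == "bin_pick"]


def log_bin_edges(n: int, n_bins: int) -> list[int]:
    """Contiguous rank cut-points with geometrically growing bin widths.

    Rank 0 is the best score; early (top) bins are narrowest, so the
    sampling density increases towards higher scores.  With fewer
    candidates than bins each candidate forms its own bin.
    """
    if n_bins < 1:
        raise DataError(f"n_bins must be >= 1, got {n_bins}")
    if n <= 0:
        return [0]
    if n <= n_bins:
        return list(range(n + 1))
    raw = np.geomspace(1, n + 1, n_bins + 1)
    edges = [0]
    for i in range(1, n_bins):
        # keep every bin non-empty: stay above the previous edge and
        # leave room for the remaining bins
        e = int(round(raw[i] - 1))
        e = max(edges[-1] + 1, min(e, n - (n_bins - i)))
        edges.append(e)
    edges.append(n)
    return edges


def select_retrospective(
    records: Sequence[ScoreRecord],
    which_score: str,
    availability: Mapping[str, bool],
    price: Mapping[str, float],
    n_bins: int = 25,
    ensemble: str | None = None,
) -> SelectionPlan:
    """Build a purchase plan from scored compounds (see module docstring)."""
    if which_score not in WHICH_SCORES:
        raise DataError(f"which_score must be one of {WHICH_SCORES}")
    if n_bins < 1:
        raise DataError(f"n_bins must be >= 1, got {n_bins}")
    missing = [r.id for r in records if r.id not in availability or r.id not in price]
    if missing:
        raise DataError(f"availability/price undefined for ids {missing[:5]}")
    ensemble = ensemble or f"{records[0].split if records else 'all'}:{which_score}"

    def frac(r: ScoreRecord) -> Fraction:
        return r.pbs_fraction if which_score == "pbs" else r.nbs_fraction

    available = [r for r in records if availability[r.id]]
    if not available:
        return SelectionPlan(ensemble, n_bins, ())

    picks: list[Pick] = []
    perfect = sorted((r for r in available if frac(r) == 1), key=lambda r: r.id)
    for r in perfect:
        picks.append(Pick(r.id, "score_one", None, float(frac(r)), price[r.id]))

    remaining = [r for r in available if frac(r) < 1]
    # descending score; equal scores ordered by id for reproducibility
    remaining.sort(key=lambda r: (-frac(r), r.id))
    edges = log_bin_edges(len(remaining), n_bins)
    for b in range(len(edges) - 1):
        members = remaining[edges[b]: edges[b + 1]]
        if not members:
            continue
        bin_mean = sum(float(frac(r)) for r in members) / len(members)
        best = min(
            members,
            key=lambda r: (price[r.id], abs(float(frac(r)) - bin_mean), r.id),
        )
        picks.append(Pick(best.id, "bin_pick", b, float(frac(best)), price[best.id]))
    return SelectionPlan(ensemble, n_bins, tuple(picks))


def merge_ensembles(plans: Sequence[SelectionPlan]) -> dict[str, list[str]]:
    """Deduplicated purchase list: id → ensembles that selected it.

    Overlap between ensemble selections is why six plans of ~25 collapse
    into a smaller purchase set.
    """
    merged: dict[str, list[str]] = {}
    for plan in plans:
        for pick in plan.picks:
            merged.setdefault(pick.id, [])
            if plan.ensemble not in merged[pick.id]:
                merged[pick.id].append(plan.ensemble)
    return merged
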
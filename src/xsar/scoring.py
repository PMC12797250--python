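"""Per-compound scoring, classification, evaluation and the 2-D landscape.

The two scores are exact rationals:

* PBS(x) = (# CBB bits x activates) / |CBB| — how completely a compound
  recovers the conserved binding bits; PBS = 1 predicts a binder.
* NBS(x) = 1 − (# CNB bits x activates) / |CNB| — how free a compound is
  of conserved non-binding bits; NBS < 1 predicts a non-binder.

Scores are kept as :class:`fractions.Fraction` alongside float views so
that the classification rule (strict equality with 1) never suffers
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import average_precision_score

from .bitmodel import BitCategorization
from .dataio import DataError
from .fingerprints import FingerprintMatrix, tanimoto_matrix


@dataclass(frozen=True)
class ScoreRecord:
    id: str
    split: str
    cbb_hits: int
    cnb_hits: int
    n_cbb: int
    n_cnb: int

    @property
    def pbs_fraction(self) -> Fraction:
        return Fraction(self.cbb_hits, self.n_cbb)

    @property
    def nbs_fraction(self) -> Fraction:
        return 1 - Fraction(self.cnb_hits, self.n_cnb)

    @property
    def pbs(self) -> float:
        return float(self.pbs_fraction)

    @property
    def nbs(self) -> float:
        return float(self.nbs_fraction)


@dataclass(frozen=True)
class Verdict:
    predicted_binder_by_pbs: bool
    predicted_nonbinder_by_nbs: bool


def score(model: BitCategorization, fps: FingerprintMatrix) -> list[ScoreRecord]:
    """Score every fingerprint row against a fitted bit model."""
    if fps.params != model.params:
        raise DataError(
            f"fingerprint params {fps.params} do not match model {model.params}"
        )
    if not model.cbb:
        raise DataError("PBS undefined: the model has an empty CBB set")
    if not model.cnb:
        raise DataError("NBS undefined: the model has an empty CNB set")
    cbb = np.fromiter(sorted(model.cbb), dtype=np.int64)
    cnb = np.fromiter(sorted(model.cnb), dtype=np.int64)
    cbb_hits = fps.bits[:, cbb].sum(axis=1)
    cnb_hits = fps.bits[:, cnb].sum(axis=1)
    return [
        ScoreRecord(cid, model.split, int(b), int(n), len(cbb), len(cnb))
        for cid, b, n in zip(fps.ids, cbb_hits, cnb_hits)
    ]


def classify(record: ScoreRecord) -> Verdict:
    """Exact-equality classification: PBS = 1 → binder; NBS < 1 → non-binder."""
    return Verdict(
        predicted_binder_by_pbs=record.pbs_fraction == 1,
        predicted_nonbinder_by_nbs=record.nbs_fraction < 1,
    )


def scores_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "split": r.split,
            "pbs": r.pbs,
            "nbs": r.nbs,
            "cbb_hits": r.cbb_hits,
            "cnb_hits": r.cnb_hits,
            "n_cbb": r.n_cbb,
            "n_cnb": r.n_cnb,
            "predicted_binder": classify(r).predicted_binder_by_pbs,
            "predicted_nonbinder": classify(r).predicted_nonbinder_by_nbs,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def tanimoto_baselines(
    fps_query: FingerprintMatrix, fps_binders: FingerprintMatrix
) -> pd.DataFrame:
    """Mean and max Tanimoto of each query against all binder fingerprints.

    The classical similarity baselines the bit-conservation scores are
    compared to.
    """
    if len(fps_binders) == 0:
        raise DataError("binder fingerprint set is empty")
    if fps_query.length != fps_binders.length:
        raise DataError("fingerprint length mismatch between query and binders")
    sims = tanimoto_matrix(fps_query.bits, fps_binders.bits)
    return pd.DataFrame(
        {"mean_sim": sims.mean(axis=1), "max_sim": sims.max(axis=1)},
        index=pd.Index(fps_query.ids, name="id"),
    )


@dataclass(frozen=True)
class OutcomeComparison:
    delta: float  # mean(score | positive) − mean(score | negative)
    u_statistic: float
    p_value: float
    method: str


_EXACT_LIMIT = 16  # exhaustive enumeration up to C(16, 8) label assignments


def _u_statistic(values: np.ndarray, mask_pos: np.ndarray) -> float:
    """Mann–Whitney U for the positive group, with 1/2 credit for ties."""
    pos = values[mask_pos][:, None]
    neg = values[~mask_pos][None, :]
    return float((pos > neg).sum() + 0.5 * (pos == neg).sum())


def compare_outcome_scores(
    scores: Sequence[float], outcomes: Sequence[bool]
) -> OutcomeComparison:
    """Two-sided Mann–Whitney U comparison of scores between outcome groups.

    For small samples (combined n ≤ 16) the p-value is computed by
    exhaustive enumeration of all label assignments of the pooled
    values, which is exact even under ties; larger samples use the
    tie-corrected normal approximation.
    """
    values = np.asarray(scores, dtype=float)
    mask = np.asarray(outcomes, dtype=bool)
    if values.shape != mask.shape:
        raise DataError("scores and outcomes differ in length")
    n_pos, n_neg = int(mask.sum()), int((~mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both outcome groups must be non-empty")
    delta = float(values[mask].mean() - values[~mask].mean())
    u_obs = _u_statistic(values, mask)
    n = n_pos + n_neg
    if n <= _EXACT_LIMIT:
        mu = n_pos * n_neg / 2.0
        extreme = 0
        for idx in combinations(range(n), n_pos):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            if abs(_u_statistic(values, m) - mu) >= abs(u_obs - mu) - 1e-12:
                extreme += 1
        p = extreme / comb(n, n_pos)
        method = "exact-enumeration"
    else:
        res = stats.mannwhitneyu(
            values[mask], values[~mask], alternative="two-sided", method="asymptotic"
        )
        p = float(res.pvalue)
        method = "normal-approximation"
    return OutcomeComparison(delta, u_obs, min(p, 1.0), method)


def pr_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision–recall curve (step-function convention).

    Equal scores are grouped into a single operating point, so the value
    matches an exhaustive sweep over distinct thresholds.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise DataError("PR-AUC needs at least one positive and one negative label")
    return float(average_precision_score(y, s))


def landscape(
    fps: FingerprintMatrix, seed: int, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE embedding of the fingerprints under Jaccard distance.

    Diagnostic only: coordinates are reproducible for a fixed seed but
    not comparable across runs or datasets, and no downstream selection
    consumes them.
    """
    n = len(fps)
    if n <= perplexity:
        raise DataError(
            f"t-SNE needs more samples ({n}) than perplexity ({perplexity}); "
            "lower the perplexity for small datasets"
        )
    emb = TSNE(
        n_components=2,
        metric="jaccard",
        perplexity=perplexity,
        random_state=seed,
        init="random",
    ).fit_transform(fps.bits.astype(bool))
    return np.asarray(emb, dtype=float)
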
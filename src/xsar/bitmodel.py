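"""Per-bit conservation scores and the four-way bit categorisation.

Given binders B and non-binders NB, the conservation score of bit m is
S_m = (# binders with bit m active) / |B|.  Each of the M fingerprint
positions then falls in exactly one category:

* CBB — conserved binding bits, active in every binder (S_m = 1),
  regardless of non-binder status;
* CNB — conserved non-binding bits, never active in a binder (S_m = 0)
  but active in at least one non-binder;
* UCB — unconserved bits, active in some but not all binders
  (0 < S_m < 1);
* USB — unsampled bits, active in no compound at all.

Membership is decided with exact integer counts (count == |B| or
count == 0), never with a floating tolerance: S_m is a rational number
and the boundary cases are the whole point of the categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import DataError, LabelledDataset
from .fingerprints import FingerprintMatrix, FingerprintParams, _query_mol
from rdkit import Chem

MODEL_FORMAT_VERSION = 1


class UndefinedModelError(DataError):
    """Raised when |B| = 0: conservation scores are a division by zero."""


@dataclass(frozen=True)
class BitCategorization:
    """The fitted model: conservation vector plus the four disjoint bit sets."""

    split: str
    params: FingerprintParams
    n_binders: int
    n_nonbinders: int
    binder_counts: np.ndarray  # per-bit active-binder counts (exact integers)
    cbb: frozenset[int]
    cnb: frozenset[int]
    ucb: frozenset[int]
    usb: frozenset[int]

    def __post_init__(self):
        M = self.params.length
        sets = (self.cbb, self.cnb, self.ucb, self.usb)
        if sum(len(s) for s in sets) != M:
            raise DataError("bit categories must sum to the fingerprint length")
        if len(frozenset().union(*sets)) != M:
            raise DataError("bit categories must be disjoint and cover all bits")

    @property
    def conservation(self) -> np.ndarray:
        """S_m vector in [0, 1] (float view of the exact counts)."""
        return self.binder_counts / self.n_binders

    def category_of(self, bit: int) -> str:
        for name in ("cbb", "cnb", "ucb", "usb"):
            if bit in getattr(self, name):
                return name
        raise KeyError(bit)


def conservation_scores(
    fps: FingerprintMatrix, dataset: LabelledDataset
) -> np.ndarray:
    """Fraction of binders in which each bit is active (length-M vector)."""
    if dataset.n_binders == 0:
        raise UndefinedModelError(
            "conservation scores are undefined with zero binders"
        )
    counts = fps.rows(sorted(dataset.binder_ids)).sum(axis=0)
    return counts / dataset.n_binders


def categorize_bits(
    fps: FingerprintMatrix, dataset: LabelledDataset
) -> BitCategorization:
    """Fit the bit model: partition all M bits into CBB/CNB/UCB/USB."""
    n_b = dataset.n_binders
    if n_b == 0:
        raise UndefinedModelError("cannot categorize bits with zero binders")
    binder_counts = fps.rows(sorted(dataset.binder_ids)).sum(axis=0).astype(np.int64)
    if dataset.n_nonbinders:
        nonbinder_counts = (
            fps.rows(sorted(dataset.nonbinder_ids)).sum(axis=0).astype(np.int64)
        )
    else:
        nonbinder_counts = np.zeros(fps.length, dtype=np.int64)

    cbb = np.flatnonzero(binder_counts == n_b)
    ucb = np.flatnonzero((binder_counts > 0) & (binder_counts < n_b))
    never_in_binders = binder_counts == 0
    cnb = np.flatnonzero(never_in_binders & (nonbinder_counts > 0))
    usb = np.flatnonzero(never_in_binders & (nonbinder_counts == 0))
    return BitCategorization(
        split=dataset.split,
        params=fps.params,
        n_binders=n_b,
        n_nonbinders=dataset.n_nonbinders,
        binder_counts=binder_counts,
        cbb=frozenset(int(i) for i in cbb),
        cnb=frozenset(int(i) for i in cnb),
        ucb=frozenset(int(i) for i in ucb),
        usb=frozenset(int(i) for i in usb),
    )


def compare_categorizations(
    a: BitCategorization, b: BitCategorization, c: BitCategorization
) -> dict[str, frozenset[int]]:
    """Seven-region Venn partition of three CBB sets.

    Keys: ``a_only``, ``b_only``, ``c_only``, ``ab``, ``ac``, ``bc``
    (pairwise, excluding the triple) and ``abc``.
    """
    for other in (b, c):
        if other.params != a.params:
            raise DataError("categorizations use different fingerprint parameters")
    A, B, C = a.cbb, b.cbb, c.cbb
    abc = A & B & C
    return {
        "abc": abc,
        "ab": (A & B) - abc,
        "ac": (A & C) - abc,
        "bc": (B & C) - abc,
        "a_only": A - B - C,
        "b_only": B - A - C,
        "c_only": C - A - B,
    }


def feature_prevalence_in_bits(
    cat: BitCategorization, provenance: dict[int, str], pattern: str
) -> float:
    """Fraction of CBB whose exemplar environment contains a substructure.

    This is the census behind statements like "90% of the diving CBB
    contain a methylpiperazine": each conserved binding bit is mapped to
    its exemplar atom environment and matched against the query.
    """
    q = _query_mol(pattern)
    uncovered = sorted(bit for bit in cat.cbb if bit not in provenance)
    if uncovered:
        raise DataError(f"no provenance for CBB bits {uncovered}")
    if not cat.cbb:
        raise DataError("CBB is empty; prevalence undefined")
    hits = 0
    for bit in cat.cbb:
        # exemplar environments are molecule fragments and may not fully
        # sanitize (broken valences at the cut bonds); match leniently
        exemplar = Chem.MolFromSmiles(provenance[bit], sanitize=False)
        if exemplar is None:
            continue
        exemplar.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(exemplar)
        if exemplar.HasSubstructMatch(q):
            hits += 1
    return hits / len(cat.cbb)


def to_json(cat: BitCategorization, path: str | Path | None = None) -> str:
    """Serialise a fitted model to versioned JSON (scoring needs no training table).

    The document reserves a ``bit_weights`` field (null for now) so a
    weighted variant can reuse the format.
    """
    doc = {
        "format": "xsar-bit-model",
        "version": MODEL_FORMAT_VERSION,
        "split": cat.split,
        "params": {
            "length": cat.params.length,
            "radius": cat.params.radius,
            "invariants": cat.params.invariants,
        },
        "n_binders": cat.n_binders,
        "n_nonbinders": cat.n_nonbinders,
        "binder_counts": cat.binder_counts.tolist(),
        "cbb": sorted(cat.cbb),
        "cnb": sorted(cat.cnb),
        "ucb": sorted(cat.ucb),
        "usb": sorted(cat.usb),
        "bit_weights": None,
    }
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def from_json(source: str | Path) -> BitCategorization:
    text = str(source)
    if not text.lstrip().startswith("{"):
        text = Path(source).read_text(encoding="utf-8")
    doc = json.loads(text)
    if doc.get("format") != "xsar-bit-model":
        raise DataError("not an xsar bit-model document")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise DataError(f"unsupported model version {doc.get('version')}")
    params = FingerprintParams(**doc["params"])
    return BitCategorization(
        split=doc["split"],
        params=params,
        n_binders=doc["n_binders"],
        n_nonbinders=doc["n_nonbinders"],
        binder_counts=np.asarray(doc["binder_counts"], dtype=np.int64),
        cbb=frozenset(doc["cbb"]),
        cnb=frozenset(doc["cnb"]),
        ucb=frozenset(doc["ucb"]),
        usb=frozenset(doc["usb"]),
    )
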
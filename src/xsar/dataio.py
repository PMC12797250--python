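"""Compound table I/O and pose-split dataset construction.

A dataset is a binary-labelled table of molecules: each row carries an
identifier, a SMILES string, an optional crystallographic outcome
(binder / non-binder) and, for binders, an optional binding-pose label
(``lateral`` or ``diving``).  The pose splits re-interpret the binary
label so that a pose-specific model can be fitted: under the ``lateral``
split, diving binders count as non-binders, and vice versa; the ``all``
split keeps every resolved compound as a binder.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

SPLITS = ("all", "lateral", "diving")
POSES = ("lateral", "diving", "none")

_TRUE_TOKENS = {"1", "true", "binder", "yes"}
_FALSE_TOKENS = {"0", "false", "non-binder", "nonbinder", "non_binder", "no"}


class DataError(ValueError):
    """Base class for dataset-level failures."""


class ConfigError(DataError):
    """A required column or parameter is missing or malformed."""


class DuplicateIdError(DataError):
    pass


class EmptyInputError(DataError):
    pass


class LabellingError(DataError):
    """A binder lacks the pose label a pose split requires."""


@dataclass(frozen=True)
class Compound:
    """One molecule with its label and provenance.

    ``smiles`` is the RDKit-canonical form; the string as read from disk
    is retained in ``original_smiles``.
    """

    id: str
    smiles: str
    outcome: bool | None = None
    pose: str | None = None
    original_smiles: str | None = None
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise DataError("compound id must be non-empty")
        if self.pose is not None and self.pose not in POSES:
            raise DataError(f"unknown pose {self.pose!r} for compound {self.id!r}")


@dataclass(frozen=True)
class Rejection:
    row: int
    id: str | None
    reason: str


@dataclass
class LabelledDataset:
    """An ordered compound collection partitioned into binders and non-binders.

    ``binder_ids`` and ``nonbinder_ids`` are disjoint and together cover
    every labelled compound; compounds with ``outcome=None`` (e.g. a
    screening catalogue) belong to neither set.
    """

    compounds: list[Compound]
    split: str = "all"
    binder_ids: frozenset[str] = None  # type: ignore[assignment]
    nonbinder_ids: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.split not in SPLITS:
            raise DataError(f"split must be one of {SPLITS}, got {self.split!r}")
        ids = [c.id for c in self.compounds]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise DuplicateIdError(f"duplicate compound id {dup!r}")
        if self.binder_ids is None or self.nonbinder_ids is None:
            self.binder_ids = frozenset(
                c.id for c in self.compounds if c.outcome is True
            )
            self.nonbinder_ids = frozenset(
                c.id for c in self.compounds if c.outcome is False
            )
        self.binder_ids = frozenset(self.binder_ids)
        self.nonbinder_ids = frozenset(self.nonbinder_ids)
        if self.binder_ids & self.nonbinder_ids:
            raise DataError("binder and non-binder id sets overlap")
        labelled = {c.id for c in self.compounds if c.outcome is not None}
        if self.binder_ids | self.nonbinder_ids != labelled:
            raise DataError("binder ∪ non-binder ids must cover all labelled ids")

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def n_binders(self) -> int:
        return len(self.binder_ids)

    @property
    def n_nonbinders(self) -> int:
        return len(self.nonbinder_ids)

    def compound(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)


def parse_outcome(value: object) -> bool:
    """Map a cell value to a binary outcome; raises on anything unrecognised."""
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise DataError(f"unrecognised outcome value {value!r}")


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparsable SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class ColumnSchema:
    """Column-name mapping for :func:`read_compound_table`.

    Deposited tables vary in their headers, so the mapping is always
    user-supplied rather than guessed.
    """

    id: str
    smiles: str
    outcome: str | None = None
    pose: str | None = None
    extras: Sequence[str] = ()


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_compound_table(
    path: str | Path,
    schema: ColumnSchema,
    delimiter: str | None = None,
) -> tuple[LabelledDataset, list[Rejection]]:
    """Read a CSV/TSV compound table.

    Invalid SMILES and unrecognised outcome values are rejected row by
    row (returned, never silently dropped); duplicate ids and missing
    mandatory columns abort the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter or _sniff_delimiter(path), dtype=str)
    needed = [schema.id, schema.smiles]
    if schema.outcome:
        needed.append(schema.outcome)
    if schema.pose:
        needed.append(schema.pose)
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ConfigError(f"missing mandatory column(s) {missing} in {path.name}")

    compounds: list[Compound] = []
    rejections: list[Rejection] = []
    seen_ids: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(frame.columns, row))
        cid = str(rec[schema.id]).strip()
        if cid in seen_ids:
            raise DuplicateIdError(f"duplicate compound id {cid!r} at row {row_number}")
        raw_smiles = str(rec[schema.smiles]).strip()
        try:
            smiles = canonical_smiles(raw_smiles)
        except DataError as exc:
            rejections.append(Rejection(row_number, cid, str(exc)))
            continue
        outcome: bool | None = None
        if schema.outcome:
            cell = rec[schema.outcome]
            if pd.notna(cell) and str(cell).strip() != "":
                try:
                    outcome = parse_outcome(cell)
                except DataError as exc:
                    rejections.append(Rejection(row_number, cid, str(exc)))
                    continue
        pose = None
        if schema.pose:
            cell = rec[schema.pose]
            if pd.notna(cell) and str(cell).strip() != "":
                pose = str(cell).strip().lower()
                if pose not in POSES:
                    rejections.append(
                        Rejection(row_number, cid, f"unknown pose {pose!r}")
                    )
                    continue
        extras = {k: rec[k] for k in schema.extras if k in rec}
        seen_ids.add(cid)
        compounds.append(
            Compound(cid, smiles, outcome, pose, original_smiles=raw_smiles,
                     extras=extras)
        )
    if not compounds:
        raise EmptyInputError(f"no valid rows in {path.name}")
    if rejections:
        log.warning("%d row(s) rejected reading %s", len(rejections), path.name)
    return LabelledDataset(compounds), rejections


def read_sdf(path: str | Path, id_prop: str | None = None) -> LabelledDataset:
    """Read compounds from an SDF file; SMILES derived from the structure block."""
    supplier = Chem.SDMolSupplier(str(path))
    compounds = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        if id_prop and mol.HasProp(id_prop):
            cid = mol.GetProp(id_prop)
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            cid = mol.GetProp("_Name")
        else:
            cid = f"SDF{i}"
        compounds.append(Compound(cid, Chem.MolToSmiles(mol)))
    if not compounds:
        raise EmptyInputError(f"no valid molecules in {path}")
    return LabelledDataset(compounds)


def write_compound_table(dataset: LabelledDataset, path: str | Path) -> None:
    rows = []
    for c in dataset.compounds:
        rows.append(
            {
                "id": c.id,
                "smiles": c.smiles,
                "outcome": "" if c.outcome is None else int(c.outcome),
                "pose": c.pose or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def make_pose_split(dataset: LabelledDataset, split: str) -> LabelledDataset:
    """Re-label a dataset for a pose-specific model.

    Binders carrying the other pose are counted as non-binders; the
    ``all`` split counts any resolved pose as binder.  The compound list
    (and the original outcome/pose fields) is unchanged — only the
    binder/non-binder partition moves.
    """
    split = split.lower()
    if split not in SPLITS:
        raise DataError(f"split must be one of {SPLITS}, got {split!r}")
    if split == "all":
        return LabelledDataset(
            list(dataset.compounds),
            split="all",
            binder_ids=dataset.binder_ids,
            nonbinder_ids=dataset.nonbinder_ids,
        )
    binders, nonbinders = set(), set(dataset.nonbinder_ids)
    for c in dataset.compounds:
        if c.id not in dataset.binder_ids:
            continue
        if c.pose not in ("lateral", "diving"):
            raise LabellingError(
                f"binder {c.id!r} lacks a pose label required for split {split!r}"
            )
        if c.pose == split:
            binders.add(c.id)
        else:
            nonbinders.add(c.id)
    return LabelledDataset(
        list(dataset.compounds),
        split=split,
        binder_ids=frozenset(binders),
        nonbinder_ids=frozenset(nonbinders),
    )


def subset(dataset: LabelledDataset, ids: Iterable[str]) -> LabelledDataset:
    """Restrict a dataset to ``ids``, preserving order and labels."""
    keep = set(ids)
    compounds = [c for c in dataset.compounds if c.id in keep]
    return LabelledDataset(
        compounds,
        split=dataset.split,
        binder_ids=dataset.binder_ids & keep,
        nonbinder_ids=dataset.nonbinder_ids & keep,
    )


def relabel(dataset: LabelledDataset, outcomes: Mapping[str, bool]) -> LabelledDataset:
    """Return a copy with outcomes overridden for the given ids."""
    compounds = [
        replace(c, outcome=outcomes[c.id]) if c.id in outcomes else c
        for c in dataset.compounds
    ]
    return LabelledDataset(compounds, split=dataset.split)
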
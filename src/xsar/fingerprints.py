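"""Morgan fingerprints, similarity, substructure census and Rule-of-Five.

The whole bit-conservation method operates on hashed circular (Morgan)
fingerprints: length 2048, radius 6, feature-based atom invariants by
default (connectivity invariants available via ``invariants``).  Bits
are strictly binary — presence/absence of a local atom–bond
environment; counts are never used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator

from .dataio import DataError, LabelledDataset

log = logging.getLogger(__name__)

INVARIANT_MODES = ("feature", "connectivity")


@dataclass(frozen=True)
class FingerprintParams:
    length: int = 2048
    radius: int = 6
    invariants: str = "feature"

    def __post_init__(self):
        if self.invariants not in INVARIANT_MODES:
            raise DataError(
                f"invariants must be one of {INVARIANT_MODES}, got {self.invariants!r}"
            )
        if self.length < 1 or self.radius < 0:
            raise DataError("fingerprint length must be >=1 and radius >=0")


def _generator(params: FingerprintParams):
    inv = (
        rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        if params.invariants == "feature"
        else None
    )
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=params.radius, fpSize=params.length, atomInvariantsGenerator=inv
    )


@dataclass
class FingerprintMatrix:
    """n × M binary matrix, rows in dataset order."""

    ids: list[str]
    bits: np.ndarray
    params: FingerprintParams = field(default_factory=FingerprintParams)

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape != (len(self.ids), self.params.length):
            raise DataError(
                f"bit matrix shape {self.bits.shape} does not match "
                f"{len(self.ids)} ids × length {self.params.length}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise DataError("fingerprint entries must be binary")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self.params.length

    def row(self, cid: str) -> np.ndarray:
        return self.bits[self.ids.index(cid)]

    def rows(self, ids: Iterable[str]) -> np.ndarray:
        index = {cid: i for i, cid in enumerate(self.ids)}
        return self.bits[[index[cid] for cid in ids]]

    def subset(self, ids: Sequence[str]) -> "FingerprintMatrix":
        return FingerprintMatrix(list(ids), self.rows(ids), self.params)


def _mol(smiles: str, cid: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for compound {cid!r}" if cid else ""
        raise DataError(f"unparsable SMILES {smiles!r}{who}")
    return mol


def fingerprint(
    dataset: LabelledDataset | Sequence[str],
    params: FingerprintParams | None = None,
    ids: Sequence[str] | None = None,
) -> FingerprintMatrix:
    """Fingerprint a dataset (or a bare SMILES sequence) into a binary matrix."""
    params = params or FingerprintParams()
    if isinstance(dataset, LabelledDataset):
        pairs = [(c.id, c.smiles) for c in dataset.compounds]
    else:
        smiles_list = list(dataset)
        ids = list(ids) if ids is not None else [str(i) for i in range(len(smiles_list))]
        pairs = list(zip(ids, smiles_list))
    gen = _generator(params)
    bits = np.zeros((len(pairs), params.length), dtype=np.uint8)
    for i, (cid, smiles) in enumerate(pairs):
        fp = gen.GetFingerprint(_mol(smiles, cid))
        arr = np.zeros(params.length, dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(fp, arr)
        bits[i] = arr
    return FingerprintMatrix([p[0] for p in pairs], bits, params)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two binary rows.

    Two all-zero rows are identical objects and score 1 (logged, since
    0/0 would otherwise be undefined).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise DataError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        log.debug("tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def tanimoto_matrix(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto, query rows × reference rows (vectorised)."""
    q = np.asarray(query, dtype=np.int32)
    r = np.asarray(reference, dtype=np.int32)
    inter = q @ r.T
    union = q.sum(axis=1)[:, None] + r.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return sim


def _query_mol(pattern: str) -> Chem.Mol:
    q = Chem.MolFromSmarts(pattern)
    if q is None or q.GetNumAtoms() == 0:
        raise DataError(f"invalid substructure pattern {pattern!r}")
    return q


def substructure_count(
    dataset: LabelledDataset, pattern: str
) -> tuple[pd.Series, int]:
    """Per-compound subgraph-containment flag for a SMARTS pattern, plus total."""
    q = _query_mol(pattern)
    flags = {
        c.id: _mol(c.smiles, c.id).HasSubstructMatch(q) for c in dataset.compounds
    }
    series = pd.Series(flags, name=pattern)
    return series, int(series.sum())


@dataclass(frozen=True)
class Ro5Result:
    mw: float
    logp: float
    hbd: int
    hba: int
    violations: int
    violates: bool


def rule_of_five(smiles: str, min_failures: int = 1) -> Ro5Result:
    """Lipinski Rule-of-Five check.

    ``violates`` is true when at least ``min_failures`` of the four
    criteria fail (MW > 500, logP > 5, HBD > 5, HBA > 10).  The default
    of 1 treats any single failure as a violation; the classic >=2
    reading is available via ``min_failures=2``.
    """
    mol = _mol(smiles)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    hbd = Lipinski.NumHDonors(mol)
    hba = Lipinski.NumHAcceptors(mol)
    violations = sum([mw > 500, logp > 5, hbd > 5, hba > 10])
    return Ro5Result(mw, logp, hbd, hba, violations, violations >= min_failures)


def heavy_atom_count(smiles: str) -> int:
    return _mol(smiles).GetNumHeavyAtoms()


def bit_provenance(
    dataset: LabelledDataset, params: FingerprintParams | None = None
) -> dict[int, str]:
    """Map each active bit index to one exemplar atom-environment SMILES.

    Hashed bits may collide; the exemplar recorded is the first
    environment encountered that sets the bit, which is what the
    interpretability figures depict.
    """
    params = params or FingerprintParams()
    gen = _generator(params)
    provenance: dict[int, str] = {}
    for c in dataset.compounds:
        mol = _mol(c.smiles, c.id)
        out = rdFingerprintGenerator.AdditionalOutput()
        out.AllocateBitInfoMap()
        gen.GetFingerprint(mol, additionalOutput=out)
        for bit, envs in out.GetBitInfoMap().items():
            if bit in provenance:
                continue
            atom, radius = envs[0]
            if radius == 0:
                provenance[bit] = Chem.MolFragmentToSmiles(mol, atomsToUse=[atom])
            else:
                env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
                sub = Chem.PathToSubmol(mol, env)
                provenance[bit] = Chem.MolToSmiles(sub)
    return provenance


def save_matrix(fps: FingerprintMatrix, path: str | Path) -> None:
    """Persist as sparse text: header line with params, then ``id<TAB>i1,i2,...``."""
    with open(path, "w", encoding="utf-8") as fh:
        p = fps.params
        fh.write(f"#xsar-fingerprints\tlength={p.length}\tradius={p.radius}\t"
                 f"invariants={p.invariants}\n")
        for cid, row in zip(fps.ids, fps.bits):
            active = ",".join(str(i) for i in np.flatnonzero(row))
            fh.write(f"{cid}\t{active}\n")


def load_matrix(path: str | Path) -> FingerprintMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "#xsar-fingerprints":
            raise DataError(f"{path} is not a fingerprint matrix file")
        kv = dict(item.split("=", 1) for item in header[1:])
        params = FingerprintParams(
            length=int(kv["length"]), radius=int(kv["radius"]),
            invariants=kv["invariants"],
        )
        ids, rows = [], []
        for line in fh:
            cid, _, active = line.rstrip("\n").partition("\t")
            row = np.zeros(params.length, dtype=np.uint8)
            if active:
                row[[int(i) for i in active.split(",")]] = 1
            ids.append(cid)
            rows.append(row)
    return FingerprintMatrix(ids, np.array(rows, dtype=np.uint8), params)
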
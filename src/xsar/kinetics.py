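"""Post-processing of pulsed-kinetics (GCI/SPR-style) readouts.

Inputs are per-compound association and dissociation rates with the
instrument's percentage errors and the maximum observed binding signal
(R_max).  The module derives K_D = k_d / k_a with a root-sum-square
propagated error, calls hits under stringent error/signal criteria,
computes ligand efficiency, and relates fitted to theoretical R_max for
a 1:1 surface interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .dataio import DataError
from .fingerprints import heavy_atom_count

ERROR_UNITS = ("percent", "fraction")


@dataclass(frozen=True)
class KineticConstants:
    """Gas constant in kcal/(mol K) and assay temperature in kelvin."""

    gas_constant: float = 1.987e-3
    temperature: float = 298.0


@dataclass(frozen=True)
class KineticRecord:
    """One compound's fitted kinetics.

    ``delta_ka``/``delta_kd`` are stored as fractions (0.10 = 10%);
    :func:`read_kinetics_table` converts from the instrument's percent
    export.
    """

    id: str
    ka: float  # association rate, M^-1 s^-1
    kd: float  # dissociation rate, s^-1
    delta_ka: float
    delta_kd: float
    rmax: float | None = None  # fitted maximum signal, pg mm^-2
    heavy_atoms: int | None = None
    smiles: str | None = None

    def __post_init__(self):
        if self.ka <= 0 or self.kd <= 0:
            raise DataError(f"{self.id}: rates must be positive")
        if self.delta_ka < 0 or self.delta_kd < 0:
            raise DataError(f"{self.id}: errors must be non-negative")


def kd_with_error(record: KineticRecord) -> tuple[float, float]:
    """K_D = k_d / k_a (M) with root-sum-square propagated relative error."""
    k_D = record.kd / record.ka
    err = k_D * math.sqrt(record.delta_ka**2 + record.delta_kd**2)
    return k_D, err


def call_hits(records: Sequence[KineticRecord]) -> list[bool]:
    """Stringent hit calling: both relative errors < 25% and R_max > 10.

    All three inequalities are strict, so a record sitting exactly on a
    boundary is not a hit.
    """
    verdicts = []
    for r in records:
        if r.rmax is None:
            raise DataError(f"{r.id}: R_max required for hit calling")
        verdicts.append(r.delta_ka < 0.25 and r.delta_kd < 0.25 and r.rmax > 10)
    return verdicts


def ligand_efficiency(
    k_D: float, heavy_atoms: int, constants: KineticConstants = KineticConstants()
) -> float:
    """LE = −R·T·ln(K_D) / N in kcal/(mol × heavy atom)."""
    if k_D <= 0:
        raise DataError("K_D must be positive")
    if heavy_atoms < 1:
        raise DataError("heavy-atom count must be >= 1")
    return (
        -constants.gas_constant * constants.temperature * math.log(k_D) / heavy_atoms
    )


def theoretical_rmax(
    immobilised_mass: float, mw_protein: float, mw_analyte: float
) -> float:
    """Expected R_max for an ideal 1:1 interaction (pg mm^-2).

    The surface-mass relation: immobilised receptor mass scaled by the
    analyte/receptor molecular-weight ratio.
    """
    if immobilised_mass <= 0 or mw_protein <= 0 or mw_analyte <= 0:
        raise DataError("all R_max arguments must be positive")
    return immobilised_mass * mw_analyte / mw_protein


def percent_occupancy(fitted_rmax: float, theoretical: float) -> float:
    """Fraction of the theoretical surface capacity the fit reaches."""
    if theoretical <= 0:
        raise DataError("theoretical R_max must be positive")
    return fitted_rmax / theoretical


def read_kinetics_table(
    path: str | Path, error_unit: str = "percent"
) -> list[KineticRecord]:
    """Read a kinetics CSV (columns: id, ka, kd, delta_ka, delta_kd,
    optional rmax, heavy_atoms, smiles).

    ``error_unit`` declares how the error columns are expressed; the
    default matches the instrument's percent export.  Being explicit
    here matters: a silent percent/fraction mix-up scales every derived
    K_D error by 100.
    """
    if error_unit not in ERROR_UNITS:
        raise DataError(f"error_unit must be one of {ERROR_UNITS}")
    frame = pd.read_csv(path)
    required = {"id", "ka", "kd", "delta_ka", "delta_kd"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"kinetics table missing column(s) {sorted(missing)}")
    scale = 0.01 if error_unit == "percent" else 1.0
    records = []
    for row in frame.itertuples(index=False):
        rec = row._asdict()
        records.append(
            KineticRecord(
                id=str(rec["id"]),
                ka=float(rec["ka"]),
                kd=float(rec["kd"]),
                delta_ka=float(rec["delta_ka"]) * scale,
                delta_kd=float(rec["delta_kd"]) * scale,
                rmax=float(rec["rmax"]) if "rmax" in rec and pd.notna(rec["rmax"]) else None,
                heavy_atoms=int(rec["heavy_atoms"])
                if "heavy_atoms" in rec and pd.notna(rec["heavy_atoms"])
                else None,
                smiles=str(rec["smiles"])
                if "smiles" in rec and pd.notna(rec["smiles"])
                else None,
            )
        )
    return records


def process_records(
    records: Sequence[KineticRecord],
    constants: KineticConstants = KineticConstants(),
    immobilised_mass: float | None = None,
    mw_protein: float | None = None,
) -> pd.DataFrame:
    """Derive K_D ± error, hit calls and ligand efficiency for a batch.

    Heavy-atom counts are taken from the record or, failing that,
    computed from the SMILES (non-hydrogen atoms).
    """
    rows = []
    hits = call_hits(records) if all(r.rmax is not None for r in records) else None
    for i, r in enumerate(records):
        if r.heavy_atoms is None and r.smiles is not None:
            r = replace(r, heavy_atoms=heavy_atom_count(r.smiles))
        k_D, k_D_err = kd_with_error(r)
        le = (
            ligand_efficiency(k_D, r.heavy_atoms, constants)
            if r.heavy_atoms
            else None
        )
        row = {
            "id": r.id,
            "ka": r.ka,
            "kd": r.kd,
            "KD": k_D,
            "KD_err": k_D_err,
            "rmax": r.rmax,
            "heavy_atoms": r.heavy_atoms,
            "ligand_efficiency": le,
            "hit": hits[i] if hits is not None else None,
        }
        if immobilised_mass and mw_protein and r.smiles:
            from rdkit import Chem
            from rdkit.Chem import Descriptors

            mw = Descriptors.MolWt(Chem.MolFromSmiles(r.smiles))
            theo = theoretical_rmax(immobilised_mass, mw_protein, mw)
            row["theoretical_rmax"] = theo
            if r.rmax is not None:
                row["occupancy"] = percent_occupancy(r.rmax, theo)
        rows.append(row)
    return pd.DataFrame(rows)
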
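"""Post-processing of quantum-chemistry scalar tables.

The upstream electronic-structure calculations (geometry optimization,
orbital energies, Mulliken charges, counterpoise corrections) are treated
purely as data producers.  This module ingests their scalar outputs and
computes every closed-form derived quantity of the analysis: BSSE-corrected
binding energies, transition-state-theory recovery times, frontier-orbital
gaps and their relative changes on functionalization/adsorption, orbital
donation gaps, and bond-length change percentages.

Energies are in kcal/mol unless noted.  Orbital energies are kept in the
units in which they were tabulated ("printed units"): every derived orbital
quantity here is a difference or a ratio, so no unit conversion is ever
required or applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "QMRecord",
    "RecoveryParams",
    "GAS_CONSTANT_KCAL",
    "load_qm_records",
    "binding_energy",
    "recovery_time",
    "format_duration",
    "homo_lumo_gap",
    "band_gap_change_percent",
    "donation_gaps",
    "bond_change_percent",
    "recovery_table",
]

#: Molar gas constant in kcal mol^-1 K^-1 (3-significant-figure convention,
#: the value that reproduces the published recovery-time tables).
GAS_CONSTANT_KCAL = 1.987e-3

_SECONDS = {"day": 86400.0, "h": 3600.0, "s": 1.0, "ms": 1e-3}


@dataclass(frozen=True)
class QMRecord:
    """Scalar quantum-chemistry results for one chemical species."""

    species_id: str
    total_energy: float | None = None
    homo: float | None = None
    lumo: float | None = None
    dipole: float | None = None
    binding_energy: float | None = None
    bond_lengths: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.homo is not None and self.lumo is not None:
            if self.lumo < self.homo:
                raise ValueError(
                    f"{self.species_id}: LUMO ({self.lumo}) below HOMO ({self.homo})"
                )
        for bond, length in self.bond_lengths.items():
            if not length > 0:
                raise ValueError(f"{self.species_id}: bond {bond} has non-positive length")


@dataclass(frozen=True)
class RecoveryParams:
    """Conditions for the transition-state-theory desorption time.

    temperature
        Kelvin.
    attempt_frequency
        Prefactor nu0 in Hz; the light/phonon frequency driving desorption.
    gas_constant
        Boltzmann constant on a molar energy scale, kcal mol^-1 K^-1,
        because adsorption energies are tabulated per mole.
    """

    temperature: float = 298.0
    attempt_frequency: float = 1e12
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not self.attempt_frequency > 0:
            raise ValueError("attempt frequency must be positive")
        if not self.gas_constant > 0:
            raise ValueError("gas constant must be positive")


def _normalize_number(text: object) -> float:
    """Parse a table scalar, tolerating unicode minus signs and stray space."""
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip().replace("−", "-").replace("–", "-")
    s = s.replace("- ", "-").replace(" ", "")
    return float(s)


def load_qm_records(path: str | Path) -> dict[str, QMRecord]:
    """Read a delimited table of per-species QM scalars.

    The file must have a header row including ``species_id`` (or ``species``)
    plus at least one scalar column.  Bond-length columns are identified by
    bracketed names such as ``[O2-H3]``.  Missing optional values stay absent
    (``None``), never silently zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    frame.columns = [c.strip() for c in frame.columns]
    if "species_id" not in frame.columns and "species" in frame.columns:
        frame = frame.rename(columns={"species": "species_id"})
    if "species_id" not in frame.columns:
        raise ValueError(f"{path}: no species_id column")
    if len(frame) == 0:
        raise ValueError(f"{path}: no records")
    if len(frame.columns) < 2:
        raise ValueError(f"{path}: species_id present but no scalar columns")

    scalar_cols = {
        "total_energy": "total_energy",
        "homo": "homo",
        "lumo": "lumo",
        "dipole": "dipole",
        "dipole_debye": "dipole",
        "binding_energy": "binding_energy",
    }
    records: dict[str, QMRecord] = {}
    for row_idx, row in frame.iterrows():
        species = str(row["species_id"]).strip()
        if species in records:
            raise ValueError(f"{path}: duplicate species_id {species!r}")
        kwargs: dict = {}
        bonds: dict[str, float] = {}
        for col in frame.columns:
            if col == "species_id":
                continue
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            if isinstance(raw, str) and raw.strip() == "":
                continue
            try:
                value = _normalize_number(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} in row {row_idx} column {col!r}"
                ) from exc
            if col in scalar_cols:
                kwargs[scalar_cols[col]] = value
            elif col.startswith("[") and col.endswith("]"):
                bonds[col] = value
            # other columns (printed reference values etc.) are ignored here
        records[species] = QMRecord(species_id=species, bond_lengths=bonds, **kwargs)
    return records


def binding_energy(
    e_complex: float, e_drug: float, e_carrier: float, bsse: float = 0.0
) -> float:
    """Counterpoise-corrected complexation energy.

    E_b = E(complex) - [E(drug) + E(carrier)] + BSSE, all in kcal/mol.
    Negative values mean favourable adsorption.
    """
    for name, v in (("e_complex", e_complex), ("e_drug", e_drug),
                    ("e_carrier", e_carrier), ("bsse", bsse)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite")
    return e_complex - (e_drug + e_carrier) + bsse


def recovery_time(e_b: float, params: RecoveryParams = RecoveryParams()) -> float:
    """Transition-state-theory desorption (recovery) time in seconds.

    tau = nu0^-1 * exp(|E_b| / (R T)).  The adsorption energy ``e_b`` must be
    negative (bound state); the magnitude enters the Boltzmann factor, so a
    more strongly bound drug takes exponentially longer to release.
    """
    if not math.isfinite(e_b):
        raise ValueError("binding energy must be finite")
    if e_b > 0:
        raise ValueError("adsorption energy must be <= 0 (bound-state convention)")
    rt = params.gas_constant * params.temperature
    return math.exp(abs(e_b) / rt) / params.attempt_frequency


def format_duration(seconds: float) -> str:
    """Render a time in the mixed units of the desorption table.

    Days are used from 10 days up; otherwise the largest of h/s/ms giving a
    mantissa of at least 0.1; the value is rounded to one decimal.
    """
    if seconds < 0:
        raise ValueError("duration must be non-negative")
    if seconds >= 10 * _SECONDS["day"]:
        unit = "day"
    elif seconds >= 0.1 * _SECONDS["h"]:
        unit = "h"
    elif seconds >= 0.1:
        unit = "s"
    else:
        unit = "ms"
    return f"{seconds / _SECONDS[unit]:.1f} {unit}"


def homo_lumo_gap(record: QMRecord) -> float:
    """Frontier-orbital gap Eg = LUMO - HOMO, in the tabulated units."""
    if record.homo is None or record.lumo is None:
        raise ValueError(f"{record.species_id}: missing orbital energy")
    return record.lumo - record.homo


def band_gap_change_percent(record: QMRecord, reference: QMRecord) -> float:
    """Signed percent change of the frontier gap relative to a reference."""
    gap = homo_lumo_gap(record)
    ref_gap = homo_lumo_gap(reference)
    if ref_gap == 0:
        raise ValueError(f"{reference.species_id}: zero reference gap")
    return 100.0 * (gap - ref_gap) / ref_gap


def donation_gaps(drug: QMRecord, carrier: QMRecord) -> tuple[float, float]:
    """Forward and backward charge-donation gaps between two species.

    forward  = |HOMO(drug)  - LUMO(carrier)|  (drug donates)
    backward = |HOMO(carrier) - LUMO(drug)|   (carrier donates)

    The smaller gap marks the dominant donation direction.
    """
    for rec in (drug, carrier):
        if rec.homo is None or rec.lumo is None:
            raise ValueError(f"{rec.species_id}: missing orbital energy")
    forward = abs(drug.homo - carrier.lumo)
    backward = abs(carrier.homo - drug.lumo)
    return forward, backward


def bond_change_percent(length_before: float, length_after: float) -> float:
    """Signed percent change of a bond length on complexation."""
    if not (length_before > 0 and length_after > 0):
        raise ValueError("bond lengths must be positive")
    return 100.0 * (length_after - length_before) / length_before


def recovery_table(
    binding_energies: Mapping[str, float],
    attempt_frequencies: tuple[float, ...] = (1e12, 1e13, 1e14),
    temperature: float = 298.0,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> pd.DataFrame:
    """Desorption times for each species at several attempt frequencies.

    Returns a tidy frame with columns species, nu_hz, seconds, label.
    """
    rows = []
    for species, e_b in binding_energies.items():
        for nu in attempt_frequencies:
            params = RecoveryParams(temperature, nu, gas_constant)
            tau = recovery_time(e_b, params)
            rows.append(
                {"species": species, "nu_hz": nu, "seconds": tau,
                 "label": format_duration(tau)}
            )
    return pd.DataFrame(rows)
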
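"""Solubility data model, measurement-equation conversions, and I/O.

A solubility record couples the state (T, P) with three measured quantities:
the solute mole fraction y, the solvent density rho (g/L) and the solubility
S (g/L).  The three are redundant — y can be recomputed from (S, rho) and the
two molar masses — and that redundancy is the dataset's integrity check.

The 27-point vitamin A (retinol) / supercritical CO2 dataset spanning
303.15-323.15 K and 90-245 bar ships with the package and is addressable as
``"bundled:table2"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import pandas as pd

from .errors import DomainError, FormatError, ValidationError

#: Molar masses, g/mol.  The solute value is for retinol (C20H30O).
M_RETINOL = 286.45
M_CO2 = 44.01

#: Relative tolerance for the stored-vs-recomputed mole-fraction check;
#: sized for values printed to 3 significant figures.
CONSISTENCY_RTOL = 0.015

_CSV_COLUMNS = ("T_K", "P_bar", "y", "rho_gL", "S_gL")
_BUNDLED = {"bundled:table2": "table2_vitamin_a_scco2.csv"}


# ---------------------------------------------------------------------------
# Measurement equations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementContext:
    """Raw sampling quantities from which y and S are derived.

    C_A — solute concentration in the accumulation vial (g/L);
    V_A — accumulation-vial volume (L); V_l — sampling-circuit volume (L);
    M_A, M_C — solute and solvent molar masses (g/mol); rho — solvent
    density in the circuit (g/L).
    """

    C_A: float
    V_A: float
    V_l: float
    M_A: float
    M_C: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("C_A", "V_A", "V_l", "M_A", "M_C", "rho"):
            if getattr(self, name) <= 0:
                raise DomainError(f"MeasurementContext.{name} must be positive")


def mole_fraction_from_concentration(ctx: MeasurementContext) -> float:
    """y = n_A / (n_A + n_C) with n_A = C_A V_A / M_A, n_C = V_l rho / M_C."""
    n_A = ctx.C_A * ctx.V_A / ctx.M_A
    n_C = ctx.V_l * ctx.rho / ctx.M_C
    return n_A / (n_A + n_C)


def solubility_from_concentration(C_A: float, V_A: float, V_l: float) -> float:
    """S (g/L) = C_A * V_A / V_l."""
    if C_A < 0 or V_A <= 0 or V_l <= 0:
        raise DomainError("C_A must be >= 0 and volumes positive")
    return C_A * V_A / V_l


def mole_fraction_from_solubility(S: float, rho: float,
                                  M_A: float = M_RETINOL,
                                  M_C: float = M_CO2) -> float:
    """y from the solubility S and solvent density rho (both g/L).

    Algebraic elimination of the vial quantities gives
    y = (S/M_A) / (S/M_A + rho/M_C).
    """
    if S <= 0 or rho <= 0 or M_A <= 0 or M_C <= 0:
        raise DomainError("S, rho, M_A, M_C must be positive")
    nA = S / M_A
    nC = rho / M_C
    return nA / (nA + nC)


def solubility_from_mole_fraction(y: float, rho: float,
                                  M_A: float = M_RETINOL,
                                  M_C: float = M_CO2) -> float:
    """Inverse of :func:`mole_fraction_from_solubility`."""
    if not 0 < y < 1:
        raise DomainError("y must lie in (0, 1)")
    if rho <= 0:
        raise DomainError("rho must be positive")
    return M_A * rho * y / ((1.0 - y) * M_C)


# ---------------------------------------------------------------------------
# Records and dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentalPoint:
    """One (T, P, y, rho, S) solubility record."""

    T: float        # K
    P: float        # bar
    y: float        # mole fraction
    rho: float      # g/L
    S: float        # g/L

    def __post_init__(self) -> None:
        if self.T <= 0 or self.P <= 0 or self.rho <= 0:
            raise ValidationError("T, P, rho must be positive")
        if not 0 < self.y < 1:
            raise ValidationError(f"0 < y < 1 violated (y={self.y})")
        if self.S <= 0:
            raise ValidationError("S must be positive")

    def recomputed_y(self, M_A: float = M_RETINOL, M_C: float = M_CO2) -> float:
        return mole_fraction_from_solubility(self.S, self.rho, M_A, M_C)


@dataclass(frozen=True)
class SolubilityDataset:
    """Ordered collection of solubility records for one solute/solvent pair."""

    points: tuple[ExperimentalPoint, ...]
    solute_id: str = "retinol"
    solvent_id: str = "CO2"

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[ExperimentalPoint]:
        return iter(self.points)

    def temperatures(self) -> tuple[float, ...]:
        seen: list[float] = []
        for p in self.points:
            if p.T not in seen:
                seen.append(p.T)
        return tuple(sorted(seen))

    def isotherm(self, T: float, atol: float = 1e-9) -> "SolubilityDataset":
        pts = tuple(p for p in self.points if abs(p.T - T) <= atol)
        return SolubilityDataset(pts, self.solute_id, self.solvent_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T_K": [p.T for p in self.points],
             "P_bar": [p.P for p in self.points],
             "y": [p.y for p in self.points],
             "rho_gL": [p.rho for p in self.points],
             "S_gL": [p.S for p in self.points]})

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def _dataset_from_frame(df: pd.DataFrame, solute_id: str,
                        solvent_id: str) -> SolubilityDataset:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {missing}")
    bad_rows: list[str] = []
    for col in _CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        nan_idx = df.index[coerced.isna()].tolist()
        if nan_idx:
            raise FormatError(
                f"non-numeric value in column {col!r} at row(s) {nan_idx}")
        df[col] = coerced
    df = df.sort_values(["T_K", "P_bar"], kind="mergesort").reset_index(drop=True)
    points = []
    for idx, row in df.iterrows():
        try:
            points.append(ExperimentalPoint(
                T=row.T_K, P=row.P_bar, y=row.y, rho=row.rho_gL, S=row.S_gL))
        except ValidationError as exc:
            bad_rows.append(f"row {idx}: {exc}")
    if bad_rows:
        raise ValidationError("invalid record(s): " + "; ".join(bad_rows))
    ds = SolubilityDataset(tuple(points), solute_id, solvent_id)
    for T in ds.temperatures():
        if len(ds.isotherm(T)) < 3:
            raise ValidationError(
                f"isotherm at {T} K has fewer than 3 points")
    return ds


def load_dataset(source: str, solute_id: str = "retinol",
                 solvent_id: str = "CO2") -> SolubilityDataset:
    """Read a solubility dataset from a CSV path or a ``bundled:`` name.

    The CSV schema is the five columns T_K, P_bar, y, rho_gL, S_gL with a
    mandatory header, comma separators and period decimals.
    """
    if source in _BUNDLED:
        with resources.files("scfsol.data").joinpath(_BUNDLED[source]).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    return _dataset_from_frame(df, solute_id, solvent_id)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    """Per-row stored-vs-recomputed mole-fraction deviations."""

    rows: tuple[dict, ...]
    max_rel_dev: float
    n_flagged: int

    def to_json(self) -> str:
        return json.dumps({"rows": list(self.rows),
                           "max_rel_dev": self.max_rel_dev,
                           "n_flagged": self.n_flagged}, indent=2)


def validate_dataset(ds: SolubilityDataset, M_A: float = M_RETINOL,
                     M_C: float = M_CO2,
                     rtol: float = CONSISTENCY_RTOL) -> ValidationReport:
    """Cross-check every stored y against the value implied by (S, rho).

    Report-only: rows whose relative deviation exceeds ``rtol`` are flagged,
    never altered.  A single non-monotonic y step inside an isotherm is a
    legitimate experimental feature and is not flagged.
    """
    rows = []
    for idx, p in enumerate(ds.points):
        rel = abs(p.recomputed_y(M_A, M_C) - p.y) / p.y
        rows.append({"index": idx, "T_K": p.T, "P_bar": p.P,
                     "rel_dev": rel, "flagged": bool(rel > rtol)})
    max_dev = max((r["rel_dev"] for r in rows), default=0.0)
    return ValidationReport(tuple(rows), max_dev,
                            sum(r["flagged"] for r in rows))
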
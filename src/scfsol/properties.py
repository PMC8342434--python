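"""Pure-component properties.

Component records (critical constants, acentric factor, solid molar volume,
fusion/vaporization data), Joback group-contribution estimation for solutes
whose critical properties were never measured, and sublimation-pressure
models: the constant-enthalpy Clausius–Clapeyron extrapolation from the
triple point and an extended-Antoine (Yaws-type) vapor-pressure correlation.

Units at every public interface: temperature K, pressure bar, molar mass
g/mol, molar volume cm^3/mol, enthalpy J/mol.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, DomainError, UnderdeterminedError

logger = logging.getLogger("scfsol")

#: Gas constant, J/(mol K).
R_J = 8.31446
#: Gas constant, cm^3 bar / (mol K) — the unit system of the EOS layer.
R_CM3_BAR = 83.1446
#: 1 atm in bar (Lee–Kesler works in atm).
ATM_BAR = 1.01325


# ---------------------------------------------------------------------------
# Component records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """Pure-species constants used by the EOS and equilibrium layers.

    ``Vs`` (solid molar volume) is required only for solid solutes, where it
    enters the Poynting correction.  ``kappa1`` is the Stryjek–Vera
    component-specific parameter; zero reduces the SV alpha to its
    ``kappa0``-only form.
    """

    name: str
    M: float                       # g/mol
    Tc: float                      # K
    Pc: float                      # bar
    omega: float
    kappa1: float = 0.0
    Vs: float | None = None        # cm^3/mol, solid solutes
    Tf: float | None = None        # K, normal fusion temperature
    dHf: float | None = None       # J/mol, fusion enthalpy
    dHv: float | None = None       # J/mol, vaporization enthalpy

    def __post_init__(self) -> None:
        if self.M <= 0 or self.Tc <= 0 or self.Pc <= 0:
            raise DomainError(f"{self.name}: M, Tc, Pc must be positive")
        if abs(self.omega) >= 2:
            raise DomainError(f"{self.name}: |omega| must be < 2")
        if self.Vs is not None and self.Vs <= 0:
            raise DomainError(f"{self.name}: Vs must be positive")


def carbon_dioxide(omega: float = 0.225, kappa1: float = 0.04285) -> Component:
    """CO2 record: Tc = 304.18 K, Pc = 73.8 bar.

    omega = 0.225 and the Stryjek–Vera kappa1 are standard literature values;
    both are overridable.
    """
    return Component(name="CO2", M=44.01, Tc=304.18, Pc=73.8,
                     omega=omega, kappa1=kappa1)


# ---------------------------------------------------------------------------
# Sublimation pressure (Clausius–Clapeyron from the triple point)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SublimationModel:
    """Triple-point anchor for the constant-enthalpy sublimation curve."""

    Pt: float    # bar
    Tt: float    # K
    dHs: float   # J/mol

    def __post_init__(self) -> None:
        if self.Pt <= 0 or self.Tt <= 0 or self.dHs < 0:
            raise DomainError("SublimationModel requires Pt, Tt > 0 and dHs >= 0")


def sublimation_enthalpy(dHv: float, dHf: float) -> float:
    """Sublimation enthalpy at the triple point: dHs = dHv + dHf (J/mol)."""
    if dHv < 0 or dHf < 0:
        raise DomainError("enthalpies must be non-negative")
    return dHv + dHf


def clapeyron_sublimation_pressure(T: float, model: SublimationModel) -> float:
    """Sublimation pressure (bar) assuming temperature-independent dHs.

    P_sub(T) = Pt * exp(-(dHs/R) * (1/T - 1/Tt)); strictly increasing in T
    and equal to Pt at the triple point.
    """
    if T <= 0:
        raise DomainError("T must be positive")
    return model.Pt * math.exp(-(model.dHs / R_J) * (1.0 / T - 1.0 / model.Tt))


# ---------------------------------------------------------------------------
# Vapor-pressure correlation  ln P = A + B/(T+C) + D ln T + E T
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VaporPressureCorrelation:
    """Extended-Antoine (Yaws-type) correlation, P in bar, T in K."""

    A: float
    B: float
    C: float
    D: float
    E: float
    Tmin: float = 0.0
    Tmax: float = math.inf


def evaluate_vapor_pressure(T: float, corr: VaporPressureCorrelation) -> float:
    """P_sat(T) in bar from ln P = A + B/(T+C) + D ln T + E T."""
    if not (corr.Tmin <= T <= corr.Tmax):
        raise DomainError(f"T={T} outside correlation range "
                          f"[{corr.Tmin}, {corr.Tmax}]")
    if T + corr.C == 0:
        raise DomainError("singularity: T + C = 0")
    return math.exp(corr.A + corr.B / (T + corr.C)
                    + corr.D * math.log(T) + corr.E * T)


def fit_vapor_pressure_correlation(
    points: Sequence[tuple[float, float]],
) -> tuple[VaporPressureCorrelation, float]:
    """Least squares in ln P over (T, Psat) pairs.

    With >= 5 points all five coefficients are fitted; with 3 or 4 points a
    reduced Antoine form (A, B, C only) is used.  Returns the correlation and
    the residual 2-norm in ln P.
    """
    pts = [(float(t), float(p)) for t, p in points]
    if any(t <= 0 or p <= 0 for t, p in pts):
        raise DomainError("T and Psat must be positive")
    n = len(pts)
    T = np.array([t for t, _ in pts])
    lnP = np.log([p for _, p in pts])
    full = n >= 5
    if n < 3:
        raise UnderdeterminedError(f"{n} points cannot determine the correlation")

    def model(theta: np.ndarray) -> np.ndarray:
        if full:
            A, B, C, D, E = theta
        else:
            A, B, C = theta
            D = E = 0.0
        return A + B / (T + C) + D * np.log(T) + E * T

    x0 = np.array([lnP.mean(), -1000.0, 0.0, 0.0, 0.0][: 5 if full else 3])
    sol = least_squares(lambda th: model(th) - lnP, x0, method="lm",
                        xtol=1e-14, ftol=1e-14, max_nfev=20000)
    th = sol.x
    if full:
        corr = VaporPressureCorrelation(*th, Tmin=T.min(), Tmax=T.max())
    else:
        corr = VaporPressureCorrelation(th[0], th[1], th[2], 0.0, 0.0,
                                        Tmin=T.min(), Tmax=T.max())
    return corr, float(np.linalg.norm(model(th) - lnP))


# ---------------------------------------------------------------------------
# Joback group-contribution estimation
# ---------------------------------------------------------------------------

def load_group_table() -> dict[str, dict[str, float]]:
    """Joback group increments shipped with the package (data/joback_groups.csv)."""
    table: dict[str, dict[str, float]] = {}
    with resources.files("scfsol.data").joinpath("joback_groups.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["group"]] = {
                "tc": float(row["tc"]),
                "pc": float(row["pc"]),
                "tb": float(row["tb"]),
                "n_atoms": int(row["n_atoms"]),
            }
    return table


#: Retinol (C20H30O) Joback decomposition: trimethylcyclohexene ring bearing a
#: conjugated tetraene chain terminated by a primary alcohol.
RETINOL_GROUPS: Mapping[str, int] = {
    "-CH3": 5,           # two gem-dimethyl + ring methyl + two chain methyls
    ">CH2": 1,           # the CH2-OH carbon
    "=CH-": 6,           # chain olefinic CH
    "=C<": 2,            # substituted chain olefinic C
    "ring>CH2": 3,
    "ring>C<": 1,
    "ring=C<": 2,        # the trisubstituted ring double bond
    "-OH (alcohol)": 1,
}


def _lee_kesler_omega(Tb: float, Tc: float, Pc_bar: float) -> float:
    """Acentric factor from the Lee–Kesler vapor-pressure correlation."""
    theta = Tb / Tc
    pc_atm = Pc_bar / ATM_BAR
    num = (-math.log(pc_atm) - 5.92714 + 6.09648 / theta
           + 1.28862 * math.log(theta) - 0.169347 * theta ** 6)
    den = (15.2518 - 15.6875 / theta - 13.4721 * math.log(theta)
           + 0.43577 * theta ** 6)
    return num / den


def estimate_solute_properties(
    group_counts: Mapping[str, int],
    *,
    name: str = "solute",
    M: float,
    rho_solid: float | None = None,
    Vs: float | None = None,
    overrides: Mapping[str, float] | None = None,
    table: Mapping[str, Mapping[str, float]] | None = None,
) -> Component:
    """Build a solute ``Component`` from Joback group counts.

    Tb (Joback), then Tc and Pc (Joback), then omega (Lee–Kesler from the
    estimated Tb).  ``overrides`` replaces any estimated field with a
    user-supplied value; ``rho_solid`` (g/cm^3) supplies Vs = M/rho_solid when
    Vs is not given directly.  Every estimated value is logged so model runs
    are auditable.
    """
    if not group_counts:
        raise ConfigError("empty group set")
    tab = table if table is not None else load_group_table()
    unknown = [g for g in group_counts if g not in tab]
    if unknown:
        raise ConfigError(f"unknown group id(s): {unknown}")
    overrides = dict(overrides or {})

    s_tc = sum(tab[g]["tc"] * n for g, n in group_counts.items())
    s_pc = sum(tab[g]["pc"] * n for g, n in group_counts.items())
    s_tb = sum(tab[g]["tb"] * n for g, n in group_counts.items())
    n_atoms = sum(tab[g]["n_atoms"] * n for g, n in group_counts.items())

    Tb = overrides.get("Tb", 198.2 + s_tb)
    Tc = overrides.get("Tc", Tb / (0.584 + 0.965 * s_tc - s_tc ** 2))
    Pc = overrides.get("Pc", (0.113 + 0.0032 * n_atoms - s_pc) ** -2)
    omega = overrides.get("omega", _lee_kesler_omega(Tb, Tc, Pc))
    if Vs is None and rho_solid is not None:
        Vs = M / rho_solid
    if "Vs" in overrides:
        Vs = overrides["Vs"]

    for key, val, src in [("Tb", Tb, "Joback"), ("Tc", Tc, "Joback"),
                          ("Pc", Pc, "Joback"),
                          ("omega", omega, "Lee-Kesler")]:
        prov = "override" if key in overrides else src
        logger.info("property %s.%s = %.6g (%s)", name, key, val, prov)
    if Vs is not None:
        logger.info("property %s.Vs = %.6g cm^3/mol", name, Vs)

    return Component(name=name, M=M, Tc=Tc, Pc=Pc, omega=omega,
                     kappa1=overrides.get("kappa1", 0.0), Vs=Vs,
                     Tf=overrides.get("Tf"), dHf=overrides.get("dHf"),
                     dHv=overrides.get("dHv"))


def default_retinol(overrides: Mapping[str, float] | None = None) -> Component:
    """Retinol record with Joback/Lee–Kesler estimated critical properties.

    M = 286.45 g/mol; solid density defaults to 0.95 g/cm^3, giving
    Vs ~ 301.5 cm^3/mol (enters only the Poynting factor).  Fusion point
    ~335 K (62 C) is retained as metadata for seeding sublimation-pressure
    estimates.
    """
    base = estimate_solute_properties(
        RETINOL_GROUPS, name="retinol", M=286.45, rho_solid=0.95,
        overrides=overrides)
    if base.Tf is None:
        base = replace(base, Tf=335.15)
    return base
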
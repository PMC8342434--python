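"""Per-isotherm regression of interaction parameters and temperature trends.

For each (EOS, mixing rule, isotherm) the adjustable set is (kij, Psub) under
vdW1 and (kij, lij, Psub) under vdW2 — the sublimation pressure acts as an
isotherm-level parameter because no measured value exists for heavy,
thermally fragile solutes.  The objective is the average absolute relative
deviation of calculated vs experimental mole fractions,

    AARD% = (100/N) sum_i |y_calc,i - y_exp,i| / y_exp,i,

minimized by bounded Nelder–Mead from seeded Latin-hypercube starts (the
objective is cheap but non-smooth where the compressibility root switches).
Fitted kij (and lij) across isotherms are then regressed linearly in T:
kij = A1*T + A2, lij = A3*T + A4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .dataset import SolubilityDataset
from .eos_core import MixingRuleSpec, get_eos
from .equilibrium import EquilibriumProblem
from .errors import (ConvergenceError, DomainError, FitError,
                     NonphysicalStateError, UnderdeterminedError)
from .properties import Component

logger = logging.getLogger("scfsol")

#: Default search bounds: interaction parameters on a linear scale, the
#: sublimation pressure on log10(bar).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kij": (-1.0, 1.5),
    "lij": (-1.0, 1.5),
    "log10_Psub": (-14.0, 1.0),
}

DEFAULT_STARTS = 16
_PENALTY = 1e6


def aard(y_calc: Sequence[float], y_exp: Sequence[float]) -> float:
    """Average absolute relative deviation, in percent."""
    yc = np.asarray(y_calc, dtype=float)
    ye = np.asarray(y_exp, dtype=float)
    if yc.shape != ye.shape:
        raise ValueError(f"shape mismatch: {yc.shape} vs {ye.shape}")
    if yc.size == 0:
        raise ValueError("empty vectors")
    if np.any(ye == 0):
        raise DomainError("experimental mole fractions must be nonzero")
    return float(100.0 / ye.size * np.sum(np.abs(yc - ye) / np.abs(ye)))


@dataclass(frozen=True)
class IsothermFit:
    """Best-fit parameters and diagnostics for one (EOS, rule, T) triple."""

    T: float
    eos_id: str
    rule_id: str
    kij: float
    lij: float | None
    Psub: float            # bar
    aard_pct: float
    n_points: int
    n_starts: int
    converged: bool
    start_results: tuple[dict, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class TrendCoefficients:
    """Linear temperature trends of the interaction parameters (T in K)."""

    A1: float              # kij slope
    A2: float              # kij intercept
    A3: float | None = None  # lij slope (vdW2 only)
    A4: float | None = None  # lij intercept


# ---------------------------------------------------------------------------
# Isotherm model evaluation
# ---------------------------------------------------------------------------

def _model_isotherm_y(T: float, pressures: np.ndarray, solute: Component,
                      solvent: Component, eos, kij: float, lij: float,
                      Psub: float, rule_id: str,
                      phi_sub: float = 1.0) -> np.ndarray:
    """Model mole fractions along one isotherm; NaN where the solve fails."""
    from .equilibrium import solve_solubility

    rule = MixingRuleSpec(rule_id, kij=kij,
                          lij=lij if rule_id == "vdw2" else 0.0)
    out = np.empty(pressures.size)
    for i, P in enumerate(pressures):
        try:
            prob = EquilibriumProblem(T=T, P=float(P), solute=solute,
                                      solvent=solvent, eos=eos, rule=rule,
                                      Psub=Psub, phi_sub=phi_sub)
            out[i] = solve_solubility(prob).y
        except (DomainError, NonphysicalStateError, ConvergenceError,
                OverflowError):
            out[i] = np.nan
    return out


def _dilute_phi_factory(T, pressures, solute, solvent, eos, rule_id,
                        phi_sub):
    """Dilute-limit solubility per unit sublimation pressure.

    Returns ``shape(kij, lij) -> array`` with shape_i = E(y->0)_i / P_i, so
    that the model prediction is approximately Psub * shape_i.  Used only to
    seed the optimizer; the full fixed point defines the objective.
    """
    from .eos_core import lnphi_solute_binary, pure_params
    from .equilibrium import Y_FLOOR
    from .properties import R_CM3_BAR

    aA, bA = pure_params(solute, T, eos)
    aC, bC = pure_params(solvent, T, eos)
    Vs = solute.Vs

    def shape(kij: float, lij: float):
        rule = MixingRuleSpec(rule_id, kij=kij,
                              lij=lij if rule_id == "vdw2" else 0.0)
        out = np.empty(pressures.size)
        for i, P in enumerate(pressures):
            try:
                lnphi = lnphi_solute_binary(T, float(P), Y_FLOOR,
                                            aA, bA, aC, bC, eos, rule)
                E0 = phi_sub * math.exp(
                    Vs * float(P) / (R_CM3_BAR * T)) / math.exp(lnphi)
            except (NonphysicalStateError, OverflowError):
                return None
            out[i] = E0 / float(P)
        return out

    return shape


def _optimal_scale(shape: np.ndarray, y_exp: np.ndarray) -> float:
    """argmin_s of sum_i |s*shape_i - y_exp_i| / y_exp_i (exact).

    The objective is piecewise linear and convex in s, so the minimum sits
    at one of the breakpoints s = y_exp_i / shape_i.
    """
    r = shape / y_exp
    candidates = 1.0 / r
    costs = [np.abs(s * r - 1.0).sum() for s in candidates]
    return float(candidates[int(np.argmin(costs))])


def fit_isotherm(
    data: SolubilityDataset,
    solute: Component,
    solvent: Component,
    eos: str,
    rule_id: str,
    *,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = DEFAULT_STARTS,
    seed: int = 0,
    phi_sub: float = 1.0,
) -> IsothermFit:
    """Fit (kij[, lij], Psub) to one isotherm by multi-start local search.

    ``data`` must hold a single temperature with at least 3 points.  Starts
    are a seeded Latin-hypercube over the bounds; every start's outcome is
    kept in ``start_results`` for audit.
    """
    temps = data.temperatures()
    if len(temps) != 1:
        raise ValueError(f"expected one isotherm, got temperatures {temps}")
    if len(data) < 3:
        raise UnderdeterminedError("need at least 3 points per isotherm")
    T = temps[0]
    eos_spec = get_eos(eos)
    rule_id = rule_id.lower()
    two_param = rule_id == "vdw2"
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    for k, (lo, hi) in b.items():
        if lo >= hi:
            raise ValueError(f"bounds for {k} are not well-ordered")
    names = ["kij", "lij", "log10_Psub"] if two_param else ["kij", "log10_Psub"]
    box = [b[n] for n in names]

    pressures = np.array([p.P for p in data])
    y_exp = np.array([p.y for p in data])

    def unpack(theta: np.ndarray) -> tuple[float, float, float]:
        if two_param:
            kij, lij, lp = theta
        else:
            (kij, lp), lij = theta, 0.0
        return float(kij), float(lij), 10.0 ** float(lp)

    def objective(theta: np.ndarray) -> float:
        kij, lij, Psub = unpack(theta)
        if Psub >= pressures.min():
            return _PENALTY
        y_calc = _model_isotherm_y(T, pressures, solute, solvent, eos_spec,
                                   kij, lij, Psub, rule_id, phi_sub)
        if np.isnan(y_calc).any():
            return _PENALTY
        return aard(y_calc, y_exp)

    # Stage A: Latin-hypercube scan over the interaction parameters with the
    # sublimation pressure profiled out.  In the dilute limit y is
    # proportional to Psub, so for each (kij[, lij]) the AARD-optimal scale
    # is the weighted median of the experimental/model ratios — an exact 1D
    # subproblem that collapses the search space by one dimension.
    phis = _dilute_phi_factory(T, pressures, solute, solvent, eos_spec,
                               rule_id, phi_sub)
    n_scan = max(64, 4 * n_starts)
    sampler = qmc.LatinHypercube(d=len(names) - 1, seed=seed)
    lo = np.array([b[n][0] for n in names[:-1]])
    hi = np.array([b[n][1] for n in names[:-1]])
    scan = lo + sampler.random(n_scan) * (hi - lo)
    lp_lo, lp_hi = b["log10_Psub"]
    candidates = []
    for row in scan:
        kij = float(row[0])
        lij = float(row[1]) if two_param else 0.0
        shape = phis(kij, lij)      # y per unit Psub, dilute limit
        if shape is None:
            continue
        s_opt = _optimal_scale(shape, y_exp)
        lp = min(max(math.log10(s_opt), lp_lo), lp_hi)
        theta = np.array([kij, lij, lp] if two_param else [kij, lp])
        candidates.append((objective(theta), theta))
    candidates.sort(key=lambda c: c[0])

    # Stage B: bounded Nelder-Mead polish from the best scan candidates.
    results = []
    for fun0, x0 in candidates[:n_starts]:
        res = minimize(objective, x0, method="Nelder-Mead", bounds=box,
                       options={"xatol": 1e-7, "fatol": 1e-9,
                                "maxfev": 2000})
        results.append({"start": x0.tolist(), "start_fun": float(fun0),
                        "x": res.x.tolist(),
                        "fun": float(res.fun), "success": bool(res.success),
                        "nfev": int(res.nfev)})
    feasible = [r for r in results if r["fun"] < _PENALTY]
    if not feasible:
        raise FitError(f"all {n_starts} starts failed for {eos}-{rule_id} "
                       f"at {T} K: {results}")
    best = min(feasible, key=lambda r: r["fun"])
    kij, lij, Psub = unpack(np.array(best["x"]))
    return IsothermFit(T=T, eos_id=eos_spec.family_id, rule_id=rule_id,
                       kij=kij, lij=lij if two_param else None, Psub=Psub,
                       aard_pct=best["fun"], n_points=len(data),
                       n_starts=n_starts, converged=best["success"],
                       start_results=tuple(results))


def fit_all(
    data: SolubilityDataset,
    solute: Component,
    solvent: Component,
    eos_ids: Sequence[str] = ("srk", "pr", "sv", "dptg"),
    rule_ids: Sequence[str] = ("vdw1", "vdw2"),
    **kwargs,
) -> tuple[list[IsothermFit], pd.DataFrame]:
    """One fit per (EOS, rule, isotherm) plus a correlation-table summary.

    The summary frame mirrors the per-isotherm layout (kij, lij, Psub,
    AARD%) and appends a mean AARD per (EOS, rule) for ranking; failed cells
    are recorded as NaN rows and do not abort the sweep.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    fits: list[IsothermFit] = []
    rows = []
    for eos_id in eos_ids:
        for rule_id in rule_ids:
            for T in data.temperatures():
                try:
                    fit = fit_isotherm(data.isotherm(T), solute, solvent,
                                       eos_id, rule_id, **kwargs)
                    fits.append(fit)
                    rows.append({"eos": eos_id, "rule": rule_id, "T_K": T,
                                 "kij": fit.kij, "lij": fit.lij,
                                 "Psub_bar": fit.Psub,
                                 "aard_pct": fit.aard_pct})
                except FitError as exc:
                    logger.warning("fit failed: %s", exc)
                    rows.append({"eos": eos_id, "rule": rule_id, "T_K": T,
                                 "kij": np.nan, "lij": np.nan,
                                 "Psub_bar": np.nan, "aard_pct": np.nan})
    table = pd.DataFrame(rows)
    overall = (table.groupby(["eos", "rule"], sort=False)["aard_pct"]
               .mean().rename("overall_aard_pct").reset_index())
    table = table.merge(overall, on=["eos", "rule"], how="left")
    return fits, table


def fit_interaction_trend(fits: Sequence[IsothermFit]) -> TrendCoefficients:
    """OLS of kij (and lij, if present) against temperature in kelvin."""
    if len(fits) < 2:
        raise UnderdeterminedError("need at least 2 isotherms for a trend")
    ids = {(f.eos_id, f.rule_id) for f in fits}
    if len(ids) != 1:
        raise ValueError(f"fits mix (EOS, rule) combinations: {ids}")
    T = np.array([f.T for f in fits])
    k = np.array([f.kij for f in fits])
    A1, A2 = np.polyfit(T, k, 1)
    A3 = A4 = None
    if all(f.lij is not None for f in fits):
        A3, A4 = np.polyfit(T, np.array([f.lij for f in fits]), 1)
        A3, A4 = float(A3), float(A4)
    return TrendCoefficients(A1=float(A1), A2=float(A2), A3=A3, A4=A4)


def linear_trend(T: Sequence[float], values: Sequence[float]
                 ) -> tuple[float, float]:
    """Slope and intercept of an OLS line value = slope*T + intercept."""
    T = np.asarray(T, dtype=float)
    v = np.asarray(values, dtype=float)
    if T.size < 2:
        raise UnderdeterminedError("need at least two points")
    slope, intercept = np.polyfit(T, v, 1)
    return float(slope), float(intercept)
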
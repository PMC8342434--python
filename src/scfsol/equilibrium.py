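"""Solid–supercritical-fluid equilibrium.

A pure, incompressible solid in contact with a supercritical solvent that
does not dissolve into the solid phase.  Equating solid and fluid fugacities
gives the working relation

    y = (P_sub / P) * E,
    E = phi_sub * exp(Vs (P - P_sub) / RT) / phi_scf(T, P, y)

where E is the enhancement factor over the ideal estimate P_sub/P: a
Poynting pressure correction on the solid fugacity, the (near-unity)
saturated-vapor fugacity coefficient phi_sub, and — dominating everything —
the solute fugacity coefficient phi_scf in the dense fluid.  Because
phi_scf depends on composition, y is a fixed point, solved here by damped
direct iteration with a bisection fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .eos_core import (CubicEOSSpec, MixingRuleSpec, get_eos,
                       lnphi_solute_binary, pure_params)
from .errors import ConvergenceError, DomainError, NonphysicalStateError
from .properties import Component, R_CM3_BAR

logger = logging.getLogger("scfsol")

#: Below this mole fraction the composition is clamped for EOS evaluation
#: (phi_scf is composition-insensitive in the dilute limit).
Y_FLOOR = 1e-12

#: Relative fixed-point tolerance on y.
Y_RTOL = 1e-12

MAX_ITER = 200


@dataclass(frozen=True)
class EquilibriumProblem:
    """One solid-solubility state: components, model, and solid properties."""

    T: float                 # K
    P: float                 # bar
    solute: Component
    solvent: Component
    eos: CubicEOSSpec
    rule: MixingRuleSpec
    Psub: float              # bar, solute sublimation pressure at T
    phi_sub: float = 1.0     # saturated-vapor fugacity coefficient

    def __post_init__(self) -> None:
        if not 0 < self.Psub < self.P:
            raise DomainError("require 0 < Psub < P")
        if not 0 < self.phi_sub <= 1.05:
            raise DomainError("phi_sub must lie in (0, 1.05]")
        if self.solute.Vs is None:
            raise DomainError("solute needs a solid molar volume Vs")


@dataclass(frozen=True)
class SolubilitySolution:
    """Converged solubility with diagnostics."""

    y: float
    E: float
    phi_scf: float
    iterations: int
    residual: float


def enhancement_factor(P: float, Psub: float, Vs: float, T: float,
                       phi_sub: float, phi_scf: float) -> float:
    """E = phi_sub * exp(Vs (P - Psub) / RT) / phi_scf.

    Vs in cm^3/mol and pressures in bar match R = 83.1446 cm^3 bar/(mol K).
    """
    if not P >= Psub > 0:
        raise DomainError("require P >= Psub > 0")
    if phi_scf <= 0:
        raise DomainError("phi_scf must be positive")
    poynting = math.exp(Vs * (P - Psub) / (R_CM3_BAR * T))
    return phi_sub * poynting / phi_scf


class _PhiSCF:
    """phi_scf(y) at fixed (T, P), caching the pure EOS parameters."""

    def __init__(self, prob: EquilibriumProblem) -> None:
        self.prob = prob
        self._aA, self._bA = pure_params(prob.solute, prob.T, prob.eos)
        self._aC, self._bC = pure_params(prob.solvent, prob.T, prob.eos)

    def __call__(self, y: float) -> float:
        y = min(max(y, Y_FLOOR), 1.0 - Y_FLOOR)
        lnphi = lnphi_solute_binary(
            self.prob.T, self.prob.P, y, self._aA, self._bA,
            self._aC, self._bC, self.prob.eos, self.prob.rule)
        return math.exp(lnphi)


def solve_solubility(prob: EquilibriumProblem) -> SolubilitySolution:
    """Solve y = (Psub/P) E(y) by damped fixed-point iteration.

    Starts from the ideal estimate y0 = Psub/P; a 0.5 damping factor is
    applied when successive updates oscillate in sign.  If 200 iterations do
    not converge to relative tolerance 1e-12, a bisection fallback on
    g(y) = y - (Psub/P) E(y) over (1e-12, 0.5) is attempted.
    """
    phi_of = _PhiSCF(prob)
    ratio = prob.Psub / prob.P
    Vs = prob.solute.Vs

    def step(y: float) -> tuple[float, float]:
        phi = phi_of(y)
        E = enhancement_factor(prob.P, prob.Psub, Vs, prob.T,
                               prob.phi_sub, phi)
        return ratio * E, phi

    y = ratio
    prev_delta = 0.0
    damp = 1.0
    for it in range(1, MAX_ITER + 1):
        y_new, phi = step(y)
        if y_new >= 1.0:
            break  # escaped (0, 1): go to bisection
        delta = y_new - y
        resid = abs(delta) / max(abs(y_new), Y_FLOOR)
        if resid < Y_RTOL:
            E = enhancement_factor(prob.P, prob.Psub, Vs, prob.T,
                                   prob.phi_sub, phi)
            return SolubilitySolution(y=y_new, E=E, phi_scf=phi,
                                      iterations=it, residual=resid)
        damp = 0.5 * damp if delta * prev_delta < 0 else min(1.0, 2.0 * damp)
        prev_delta = delta
        y = y + damp * delta

    return _bisection_fallback(prob, phi_of, ratio)


def _bisection_fallback(prob: EquilibriumProblem, phi_of: _PhiSCF,
                        ratio: float) -> SolubilitySolution:
    Vs = prob.solute.Vs

    def g(y: float) -> float:
        E = enhancement_factor(prob.P, prob.Psub, Vs, prob.T,
                               prob.phi_sub, phi_of(y))
        return y - ratio * E

    lo, hi = Y_FLOOR, 0.5
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise ConvergenceError(
            f"solubility fixed point did not converge and g has no sign "
            f"change on ({lo}, {hi}) at T={prob.T} K, P={prob.P} bar")
    it = 0
    while hi - lo > Y_RTOL * max(hi, Y_FLOOR) and it < 200:
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if glo * gm <= 0:
            hi, ghi = mid, gm
        else:
            lo, glo = mid, gm
        it += 1
    y = 0.5 * (lo + hi)
    phi = phi_of(y)
    E = enhancement_factor(prob.P, prob.Psub, Vs, prob.T, prob.phi_sub, phi)
    return SolubilitySolution(y=ratio * E, E=E, phi_scf=phi,
                              iterations=MAX_ITER + it,
                              residual=abs(ratio * E - y) / max(y, Y_FLOOR))


def solubility_isotherm(
    T: float, pressures: Sequence[float], solute: Component,
    solvent: Component, eos: CubicEOSSpec | str, rule: MixingRuleSpec,
    Psub: float, phi_sub: float = 1.0,
) -> list[tuple[float, SolubilitySolution | None]]:
    """Solubility along an isotherm; per-point failures are reported, not fatal."""
    eos = get_eos(eos)
    out: list[tuple[float, SolubilitySolution | None]] = []
    n_fail = 0
    for P in pressures:
        try:
            prob = EquilibriumProblem(T=T, P=P, solute=solute,
                                      solvent=solvent, eos=eos, rule=rule,
                                      Psub=Psub, phi_sub=phi_sub)
            out.append((P, solve_solubility(prob)))
        except (DomainError, NonphysicalStateError, ConvergenceError) as exc:
            logger.warning("isotherm point T=%s P=%s failed: %s", T, P, exc)
            out.append((P, None))
            n_fail += 1
    if pressures and n_fail == len(pressures):
        raise ConvergenceError(f"all points failed on the {T} K isotherm")
    return out
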
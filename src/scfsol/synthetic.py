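"""Synthetic solubility datasets with known ground truth.

Generates isothermal solid-solubility data from a chosen EOS + mixing rule
with known (kij, lij, Psub) per isotherm, then applies multiplicative
measurement noise y_noisy = y_model * (1 + eps), eps ~ N(0, cv) truncated at
three sigma so mole fractions stay positive.  Densities come from a lookup
table — mirroring practice, where the solvent density is taken from a
dedicated reference correlation rather than from the cubic EOS — and the
solubility column is recomputed from the noisy y so each record stays
internally consistent.

The ``table2-like`` preset copies the experimental design of the bundled
vitamin A fixture: isotherms at 303.15/313.15/323.15 K with 11/9/7 pressures
in 90-245 bar, and a default noise CV of 0.06 matching the stated < 6%
experimental uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dataset import (ExperimentalPoint, SolubilityDataset, load_dataset,
                      solubility_from_mole_fraction)
from .eos_core import MixingRuleSpec, get_eos
from .equilibrium import EquilibriumProblem, solve_solubility
from .errors import ConvergenceError, DomainError, NonphysicalStateError
from .properties import Component, carbon_dioxide, default_retinol


@dataclass(frozen=True)
class IsothermTruth:
    """Ground-truth generating parameters for one isotherm."""

    T: float
    pressures: tuple[float, ...]
    kij: float
    lij: float
    Psub: float      # bar


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic-data experiment."""

    eos_id: str
    rule_id: str
    isotherms: tuple[IsothermTruth, ...]
    density: Mapping[tuple[float, float], float]   # (T, P) -> rho g/L
    noise_cv: float = 0.0
    seed: int | None = None
    solute: Component = field(default_factory=default_retinol)
    solvent: Component = field(default_factory=carbon_dioxide)
    phi_sub: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_cv <= 0.2:
            raise DomainError("noise_cv must lie in [0, 0.2]")
        if self.noise_cv > 0 and self.seed is None:
            raise DomainError("a seed is mandatory when noise_cv > 0")


def make_fixture_like(
    eos_id: str = "pr",
    rule_id: str = "vdw2",
    *,
    kij: float | Mapping[float, float] = 0.52,
    lij: float | Mapping[float, float] = 0.47,
    Psub: float | Mapping[float, float] = 2e-8,
    noise_cv: float = 0.06,
    seed: int | None = 0,
    temperatures: Sequence[float] | None = None,
) -> SyntheticSpec:
    """Preset copying the bundled fixture's (T, P) grid and density column.

    ``kij``/``lij``/``Psub`` may be scalars (shared across isotherms) or
    per-temperature mappings.  ``temperatures`` restricts the preset to a
    subset of the three isotherms.  The default truth parameters are chosen
    so the generated mole fractions fall in the measured 1e-5 to 2e-4 range
    under the default (Joback-estimated) solute property set.
    """
    ds = load_dataset("bundled:table2")
    temps = tuple(temperatures) if temperatures else ds.temperatures()

    def at(v, T):
        return float(v[T]) if isinstance(v, Mapping) else float(v)

    isotherms = []
    density: dict[tuple[float, float], float] = {}
    for T in temps:
        iso = ds.isotherm(T)
        isotherms.append(IsothermTruth(
            T=T, pressures=tuple(p.P for p in iso),
            kij=at(kij, T), lij=at(lij, T), Psub=at(Psub, T)))
        for p in iso:
            density[(T, p.P)] = p.rho
    return SyntheticSpec(eos_id=eos_id, rule_id=rule_id,
                         isotherms=tuple(isotherms), density=density,
                         noise_cv=noise_cv, seed=seed)


def generate(spec: SyntheticSpec) -> tuple[SolubilityDataset, dict]:
    """Dataset drawn from ``spec`` plus a serializable ground-truth record.

    Grid points where the equilibrium solver fails are dropped with a
    warning counter in the truth record; more than half dropping is a spec
    error.  With ``noise_cv = 0`` the y column equals the model output
    exactly and the same seed always reproduces identical bytes.
    """
    eos = get_eos(spec.eos_id)
    rng = np.random.default_rng(spec.seed)
    points: list[ExperimentalPoint] = []
    n_grid = 0
    n_drop = 0
    for iso in spec.isotherms:
        rule = MixingRuleSpec(
            spec.rule_id, kij=iso.kij,
            lij=iso.lij if spec.rule_id == "vdw2" else 0.0)
        for P in iso.pressures:
            n_grid += 1
            try:
                prob = EquilibriumProblem(
                    T=iso.T, P=P, solute=spec.solute, solvent=spec.solvent,
                    eos=eos, rule=rule, Psub=iso.Psub, phi_sub=spec.phi_sub)
                y = solve_solubility(prob).y
            except (DomainError, NonphysicalStateError, ConvergenceError):
                n_drop += 1
                continue
            if spec.noise_cv > 0:
                eps = float(rng.normal(0.0, spec.noise_cv))
                eps = max(-3.0 * spec.noise_cv,
                          min(3.0 * spec.noise_cv, eps))
                y = y * (1.0 + eps)
            rho = spec.density[(iso.T, P)]
            S = solubility_from_mole_fraction(
                y, rho, spec.solute.M, spec.solvent.M)
            points.append(ExperimentalPoint(T=iso.T, P=P, y=y, rho=rho, S=S))
    if n_grid and n_drop > 0.5 * n_grid:
        raise DomainError(
            f"{n_drop}/{n_grid} grid points failed; spec unusable")
    truth = {
        "eos": spec.eos_id, "rule": spec.rule_id,
        "noise_cv": spec.noise_cv, "seed": spec.seed,
        "n_dropped": n_drop,
        "isotherms": [
            {"T_K": iso.T, "kij": iso.kij, "lij": iso.lij,
             "Psub_bar": iso.Psub, "pressures_bar": list(iso.pressures)}
            for iso in spec.isotherms],
    }
    ds = SolubilityDataset(tuple(points),
                           solute_id=spec.solute.name,
                           solvent_id=spec.solvent.name)
    return ds, truth


def write_truth(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
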
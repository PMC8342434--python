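"""Generalized two-parameter cubic equation-of-state engine.

Every family handled here is a member of

    P = RT/(v - b) - a(T) / [(v + d1*b)(v + d2*b)]

so SRK (d1=1, d2=0), Peng–Robinson (d1=1+sqrt2, d2=1-sqrt2), Stryjek–Vera
(PR structure, PRSV alpha) and the perturbation-theory DPTG family all share
one compressibility cubic and one fugacity-coefficient closed form, differing
only in (d1, d2, Omega_a, Omega_b, alpha).  Mixtures use the van der Waals
one-parameter (vdW1: kij on the attraction term) or two-parameter (vdW2:
kij + lij, quadratic co-volume) rules.

In terms of A = aP/(RT)^2 and B = bP/RT, with s = d1+d2 and p = d1*d2, the
compressibility cubic is

    Z^3 + [(s-1)B - 1] Z^2 + [(p-s)B^2 - sB + A] Z - [pB^3 + pB^2 + AB] = 0

and the component fugacity coefficient for vdW-type rules is

    ln phi_i = (bbar_i/b)(Z-1) - ln(Z-B)
               + A/((d1-d2)B) * (bbar_i/b - abar_i/a) * ln[(Z+d1*B)/(Z+d2*B)]

with abar_i = 2 sum_j x_j sqrt(a_i a_j)(1-kij) and
bbar_i = 2 sum_j x_j b_ij - b (b_ij = (1-lij)(b_i+b_j)/2), which reduces to
bbar_i = b_i under vdW1.  Mole-fraction weighting of ln phi_i recovers the
mixture ln phi identically (Euler consistency).

Units: T in K, P in bar, a in bar cm^6/mol^2, b and v in cm^3/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError, DomainError, NonphysicalStateError
from .properties import Component, R_CM3_BAR

_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# EOS family registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CubicEOSSpec:
    """One member of the generalized two-parameter cubic family."""

    family_id: str
    delta1: float
    delta2: float
    Omega_a: float
    Omega_b: float
    alpha_id: str

    def __post_init__(self) -> None:
        if self.delta1 < self.delta2:
            raise ConfigError("delta1 must be >= delta2")
        if self.Omega_a <= 0 or self.Omega_b <= 0:
            raise ConfigError("Omega_a and Omega_b must be positive")


def critical_point_coefficients(delta1: float, delta2: float
                                ) -> tuple[float, float, float]:
    """(Omega_a, Omega_b, Zc) making the cubic satisfy dP/dv = d2P/dv2 = 0
    at the critical point, for an arbitrary denominator pair.

    At T = Tc, P = Pc the dimensionless A and B equal Omega_a and Omega_b and
    the compressibility cubic must have a triple root Zc, which gives three
    equations in (Omega_a, Omega_b, Zc); eliminating Omega_a and Zc leaves a
    one-dimensional root problem in Omega_b.
    """
    s, p = delta1 + delta2, delta1 * delta2

    def resid(B: float) -> float:
        Zc = (1.0 - (s - 1.0) * B) / 3.0
        A = 3.0 * Zc ** 2 - (p - s) * B ** 2 + s * B
        return Zc ** 3 - p * B ** 3 - p * B ** 2 - A * B

    B = brentq(resid, 1e-8, 0.33, xtol=1e-15, rtol=8.9e-16)
    Zc = (1.0 - (s - 1.0) * B) / 3.0
    A = 3.0 * Zc ** 2 - (p - s) * B ** 2 + s * B
    return A, B, Zc


def _build_registry() -> dict[str, CubicEOSSpec]:
    # SRK and PR use the canonical literature constants; the DPTG entry uses
    # denominator (2, 0) with Omegas derived from the critical constraints
    # and a PR-type alpha, and is overridable via register_eos.
    oa, ob, _ = critical_point_coefficients(2.0, 0.0)
    return {
        "srk": CubicEOSSpec("srk", 1.0, 0.0, 0.42748, 0.08664, "soave"),
        "pr": CubicEOSSpec("pr", 1.0 + _SQRT2, 1.0 - _SQRT2,
                           0.45724, 0.07780, "peng-robinson"),
        "sv": CubicEOSSpec("sv", 1.0 + _SQRT2, 1.0 - _SQRT2,
                           0.45724, 0.07780, "stryjek-vera"),
        "dptg": CubicEOSSpec("dptg", 2.0, 0.0, oa, ob, "peng-robinson"),
    }


EOS_REGISTRY: dict[str, CubicEOSSpec] = _build_registry()


def get_eos(name: str | CubicEOSSpec) -> CubicEOSSpec:
    if isinstance(name, CubicEOSSpec):
        return name
    try:
        return EOS_REGISTRY[name.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown EOS {name!r}; known: {sorted(EOS_REGISTRY)}") from None


def register_eos(spec: CubicEOSSpec) -> None:
    """Add or replace a (possibly custom) family in the registry."""
    EOS_REGISTRY[spec.family_id.lower()] = spec


# ---------------------------------------------------------------------------
# alpha(T) functions
# ---------------------------------------------------------------------------

def alpha(T: float, c: Component, eos: CubicEOSSpec) -> float:
    """Temperature dependence of the attraction term; alpha(Tc) = 1."""
    if T <= 0:
        raise DomainError("T must be positive")
    Tr = T / c.Tc
    sq = math.sqrt(Tr)
    if eos.alpha_id == "soave":
        m = 0.480 + 1.574 * c.omega - 0.176 * c.omega ** 2
    elif eos.alpha_id == "peng-robinson":
        m = 0.37464 + 1.54226 * c.omega - 0.26992 * c.omega ** 2
    elif eos.alpha_id == "stryjek-vera":
        k0 = (0.378893 + 1.4897153 * c.omega - 0.17131848 * c.omega ** 2
              + 0.0196554 * c.omega ** 3)
        m = k0 + c.kappa1 * (1.0 + sq) * (0.7 - Tr)
    else:
        raise ConfigError(f"unknown alpha function {eos.alpha_id!r}")
    return (1.0 + m * (1.0 - sq)) ** 2


def pure_params(c: Component, T: float, eos: CubicEOSSpec
                ) -> tuple[float, float]:
    """Attraction a_i (bar cm^6/mol^2) and co-volume b_i (cm^3/mol)."""
    if T <= 0:
        raise DomainError("T must be positive")
    a = eos.Omega_a * (R_CM3_BAR * c.Tc) ** 2 / c.Pc * alpha(T, c, eos)
    b = eos.Omega_b * R_CM3_BAR * c.Tc / c.Pc
    return a, b


# ---------------------------------------------------------------------------
# Mixing rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixingRuleSpec:
    """van der Waals mixing rule: vdW1 (kij) or vdW2 (kij + lij)."""

    rule_id: str
    kij: float = 0.0
    lij: float = 0.0

    def __post_init__(self) -> None:
        rid = self.rule_id.lower()
        if rid not in ("vdw1", "vdw2"):
            raise ConfigError(f"unknown mixing rule {self.rule_id!r}")
        object.__setattr__(self, "rule_id", rid)
        if rid == "vdw1" and self.lij != 0.0:
            raise ConfigError("vdW1 has no co-volume parameter lij")


def _pair_matrices(a: np.ndarray, b: np.ndarray, rule: MixingRuleSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal combining rules a_ij, b_ij (kij, lij zero on diagonal)."""
    n = a.size
    off = 1.0 - np.eye(n)
    aij = np.sqrt(np.outer(a, a)) * (1.0 - rule.kij * off)
    if rule.rule_id == "vdw2":
        bij = 0.5 * np.add.outer(b, b) * (1.0 - rule.lij * off)
    else:
        bij = 0.5 * np.add.outer(b, b)
    return aij, bij


def mix_params(x: Sequence[float], a: Sequence[float], b: Sequence[float],
               rule: MixingRuleSpec) -> tuple[float, float]:
    """Mixture (a_mix, b_mix); vdW1 uses the linear co-volume rule."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (x.shape == a.shape == b.shape):
        raise ValueError("x, a, b must have matching shapes")
    aij, bij = _pair_matrices(a, b, rule)
    a_mix = float(x @ aij @ x)
    if rule.rule_id == "vdw1":
        b_mix = float(x @ b)
    else:
        b_mix = float(x @ bij @ x)
    return a_mix, b_mix


# ---------------------------------------------------------------------------
# Compressibility roots
# ---------------------------------------------------------------------------

def _cubic_real_roots(c2: float, c1: float, c0: float) -> list[float]:
    """Real roots of z^3 + c2 z^2 + c1 z + c0, Newton-polished.

    Closed form (trigonometric for three real roots, Cardano otherwise);
    cheap enough for the inner loop of the solubility regression.
    """
    q = c1 / 3.0 - c2 * c2 / 9.0
    r = (c1 * c2 - 3.0 * c0) / 6.0 - c2 ** 3 / 27.0
    disc = q ** 3 + r * r
    shift = c2 / 3.0
    if disc > 0.0:  # one real root
        sq = math.sqrt(disc)
        u = math.copysign(abs(r + sq) ** (1.0 / 3.0), r + sq)
        w = math.copysign(abs(r - sq) ** (1.0 / 3.0), r - sq)
        roots = [u + w - shift]
    elif q == 0.0:  # triple root
        roots = [math.copysign(abs(2.0 * r) ** (1.0 / 3.0), r) - shift
                 if r != 0.0 else -shift]
    else:  # three real roots
        mq = math.sqrt(-q)
        arg = max(-1.0, min(1.0, r / mq ** 3))
        theta = math.acos(arg) / 3.0
        roots = [2.0 * mq * math.cos(theta - 2.0 * math.pi * k / 3.0) - shift
                 for k in range(3)]
    out = []
    for z in roots:
        for _ in range(2):  # Newton polish
            f = ((z + c2) * z + c1) * z + c0
            df = (3.0 * z + 2.0 * c2) * z + c1
            if df != 0.0:
                z -= f / df
        out.append(z)
    return sorted(out)


def _z_cubic_coeffs(A: float, B: float, eos: CubicEOSSpec
                    ) -> tuple[float, float, float]:
    s = eos.delta1 + eos.delta2
    p = eos.delta1 * eos.delta2
    c2 = (s - 1.0) * B - 1.0
    c1 = (p - s) * B * B - s * B + A
    c0 = -(p * B ** 3 + p * B * B + A * B)
    return c2, c1, c0


def solve_Z(T: float, P: float, a_mix: float, b_mix: float,
            eos: CubicEOSSpec) -> tuple[list[float], float]:
    """All physical compressibility roots and the supercritical-phase root.

    Physical means v = ZRT/P > b.  The selected root is the largest real
    root; when two candidates nearly coincide the one with lower Gibbs
    energy (smaller mixture fugacity) wins.
    """
    if T <= 0 or P <= 0:
        raise DomainError("T and P must be positive")
    RT = R_CM3_BAR * T
    A = a_mix * P / (RT * RT)
    B = b_mix * P / RT
    roots = _cubic_real_roots(*_z_cubic_coeffs(A, B, eos))
    phys = [z for z in roots if z > B and z > 0.0]
    if not phys:
        raise NonphysicalStateError(
            f"no root with v > b at T={T} K, P={P} bar")
    zsel = max(phys)
    if len(phys) > 1 and (zsel - min(phys)) < 1e-7 * zsel:
        zsel = min(phys,
                   key=lambda z: _lnphi_from_Z(z, A, B, eos))
    return phys, zsel


def _lnphi_from_Z(Z: float, A: float, B: float, eos: CubicEOSSpec) -> float:
    """Mixture (or pure) ln phi from a given root of the cubic."""
    d1, d2 = eos.delta1, eos.delta2
    base = Z - 1.0 - math.log(Z - B)
    if A == 0.0:
        return base
    if B < 1e-14:
        return base - A / Z
    if d1 == d2:
        return base - A / (Z + d1 * B)
    return base + A / ((d1 - d2) * B) * math.log((Z + d2 * B) / (Z + d1 * B))


def lnphi_pure(c: Component, T: float, P: float, eos: CubicEOSSpec) -> float:
    """ln phi of a pure component at (T, P), supercritical-phase root."""
    a, b = pure_params(c, T, eos)
    RT = R_CM3_BAR * T
    A = a * P / (RT * RT)
    B = b * P / RT
    _, Z = solve_Z(T, P, a, b, eos)
    return _lnphi_from_Z(Z, A, B, eos)


# ---------------------------------------------------------------------------
# Mixture state and component fugacities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureState:
    """Resolved mixture state: EOS parameters, root, and fugacities."""

    T: float
    P: float
    x: tuple[float, ...]
    a_mix: float
    b_mix: float
    Z: float
    v: float                      # cm^3/mol
    lnphi: tuple[float, ...]      # per-component ln phi_hat

    @property
    def lnphi_mix(self) -> float:
        return float(np.dot(self.x, self.lnphi))


def lnphi_components(
    T: float, P: float, x: Sequence[float],
    components: Sequence[Component], eos: CubicEOSSpec,
    rule: MixingRuleSpec,
    pure: tuple[Sequence[float], Sequence[float]] | None = None,
) -> MixtureState:
    """Per-component ln phi_hat_i for the mixture at (T, P, x).

    ``pure`` optionally supplies precomputed (a_i, b_i) vectors so that
    regression loops at fixed temperature skip the alpha evaluations.
    """
    x = np.asarray(x, dtype=float)
    if abs(x.sum() - 1.0) > 1e-12:
        raise DomainError("mole fractions must sum to 1")
    if pure is None:
        ab = [pure_params(c, T, eos) for c in components]
        a = np.array([p[0] for p in ab])
        b = np.array([p[1] for p in ab])
    else:
        a = np.asarray(pure[0], dtype=float)
        b = np.asarray(pure[1], dtype=float)

    aij, bij = _pair_matrices(a, b, rule)
    a_mix = float(x @ aij @ x)
    if rule.rule_id == "vdw1":
        b_mix = float(x @ b)
        bbar = b.copy()
    else:
        b_mix = float(x @ bij @ x)
        bbar = 2.0 * (bij @ x) - b_mix
    abar = 2.0 * (aij @ x)

    RT = R_CM3_BAR * T
    A = a_mix * P / (RT * RT)
    B = b_mix * P / RT
    _, Z = solve_Z(T, P, a_mix, b_mix, eos)
    v = Z * RT / P

    d1, d2 = eos.delta1, eos.delta2
    base = (bbar / b_mix) * (Z - 1.0) - math.log(Z - B)
    # attraction contribution, written to stay finite as a_mix -> 0
    g = a_mix * bbar / b_mix - abar        # bar cm^6/mol^2, per component
    if B < 1e-14:
        attr = g * P / (RT * RT * Z)
    elif d1 == d2:
        attr = (g / (b_mix * RT)) * B / (Z + d1 * B)
    else:
        attr = (g / ((d1 - d2) * b_mix * RT)) * math.log(
            (Z + d1 * B) / (Z + d2 * B))
    lnphi = base + attr
    return MixtureState(T=T, P=P, x=tuple(x), a_mix=a_mix, b_mix=b_mix,
                        Z=Z, v=v, lnphi=tuple(lnphi))


def lnphi_solute_binary(T: float, P: float, y: float,
                        aA: float, bA: float, aC: float, bC: float,
                        eos: CubicEOSSpec, rule: MixingRuleSpec) -> float:
    """ln phi_hat of the solute in a binary at solute mole fraction y.

    Scalar fast path for the solubility fixed point: identical mathematics
    to :func:`lnphi_components` restricted to two components and returning
    only the first (solute) fugacity, with no array allocation.  The two
    code paths are cross-checked against each other in the test suite.
    """
    x1, x2 = y, 1.0 - y
    a12 = math.sqrt(aA * aC) * (1.0 - rule.kij)
    a_mix = x1 * x1 * aA + 2.0 * x1 * x2 * a12 + x2 * x2 * aC
    if rule.rule_id == "vdw1":
        b_mix = x1 * bA + x2 * bC
        bbar = bA
    else:
        b12 = 0.5 * (bA + bC) * (1.0 - rule.lij)
        b_mix = x1 * x1 * bA + 2.0 * x1 * x2 * b12 + x2 * x2 * bC
        bbar = 2.0 * (x1 * bA + x2 * b12) - b_mix
    abar = 2.0 * (x1 * aA + x2 * a12)

    RT = R_CM3_BAR * T
    A = a_mix * P / (RT * RT)
    B = b_mix * P / RT
    roots = _cubic_real_roots(*_z_cubic_coeffs(A, B, eos))
    Z = -1.0
    for z in roots:
        if z > B and z > 0.0 and z > Z:
            Z = z
    if Z < 0.0:
        raise NonphysicalStateError(
            f"no root with v > b at T={T} K, P={P} bar")

    d1, d2 = eos.delta1, eos.delta2
    base = (bbar / b_mix) * (Z - 1.0) - math.log(Z - B)
    g = a_mix * bbar / b_mix - abar
    if B < 1e-14:
        return base + g * P / (RT * RT * Z)
    if d1 == d2:
        return base + (g / (b_mix * RT)) * B / (Z + d1 * B)
    return base + (g / ((d1 - d2) * b_mix * RT)) * math.log(
        (Z + d1 * B) / (Z + d2 * B))
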
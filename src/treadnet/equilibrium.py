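"""Equilibrium network length from the two coupled feedbacks.

Two relations tie the treadmilling length L to the mean bound-cofilin density
CB.  Disassembly shortens long, cofilin-rich networks:

    L = k1 * A0**alpha * V / CB**beta                      (disassembly feedback)

while binding loads cofilin onto longer networks, attenuated by local
depletion of the free pool:

    CB = k2 * rB * A0 * C0 * (L / V) * D / (rB * A0 * W * L + D)   (binding feedback)

The first is decreasing in L, the second increasing and saturating, so the
curves cross exactly once: every parameter combination has a unique
equilibrium (L*, CB*).  For the standard exponents alpha = 2, beta = 1 the
intersection is the positive root of a quadratic, which this module uses as
the closed form and cross-checks with a bracketing root search.

The strength of depletion is summarized by the dimensionless number
``rB * A0 * W * L / D``: below ~1 depletion is negligible; values of 10-100
(keratocyte-scale lamellipodia) mean the free pool near the network is mostly
consumed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .transport import CofilinKinetics

__all__ = [
    "EquilibriumParams",
    "EquilibriumSolution",
    "feedback_curves",
    "solve_equilibrium",
    "depletion_number",
    "depletion_limit_length",
    "length_phase_map",
    "compensate",
]


@dataclass(frozen=True)
class EquilibriumParams:
    """Feedback-model parameters.

    k1 (s/µM) sets the magnitude of the effective debranching/severing rate;
    k2 (dimensionless) absorbs the geometric prefactor of the binding
    estimate.  The generalized exponents default to the standard alpha = 2,
    beta = 1.
    """

    k1: float = 1.0
    k2: float = 0.5
    alpha: float = 2.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


@dataclass(frozen=True)
class EquilibriumSolution:
    """The unique intersection (L*, CB*) of the two feedback curves."""

    L_star: float
    CB_star: float
    depletion_factor: float


def _check_positive(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")


def disassembly_curve(L, A0: float, V: float, params: EquilibriumParams):
    """CB(L) implied by the disassembly relation, ``(k1 A0^alpha V / L)^(1/beta)``."""
    L = np.asarray(L, dtype=float)
    out = (params.k1 * A0**params.alpha * V / L) ** (1.0 / params.beta)
    return out if out.ndim else float(out)


def binding_curve(L, A0: float, V: float, C0: float, W: float,
                  kinetics: CofilinKinetics, params: EquilibriumParams):
    """CB(L) implied by cofilin binding with depletion: increasing, saturating."""
    L = np.asarray(L, dtype=float)
    rB, D = kinetics.rB, kinetics.D
    out = params.k2 * rB * A0 * C0 * (L / V) * D / (rB * A0 * W * L + D)
    return out if out.ndim else float(out)


def feedback_curves(L_grid, A0: float, V: float, C0: float, W: float,
                    kinetics: CofilinKinetics,
                    params: EquilibriumParams = EquilibriumParams()
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Both CB(L) curves on a length grid (µM): (disassembly, binding)."""
    L_grid = np.asarray(L_grid, dtype=float)
    if np.any(L_grid <= 0):
        raise ValueError("L grid must be positive")
    return (disassembly_curve(L_grid, A0, V, params),
            binding_curve(L_grid, A0, V, C0, W, kinetics, params))


def solve_equilibrium(A0: float, V: float, C0: float, W: float,
                      kinetics: CofilinKinetics,
                      params: EquilibriumParams = EquilibriumParams(),
                      method: str = "auto") -> EquilibriumSolution:
    """Solve the two-feedback system for (L*, CB*).

    For alpha = 2, beta = 1 the system reduces to the quadratic

        (k2 rB A0 C0 D / V) L**2 - k1 A0**2 V rB A0 W L - k1 A0**2 V D = 0,

    whose single positive root is returned (``method="closed"``).  Any
    exponent pair is handled by a bracketing root search on the difference of
    the two curves (``method="numeric"``); ``"auto"`` picks the closed form
    when it applies.
    """
    _check_positive(A0=A0, V=V, C0=C0, W=W)
    if kinetics.rB <= 0 or kinetics.D <= 0 or C0 <= 0:
        raise ValueError("rB, D and C0 must be positive for an equilibrium")
    rB, D = kinetics.rB, kinetics.D

    closed_ok = params.alpha == 2.0 and params.beta == 1.0
    if method == "auto":
        method = "closed" if closed_ok else "numeric"
    if method == "closed":
        if not closed_ok:
            raise ValueError("closed form requires alpha=2, beta=1")
        qa = params.k2 * rB * A0 * C0 * D / V
        qb = -params.k1 * A0**2 * V * rB * A0 * W
        qc = -params.k1 * A0**2 * V * D
        L = (-qb + math.sqrt(qb**2 - 4 * qa * qc)) / (2 * qa)
    elif method == "numeric":
        def diff(L):
            return (disassembly_curve(L, A0, V, params)
                    - binding_curve(L, A0, V, C0, W, kinetics, params))
        lo, hi = 1e-9, 1.0
        while diff(hi) > 0:
            hi *= 2
            if hi > 1e12:
                raise RuntimeError("failed to bracket the equilibrium length")
        L = brentq(diff, lo, hi, xtol=1e-14, rtol=1e-12)
    else:
        raise ValueError(f"unknown method {method!r}")

    CB = binding_curve(L, A0, V, C0, W, kinetics, params)
    dep = kinetics.D / (rB * A0 * W * L + kinetics.D)
    return EquilibriumSolution(L_star=float(L), CB_star=float(CB), depletion_factor=float(dep))


def depletion_number(rB: float, A0: float, W: float, L: float, D: float) -> float:
    """Dimensionless depletion strength ``rB * A0 * W * L / D``.

    Values well below 1 mean diffusion keeps the free pool topped up; values
    of 10-100 mean severe local depletion.
    """
    if min(rB, A0, W, L) < 0:
        raise ValueError("inputs must be nonnegative")
    if D <= 0:
        raise ValueError("D must be positive")
    return rB * A0 * W * L / D


def depletion_limit_length(A0: float, V: float, C0: float, W: float,
                           kinetics: CofilinKinetics,
                           params: EquilibriumParams = EquilibriumParams()) -> float:
    """Equilibrium length in the strong-depletion limit.

    When depletion dominates, the binding curve saturates at
    ``CB ~ k2 * D * C0 / (V * W)``; substituting into the disassembly relation
    gives ``L ~ (k1 / k2) * A0**alpha * V**(1+beta) ... `` which for the
    standard exponents is ``(k1/k2) * A0**2 * V**2 * W / (D * C0)`` — linear in
    W and quadratic in A0.  Warns when the depletion number at that length is
    not actually large.
    """
    _check_positive(A0=A0, V=V, C0=C0, W=W)
    CB_lim = params.k2 * kinetics.D * C0 / (V * W)
    L = params.k1 * A0**params.alpha * V / CB_lim**params.beta
    dn = depletion_number(kinetics.rB, A0, W, L, kinetics.D)
    if dn < 10:
        warnings.warn(f"depletion number {dn:.2g} is not >> 1; the strong-depletion "
                      "limit is a poor approximation here", stacklevel=2)
    return L


def length_phase_map(vary: tuple[str, str], grid1: Iterable[float],
                     grid2: Iterable[float], fixed: dict,
                     kinetics: CofilinKinetics,
                     params: EquilibriumParams = EquilibriumParams()) -> np.ndarray:
    """Matrix of equilibrium lengths over a two-parameter sweep.

    ``vary`` names the two swept parameters, each of "C0", "A0" or "W";
    ``fixed`` supplies the remaining ones of (A0, V, C0, W).  Entry [i, j]
    corresponds to ``grid1[i]``, ``grid2[j]``.
    """
    allowed = {"C0", "A0", "W"}
    if not set(vary) <= allowed or vary[0] == vary[1]:
        raise ValueError(f"vary must be two distinct names from {allowed}")
    g1 = list(grid1)
    g2 = list(grid2)
    out = np.empty((len(g1), len(g2)))
    for i, v1 in enumerate(g1):
        for j, v2 in enumerate(g2):
            kw = dict(fixed)
            kw[vary[0]] = v1
            kw[vary[1]] = v2
            out[i, j] = solve_equilibrium(kinetics=kinetics, params=params, **kw).L_star
    return out


def compensate(target_L: float, adjust: str, fixed: dict,
               kinetics: CofilinKinetics,
               params: EquilibriumParams = EquilibriumParams(),
               bracket: tuple[float, float] = (1e-6, 1e6)) -> float:
    """Invert the solver: find the value of one control parameter giving target_L.

    Supports the compensation workflow: after a perturbation (say a drop in
    A0), find the C0 to decrease — or the W to increase — that restores the
    original length.  ``adjust`` is "C0" or "W"; ``fixed`` holds the other
    three of (A0, V, C0, W).
    """
    if adjust not in ("C0", "W"):
        raise ValueError("adjust must be 'C0' or 'W'")
    _check_positive(target_L=target_L)

    def diff(val):
        kw = dict(fixed)
        kw[adjust] = val
        return solve_equilibrium(kinetics=kinetics, params=params, **kw).L_star - target_L

    lo, hi = bracket
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo * f_hi > 0:
        raise ValueError("target length not reachable within the bracket")
    return brentq(diff, lo, hi, xtol=1e-12, rtol=1e-12)
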
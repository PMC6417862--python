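"""Steering of heterogeneous actin networks modeled as coupled elastic beams.

Two sub-networks ("lanes") of equal width W grow side by side at speeds V1 and
V2 with elastic moduli E1 and E2.  Because they are mechanically attached, a
speed mismatch forces the pair onto a circular arc — always bending toward the
slower lane — with radius

    R = W * [ (V1+V2)/(V1-V2) + (sigma-1)(V1*sigma - V2) / (4*sigma*(V1-V2)) ]

and combined elongation speed

    Vh = (V1+V2)/2 - (V1-V2)(V1^2 sigma^2 - V2^2) / (2 (V1^2 sigma^2 + 6 V1 V2 sigma + V2^2)),

where sigma = E2/E1.  Elasticity is tied to actin density through
E ~ A**tau (tau ~ 2.5 for random isotropic meshes; ~0.5 has been reported for
branched arrays — predictions are not very sensitive to the choice).

ADF/Cofilin enters in two ways: the lanes compete for the same free-cofilin
pool, so their equilibrium lengths must be solved jointly with a shared
depletion factor; and the density profiles A_i(y) decay toward each lane's
trailing edge, making sigma — hence the local curvature — a function of the
distance from the leading edge.  Past the shorter lane's trailing edge the
survivor grows straight, which is how raising the cofilin concentration
straightens (or, in symmetric multi-lane patterns, induces) steering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .equilibrium import EquilibriumParams, solve_equilibrium
from .transport import CofilinKinetics

__all__ = [
    "ElasticBeamPair",
    "ShapeCurve",
    "elasticity_ratio",
    "curvature_radius",
    "combined_speed",
    "coupled_equilibrium_lengths",
    "heterogeneous_shape",
]

STRAIGHT = math.inf


@dataclass(frozen=True)
class ElasticBeamPair:
    """Two side-by-side growing sub-networks.

    Speeds V1, V2 (µm/s), leading-edge densities A1, A2 (µM), lane width W
    (µm) and the elasticity-density exponent tau.  The elastic-modulus ratio
    sigma = E2/E1 = (A2/A1)**tau is derived from the densities.
    """

    V1: float
    V2: float
    A1: float
    A2: float
    W: float
    tau: float = 2.5

    def __post_init__(self) -> None:
        if min(self.V1, self.V2, self.A1, self.A2, self.W) <= 0:
            raise ValueError("speeds, densities and width must be positive")

    @property
    def sigma(self) -> float:
        return elasticity_ratio(self.A1, self.A2, self.tau)


@dataclass
class ShapeCurve:
    """Simulated centerline of a heterogeneous network.

    Curvature is reported as a magnitude ``kappa >= 0`` plus a turn direction
    ("lane1" / "lane2" / "straight"); ``mean_curvature_radius`` is the inverse
    of the arclength-weighted mean curvature over the whole centerline, so a
    straight tail dilutes the mean and enlarges the reported radius.
    """

    s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    kappa: np.ndarray
    turn_direction: str
    Vh: float
    mean_curvature_radius: float


def elasticity_ratio(A1: float, A2: float, tau: float = 2.5) -> float:
    """sigma = E2/E1 = (A2/A1)**tau from the elasticity-density scaling E ~ A**tau."""
    if A1 <= 0 or A2 <= 0:
        raise ValueError("densities must be positive")
    return (A2 / A1) ** tau


def curvature_radius(W: float, V1: float, V2: float, sigma: float
                     ) -> tuple[float, str]:
    """Radius of the circular arc a mismatched beam pair settles on.

    Returns ``(R, direction)`` with R in µm (``inf`` for matched speeds) and
    the direction the pair bends, always toward the slower lane.  For equal
    elasticity (sigma = 1) the bracket collapses to the simple geometric
    result R = W (V1+V2)/(V1-V2).
    """
    if W <= 0 or V1 <= 0 or V2 <= 0 or sigma <= 0:
        raise ValueError("W, V1, V2 and sigma must be positive")
    if V1 == V2:
        return STRAIGHT, "straight"
    R = W * ((V1 + V2) / (V1 - V2)
             + (sigma - 1.0) * (V1 * sigma - V2) / (4.0 * sigma * (V1 - V2)))
    direction = "lane2" if V1 > V2 else "lane1"
    return abs(R), direction


def combined_speed(V1: float, V2: float, sigma: float) -> float:
    """Elongation speed of the coupled pair (µm/s), slightly below the mean speed."""
    if V1 <= 0 or V2 <= 0 or sigma <= 0:
        raise ValueError("V1, V2 and sigma must be positive")
    num = (V1 - V2) * (V1**2 * sigma**2 - V2**2)
    den = 2.0 * (V1**2 * sigma**2 + 6.0 * V1 * V2 * sigma + V2**2)
    return (V1 + V2) / 2.0 - num / den


def coupled_equilibrium_lengths(lane1: tuple[float, float], lane2: tuple[float, float],
                                C0: float, W1: float, W2: float,
                                kinetics: CofilinKinetics,
                                params: EquilibriumParams = EquilibriumParams()
                                ) -> tuple[float, float]:
    """Joint equilibrium lengths of two lanes sharing one free-cofilin pool.

    Each lane obeys its own disassembly relation L_i = k1 A_i**2 V_i / CB_i,
    but the binding relations share a single depletion factor
    ``D / (rB (A1 W1 L1 + A2 W2 L2) + D)``.  Substituting the first into the
    second reduces the system to one scalar equation: with
    K_i = V_i sqrt(k1 A_i / (k2 rB C0)), both lengths are L_i = K_i * s where
    s solves s**2 - b s - 1 = 0, b = rB (A1 W1 K1 + A2 W2 K2) / D.  Because b
    grows when the partner lane is added, both joint lengths exceed the
    isolated ones, and the sparser lane — whose own depletion is weakest —
    gains the most in relative terms.

    ``lane1``/``lane2`` are (A0, V) pairs.  Requires the standard exponents
    alpha = 2, beta = 1.
    """
    if params.alpha != 2.0 or params.beta != 1.0:
        raise ValueError("coupled closed form requires alpha=2, beta=1")
    (A1, V1), (A2, V2) = lane1, lane2
    if min(A1, V1, A2, V2, C0, W1, W2) <= 0:
        raise ValueError("all parameters must be positive")
    rB, D = kinetics.rB, kinetics.D
    K1 = V1 * math.sqrt(params.k1 * A1 / (params.k2 * rB * C0))
    K2 = V2 * math.sqrt(params.k1 * A2 / (params.k2 * rB * C0))
    b = rB * (A1 * W1 * K1 + A2 * W2 * K2) / D
    s = (b + math.sqrt(b * b + 4.0)) / 2.0
    return K1 * s, K2 * s


def heterogeneous_shape(pair: ElasticBeamPair,
                        A1_profile: Callable[[float], float] | None = None,
                        A2_profile: Callable[[float], float] | None = None,
                        L1: float = math.inf, L2: float = math.inf,
                        ds: float = 0.25,
                        total_length: float | None = None) -> ShapeCurve:
    """Integrate the centerline of a growing heterogeneous network.

    At arclength s from the leading edge the local elasticity ratio is
    ``sigma(s) = (A2(s)/A1(s))**tau`` (profiles default to the constant lane
    densities) and the local curvature follows :func:`curvature_radius`.
    Beyond the shorter lane's trailing edge ``min(L1, L2)`` the surviving lane
    grows straight (curvature exactly zero).  The centerline is integrated to
    ``total_length`` (default: ``max(L1, L2)``, which must then be finite).
    """
    A1_fn = A1_profile if A1_profile is not None else (lambda s: pair.A1)
    A2_fn = A2_profile if A2_profile is not None else (lambda s: pair.A2)
    if total_length is None:
        total_length = max(L1, L2)
    if not math.isfinite(total_length) or total_length <= 0:
        raise ValueError("total integration length must be finite and positive")
    if ds <= 0:
        raise ValueError("ds must be positive")

    n = int(math.ceil(total_length / ds))
    s_nodes = np.linspace(0.0, total_length, n + 1)
    kappa = np.zeros(n + 1)
    L_short = min(L1, L2)
    straight = pair.V1 == pair.V2
    for k, s_k in enumerate(s_nodes):
        if s_k >= L_short or straight:
            continue
        a1, a2 = A1_fn(s_k), A2_fn(s_k)
        if a1 <= 0 or a2 <= 0:
            raise ValueError("density profiles must stay positive inside the lanes")
        sig = (a2 / a1) ** pair.tau
        R, _ = curvature_radius(pair.W, pair.V1, pair.V2, sig)
        kappa[k] = 0.0 if math.isinf(R) else 1.0 / R

    direction = ("straight" if straight
                 else ("lane2" if pair.V1 > pair.V2 else "lane1"))
    # grow along +y, bend toward the slower lane; lane1 on the left (-x)
    sign = 0.0 if straight else (-1.0 if direction == "lane1" else 1.0)
    theta = np.concatenate([[0.0], np.cumsum(0.5 * (kappa[1:] + kappa[:-1])
                                             * np.diff(s_nodes))]) * sign
    x = np.concatenate([[0.0], np.cumsum(np.sin(theta[:-1] + np.diff(theta) / 2)
                                         * np.diff(s_nodes))])
    y = np.concatenate([[0.0], np.cumsum(np.cos(theta[:-1] + np.diff(theta) / 2)
                                         * np.diff(s_nodes))])

    mean_kappa = np.trapezoid(kappa, s_nodes) / total_length
    mean_R = math.inf if mean_kappa == 0 else 1.0 / mean_kappa
    return ShapeCurve(s=s_nodes, x=x, y=y, kappa=kappa, turn_direction=direction,
                      Vh=combined_speed(pair.V1, pair.V2, pair.sigma),
                      mean_curvature_radius=mean_R)
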
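"""Stochastic fragmentation of the actin network at the trailing edge.

The branched network is idealized as a square lattice: nodes are effective
crosslinking/branching points, edges are actin-filament arrays connecting
them.  Bound ADF/Cofilin removes nodes stochastically at a rate that grows
with the bound-cofilin density and falls with the *local* actin density,

    P = k_break * CB**beta / A_local**alpha      (defaults beta=1, alpha=2),

so that a local thinning of the network accelerates further breakage — the
positive feedback behind the avalanche-like collapse at the trailing edge.
Pieces disconnected from the leading edge diffuse away and are deleted, which
is why the network disassembles by macroscopic fragmentation rather than
erosion.  After an initial growth phase the length fluctuates around an
equilibrium, and a continuum mean-field treatment of the broken-node fraction
reproduces the scaling L ~ V * A0**alpha / CB**beta.

Row 0 of the lattice is the leading edge; fresh, fully intact, fully dense
rows are prepended there as the network grows at speed V, so row index times
the lattice spacing is the distance y from the leading edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label

__all__ = [
    "LatticeNetwork",
    "FragmentationParams",
    "ContinuumParams",
    "EquilibriumTrajectory",
    "build_lattice",
    "local_density",
    "node_breakage_rate",
    "advance_network",
    "run_to_equilibrium",
    "continuum_prediction",
    "calibrate_continuum",
]


@dataclass
class LatticeNetwork:
    """Square-lattice network state.

    ``intact`` has shape (rows, cols); row 0 is the leading edge.  Edges exist
    between 4-adjacent intact nodes.  ``A0`` is the actin density (µM) that a
    fully intact region maps to; ``a`` is the lattice spacing (µm).
    """

    intact: np.ndarray
    a: float
    A0: float
    growth_carry: float = 0.0  # accumulated sub-row growth (µm)

    @property
    def n_rows(self) -> int:
        return self.intact.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intact.shape[1]

    def length(self, min_occupancy: float = 0.0) -> float:
        """Distance from the leading edge to the trailing edge (µm).

        With ``min_occupancy = 0`` the trailing edge is the furthest row holding
        any intact node.  A positive fraction (e.g. 0.1) ignores straggler
        chains thinner than that share of the columns, mimicking how a length
        is read off a fluorescence image where a lone node is invisible.
        """
        occ = self.intact.mean(axis=1)
        thr = max(min_occupancy, 0.5 / self.n_cols)
        rows = np.flatnonzero(occ >= thr) if min_occupancy > 0 else \
            np.flatnonzero(self.intact.any(axis=1))
        return 0.0 if rows.size == 0 else float((rows[-1] + 1) * self.a)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Horizontal and vertical intact-edge indicator arrays."""
        g = self.intact
        horiz = g[:, :-1] & g[:, 1:]
        vert = g[:-1, :] & g[1:, :]
        return horiz, vert


@dataclass(frozen=True)
class FragmentationParams:
    """Node-breakage law parameters.

    ``k_break`` is the rate prefactor, chosen so P is in 1/s when CB and A are
    in µM (units µM**(alpha-beta)/s for the default exponents).  The local
    density is a uniform-disc average of intact edges within ``kernel_radius``
    of a node (default 2 lattice spacings).  ``density_floor_frac`` marks the
    fraction of A0 below which a node is considered effectively disconnected:
    its breakage probability saturates toward 1 within a step and it is
    excluded from the time-step resolution contract dt * P <= 0.2.
    """

    alpha: float = 2.0
    beta: float = 1.0
    k_break: float = 0.25
    kernel_radius_factor: float = 2.0  # in units of the lattice spacing
    dt: float | None = None  # None: auto, 0.2 / (breakage rate at the density floor)
    density_floor_frac: float = 0.2

    def resolve_dt(self, A0: float, CB_max: float) -> float:
        """Auto time step honouring dt * P <= 0.2 down to the density floor."""
        if self.dt is not None:
            return self.dt
        floor = self.density_floor_frac * A0
        p_floor = self.k_break * CB_max**self.beta / floor**self.alpha
        return 0.2 / p_floor if p_floor > 0 else 10.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("exponents must be nonnegative")
        if self.k_break < 0:
            raise ValueError("k_break must be nonnegative")
        if self.kernel_radius_factor < 1.0:
            raise ValueError("kernel radius must be at least one lattice spacing")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class ContinuumParams:
    """Mean-field closure: critical broken-node fraction q_c and prefactor c."""

    q_c: float = 0.4
    c: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.q_c < 1:
            raise ValueError("q_c must lie in (0, 1)")
        if self.c <= 0:
            raise ValueError("c must be positive")


def build_lattice(W: float, initial_L: float, a: float, A0: float) -> LatticeNetwork:
    """A fully intact lattice of width W and length initial_L (µm)."""
    if W <= 0 or a <= 0:
        raise ValueError("W and a must be positive")
    if W / a < 4:
        raise ValueError("need at least 4 columns across the width")
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    n_cols = int(round(W / a))
    n_rows = max(1, int(round(initial_L / a)))
    return LatticeNetwork(intact=np.ones((n_rows, n_cols), dtype=bool), a=a, A0=A0)


def local_density(lattice: LatticeNetwork, node: tuple[int, int] | None = None,
                  kernel_radius_factor: float = 2.0):
    """Local actin density (µM) as a kernel-weighted count of nearby intact edges.

    The count is normalized by the same kernel applied to an all-intact lattice
    of the same extent, so a fresh lattice maps to A0 everywhere (including at
    the lattice borders) and removing half the edges in a node's kernel halves
    its density.  With ``node=None`` the full (rows, cols) density field is
    returned.
    """
    horiz, vert = lattice.edge_arrays()

    # accumulate, for every node, the intact edges whose midpoint falls inside
    # the disc, and the capacity (all lattice edge slots in the disc); a
    # horizontal edge (j, i) connects nodes (j, i)-(j, i+1), a vertical edge
    # (j, i) connects (j, i)-(j+1, i).
    rows, cols = lattice.intact.shape
    cnt = np.zeros((rows, cols))
    cap = np.zeros((rows, cols))
    ones_h = np.ones_like(horiz, dtype=float)
    ones_v = np.ones_like(vert, dtype=float)

    r = kernel_radius_factor
    n = int(math.floor(r + 1))
    offs = range(-n, n + 1)
    h_f = horiz.astype(float)
    v_f = vert.astype(float)
    for dj in offs:
        for di in offs:
            if (dj**2 + (di + 0.5) ** 2) <= r**2 + 1e-12:
                _acc_shift(cnt, h_f, dj, di)
                _acc_shift(cap, ones_h, dj, di)
            if ((dj + 0.5) ** 2 + di**2) <= r**2 + 1e-12:
                _acc_shift(cnt, v_f, dj, di)
                _acc_shift(cap, ones_v, dj, di)

    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(cap > 0, cnt / cap, 0.0) * lattice.A0
    if node is None:
        return dens
    j, i = node
    if not (0 <= j < rows and 0 <= i < cols):
        raise IndexError("node outside the lattice")
    return float(dens[j, i])


def _acc_shift(acc: np.ndarray, arr: np.ndarray, dj: int, di: int) -> None:
    """acc[j, i] += arr[j + dj, i + di] where defined (edge array may be smaller)."""
    rows, cols = acc.shape
    er, ec = arr.shape
    j0, j1 = max(0, -dj), min(rows, er - dj)
    i0, i1 = max(0, -di), min(cols, ec - di)
    if j0 >= j1 or i0 >= i1:
        return
    acc[j0:j1, i0:i1] += arr[j0 + dj:j1 + dj, i0 + di:i1 + di]


def node_breakage_rate(A_local, CB: float, params: FragmentationParams):
    """Per-node breakage rate k_break * CB**beta / A_local**alpha (1/s).

    Vectorized over ``A_local``.  Nodes with zero local density (isolated
    remnants) are effectively instantaneously breakable: their rate is
    returned as +inf and the sampling layer turns that into probability 1.
    """
    A_arr = np.asarray(A_local, dtype=float)
    num = params.k_break * CB**params.beta
    with np.errstate(divide="ignore"):
        rate = np.where(A_arr > 0, num / np.maximum(A_arr, 1e-300)**params.alpha,
                        np.inf if num > 0 else 0.0)
    return rate if rate.ndim else float(rate)


def advance_network(lattice: LatticeNetwork, params: FragmentationParams,
                    CB, V: float, dt: float, rng: np.random.Generator
                    ) -> list[int]:
    """One time step: grow, break nodes, prune disconnected fragments.

    ``CB`` is either a scalar (spatially constant bound cofilin, the standard
    simplification) or a callable CB(y) evaluated at each row's distance from
    the leading edge.  Returns the list of pruned fragment sizes (node counts).
    The step contract dt * P <= 0.2 is enforced for nodes above the density
    floor; below it the node is treated as instantaneously breakable.
    """
    # --- growth: prepend fully intact rows at the leading edge
    lattice.growth_carry += V * dt
    n_new = int(math.floor(lattice.growth_carry / lattice.a + 1e-12))
    if n_new > 0:
        lattice.growth_carry -= n_new * lattice.a
        fresh = np.ones((n_new, lattice.n_cols), dtype=bool)
        lattice.intact = np.vstack([fresh, lattice.intact])

    if not lattice.intact.any():
        return []

    # --- breakage
    dens = local_density(lattice, kernel_radius_factor=params.kernel_radius_factor)
    if callable(CB):
        y_rows = (np.arange(lattice.n_rows) * lattice.a)
        CB_grid = np.asarray(CB(y_rows), dtype=float)[:, None]
    else:
        CB_grid = float(CB)
    rate = node_breakage_rate(dens, 1.0, params) * np.power(CB_grid, params.beta)

    floor = params.density_floor_frac * lattice.A0
    resolved = lattice.intact & (dens >= floor)
    max_rate = rate[resolved].max() if resolved.any() else 0.0
    if dt * max_rate > 0.2 + 1e-9:
        raise ValueError(
            f"dt * max(P) = {dt * max_rate:.3f} > 0.2; reduce dt to resolve breakage")

    with np.errstate(over="ignore"):
        p = 1.0 - np.exp(-np.clip(rate, 0.0, 1e6) * dt)
    p = np.where(np.isfinite(rate), p, 1.0)
    breaks = lattice.intact & (rng.random(lattice.intact.shape) < p)
    lattice.intact &= ~breaks

    # --- prune everything not connected to the leading-edge row
    return _prune(lattice)


def _prune(lattice: LatticeNetwork) -> list[int]:
    labels, n_lab = label(lattice.intact)  # 4-connectivity by default
    if n_lab == 0:
        return []
    anchored = np.unique(labels[0, :])
    anchored = anchored[anchored > 0]
    sizes = np.bincount(labels.ravel(), minlength=n_lab + 1)
    removed = [int(sizes[k]) for k in range(1, n_lab + 1) if k not in set(anchored)]
    keep = np.isin(labels, anchored) & (labels > 0)
    lattice.intact &= keep
    # trim far-trailing broken rows, but keep a margin of vacated rows so the
    # local-density kernel sees the empty space behind the trailing edge
    margin = 4
    rows = np.flatnonzero(lattice.intact.any(axis=1))
    if rows.size and rows[-1] + 1 + margin < lattice.n_rows:
        lattice.intact = lattice.intact[: rows[-1] + 1 + margin, :]
    return removed


@dataclass
class EquilibriumTrajectory:
    """Result of :func:`run_to_equilibrium`."""

    times: np.ndarray
    lengths: np.ndarray
    fragment_sizes: list[int]
    profile_y: np.ndarray  # distances scaled to the mean equilibrium length
    profile_A: np.ndarray  # mean density profile, aligned per-snapshot to L(t)
    transient_end: float | None
    reached_equilibrium: bool
    length_mean: float | None
    length_std: float | None


def run_to_equilibrium(W: float, V: float, A0: float, CB, params: FragmentationParams,
                       T: float, seed: int, a: float = 0.5,
                       record_every: int = 1,
                       min_row_occupancy: float = 0.1) -> EquilibriumTrajectory:
    """Grow a lattice network under breakage until it treadmills, and summarize.

    The transient is diagnosed, not assumed: its end is the first time the
    length retreats by more than two lattice rows from its running maximum
    (the first macroscopic fragmentation); the equilibrium window starts at
    twice that time.  If no retreat happens within T the trajectory is flagged
    as not equilibrated and the summary statistics are None.
    """
    rng = np.random.default_rng(seed)
    lattice = build_lattice(W, a, a, A0)  # start one row long
    CB_max = CB if not callable(CB) else float(np.max(CB(np.linspace(0, 10 * W, 256))))
    dt = params.resolve_dt(A0, CB_max)
    if V > 0:
        dt = min(dt, a / V)  # resolve growth row by row
    n_steps = int(math.ceil(T / dt))
    times, lengths = [], []
    fragments: list[int] = []
    profile_acc: dict[int, tuple[np.ndarray, int]] = {}
    prof_sum = None
    prof_n = 0

    xi = np.linspace(0.0, 1.2, 61)  # normalized distance y / L(t)
    retreat_t = None
    run_max = 0.0
    for step in range(n_steps):
        t = (step + 1) * dt
        fragments.extend(advance_network(lattice, params, CB, V, dt, rng))
        L = lattice.length(min_row_occupancy)
        if retreat_t is None:
            if L > run_max:
                run_max = L
            elif run_max - L > 2 * a:
                retreat_t = t
        if step % record_every == 0:
            times.append(t)
            lengths.append(L)
        # accumulate the mean density profile once past the transient; each
        # snapshot is rescaled to its own instantaneous length before
        # averaging, so the sharp trailing-edge drop is not smeared by the
        # length fluctuations
        if retreat_t is not None and t >= 2 * retreat_t and step % (5 * record_every) == 0 \
                and L > 0:
            dens = local_density(lattice, kernel_radius_factor=params.kernel_radius_factor)
            row_mean = np.where(lattice.intact, dens, 0.0).sum(axis=1) / lattice.n_cols
            y_rows = np.arange(row_mean.size) * a
            snap = np.interp(xi * L, y_rows, row_mean, right=0.0)
            if prof_sum is None:
                prof_sum = np.zeros_like(snap)
            prof_sum += snap
            prof_n += 1

    times = np.asarray(times)
    lengths = np.asarray(lengths)
    reached = retreat_t is not None and 2 * retreat_t < T
    if reached:
        window = times >= 2 * retreat_t
        l_mean = float(lengths[window].mean())
        l_std = float(lengths[window].std(ddof=1)) if window.sum() > 1 else 0.0
    else:
        l_mean = l_std = None
    if prof_sum is not None and prof_n > 0 and l_mean is not None:
        profile_A = prof_sum / prof_n
        profile_y = xi * l_mean
    else:
        profile_A = np.array([])
        profile_y = np.array([])
    return EquilibriumTrajectory(times=times, lengths=lengths, fragment_sizes=fragments,
                                 profile_y=profile_y, profile_A=profile_A,
                                 transient_end=retreat_t, reached_equilibrium=reached,
                                 length_mean=l_mean, length_std=l_std)


def continuum_prediction(V: float, A0: float, CB: float, params: FragmentationParams,
                         cont: ContinuumParams,
                         y: np.ndarray | None = None
                         ) -> tuple[float, np.ndarray | None]:
    """Mean-field equilibrium length and density profile.

    The broken-node fraction q(y) of material that has drifted a distance y
    accumulates as V dq/dy = P(A0, CB) (1 - q) with q(0) = 0, so
    q(y) = 1 - exp(-P y / V).  The network end is where q reaches the critical
    fraction q_c, giving

        L = c * ln(1/(1 - q_c)) * V * A0**alpha / (k_break * CB**beta).

    The density profile is A0 * (1 - q(y)) up to L — near-flat, then the
    avalanche collapse truncates it to zero.  Returns (L, A(y)) with A(y)
    evaluated on ``y`` if given, else None.
    """
    if CB <= 0:
        raise ValueError("no finite equilibrium: CB must be positive")
    P0 = params.k_break * CB**params.beta / A0**params.alpha
    L = cont.c * math.log(1.0 / (1.0 - cont.q_c)) * V / P0
    profile = None
    if y is not None:
        y = np.asarray(y, dtype=float)
        q = 1.0 - np.exp(-P0 * y / V)
        profile = np.where(y <= L, A0 * (1.0 - q), 0.0)
    return L, profile


def calibrate_continuum(stochastic_mean_length: float, V: float, A0: float, CB: float,
                        params: FragmentationParams,
                        cont: ContinuumParams = ContinuumParams()) -> ContinuumParams:
    """Fix the continuum prefactor c so the prediction matches one stochastic mean."""
    L_raw, _ = continuum_prediction(V, A0, CB, params, ContinuumParams(q_c=cont.q_c, c=1.0))
    return ContinuumParams(q_c=cont.q_c, c=stochastic_mean_length / L_raw)
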
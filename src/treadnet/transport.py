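"""Reaction–advection–diffusion model of ADF/Cofilin around a growing actin network.

Two concentration fields live on a flat 2D chamber: free ADF/Cofilin ``CF(x, y, t)``
diffuses in the solute, bound ADF/Cofilin ``CB(x, y, t)`` rides on the network
material, which drifts away from the (stationary) leading edge at the growth
speed ``V``.  Inside the network mask the two fields exchange through binding
(``rB * A * CF``) and slow unbinding (``rU * CB``)::

    dCB/dt = -V dCB/dy + rB * A * CF - rU * CB
    dCF/dt =  D lap(CF) - rB * A * CF + rU * CB

The module also carries the closed-form "simple model" of cofilin loading
(``CB = kB * C0 * A * y / V``, no depletion) and a quasi-steady estimate of the
free concentration near the network, used as an order-of-magnitude oracle for
the full simulation.

Conventions: concentrations in µM, lengths in µm, times in s.  The leading edge
is a fixed horizontal line; the network occupies a ``W x L(t)`` rectangle below
it (+y is the drift direction) and elongates as ``L(t) = V * t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import coo_matrix, lil_matrix
from scipy.sparse.linalg import splu

__all__ = [
    "CofilinKinetics",
    "NetworkGeometry",
    "ActinProfile",
    "ThresholdModel",
    "GridSpec",
    "ChamberField",
    "ChamberSeries",
    "simple_bound_profile",
    "simple_equilibrium_length",
    "quasi_steady_estimate",
    "simulate_chamber",
    "depletion_timecourse",
]


@dataclass(frozen=True)
class CofilinKinetics:
    """Kinetic parameters of ADF/Cofilin.

    Parameters
    ----------
    C0 : float
        Initial (far-field) free ADF/Cofilin concentration, µM.
    D : float
        Diffusion coefficient of free ADF/Cofilin, µm²/s.
    rB : float
        Binding rate constant, 1/(s·µM).  The simple closed-form model calls
        this quantity ``kB``; it is the same number.
    rU : float
        Unbinding rate, 1/s.
    diffusion_correction : float
        Dimensionless factor applied to ``D`` inside the network, in (0, 1].
        Steric hindrance by even a dense network reduces diffusion by a few
        percent only, hence the default 1.0.
    """

    C0: float
    D: float
    rB: float
    rU: float
    diffusion_correction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("C0", "D", "rB", "rU"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if not 0 < self.diffusion_correction <= 1:
            raise ValueError("diffusion_correction must lie in (0, 1]")

    @property
    def kB(self) -> float:
        """Alias used by the simple model (binding constant, 1/(s·µM))."""
        return self.rB


@dataclass(frozen=True)
class NetworkGeometry:
    """Geometry of the growing network: width W (µm) and growth speed V (µm/s)."""

    W: float
    V: float

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("W must be positive")
        if self.V < 0:
            raise ValueError("V must be nonnegative")

    def length(self, t: float) -> float:
        """Network length L(t) = V * t (µm)."""
        if t < 0:
            raise ValueError("t must be nonnegative")
        return self.V * t


class ActinProfile:
    """Filamentous-actin density along the network, constant or tabulated.

    ``A(y)`` is evaluated as a function of the distance y (µm) from the leading
    edge.  A constant profile returns ``A0`` everywhere; a tabulated profile is
    linearly interpolated and clamped to its end values.
    """

    def __init__(self, A0: float, y: Sequence[float] | None = None,
                 A: Sequence[float] | None = None):
        if A0 < 0:
            raise ValueError("A0 must be nonnegative")
        self.A0 = float(A0)
        if (y is None) != (A is None):
            raise ValueError("provide both y and A, or neither")
        if y is not None:
            y_arr = np.asarray(y, dtype=float)
            A_arr = np.asarray(A, dtype=float)
            if np.any(A_arr < 0):
                raise ValueError("A(y) must be nonnegative everywhere")
            if not math.isclose(A_arr[0], A0, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("A(y=0) must equal A0")
            self._y, self._A = y_arr, A_arr
        else:
            self._y = self._A = None

    @property
    def is_constant(self) -> bool:
        return self._y is None

    def __call__(self, y):
        if self._y is None:
            return np.full_like(np.asarray(y, dtype=float), self.A0) \
                if np.ndim(y) else self.A0
        return np.interp(y, self._y, self._A)


@dataclass(frozen=True)
class ThresholdModel:
    """Critical bound-cofilin-per-actin ratio gamma = CB/A at which the network falls apart."""

    gamma: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Uniform square grid: domain extents Lx × Ly (µm) and spacing dx (µm)."""

    Lx: float
    Ly: float
    dx: float = 1.0

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.dx) <= 0:
            raise ValueError("grid extents and spacing must be positive")

    @property
    def nx(self) -> int:
        return int(round(self.Lx / self.dx)) + 1

    @property
    def ny(self) -> int:
        return int(round(self.Ly / self.dx)) + 1

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.linspace(0.0, self.Lx, self.nx),
                np.linspace(0.0, self.Ly, self.ny))


@dataclass
class ChamberField:
    """A snapshot of the chamber: free and bound concentration grids (ny, nx)."""

    t: float
    x: np.ndarray
    y: np.ndarray
    CF: np.ndarray
    CB: np.ndarray
    mask: np.ndarray  # True inside the network
    dx: float

    def total_cofilin(self) -> float:
        """Area integral of CF + CB over the domain (µM·µm²), trapezoid-free cell sum."""
        return float((self.CF.sum() + self.CB.sum()) * self.dx**2)


@dataclass
class ChamberSeries:
    """Output of :func:`simulate_chamber`: fields at the requested times."""

    fields: list[ChamberField]
    geometry: NetworkGeometry
    kinetics: CofilinKinetics
    leading_edge_y: float

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.fields])


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def simple_bound_profile(kinetics: CofilinKinetics, actin: ActinProfile,
                         geometry: NetworkGeometry, y: float, t: float) -> float:
    """Bound cofilin at distance y from the leading edge, simple no-depletion model.

    A material point takes time ``y / V`` to drift a distance y from the
    leading edge; loading at the constant rate ``kB * C0 * A`` over that time
    gives ``CB = kB * C0 * A * y / V``.  Fresh actin is cofilin-free, so
    ``CB(0) = 0``.
    """
    if not actin.is_constant:
        raise ValueError("the simple model assumes a constant actin density")
    if geometry.V <= 0:
        raise ValueError("simple model requires a positive growth speed V")
    L = geometry.length(t)
    if not 0 <= y <= L + 1e-12:
        raise ValueError(f"y={y} outside the network [0, {L}]")
    return kinetics.kB * kinetics.C0 * actin.A0 * y / geometry.V


def simple_equilibrium_length(threshold: ThresholdModel, kinetics: CofilinKinetics,
                              geometry: NetworkGeometry) -> float:
    """Equilibrium length of the simple model, ``L* = gamma * V / (kB * C0)``.

    The network falls apart where the bound-cofilin-per-actin ratio reaches
    ``gamma``; without depletion that happens at a length independent of both
    the width W and the actin density A.  Returns ``inf`` when ``kB * C0 == 0``
    (no finite equilibrium: the network never accumulates enough cofilin).
    """
    denom = kinetics.kB * kinetics.C0
    if denom == 0:
        return math.inf
    return threshold.gamma * geometry.V / denom


def quasi_steady_estimate(kinetics: CofilinKinetics, geometry: NetworkGeometry,
                          L: float, A: float, CB: float = 0.0) -> tuple[float, float]:
    """Quasi-steady estimate of local free cofilin and the leading-edge binding rate.

    Balancing diffusive resupply against the binding sink of a ``W x L``
    network (with the unbinding return flux ``W * L * CB * rU``)::

        CF    ~ (C0 * D + W * L * CB * rU) / (D + A * W * L * rB)
        dCB/dt ~ rB * A * C0 * D / (D + A * W * L * rB)

    Both decrease as the network grows.  A rough order-of-magnitude estimate,
    not a solution of the PDE.
    """
    if min(L, A, CB) < 0:
        raise ValueError("L, A and CB must be nonnegative")
    W, D = geometry.W, kinetics.D
    denom = D + A * W * L * kinetics.rB
    CF_est = (kinetics.C0 * D + W * L * CB * kinetics.rU) / denom
    rate_est = kinetics.rB * A * kinetics.C0 * D / denom
    return CF_est, rate_est


# ---------------------------------------------------------------------------
# Full 2D simulation
# ---------------------------------------------------------------------------

def _diffusion_solver(grid: GridSpec, D_cell: np.ndarray, dt: float,
                      boundary: str):
    """Backward-Euler diffusion operator ``(I - dt * div(D grad))`` factorized once.

    ``D_cell`` is the per-cell diffusivity (µm²/s); face diffusivities are
    harmonic means, so a uniform field stays uniform.  Dirichlet rows (far-field
    mode) pin the boundary values; Neumann (closed mode) uses zero-flux faces,
    which conserves mass exactly up to the direct-solver roundoff.
    """
    ny, nx = D_cell.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    A = lil_matrix((n, n))
    r = dt / grid.dx**2

    dirichlet = np.zeros((ny, nx), dtype=bool)
    if boundary == "far-field":
        dirichlet[0, :] = dirichlet[-1, :] = True
        dirichlet[:, 0] = dirichlet[:, -1] = True

    def face_D(a, b):
        return 2.0 * a * b / (a + b) if (a + b) > 0 else 0.0

    for j in range(ny):
        for i in range(nx):
            k = idx[j, i]
            if dirichlet[j, i]:
                A[k, k] = 1.0
                continue
            diag = 1.0
            for (jj, ii) in ((j - 1, i), (j + 1, i), (j, i - 1), (j, i + 1)):
                if 0 <= jj < ny and 0 <= ii < nx:
                    d = face_D(D_cell[j, i], D_cell[jj, ii])
                    diag += r * d
                    A[k, idx[jj, ii]] = -r * d
                # out-of-domain neighbour: zero-flux face, no term
            A[k, k] = diag
    return splu(A.tocsc())


def _diffusion_solver_fast(grid: GridSpec, D: float, dt: float, boundary: str):
    """Constant-diffusivity fast path for the backward-Euler operator."""
    ny, nx = grid.ny, grid.nx
    n = ny * nx
    r = dt * D / grid.dx**2
    idx = np.arange(n).reshape(ny, nx)

    rows, cols, vals = [], [], []
    diag = np.ones(n)

    dirichlet = np.zeros((ny, nx), dtype=bool)
    if boundary == "far-field":
        dirichlet[0, :] = dirichlet[-1, :] = True
        dirichlet[:, 0] = dirichlet[:, -1] = True
    dir_flat = dirichlet.ravel()

    for shift in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        jj = np.arange(ny)[:, None] + shift[0]
        ii = np.arange(nx)[None, :] + shift[1]
        valid = (jj >= 0) & (jj < ny) & (ii >= 0) & (ii < nx)
        valid &= ~dirichlet
        src = idx[valid]
        dst = idx[np.clip(jj, 0, ny - 1), np.clip(ii, 0, nx - 1)][valid]
        rows.append(src)
        cols.append(dst)
        vals.append(np.full(src.size, -r))
        np.add.at(diag, src, r)

    diag[dir_flat] = 1.0
    rows = np.concatenate(rows + [np.arange(n)])
    cols = np.concatenate(cols + [np.arange(n)])
    vals = np.concatenate(vals + [diag])
    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return splu(A)


def simulate_chamber(kinetics: CofilinKinetics, geometry: NetworkGeometry,
                     actin: ActinProfile, t_end: float, grid: GridSpec,
                     boundary: Literal["far-field", "closed"] = "far-field",
                     saturation_smax: float | None = None,
                     dt: float | None = None,
                     output_times: Sequence[float] | None = None,
                     leading_edge_y: float | None = None,
                     initial_length: float = 0.0,
                     CF0: np.ndarray | None = None,
                     negative_tol: float = 1e-9) -> ChamberSeries:
    """Solve the two-field transport model on a 2D chamber.

    Operator splitting per step: conservative first-order upwind advection of
    CB inside the network mask, exact pairwise binding/unbinding exchange (the
    two-state reaction is linear, so its step is a closed-form relaxation), and
    backward-Euler diffusion of CF with a prefactorized sparse operator.  The
    mask is a ``W x L(t)`` rectangle hanging from the leading edge and extends
    by whole grid rows as ``V * t`` crosses row boundaries.

    Parameters of note
    ------------------
    boundary : "far-field" holds CF = C0 on the domain edge (a vast chamber);
        "closed" is zero-flux and conserves total cofilin exactly.
    saturation_smax : if given, the binding term is multiplied by
        ``max(0, 1 - CB / (smax * A))``; default off, i.e. binding is
        ``rB * A * CF`` exactly.
    leading_edge_y : y-position of the (stationary) leading edge; default
        places the network's final extent in the middle of the domain.
    initial_length : network length already present at t = 0 (µm); with V = 0
        this freezes the geometry, which is how the quasi-steady estimate is
        cross-checked against the PDE.
    CF0 : optional (ny, nx) initial free-concentration field replacing the
        uniform C0 start (e.g. a point perturbation for diffusion checks).
    """
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    nx, ny = grid.nx, grid.ny
    x, y = grid.coords()
    dx = grid.dx

    if geometry.W > grid.Lx:
        raise ValueError("network wider than the domain")
    if geometry.W / dx < 10:
        raise ValueError("grid too coarse: need at least 10 cells across the width W")

    if initial_length < 0:
        raise ValueError("initial_length must be nonnegative")
    L_end = initial_length + geometry.length(t_end)
    if leading_edge_y is None:
        leading_edge_y = max(0.0, (grid.Ly - L_end) / 2.0)
    if leading_edge_y + L_end > grid.Ly + 1e-9:
        raise ValueError("network outgrows the domain; enlarge Ly or move the leading edge")

    if dt is None:
        dt = 2.0
        if geometry.V > 0:
            dt = min(dt, 0.5 * dx / geometry.V)
        dt = min(dt, t_end) if t_end > 0 else dt
    if geometry.V * dt / dx > 0.5 + 1e-12:
        raise ValueError(
            f"advection CFL {geometry.V * dt / dx:.3f} exceeds 0.5; reduce dt")
    # uniform steps covering [0, t_end] exactly
    if t_end > 0:
        n_steps = max(1, int(math.ceil(t_end / dt - 1e-12)))
        dt = t_end / n_steps
    else:
        n_steps = 0

    if output_times is None:
        output_times = [t_end]
    output_times = sorted(float(t) for t in output_times)
    if output_times and output_times[-1] > t_end + 1e-9:
        raise ValueError("output time beyond t_end")

    # network mask geometry: columns centred in x, rows below the leading edge
    half_W = geometry.W / 2.0
    col_in = np.abs(x - grid.Lx / 2.0) <= half_W + 1e-9
    j_le = int(round(leading_edge_y / dx))  # leading-edge row index

    if CF0 is not None:
        CF0 = np.asarray(CF0, dtype=float)
        if CF0.shape != (ny, nx) or (CF0 < 0).any():
            raise ValueError("CF0 must be a nonnegative (ny, nx) array")
        CF = CF0.copy()
    else:
        CF = np.full((ny, nx), kinetics.C0, dtype=float)
    CB = np.zeros((ny, nx), dtype=float)

    uniform_D = kinetics.diffusion_correction == 1.0
    if uniform_D:
        solver = _diffusion_solver_fast(grid, kinetics.D, dt, boundary)
    else:
        solver = None  # rebuilt whenever the mask grows

    # distance-from-leading-edge per row (for tabulated actin profiles)
    y_from_le = y - y[j_le]

    fields: list[ChamberField] = []
    out_iter = iter(output_times)
    next_out = next(out_iter, None)

    def current_mask(t: float) -> tuple[np.ndarray, int]:
        n_rows = int(math.floor((initial_length + geometry.length(t)) / dx + 1e-9))
        j_tail = min(ny - 1, j_le + n_rows)
        m = np.zeros((ny, nx), dtype=bool)
        m[j_le:j_tail + 1, col_in] = True
        return m, j_tail

    mask, j_tail = current_mask(0.0)
    A_row = np.asarray(actin(np.clip(y_from_le, 0.0, None)), dtype=float)
    A_grid = np.where(mask, A_row[:, None], 0.0)

    def snapshot(t: float) -> ChamberField:
        return ChamberField(t=t, x=x.copy(), y=y.copy(), CF=CF.copy(),
                            CB=CB.copy(), mask=mask.copy(), dx=dx)

    if next_out is not None and next_out <= 1e-12:
        fields.append(snapshot(0.0))
        next_out = next(out_iter, None)

    mask_version = -1

    for step in range(n_steps):
        t_new = (step + 1) * dt

        new_mask, j_tail = current_mask(t_new)
        if new_mask.sum() != mask.sum():
            mask = new_mask
            A_grid = np.where(mask, A_row[:, None], 0.0)
            mask_version += 1
        if not uniform_D and (solver is None or mask_version != getattr(solver, "_ver", -2)):
            D_cell = np.where(mask, kinetics.D * kinetics.diffusion_correction, kinetics.D)
            solver = _diffusion_solver(grid, D_cell, dt, boundary)
            solver._ver = mask_version

        # --- advection of CB (conservative upwind, inflow CB=0 at the leading edge)
        if geometry.V > 0 and j_tail > j_le:
            c = geometry.V * dt / dx
            sub = CB[j_le:j_tail + 1, :]
            flux_in = np.vstack([np.zeros((1, nx)), sub[:-1, :]])  # from the row above
            # outflow at the trailing row is retained (the edge recedes with the material)
            out = sub.copy()
            out[-1, :] = 0.0
            CB[j_le:j_tail + 1, :] = sub + c * (flux_in - out)

        # --- reaction (exact exponential relaxation of the linear 2-state exchange)
        # the leading-edge row is the CB = 0 inflow boundary: material there has
        # age zero, so binding starts one row downstream
        m = mask.copy()
        m[j_le, :] = False
        a = kinetics.rB * A_grid[m]
        if saturation_smax is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                sat = np.where(A_grid[m] > 0,
                               np.clip(1.0 - CB[m] / (saturation_smax * A_grid[m]), 0.0, None),
                               0.0)
            a = a * sat
        u = kinetics.rU
        s_tot = CF[m] + CB[m]
        lam = a + u
        with np.errstate(divide="ignore", invalid="ignore"):
            CF_eq = np.where(lam > 0, u * s_tot / lam, CF[m])
        decay = np.exp(-lam * dt)
        CF_new = CF_eq + (CF[m] - CF_eq) * decay
        CF[m] = CF_new
        CB[m] = s_tot - CF_new

        # --- diffusion of CF (implicit)
        rhs = CF.ravel()
        if boundary == "far-field":
            b = rhs.copy()
            b_mask = np.zeros((ny, nx), dtype=bool)
            b_mask[0, :] = b_mask[-1, :] = True
            b_mask[:, 0] = b_mask[:, -1] = True
            b[b_mask.ravel()] = kinetics.C0
            CF = solver.solve(b).reshape(ny, nx)
        else:
            CF = solver.solve(rhs).reshape(ny, nx)

        min_val = min(CF.min(), CB.min())
        if min_val < -negative_tol:
            raise RuntimeError(f"negative concentration {min_val:.3e} beyond tolerance; "
                               "the scheme became unstable (reduce dt)")
        np.clip(CF, 0.0, None, out=CF)
        np.clip(CB, 0.0, None, out=CB)

        while next_out is not None and t_new >= next_out - 1e-9:
            fields.append(snapshot(t_new))
            next_out = next(out_iter, None)

    if not fields:
        fields.append(snapshot(t_end))
    return ChamberSeries(fields=fields, geometry=geometry, kinetics=kinetics,
                         leading_edge_y=leading_edge_y)


def depletion_timecourse(series: ChamberSeries,
                         region: tuple[float, float, float, float] | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean free-cofilin concentration in a rectangular region, per output time.

    ``region = (x0, x1, y0, y1)`` in µm; default is the area covered by the
    network at the final output time (the usual observation window for the
    depletion readout).  Returns ``(times, mean_CF)``.
    """
    last = series.fields[-1]
    if region is None:
        if not last.mask.any():
            raise ValueError("network mask empty; specify a region explicitly")
        ys, xs = np.where(last.mask)
        region = (last.x[xs.min()], last.x[xs.max()],
                  last.y[ys.min()], last.y[ys.max()])
    x0, x1, y0, y1 = region
    sel_x = (last.x >= x0 - 1e-9) & (last.x <= x1 + 1e-9)
    sel_y = (last.y >= y0 - 1e-9) & (last.y <= y1 + 1e-9)
    if not (sel_x.any() and sel_y.any()):
        raise ValueError("observation region lies outside the domain or is empty")
    means = np.array([f.CF[np.ix_(sel_y, sel_x)].mean() for f in series.fields])
    return series.times, means
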
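"""Synthetic observables with the statistical structure of the treadmilling assays.

Generates the four kinds of measurement the analysis pipeline consumes, so
every inference step can be exercised without imaging data:

* bound-cofilin kymographs CB(y, t), either from the full transport
  simulation (local depletion makes later-starting material paths load more
  slowly) or from the closed-form no-depletion model (all paths share the
  slope ``rB * C0 * A``);
* actin density profiles A(y) — a plateau at A0 with a logistic collapse at
  the trailing edge;
* tables of equilibrium-length records (L, V, A0, CB) following the power law
  ``L = c * V * A0**alpha / CB**beta`` with multiplicative lognormal scatter,
  over the experimental spans of cofilin concentration, width and density
  class;
* tables of initial binding slopes vs (C0, A), with the noise level
  calibrated so the Pearson correlation between slope and C0*A sits near 0.5.

Noise models: additive Gaussian for image-like kymographs, multiplicative
lognormal for strictly positive lengths and slopes.  All generators are
deterministic under a fixed seed and attach a provenance dict (parameters,
seed, package version).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .transport import (ActinProfile, CofilinKinetics, GridSpec, NetworkGeometry,
                        simulate_chamber)

__all__ = [
    "Kymograph",
    "gen_kymograph",
    "gen_density_profiles",
    "gen_length_table",
    "gen_binding_table",
    "write_table",
]

# experimental spans: cofilin concentrations (µM), widths (µm), density classes (µM)
C0_LEVELS_UM = (0.125, 0.250, 0.400, 0.500)
W_LEVELS_UM = (15.0, 30.0, 90.0)
DENSITY_CLASSES_UM = {"low": 30.0, "medium": 50.0, "high": 80.0}

# lognormal noise sd (log scale) putting Pearson R(slope, C0*A) near 0.5 for
# the spans above; from the moment identity R = sd(X)/sqrt(E[X^2] e^{s^2} - E[X]^2)
# with X = C0*A drawn from the level sets: e^{s^2} = (m^2 + 4v)/(m^2 + v)
BINDING_NOISE_SD = 0.78


@dataclass
class Kymograph:
    """Bound-cofilin intensity over a (t, y) grid.

    ``data[i, j]`` is CB at time ``t[i]`` and distance ``y[j]`` from the
    leading edge (µM-equivalent).  Row y = 0 stays near zero: fresh actin is
    cofilin-free.  ``V`` is the growth speed used to trace material paths
    y = V * (t - t0).
    """

    data: np.ndarray
    y: np.ndarray
    t: np.ndarray
    V: float
    pixel_size: float
    frame_interval: float
    noise_sd: float
    meta: dict = dc_field(default_factory=dict)

    def material_path(self, t0: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample CB along the path of material born at the leading edge at t0.

        Returns ``(t_samples, CB_samples)`` for frames with t >= t0 while the
        path stays inside the field of view.
        """
        idx = np.flatnonzero(self.t >= t0 - 1e-9)
        ts = self.t[idx]
        ys = self.V * (ts - t0)
        inside = ys <= self.y[-1] + 1e-9
        idx, ts, ys = idx[inside], ts[inside], ys[inside]
        vals = np.array([np.interp(yy, self.y, self.data[i])
                         for i, yy in zip(idx, ys)])
        return ts, vals


def _provenance(generator: str, seed: int | None, **params) -> dict:
    return {"generator": generator, "seed": seed, "version": __version__,
            "params": params}


def gen_kymograph(kinetics: CofilinKinetics, geometry: NetworkGeometry,
                  actin: ActinProfile, t_end: float,
                  noise_sd: float = 0.0, seed: int | None = None,
                  mode: str = "pde",
                  frame_interval: float = 60.0,
                  pixel_size: float | None = None,
                  grid: GridSpec | None = None) -> Kymograph:
    """Bound-cofilin kymograph CB(y, t) along the network midline.

    ``mode="pde"`` runs the 2D transport simulation (local depletion included,
    so later-starting material paths have smaller initial slopes);
    ``mode="analytic"`` uses the no-depletion closed form, in which every
    material path is exactly linear with slope ``rB * C0 * A``.  Additive
    Gaussian noise (sd in µM) is clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    L_end = geometry.length(t_end)
    if pixel_size is None:
        pixel_size = max(0.5, L_end / 100)
    times = np.arange(0.0, t_end + 1e-9, frame_interval)
    y = np.arange(0.0, L_end + 1e-9, pixel_size)

    if mode == "analytic":
        if not actin.is_constant:
            raise ValueError("analytic mode assumes a constant actin density")
        tt, yy = np.meshgrid(times, y, indexing="ij")
        # beyond the growth frontier y = V t no material exists yet; continue
        # with the frontier (oldest-material) value so interpolated material
        # paths stay exactly linear, including the t0 = 0 path on the frontier
        y_eff = np.minimum(yy, geometry.V * tt)
        data = (kinetics.rB * kinetics.C0 * actin.A0 * y_eff
                / max(geometry.V, 1e-300))
    elif mode == "pde":
        if grid is None:
            span = max(3.0 * max(L_end, geometry.W), 60.0)
            dx = max(geometry.W / 15.0, 1.0)
            grid = GridSpec(span, span, dx)
        series = simulate_chamber(kinetics, geometry, actin, t_end, grid,
                                  output_times=list(times))
        f0 = series.fields[0]
        j_le = int(round(series.leading_edge_y / f0.dx))
        i_mid = f0.CF.shape[1] // 2
        y_grid = f0.y[j_le:] - f0.y[j_le]
        data = np.stack([np.interp(y, y_grid, fld.CB[j_le:, i_mid])
                         for fld in series.fields])
        times = series.times
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = np.clip(data + rng.normal(0.0, noise_sd, data.shape), 0.0, None)

    return Kymograph(data=data, y=y, t=times, V=geometry.V,
                     pixel_size=pixel_size, frame_interval=frame_interval,
                     noise_sd=noise_sd,
                     meta=_provenance("gen_kymograph", seed, mode=mode,
                                      C0=kinetics.C0, D=kinetics.D, rB=kinetics.rB,
                                      rU=kinetics.rU, W=geometry.W, V=geometry.V,
                                      A0=actin.A0, t_end=t_end, noise_sd=noise_sd))


def gen_density_profiles(A0: float, L: float, n: int = 10,
                         drop_width: float | None = None,
                         noise_sd: float = 0.05, seed: int | None = None,
                         dy: float = 0.5) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthetic actin density profiles: flat plateau, abrupt trailing-edge drop.

    The noiseless template is ``A0 * logistic((y_c - y)/w)`` with the collapse
    centered at ``y_c = L - drop_width/2`` and ``w = drop_width/8``, hard
    zero beyond L; ``drop_width`` defaults to 10% of L.  Multiplicative
    lognormal noise (sd on the log scale) roughens each of the n profiles.

    Returns ``(y, profiles, provenance)`` with profiles of shape (n, len(y)).
    """
    if drop_width is None:
        drop_width = 0.1 * L
    if drop_width >= L:
        raise ValueError("drop width must be smaller than L")
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    y = np.arange(0.0, 1.2 * L, dy)
    y_c = L - drop_width / 2.0
    w = drop_width / 8.0
    template = A0 / (1.0 + np.exp((y - y_c) / w))
    template[y > L] = 0.0
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        noise = rng.lognormal(0.0, noise_sd, (n, y.size))
    else:
        noise = np.ones((n, y.size))
    profiles = template[None, :] * noise
    prov = _provenance("gen_density_profiles", seed, A0=A0, L=L, n=n,
                       drop_width=drop_width, noise_sd=noise_sd, dy=dy)
    return y, profiles, prov


def gen_length_table(n: int = 50, alpha: float = 2.0, beta: float = 1.0,
                     noise_sd: float = 0.1, seed: int | None = None,
                     prefactor: float = 1.0,
                     C0_levels=C0_LEVELS_UM, W_levels=W_LEVELS_UM,
                     density_classes: dict[str, float] = DENSITY_CLASSES_UM
                     ) -> pd.DataFrame:
    """Table of equilibrium-length records obeying L = c * V * A0**alpha / CB**beta.

    Each record draws a density class (A0 with 15% lognormal scatter around
    the class mean), a cofilin level C0 and a width W from the experimental
    spans; the growth speed rises weakly with density
    (V ~ 0.019 * (A0/50)**0.3 µm/s, as observed in the assays) and the mean bound cofilin
    scales with C0 (CB ~ 10 * C0 with 25% scatter).  The length then follows
    the power law with lognormal noise of log-sd ``noise_sd``.
    """
    if n < 10:
        raise ValueError("need at least 10 records")
    rng = np.random.default_rng(seed)
    classes = list(density_classes)
    cls = rng.choice(classes, n)
    A0 = np.array([density_classes[c] for c in cls]) * rng.lognormal(0.0, 0.15, n)
    C0 = rng.choice(np.asarray(C0_levels, dtype=float), n)
    W = rng.choice(np.asarray(W_levels, dtype=float), n)
    V = 0.019 * (A0 / 50.0) ** 0.3 * rng.lognormal(0.0, 0.1, n)
    CB = 10.0 * C0 * rng.lognormal(0.0, 0.25, n)
    L = prefactor * V * A0**alpha / CB**beta * rng.lognormal(0.0, noise_sd, n)
    df = pd.DataFrame({
        "L_um": L, "V_um_per_s": V, "A0_uM": A0, "CB_uM": CB,
        "C0_uM": C0, "W_um": W, "density_class": cls,
    })
    df.attrs["provenance"] = _provenance("gen_length_table", seed, n=n, alpha=alpha,
                                         beta=beta, noise_sd=noise_sd,
                                         prefactor=prefactor)
    return df


def gen_binding_table(n: int = 60, noise_sd: float = BINDING_NOISE_SD,
                      seed: int | None = None, rB: float = 0.5 / 60.0,
                      C0_levels=C0_LEVELS_UM,
                      density_classes: dict[str, float] = DENSITY_CLASSES_UM
                      ) -> pd.DataFrame:
    """Table of initial bound-cofilin slopes vs cofilin concentration and density.

    The noiseless slope is ``rB * C0 * A`` (µM/s); lognormal noise of log-sd
    ``noise_sd`` emulates the between-network variability.  At the default
    calibrated noise the Pearson correlation between slope and the product
    C0 * A lies near 0.5 over the configured spans.
    """
    if n < 10:
        raise ValueError("need at least 10 records")
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    rng = np.random.default_rng(seed)
    C0 = rng.choice(np.asarray(C0_levels, dtype=float), n)
    A = rng.choice(np.asarray(list(density_classes.values()), dtype=float), n)
    slope = rB * C0 * A * rng.lognormal(0.0, noise_sd, n)
    df = pd.DataFrame({"slope_uM_per_s": slope, "C0_uM": C0, "A_uM": A})
    df.attrs["provenance"] = _provenance("gen_binding_table", seed, n=n,
                                         noise_sd=noise_sd, rB=rB)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a generated table as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(df.attrs.get("provenance", {}), indent=2))
    return sidecar
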
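"""Configuration-driven scenario runner and reproducibility helpers.

A :class:`RunConfig` names a scenario, a seed and an output directory, plus
the scenario's unit-annotated parameters (unknown keys are rejected).  Every
run writes CSV/JSON outputs together with a ``provenance.json`` sidecar
(scenario, parameters, seed, package version) sufficient to re-execute it;
reruns with the same config byte-reproduce all CSV outputs.

Canonical internal units are µM, µm and s; parameter names carry their unit
suffix (``_uM``, ``_um``, ``_per_s``, ...), and minute-based literature values
are converted at the boundary by the caller (1/min = 1/60 s).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .equilibrium import EquilibriumParams, length_phase_map, solve_equilibrium
from .fragmentation import FragmentationParams, run_to_equilibrium
from .steering import ElasticBeamPair, coupled_equilibrium_lengths, heterogeneous_shape
from .transport import (ActinProfile, CofilinKinetics, GridSpec, NetworkGeometry,
                        depletion_timecourse, simulate_chamber)

__all__ = [
    "RunConfig",
    "TransportParams",
    "FragmentationRunParams",
    "PhaseMapParams",
    "SteeringParams",
    "run_scenario",
    "compare_runs",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TransportParams(_Strict):
    """Depletion-map scenario: full 2D transport simulation."""

    C0_uM: float = 0.125
    D_um2_per_s: float = 10.0
    rB_per_s_uM: float = 0.5 / 60.0
    rU_per_s: float = 0.31 / 60.0
    W_um: float = 30.0
    V_um_per_s: float = 1.16 / 60.0
    A_uM: float = 50.0
    t_end_s: float = 2400.0
    domain_um: float = 300.0
    dx_um: float = 2.0
    boundary: Literal["far-field", "closed"] = "far-field"


class FragmentationRunParams(_Strict):
    """Stochastic lattice fragmentation run."""

    W_um: float = 30.0
    V_um_per_s: float = 0.03
    A0_uM: float = 50.0
    CB_uM: float = 5.0
    k_break: float = 0.25
    alpha: float = 2.0
    beta: float = 1.0
    T_s: float = 6000.0
    a_um: float = 0.5


class PhaseMapParams(_Strict):
    """Equilibrium-length phase map over (C0, A0) or (W, A0)."""

    vary: Literal["C0_A0", "W_A0"] = "C0_A0"
    A0_min_uM: float = 20.0
    A0_max_uM: float = 100.0
    C0_min_uM: float = 0.05
    C0_max_uM: float = 0.6
    W_min_um: float = 10.0
    W_max_um: float = 100.0
    n_grid: int = 25
    A0_uM: float = 50.0
    C0_uM: float = 0.25
    W_um: float = 30.0
    V_um_per_s: float = 0.019
    rB_per_s_uM: float = 0.01
    D_um2_per_s: float = 10.0
    k1_s_per_uM: float = 1.0
    k2: float = 0.5


class SteeringParams(_Strict):
    """Two-lane steering sweep over cofilin concentration.

    The mean curvature radius is evaluated over a fixed observed arclength
    (the distance grown in ``t_obs_s``), so shortening of the curved sparse
    lane with rising cofilin shows up as straightening.
    """

    A1_uM: float = 30.0
    A2_uM: float = 60.0
    V1_um_per_s: float = 0.015
    V2_um_per_s: float = 0.025
    W_um: float = 15.0
    tau: float = 2.5
    C0_levels_uM: list[float] = Field(default_factory=lambda: [0.125, 0.25, 0.5])
    rB_per_s_uM: float = 0.01
    D_um2_per_s: float = 10.0
    t_obs_s: float = 1800.0


_SCENARIO_MODELS: dict[str, type[_Strict]] = {
    "depletion_map": TransportParams,
    "fragmentation": FragmentationRunParams,
    "phase_map": PhaseMapParams,
    "steering_sweep": SteeringParams,
}


class RunConfig(_Strict):
    """A reproducible run: scenario name, seed, output directory, parameters."""

    scenario: str
    seed: int = 0
    outdir: str = "out"
    params: dict = Field(default_factory=dict)

    def validated_params(self) -> _Strict:
        try:
            model = _SCENARIO_MODELS[self.scenario]
        except KeyError:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {sorted(_SCENARIO_MODELS)}") from None
        return model(**self.params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validated_params()  # reject unknown/invalid scenario keys early
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_scenario(config: RunConfig) -> Path:
    """Execute a scenario and write its result bundle; returns the output dir."""
    p = config.validated_params()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if isinstance(p, TransportParams):
        kin = CofilinKinetics(C0=p.C0_uM, D=p.D_um2_per_s, rB=p.rB_per_s_uM,
                              rU=p.rU_per_s)
        geo = NetworkGeometry(W=p.W_um, V=p.V_um_per_s)
        times = list(np.linspace(0, p.t_end_s, 9)[1:])
        series = simulate_chamber(kin, geo, ActinProfile(p.A_uM), p.t_end_s,
                                  GridSpec(p.domain_um, p.domain_um, p.dx_um),
                                  boundary=p.boundary, output_times=times)
        last = series.fields[-1]
        _write_csv(outdir / "CF_final.csv",
                   pd.DataFrame(last.CF, columns=[f"x_{v:.6g}" for v in last.x]))
        t, m = depletion_timecourse(series)
        _write_csv(outdir / "depletion_timecourse.csv",
                   pd.DataFrame({"t_s": t, "mean_CF_uM": m}))
        summary = {"max_relative_depletion_pct":
                   float(100.0 * (1.0 - last.CF.min() / kin.C0))}
    elif isinstance(p, FragmentationRunParams):
        fparams = FragmentationParams(alpha=p.alpha, beta=p.beta, k_break=p.k_break)
        traj = run_to_equilibrium(W=p.W_um, V=p.V_um_per_s, A0=p.A0_uM, CB=p.CB_uM,
                                  params=fparams, T=p.T_s, seed=config.seed, a=p.a_um)
        _write_csv(outdir / "length_timeseries.csv",
                   pd.DataFrame({"t_s": traj.times, "L_um": traj.lengths}))
        _write_csv(outdir / "density_profile.csv",
                   pd.DataFrame({"y_um": traj.profile_y, "A_uM": traj.profile_A}))
        _write_csv(outdir / "fragment_sizes.csv",
                   pd.DataFrame({"size_nodes": traj.fragment_sizes}))
        summary = {"reached_equilibrium": traj.reached_equilibrium,
                   "length_mean_um": traj.length_mean,
                   "length_std_um": traj.length_std}
    elif isinstance(p, PhaseMapParams):
        kin = CofilinKinetics(C0=p.C0_uM, D=p.D_um2_per_s, rB=p.rB_per_s_uM, rU=0.0)
        eq = EquilibriumParams(k1=p.k1_s_per_uM, k2=p.k2)
        A0s = np.linspace(p.A0_min_uM, p.A0_max_uM, p.n_grid)
        if p.vary == "C0_A0":
            g1 = np.linspace(p.C0_min_uM, p.C0_max_uM, p.n_grid)
            mat = length_phase_map(("C0", "A0"), g1, A0s,
                                   {"V": p.V_um_per_s, "W": p.W_um}, kin, eq)
            index = pd.Index(g1, name="C0_uM")
        else:
            g1 = np.linspace(p.W_min_um, p.W_max_um, p.n_grid)
            mat = length_phase_map(("W", "A0"), g1, A0s,
                                   {"V": p.V_um_per_s, "C0": p.C0_uM}, kin, eq)
            index = pd.Index(g1, name="W_um")
        df = pd.DataFrame(mat, index=index, columns=[f"A0_{v:.6g}" for v in A0s])
        df.to_csv(outdir / "phase_map.csv", float_format="%.10g")
        summary = {"L_star_min_um": float(mat.min()), "L_star_max_um": float(mat.max())}
    elif isinstance(p, SteeringParams):
        kin_base = dict(D=p.D_um2_per_s, rB=p.rB_per_s_uM, rU=0.0)
        pair = ElasticBeamPair(V1=p.V1_um_per_s, V2=p.V2_um_per_s,
                               A1=p.A1_uM, A2=p.A2_uM, W=p.W_um, tau=p.tau)
        rows = []
        for c0 in p.C0_levels_uM:
            kin = CofilinKinetics(C0=c0, **kin_base)
            L1, L2 = coupled_equilibrium_lengths((p.A1_uM, p.V1_um_per_s),
                                                 (p.A2_uM, p.V2_um_per_s),
                                                 c0, p.W_um, p.W_um, kin)
            from .steering import combined_speed
            S_obs = combined_speed(p.V1_um_per_s, p.V2_um_per_s, pair.sigma) * p.t_obs_s
            shape = heterogeneous_shape(pair, L1=L1, L2=L2, total_length=S_obs)
            rows.append({"C0_uM": c0, "L1_um": L1, "L2_um": L2,
                         "mean_curvature_radius_um": shape.mean_curvature_radius,
                         "Vh_um_per_s": shape.Vh,
                         "turn_direction": shape.turn_direction})
        _write_csv(outdir / "steering_sweep.csv", pd.DataFrame(rows))
        summary = {"n_levels": len(rows)}
    else:  # pragma: no cover - exhaustive over _SCENARIO_MODELS
        raise AssertionError("unhandled scenario parameters")

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    provenance = {"scenario": config.scenario, "seed": config.seed,
                  "version": __version__, "params": p.model_dump()}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                       sort_keys=True))
    return outdir


def compare_runs(bundle_a: str | Path, bundle_b: str | Path,
                 rtol: float = 1e-9, atol: float = 1e-12) -> dict:
    """Numeric diff of two result bundles from the same scenario.

    Compares every CSV (cell-wise, within rtol/atol) and the summary JSON.
    Returns a report dict: per-file maximum absolute difference and whether it
    is within tolerance.  Raises on mismatched schemas or scenarios.
    """
    a_dir, b_dir = Path(bundle_a), Path(bundle_b)
    prov_a = json.loads((a_dir / "provenance.json").read_text())
    prov_b = json.loads((b_dir / "provenance.json").read_text())
    if prov_a["scenario"] != prov_b["scenario"]:
        raise ValueError("bundles come from different scenarios")

    report: dict[str, dict] = {}
    for csv_a in sorted(a_dir.glob("*.csv")):
        csv_b = b_dir / csv_a.name
        if not csv_b.exists():
            raise ValueError(f"schema mismatch: {csv_a.name} missing from bundle B")
        da, db = pd.read_csv(csv_a), pd.read_csv(csv_b)
        if list(da.columns) != list(db.columns):
            raise ValueError(f"schema mismatch in {csv_a.name}")
        if da.shape != db.shape:
            # same schema, different run length: a stochastic difference
            report[csv_a.name] = {"max_abs_diff": float("inf"),
                                  "within_tolerance": False}
            continue
        num_a = da.select_dtypes("number").to_numpy(dtype=float)
        num_b = db.select_dtypes("number").to_numpy(dtype=float)
        max_diff = float(np.max(np.abs(num_a - num_b))) if num_a.size else 0.0
        within = bool(np.allclose(num_a, num_b, rtol=rtol, atol=atol))
        obj_equal = da.select_dtypes(exclude="number").equals(
            db.select_dtypes(exclude="number"))
        report[csv_a.name] = {"max_abs_diff": max_diff,
                              "within_tolerance": within and obj_equal}
    return report
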
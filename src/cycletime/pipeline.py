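"""Pipeline orchestration: config-driven end-to-end workflow.

Every stage reads and writes plain CSV/JSON files under the configured
output directory, so intermediate results are inspectable and the whole
run is reproducible from the config and its mandatory seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import multicondition as mc
from . import pseudotime as pt
from . import training as tr
from .model import DrugCondition, ModelParameters, gf_scan
from .synthetic import (
    MEASURED_MARKERS,
    SnapshotSpec,
    make_limit_cycle,
    sample_arrested_snapshot,
    sample_snapshot,
)

log = logging.getLogger("cycletime")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``load_config`` for the YAML form)."""

    outdir: str
    seed: int
    input_csv: str | None = None
    generate: dict = field(default_factory=dict)     # SnapshotSpec blocks
    period: float = 24.0
    window: int | None = None
    n_grid: int = 100
    n_bins: int = 50
    treated_conditions: tuple[str, ...] = ("nocodazole", "palbociclib")
    fraction: float = 0.05
    n_starts: int = 20
    fit_max_nfev: int = 300
    profile_threshold: float = 3.84
    profile_parameters: tuple[str, ...] = ()
    gf_grid_stop: float = 0.5
    gf_grid_step: float = 0.01
    fit_dt: float = 0.03
    true_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config field 'seed' is mandatory (no wall-clock "
                             "defaults)")
        if self.input_csv is None and not self.generate:
            raise ValueError("config needs either 'input_csv' or a 'generate' "
                             "block")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    missing = [k for k in ("outdir", "seed") if k not in raw]
    if missing:
        raise ValueError(f"config missing mandatory field(s): {missing}")
    return PipelineConfig(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage %s: done (%.1fs)", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("generate")
def _generate(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    params = ModelParameters.from_dict(cfg.true_params) if cfg.true_params \
        else ModelParameters()
    lc = make_limit_cycle(params, use_fast=True)
    tables = []
    for i, block in enumerate(cfg.generate.get("snapshots", [])):
        spec = SnapshotSpec(**{**block, "seed": cfg.seed + i})
        if spec.condition == "untreated":
            tables.append(sample_snapshot(lc, spec))
        else:
            tables.append(sample_arrested_snapshot(params, lc, spec))
    tab = pd.concat(tables, ignore_index=True)
    tab.to_csv(outdir / "snapshot.csv", index=False)
    return tab


@_stage("embed")
def _embed(cfg: PipelineConfig, tab: pd.DataFrame, outdir: Path):
    untreated = tab[tab["condition"] == "untreated"]
    mm = pt.preprocess(tab)
    mm_u = pt.MarkerMatrix(mm.values[: len(untreated)], mm.marker_names,
                           mm.cell_ids[: len(untreated)])
    coords = pt.cmd_embed(mm_u)
    circle = pt.fit_circle(coords)
    emb = pt.angles(coords, circle, mm_u)
    boundaries = pt.phase_boundaries(emb, n_bins=cfg.n_bins)
    zero = pt.mg1_angle(emb, mm_u, boundaries if len(boundaries) else None)
    emb = emb.with_zero(zero)
    asn = pt.ergodic_times(emb, cfg.period)
    if len(boundaries):
        shifted = np.sort((boundaries - zero) % (2 * np.pi))
        for ang in shifted:
            t = float(asn.time_at_angle(ang)[0])
            label = "M/G1" if min(t, cfg.period - t) < 0.25 * cfg.period else "S/G2"
            asn.boundaries.setdefault(label, (float(ang), t))
    traj_norm = pt.moving_stats(mm_u, asn, window=cfg.window, n_grid=cfg.n_grid)
    raw_vals = untreated[list(MEASURED_MARKERS)].to_numpy()
    traj_raw = pt.moving_stats(raw_vals, asn, window=cfg.window,
                               n_grid=cfg.n_grid,
                               marker_names=list(MEASURED_MARKERS))
    emb_df = pd.DataFrame({
        "cell_id": mm_u.cell_ids, "x": coords[:, 0], "y": coords[:, 1],
        "angle": emb.angle, "pseudotime": asn.time,
    })
    emb_df.to_csv(outdir / "embedding.csv", index=False)
    cols = {"grid_time": traj_norm.grid}
    for j, name in enumerate(traj_norm.marker_names):
        cols[f"{name}_med"] = traj_norm.med[:, j]
        cols[f"{name}_mad"] = traj_norm.mad[:, j]
    pd.DataFrame(cols).to_csv(outdir / "trajectory.csv", index=False)
    return mm, mm_u, emb, asn, traj_norm, traj_raw


@_stage("arrest")
def _arrest(cfg: PipelineConfig, tab, mm, mm_u, emb, asn, outdir: Path):
    estimates = {}
    for cond in cfg.treated_conditions:
        sel = np.where(tab["condition"].to_numpy() == cond)[0]
        if sel.size == 0:
            log.warning("no cells for condition %s; skipping", cond)
            continue
        mm_t = pt.MarkerMatrix(mm.values[sel], mm.marker_names,
                               mm.cell_ids[sel])
        est, cell_angles, drift = mc.estimate_arrest(
            mm_u, mm_t, emb, asn, cond, fraction=cfg.fraction, seed=cfg.seed)
        estimates[cond] = {"estimate": est, "drift": drift}
        pd.DataFrame({"cell_id": mm_t.cell_ids, "angle": cell_angles}).to_csv(
            outdir / f"angles_{cond}.csv", index=False)
    rows = [{
        "condition": c, "arrest_angle": d["estimate"].arrest_angle,
        "arrest_time": d["estimate"].arrest_time,
        "dispersion": d["estimate"].dispersion,
        "n_cells": d["estimate"].n_cells,
        "phase_label": d["estimate"].phase_label,
        "median_drift_rad": d["drift"],
    } for c, d in estimates.items()]
    pd.DataFrame(rows).to_csv(outdir / "arrest_estimates.csv", index=False)
    return estimates


@_stage("fit")
def _fit(cfg: PipelineConfig, traj_raw, estimates, asn, outdir: Path):
    arrests = {c: d["estimate"].arrest_time for c, d in estimates.items()}
    counts, edges = np.histogram(asn.time, bins=20, range=(0, cfg.period))
    centers = (edges[:-1] + edges[1:]) / 2
    order = np.argsort(counts)[::-1]
    m1 = centers[order[0]]
    far = [c for c in centers[order[1:]]
           if min(abs(c - m1), cfg.period - abs(c - m1)) > cfg.period / 5]
    m2 = far[0] if far else centers[order[1]]
    tset = tr.build_training_set(traj_raw, arrests, cfg.period,
                                 (float(m1), float(m2)))
    tset.data.to_csv(outdir / "training_set.csv", index=False)
    # warm start at the package reference parameters alongside LHS starts
    x_ref = np.array([tr._to_internal(n, getattr(tr.ModelParameters(), n))
                      for n in tr.DEFAULT_FREE])
    result = tr.fit(tset, n_starts=cfg.n_starts, seed=cfg.seed, dt=cfg.fit_dt,
                    x0_list=[x_ref], max_nfev=cfg.fit_max_nfev)
    est = {n: getattr(result.estimates, n) for n in result.free_names}
    with open(outdir / "fit_result.json", "w") as fh:
        json.dump({"objective": result.objective, "converged": result.converged,
                   "starts": result.starts, "seed": result.seed,
                   "estimates": est}, fh, indent=2)
    return tset, result


@_stage("profile")
def _profile(cfg: PipelineConfig, tset, result, outdir: Path):
    profiles = {}
    for name in cfg.profile_parameters:
        pr = tr.profile_likelihood(result, tset, name,
                                   threshold=cfg.profile_threshold,
                                   dt=cfg.fit_dt)
        profiles[name] = pr
    rows = [{"parameter": n, "ci_lo": p.ci_95[0], "ci_hi": p.ci_95[1],
             "classification": p.classification} for n, p in profiles.items()]
    pd.DataFrame(rows).to_csv(outdir / "profiles.csv", index=False)
    return profiles


@_stage("predict-gf")
def _predict_gf(cfg: PipelineConfig, result, tset, outdir: Path):
    params = result.estimates
    inits = [tr._initial_state(params, tset, iid)
             for iid in tset.initial_conditions]
    gf_grid = np.round(np.arange(1.0, cfg.gf_grid_stop - 1e-9,
                                 -cfg.gf_grid_step), 10)
    reports, threshold = gf_scan(params, inits, gf_grid,
                                 period_guess=tset.T)
    rows = [{"gf": gf, "regimes": "|".join(r.regime for r in reps)}
            for gf, reps in reports.items()]
    pd.DataFrame(rows).to_csv(outdir / "gf_scan.csv", index=False)
    return threshold


def _fitted_untreated_regime(result, tset) -> str:
    from ._fast import integrate_fast
    from .model import Trajectory, classify_regime

    p_fit = result.estimates
    s0 = tr._initial_state(p_fit, tset, "G1S")
    t_grid = np.linspace(0.0, 8 * tset.T, 1601)
    states = integrate_fast(p_fit, s0, DrugCondition.untreated(), t_grid)
    traj = Trajectory(times=t_grid, states=np.clip(states, 0, None),
                      condition=DrugCondition.untreated())
    return classify_regime(traj, p_fit).regime


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute generate -> embed -> arrest -> fit -> profile -> predict-gf.

    Returns the JSON-serialisable summary that is also written to
    ``<outdir>/summary.json``.  Fails fast with the failing stage named;
    partial outputs are retained in the output directory.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("cycletime %s, seed %d", __version__, cfg.seed)
        if cfg.input_csv:
            tab = pd.read_csv(cfg.input_csv)
        else:
            tab = _generate(cfg, outdir)
        mm, mm_u, emb, asn, traj_norm, traj_raw = _embed(cfg, tab, outdir)
        estimates = _arrest(cfg, tab, mm, mm_u, emb, asn, outdir)
        tset, result = _fit(cfg, traj_raw, estimates, asn, outdir)
        profiles = _profile(cfg, tset, result, outdir)
        threshold = _predict_gf(cfg, result, tset, outdir)
        untreated_regime = _fitted_untreated_regime(result, tset)
        summary = {
            "version": __version__,
            "seed": cfg.seed,
            "period": cfg.period,
            "arrest_estimates": {
                c: {"arrest_time": d["estimate"].arrest_time,
                    "arrest_angle": d["estimate"].arrest_angle,
                    "dispersion": d["estimate"].dispersion,
                    "median_drift_rad": d["drift"]}
                for c, d in estimates.items()},
            "fit": {"objective": result.objective,
                    "converged": result.converged,
                    "estimates": {n: getattr(result.estimates, n)
                                  for n in result.free_names}},
            "profiles": {n: {"ci_95": list(p.ci_95),
                             "classification": p.classification}
                         for n, p in profiles.items()},
            "gf_threshold": threshold,
            "untreated_regime": untreated_regime,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
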
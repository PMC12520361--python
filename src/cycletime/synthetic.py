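"""Synthetic single-cell snapshot generator.

Emulates the structure of multiplexed immunofluorescence snapshots of an
unsynchronised proliferating population: cells are scattered along the
model's limit cycle (uniformly in time under the ergodic assumption, or
with the exponential age density of a doubling population), observed with
multiplicative lognormal noise, and optionally arrested by simulating drug
switches for a fixed treatment duration.  True phases and states are
emitted in ``__``-prefixed columns for use as test oracles only.

The noise law of the real assay is not known; the multiplicative lognormal
model used here is a stand-in chosen because intensities are positive with
roughly constant coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    MEASURED_INDICES,
    STATE_NAMES,
    DrugCondition,
    ModelParameters,
    Trajectory,
    classify_regime,
    simulate,
)

__all__ = [
    "MEASURED_MARKERS",
    "EXTRA_MARKER_POOL",
    "PhaseStateMap",
    "SnapshotSpec",
    "make_limit_cycle",
    "sample_snapshot",
    "sample_arrested_snapshot",
    "sample_phase_concentrated",
    "arrest_reference_phase",
]

#: Column names of the five modelled, measured markers.
MEASURED_MARKERS = ("p21", "cycD", "cycE", "cycA", "cycB")

#: Names used for the non-modelled bump markers, mirroring a typical panel.
EXTRA_MARKER_POOL = ("pRB", "CDT1", "Gem", "p27", "Ki67", "PCNA", "MCM2")

TRUE_PHASE_COL = "__true_phase"
TRUE_STATE_PREFIX = "__true_state_"


@dataclass
class PhaseStateMap:
    """One period of the limit cycle resampled on a uniform phase grid.

    Phase is time along the cycle divided by the period, with phase zero at
    a cyclin B maximum (M phase).  Because phase is proportional to time,
    ergodic (uniform-in-time) sampling is uniform in phase.
    """

    period: float
    phase_grid: np.ndarray  # in [0, 1), strictly increasing
    states: np.ndarray      # (resolution, 6) in STATE_NAMES order

    def __post_init__(self) -> None:
        self.phase_grid = np.asarray(self.phase_grid, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if np.any(np.diff(self.phase_grid) <= 0):
            raise ValueError("phase_grid must be strictly increasing")
        if self.states.shape != (self.phase_grid.size, 6):
            raise ValueError("states must be (len(phase_grid), 6)")

    def states_at(self, phases) -> np.ndarray:
        """Periodic linear interpolation of the state at arbitrary phases."""
        phases = np.atleast_1d(np.asarray(phases, dtype=float)) % 1.0
        g = np.concatenate([self.phase_grid, [self.phase_grid[0] + 1.0]])
        s = np.vstack([self.states, self.states[:1]])
        out = np.empty((phases.size, 6))
        for j in range(6):
            out[:, j] = np.interp(phases, g, s[:, j], period=1.0)
        return out


@dataclass
class SnapshotSpec:
    """Specification of one synthetic snapshot table."""

    n_cells: int
    noise_cv: float = 0.2
    n_extra_markers: int = 7
    sampling: str = "ergodic"  # "ergodic" | "exponential-age"
    condition: str = "untreated"
    gf_fraction: float | None = None
    treatment_duration: float = 24.0
    offsets: np.ndarray | None = None  # per measured marker, a.u.
    seed: int = 0
    panel_seed: int = 0  # fixes the extra-marker profiles across tables

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_extra_markers < 0:
            raise ValueError("n_extra_markers must be nonnegative")
        if self.sampling not in ("ergodic", "exponential-age"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.condition not in ("untreated", "nocodazole", "palbociclib",
                                  "gf_fraction"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "gf_fraction" and self.gf_fraction is None:
            raise ValueError("gf_fraction condition requires a gf_fraction value")
        if self.condition != "untreated" and self.treatment_duration <= 0:
            raise ValueError("treatment_duration must be positive for treatment")
        self.offsets = (np.zeros(5) if self.offsets is None
                        else np.asarray(self.offsets, dtype=float))
        if self.offsets.shape != (5,):
            raise ValueError("offsets must have one entry per measured marker")

    def drug_condition(self) -> DrugCondition:
        if self.condition == "gf_fraction":
            return DrugCondition.untreated(gf_scale=float(self.gf_fraction))
        return DrugCondition.from_label(self.condition)

    def extra_marker_names(self) -> list[str]:
        names = list(EXTRA_MARKER_POOL[: self.n_extra_markers])
        names += [f"extra{i}" for i in range(len(names), self.n_extra_markers)]
        return names


def make_limit_cycle(
    params: ModelParameters,
    burn_in: float = 480.0,
    resolution: int = 512,
    condition: DrugCondition | None = None,
    init=None,
    dt_sample: float = 0.02,
    use_fast: bool = False,
) -> PhaseStateMap:
    """Integrate to the limit cycle and resample one period uniformly.

    The period is estimated from successive cyclin B maxima after
    ``burn_in`` hours (which should exceed two periods).  Raises
    ``RuntimeError`` when the trajectory does not settle on a regular
    oscillation, e.g. for arrested parameter regimes such as ``GF = 0``.
    """
    if resolution < 8:
        raise ValueError("resolution must be at least 8")
    condition = condition or DrugCondition.untreated()
    s0 = np.array([0.1, 0.5, 0.5, 0.5, 0.5, 0.1]) if init is None else \
        np.asarray(init, dtype=float)
    t_end = burn_in + 6 * 30.0  # room for >= 3 peaks at periods up to ~60 h
    t_grid = np.arange(0.0, t_end + dt_sample, dt_sample)
    if use_fast:
        from ._fast import integrate_fast
        states = np.clip(integrate_fast(params, s0, condition, t_grid), 0, None)
        traj = Trajectory(times=t_grid, states=states, condition=condition)
    else:
        traj = simulate(params, s0, condition, t_grid, rtol=1e-9, atol=1e-11)
    tail = t_grid >= burn_in
    report = classify_regime(
        Trajectory(times=t_grid[tail], states=traj.states[tail], condition=condition),
        params, tail_fraction=0.0)
    if report.regime != "oscillating":
        raise RuntimeError(
            f"no oscillation detected (regime = {report.regime}); "
            "parameters outside the oscillatory regime")
    from .model import _peak_times
    tp = _peak_times(t_grid[tail], traj.states[tail, 5])
    period = float(np.mean(np.diff(tp)))
    t0 = tp[-2]
    sample_t = t0 + np.arange(resolution) / resolution * period
    states = np.empty((resolution, 6))
    for j in range(6):
        states[:, j] = np.interp(sample_t, t_grid, traj.states[:, j])
    return PhaseStateMap(period=period,
                         phase_grid=np.arange(resolution) / resolution,
                         states=np.clip(states, 0.0, None))


def _draw_phases(spec: SnapshotSpec, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(spec.n_cells)
    if spec.sampling == "ergodic":
        return u
    # exponential age density of a doubling population: p(t) ~ 2^(-t/T),
    # CDF F(t) = 2 (1 - 2^(-t/T)); invert u = F(t) and divide by T.
    return -np.log2(1.0 - 0.5 * u)


def _extra_marker_profiles(spec: SnapshotSpec):
    """Randomised von-Mises-shaped bumps of phase.

    Drawn from ``panel_seed`` (not the table seed): the profiles define the
    *panel*, so tables of different conditions or replicates share the same
    marker-vs-phase relationships, as a real staining panel would.
    """
    rng = np.random.default_rng(spec.panel_seed)
    n = spec.n_extra_markers
    centers = rng.random(n)
    kappas = rng.uniform(2.0, 8.0, n)
    amps = rng.uniform(0.5, 2.0, n)
    bases = rng.uniform(0.1, 0.5, n)

    def profile(phases: np.ndarray) -> np.ndarray:
        ph = phases[:, None]
        return bases + amps * np.exp(
            kappas * (np.cos(2 * np.pi * (ph - centers)) - 1.0))

    return profile


def _noise_factors(rng, cv, shape):
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=shape)


def nearest_cycle_phase(states: np.ndarray, lc_map: PhaseStateMap) -> np.ndarray:
    """Per-row nearest limit-cycle phase (measured coordinates only)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    ref = lc_map.states[:, list(MEASURED_INDICES)]
    q = states[:, list(MEASURED_INDICES)] if states.shape[1] == 6 else states
    d2 = ((q[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    return lc_map.phase_grid[np.argmin(d2, axis=1)]


def _assemble_table(spec, phases, true_states, rng, id_prefix, extras_phase=None):
    meas = true_states[:, list(MEASURED_INDICES)] + spec.offsets
    if meas.min() <= 0:
        raise ValueError("offsets produce nonpositive expected intensities")
    profile = _extra_marker_profiles(spec)
    extra_names = spec.extra_marker_names()
    ph_for_extras = phases if extras_phase is None else extras_phase
    extras = (profile(ph_for_extras) if extra_names
              else np.empty((spec.n_cells, 0)))
    obs = np.hstack([meas, extras])
    obs = obs * _noise_factors(rng, spec.noise_cv, obs.shape)
    cols = {"cell_id": [f"{id_prefix}{i:06d}" for i in range(spec.n_cells)],
            "condition": spec.condition}
    for j, name in enumerate(list(MEASURED_MARKERS) + extra_names):
        cols[name] = obs[:, j]
    cols[TRUE_PHASE_COL] = phases % 1.0
    for j, name in enumerate(STATE_NAMES):
        cols[TRUE_STATE_PREFIX + name] = true_states[:, j]
    return pd.DataFrame(cols)


def sample_snapshot(lc_map: PhaseStateMap, spec: SnapshotSpec) -> pd.DataFrame:
    """Sample an untreated snapshot table from a limit-cycle map.

    Cells are placed on the cycle uniformly in time (ergodic) or with the
    exponential age density; each observed intensity is
    ``(state + offset) * lognormal(1, noise_cv)``.  Extra markers are smooth
    unimodal bumps of phase with the same noise model.
    """
    if spec.condition != "untreated":
        raise ValueError("sample_snapshot requires condition='untreated'; "
                         "use sample_arrested_snapshot for treatments")
    rng = np.random.default_rng(spec.seed)
    phases = _draw_phases(spec, rng)
    true_states = lc_map.states_at(phases)
    return _assemble_table(spec, phases, true_states, rng, "u")


def sample_arrested_snapshot(
    params: ModelParameters,
    lc_map: PhaseStateMap,
    spec: SnapshotSpec,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Sample a drug- or starvation-arrested endpoint snapshot.

    Each cell starts from a random phase of the untreated cycle (as in
    :func:`sample_snapshot`), is integrated under the condition's switches
    for ``treatment_duration`` hours, and its final state is observed with
    noise.  Extra (non-modelled) markers track the cell's *current* state:
    they are evaluated at the nearest limit-cycle phase of the final state.
    ``__true_phase`` records the *initial* phase, ``__arrest_phase`` the
    per-cell effective final phase; the true final state is stored in the
    ``__true_state_*`` columns.
    """
    if spec.condition == "untreated":
        raise ValueError("use sample_snapshot for untreated cells")
    from ._fast import integrate_batch
    rng = np.random.default_rng(spec.seed)
    phases = _draw_phases(spec, rng)
    inits = lc_map.states_at(phases)
    finals = integrate_batch(params, inits, spec.drug_condition(),
                             spec.treatment_duration, dt=dt)
    if not np.all(np.isfinite(finals)):
        bad = np.where(~np.isfinite(finals).all(axis=1))[0]
        raise RuntimeError(f"integration failed for cells {bad.tolist()[:10]}")
    finals = np.clip(finals, 0.0, None)
    eff_phase = nearest_cycle_phase(finals, lc_map)
    tab = _assemble_table(spec, phases, finals, rng,
                          spec.condition[:4] + "_", extras_phase=eff_phase)
    tab["__arrest_phase"] = eff_phase
    return tab


def sample_phase_concentrated(
    lc_map: PhaseStateMap,
    spec: SnapshotSpec,
    phase: float,
    kappa: float = 30.0,
) -> pd.DataFrame:
    """Snapshot of cells concentrated at one *on-cycle* phase.

    Models an arrested population whose whole marker profile is consistent
    with a single point of the cycle (phase drawn from a von Mises around
    ``phase``); the arrest phase of such a table is unambiguous, unlike a
    drug-switch endpoint that may leave the cycle manifold.
    """
    rng = np.random.default_rng(spec.seed)
    phases = (phase + rng.vonmises(0.0, kappa, spec.n_cells)
              / (2 * np.pi)) % 1.0
    true_states = lc_map.states_at(phases)
    return _assemble_table(spec, phases, true_states, rng, "conc_")


def arrest_reference_phase(
    params: ModelParameters,
    lc_map: PhaseStateMap,
    condition: DrugCondition,
    treatment_duration: float = 24.0,
    n_init: int = 64,
    dt: float = 0.01,
) -> float:
    """Ground-truth arrest phase: endpoint ensemble mapped back to the cycle.

    Integrates the treated system from ``n_init`` phases spread over the
    cycle, averages the endpoints, and returns the phase of the nearest
    limit-cycle point in the five measured coordinates.  Used as the oracle
    for arrest-time estimation.
    """
    from ._fast import integrate_batch
    from .model import arrest_phase

    inits = lc_map.states_at(np.arange(n_init) / n_init)
    finals = integrate_batch(params, inits, condition, treatment_duration, dt=dt)
    mean_final = finals.mean(axis=0)
    idx, _, _ = arrest_phase(mean_final, lc_map.states, lc_map.phase_grid)
    return float(lc_map.phase_grid[idx])
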
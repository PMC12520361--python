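"""Six-variable cell-cycle ODE model with drug switches.

The model tracks the CDK inhibitor p21/p27 (one entity, ``p21``), cyclins D,
E, A and B (``Cd``, ``Ce``, ``Ca``, ``Cb``) and the active fraction of the
E2F transcription factor (``E2Fa``; the inactive fraction is the remainder
of a conserved total ``E2Ft``).  Untreated cells live on a limit cycle;
nocodazole (``delta_noco = 1``, stabilising p21) and palbociclib
(``delta_palbo = 0``, removing CDK4/6-cyclin D action on pRB) switch the
system into a globally attracting arrested steady state.  Growth-factor
starvation is modelled by scaling the ``GF`` input.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "STATE_NAMES",
    "MEASURED_STATES",
    "MEASURED_INDICES",
    "KINETIC_NAMES",
    "ModelState",
    "ModelParameters",
    "DrugCondition",
    "Trajectory",
    "RegimeReport",
    "rhs",
    "observable",
    "simulate",
    "classify_regime",
    "gf_scan",
    "arrest_phase",
]

#: State ordering used by every array interface in this package.
STATE_NAMES = ("p21", "Cd", "E2Fa", "Ce", "Ca", "Cb")

#: Species observed by the immunofluorescence panel (E2Fa is unmeasured).
MEASURED_STATES = ("p21", "Cd", "Ce", "Ca", "Cb")
MEASURED_INDICES = (0, 1, 3, 4, 5)

#: Kinetic parameter ordering for array interfaces.
KINETIC_NAMES = (
    "Vsp", "Vsd", "Vse", "Vsa", "Vsb",
    "kx", "kdd", "kdd1", "kde", "kda", "kdb",
    "kpi", "kpii", "kpiii", "IEn",
)

_DEG_NAMES = ("Vdp", "Vdd", "Vde", "Vda", "Vdb")


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state; concentrations in arbitrary units."""

    p21: float
    Cd: float
    E2Fa: float
    Ce: float
    Ca: float
    Cb: float

    def to_array(self) -> np.ndarray:
        return np.array([self.p21, self.Cd, self.E2Fa, self.Ce, self.Ca, self.Cb])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "ModelState":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValueError(f"expected a 6-vector, got shape {a.shape}")
        return cls(*a)

    def validate(self, E2Ft: float = 1.0, tol: float = 1e-9) -> None:
        a = self.to_array()
        if np.any(a < -tol):
            raise ValueError(f"negative state component: {self}")
        if self.E2Fa > E2Ft + tol:
            raise ValueError(f"E2Fa={self.E2Fa} exceeds E2Ft={E2Ft}")


@dataclass
class ModelParameters:
    """Kinetic constants, drug strength, observation offsets and fitted inits.

    Synthesis and degradation of each species share a single rate constant
    (``Vsp`` .. ``Vsb``).  Setting any of the optional ``Vd*`` fields
    decouples the degradation rate of the corresponding species for
    sensitivity studies; ``None`` keeps the shared convention.
    """

    Vsp: float = 0.7531
    Vsd: float = 9.7117
    Vse: float = 0.1965
    Vsa: float = 1.1846
    Vsb: float = 7.5309
    kx: float = 0.4749
    kdd: float = 1.1023
    kdd1: float = 1.6388
    kde: float = 0.2187
    kda: float = 5.7373
    kdb: float = 2.0818
    kpi: float = 1.0051
    kpii: float = 0.3410
    kpiii: float = 7.7088
    IEn: float = 2.8543
    E2Ft: float = 1.0
    GF: float = 1.0
    offset_p21: float = 0.0
    offset_Cd: float = 0.0
    offset_Ce: float = 0.0
    offset_Ca: float = 0.0
    offset_Cb: float = 0.0
    init_E2F_G1S: float = 0.5
    init_E2F_G2M: float = 0.5
    Vdp: float | None = None
    Vdd: float | None = None
    Vde: float | None = None
    Vda: float | None = None
    Vdb: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in KINETIC_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name}={v} must be nonnegative and finite")
            if name != "IEn" and v <= 0:
                raise ValueError(f"parameter {name}={v} must be positive")
        if self.E2Ft <= 0:
            raise ValueError("E2Ft must be positive")
        if self.GF < 0:
            raise ValueError("GF must be nonnegative")
        for name in ("init_E2F_G1S", "init_E2F_G2M"):
            v = getattr(self, name)
            if not 0.0 <= v <= self.E2Ft:
                raise ValueError(f"{name}={v} outside [0, E2Ft]")

    # -- array plumbing -------------------------------------------------

    def kinetic_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in KINETIC_NAMES], dtype=float)

    def degradation_array(self) -> np.ndarray:
        """Effective degradation rate constants (Vdp..Vdb, shared-V default)."""
        shared = (self.Vsp, self.Vsd, self.Vse, self.Vsa, self.Vsb)
        return np.array(
            [s if d is None else d
             for s, d in zip(shared, (self.Vdp, self.Vdd, self.Vde, self.Vda, self.Vdb))],
            dtype=float,
        )

    def offsets(self) -> np.ndarray:
        return np.array([self.offset_p21, self.offset_Cd, self.offset_Ce,
                         self.offset_Ca, self.offset_Cb], dtype=float)

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        return cls(**dict(d))


@dataclass(frozen=True)
class DrugCondition:
    """Binary drug switches plus a growth-factor multiplier.

    ``delta_palbo`` equals 1 in the *absence* of palbociclib (the drug turns
    the CDK4/6-cyclin D term off), while ``delta_noco`` equals 1 in the
    *presence* of nocodazole.
    """

    delta_noco: int = 0
    delta_palbo: int = 1
    gf_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_noco not in (0, 1) or self.delta_palbo not in (0, 1):
            raise ValueError("drug switches must be 0 or 1")
        if self.gf_scale < 0:
            raise ValueError("gf_scale must be nonnegative")

    @classmethod
    def untreated(cls, gf_scale: float = 1.0) -> "DrugCondition":
        return cls(0, 1, gf_scale)

    @classmethod
    def nocodazole(cls) -> "DrugCondition":
        return cls(1, 1, 1.0)

    @classmethod
    def palbociclib(cls) -> "DrugCondition":
        return cls(0, 0, 1.0)

    @classmethod
    def from_label(cls, label: str, gf_scale: float = 1.0) -> "DrugCondition":
        label = label.lower()
        if label == "untreated":
            return cls.untreated(gf_scale)
        if label == "nocodazole":
            return cls.nocodazole()
        if label == "palbociclib":
            return cls.palbociclib()
        raise ValueError(f"unknown condition label: {label!r}")


@dataclass
class Trajectory:
    """Integrated model trajectory on an explicit time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 6) in STATE_NAMES order
    condition: DrugCondition

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 6):
            raise ValueError("states must be (n_times, 6)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]


@dataclass
class RegimeReport:
    regime: str  # "oscillating" | "arrested" | "undetermined"
    period: float | None = None
    amplitude: np.ndarray | None = None  # per-variable peak-to-peak over the tail
    steady_state: np.ndarray | None = None


def _rhs_arrays(s, kin, deg, E2Ft, gf, dnoco, dpalbo):
    p21, Cd, E2Fa, Ce, Ca, Cb = s
    (Vsp, Vsd, Vse, Vsa, Vsb,
     kx, kdd, kdd1, kde, kda, kdb,
     kpi, kpii, kpiii, IEn) = kin
    Vdp, Vdd, Vde, Vda, Vdb = deg
    act = kpii / (kpii + p21)  # p21/p27 inhibition of CDK2/CDK1-cyclin activity
    return np.array([
        Vsp * E2Fa - Vdp * p21 * (Cb / (kx + Cb)) / (1.0 + IEn * dnoco),
        Vsd * gf * E2Fa - Vdd * (Cd / (Cd + kdd)),
        (E2Ft - E2Fa) * (kpiii / (kpiii + Cb))
        * ((Cd / (Cd + kdd1)) * dpalbo + Ce * (kpi / (kpi + p21)))
        - E2Fa * Ca * act,
        Vse * E2Fa - Vde * (Ce / (Ce + kde)) * Ca * act,
        Vsa * E2Fa - Vda * (Ca / (Ca + kda)),
        Vsb * Ca * act - Vdb * (Cb / (Cb + kdb)),
    ])


def rhs(state, params: ModelParameters, condition: DrugCondition = DrugCondition.untreated()):
    """Time derivative of the six state variables.

    Parameters
    ----------
    state : ModelState or 6-vector in :data:`STATE_NAMES` order.
    params : ModelParameters
    condition : DrugCondition

    Returns
    -------
    numpy.ndarray
        Derivatives ``d(p21, Cd, E2Fa, Ce, Ca, Cb)/dt``.
    """
    params.validate()
    s = state.to_array() if isinstance(state, ModelState) else np.asarray(state, float)
    if s.shape != (6,):
        raise ValueError("state must be a 6-vector")
    return _rhs_arrays(
        s, params.kinetic_array(), params.degradation_array(),
        params.E2Ft, params.GF * condition.gf_scale,
        float(condition.delta_noco), float(condition.delta_palbo),
    )


def observable(state, params: ModelParameters) -> np.ndarray:
    """Measured outputs: the five assayed species plus background offsets."""
    s = state.to_array() if isinstance(state, ModelState) else np.asarray(state, float)
    if s.ndim == 1:
        return s[list(MEASURED_INDICES)] + params.offsets()
    return s[:, list(MEASURED_INDICES)] + params.offsets()


def simulate(
    params: ModelParameters,
    init,
    condition: DrugCondition,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model on ``t_grid`` with a stiff-capable solver.

    States slightly below zero (within ``-atol``) are clipped; materially
    negative states raise, because silent clipping would mask solver failure.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    s0 = init.to_array() if isinstance(init, ModelState) else np.asarray(init, float)
    if s0.shape != (6,):
        raise ValueError("init must be a 6-vector")
    kin = params.kinetic_array()
    deg = params.degradation_array()
    args = (kin, deg, params.E2Ft, params.GF * condition.gf_scale,
            float(condition.delta_noco), float(condition.delta_palbo))
    sol = solve_ivp(
        lambda t, y: _rhs_arrays(y, *args),
        (t_grid[0], t_grid[-1]), s0,
        t_eval=t_grid, method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    states = sol.y.T
    if states.min() < -atol:
        raise RuntimeError(
            f"materially negative state ({states.min():.3e}) — solver failure?")
    return Trajectory(times=t_grid, states=np.clip(states, 0.0, None),
                      condition=condition)


def _peak_times(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Interior local-maximum times, with parabolic sub-sample refinement."""
    i = np.where((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]))[0] + 1
    if i.size == 0:
        return np.empty(0)
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    shift = np.where(np.abs(denom) > 1e-300,
                     0.5 * (x[i - 1] - x[i + 1]) / denom, 0.0)
    dt = np.gradient(t)[i]
    return t[i] + np.clip(shift, -1, 1) * dt


def classify_regime(
    traj: Trajectory,
    params: ModelParameters | None = None,
    tail_fraction: float = 0.5,
    tol_amp_rel: float = 0.05,
    tol_ss: float = 1e-6,
    period_cv: float = 0.05,
) -> RegimeReport:
    """Classify a trajectory as oscillating, arrested or undetermined.

    Oscillating requires the cyclin B peak-to-peak amplitude over the tail
    of the trajectory to exceed ``tol_amp_rel`` times its tail mean, with at
    least three peaks whose spacings agree within ``period_cv``.  Arrested
    requires ``max |d/dt|`` at the final state below ``tol_ss`` (checked when
    ``params`` is given; otherwise a flat tail is accepted as arrested).
    """
    t, y = traj.times, traj.states
    tail = t >= t[0] + tail_fraction * (t[-1] - t[0])
    cb = y[tail, 5]
    tt = t[tail]
    amplitude = y[tail].max(axis=0) - y[tail].min(axis=0)
    amp = cb.max() - cb.min()
    if amp >= tol_amp_rel * max(cb.mean(), 1e-12):
        tp = _peak_times(tt, cb)
        if tp.size >= 3:
            spacing = np.diff(tp)
            if spacing.std() <= period_cv * spacing.mean():
                return RegimeReport("oscillating", period=float(spacing.mean()),
                                    amplitude=amplitude)
        return RegimeReport("undetermined", amplitude=amplitude)
    final = y[-1]
    if params is not None:
        d = rhs(final, params, traj.condition)
        if np.abs(d).max() >= tol_ss:
            return RegimeReport("undetermined", amplitude=amplitude)
    return RegimeReport("arrested", amplitude=amplitude, steady_state=final)


def gf_scan(
    params: ModelParameters,
    inits: Sequence,
    gf_grid: Sequence[float],
    n_cycles: float = 100.0,
    period_guess: float = 24.0,
    dt_per_period: int = 600,
    use_fast: bool = True,
) -> tuple[dict[float, list[RegimeReport]], float | None]:
    """Scan growth-factor levels downward and find where oscillation is lost.

    Simulates every ``gf_scale`` in ``gf_grid`` (descending from 1.0) from
    every initial condition in ``inits`` over ``n_cycles`` nominal periods.
    Returns per-level regime reports and the oscillation-loss threshold: the
    largest scanned level at which *no* initial condition oscillates.
    """
    gf_grid = list(gf_grid)
    if gf_grid != sorted(gf_grid, reverse=True):
        raise ValueError("gf_grid must be descending")
    t_end = n_cycles * period_guess
    t_grid = np.linspace(0.0, t_end, int(n_cycles * dt_per_period) + 1)
    reports: dict[float, list[RegimeReport]] = {}
    threshold = None
    for gf in gf_grid:
        cond = DrugCondition.untreated(gf_scale=gf)
        reps = []
        for s0 in inits:
            if use_fast:
                from ._fast import integrate_fast
                states = integrate_fast(params, s0, cond, t_grid)
                traj = Trajectory(times=t_grid, states=np.clip(states, 0, None),
                                  condition=cond)
            else:
                traj = simulate(params, s0, cond, t_grid)
            reps.append(classify_regime(traj, params))
        reports[gf] = reps
        if threshold is None and all(r.regime != "oscillating" for r in reps):
            threshold = gf
    return reports, threshold


def arrest_phase(
    final_state,
    ref_states: np.ndarray,
    ref_times: np.ndarray,
    boundaries: Mapping[str, float] | None = None,
    period: float | None = None,
    measured_only: bool = True,
):
    """Map an arrested state to the nearest point of a reference cycle.

    Euclidean nearest neighbour over the five measured coordinates (E2Fa is
    excluded as unmeasured); ties resolve to the lowest index.  Warns when
    the distance exceeds three times the reference's median inter-point
    spacing (off-manifold state).

    Parameters
    ----------
    final_state : 6-vector (or 5-vector when ``measured_only``).
    ref_states : (n, 6) or (n, 5) array covering one full period.
    ref_times : per-row pseudo-times (hours).
    boundaries : optional mapping ``{"M/G1": t0, "S/G2": t1}`` used for the
        phase label; without it the label is ``""``.

    Returns
    -------
    (index, time, label)
    """
    s = np.asarray(final_state, dtype=float)
    ref = np.asarray(ref_states, dtype=float)
    ref_times = np.asarray(ref_times, dtype=float)
    if measured_only:
        if s.shape == (6,):
            s = s[list(MEASURED_INDICES)]
        if ref.shape[1] == 6:
            ref = ref[:, list(MEASURED_INDICES)]
    d = np.linalg.norm(ref - s, axis=1)
    idx = int(np.argmin(d))
    spacing = np.linalg.norm(np.diff(ref, axis=0), axis=1)
    med_sp = float(np.median(spacing)) if spacing.size else 0.0
    if med_sp > 0 and d[idx] > 3.0 * med_sp:
        warnings.warn(
            f"arrested state is {d[idx]/med_sp:.1f}x the reference spacing "
            "away from the cycle (off-manifold)", RuntimeWarning)
    t = float(ref_times[idx])
    label = ""
    if boundaries and period:
        mg1 = boundaries.get("M/G1", 0.0)
        sg2 = boundaries.get("S/G2")
        rel = (t - mg1) % period
        if sg2 is not None:
            split = (sg2 - mg1) % period
            label = "G1/S" if rel < split else "G2/M"
            if rel < 0.25 * period:
                label = "early G1"
        else:
            label = "early G1" if rel < 0.25 * period else ""
    return idx, t, label
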
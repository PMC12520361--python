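"""Pseudo-time ordering of single-cell snapshots around the cell cycle.

The pipeline is: log/z-score preprocessing, classical multidimensional
scaling (CMD) to two dimensions, algebraic circle fit, per-cell angles with
a deterministic orientation (cyclin A peak precedes cyclin B along
increasing angle), and angle-to-time mapping either under the ergodic
assumption (equidistant times on sorted angles) or with the exponential-age
inversion for a doubling population.  Marker trajectories are summarised by
circular moving medians and moving median absolute deviations (movMMAD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "MarkerMatrix",
    "CircularEmbedding",
    "PseudotimeAssignment",
    "MarkerTrajectory",
    "preprocess",
    "cmd_embed",
    "fit_circle",
    "angles",
    "ergodic_times",
    "kafri_time",
    "kafri_times",
    "moving_stats",
    "phase_boundaries",
    "mg1_angle",
    "loo_marker_robustness",
    "bh_adjust",
    "circular_corr",
    "procrustes_transform",
]

META_COLUMNS = ("cell_id", "condition")

_CYCLIN_A_ALIASES = ("cyca", "cyclina", "cyclin_a", "cyclin a", "ccna", "ca")
_CYCLIN_B_ALIASES = ("cycb", "cyclinb", "cyclin_b", "cyclin b", "ccnb", "cb")
_CYCLIN_ALIASES = _CYCLIN_A_ALIASES + _CYCLIN_B_ALIASES + (
    "cycd", "cyclind", "cyclin_d", "cyclin d", "ccnd", "cd",
    "cyce", "cycline", "cyclin_e", "cyclin e", "ccne", "ce",
)


@dataclass
class MarkerMatrix:
    """Cells x markers matrix of log-scaled, per-marker standardised values."""

    values: np.ndarray
    marker_names: list[str]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length must match columns")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_id")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.marker_names.index(name)]

    def drop(self, name: str) -> "MarkerMatrix":
        keep = [i for i, n in enumerate(self.marker_names) if n != name]
        if len(keep) == len(self.marker_names):
            raise KeyError(name)
        return MarkerMatrix(self.values[:, keep],
                            [self.marker_names[i] for i in keep], self.cell_ids)


@dataclass
class CircularEmbedding:
    """2-D CMD coordinates with fitted circle and oriented per-cell angles.

    ``flip`` and ``zero`` record the deterministic orientation fix so the
    identical transform can be applied to cells embedded later into the
    same frame (:meth:`angle_of`).
    """

    coords: np.ndarray
    center: np.ndarray
    radius: float
    angle: np.ndarray  # oriented, in [0, 2*pi)
    flip: bool = False
    zero: float = 0.0

    def angle_of(self, coords: np.ndarray) -> np.ndarray:
        """Oriented angle of arbitrary points in this embedding's frame."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        raw = np.arctan2(coords[:, 1] - self.center[1],
                         coords[:, 0] - self.center[0])
        theta = (-raw if self.flip else raw) - self.zero
        return np.mod(theta, 2 * np.pi)

    def with_zero(self, zero_angle: float) -> "CircularEmbedding":
        """Rotate the angular origin to ``zero_angle`` (current frame)."""
        new = replace(self)
        new.zero = (self.zero + zero_angle) % (2 * np.pi)
        new.angle = np.mod(self.angle - zero_angle, 2 * np.pi)
        return new


@dataclass
class PseudotimeAssignment:
    """Per-cell times in [0, T) plus the monotone angle-to-time map."""

    time: np.ndarray
    T: float
    sorted_angles: np.ndarray  # ascending oriented angles
    sorted_times: np.ndarray   # times of the sorted cells
    boundaries: dict = field(default_factory=dict)  # label -> (angle, time)

    def time_at_angle(self, query) -> np.ndarray:
        """Interpolate the monotone angle->time map, wrapping at the period."""
        q = np.atleast_1d(np.asarray(query, dtype=float)) % (2 * np.pi)
        th = np.concatenate([[self.sorted_angles[-1] - 2 * np.pi],
                             self.sorted_angles,
                             [self.sorted_angles[0] + 2 * np.pi]])
        t = np.concatenate([[self.sorted_times[-1] - self.T],
                            self.sorted_times,
                            [self.sorted_times[0] + self.T]])
        return np.mod(np.interp(q, th, t), self.T)


@dataclass
class MarkerTrajectory:
    """Moving median / MAD of each marker on a circular pseudo-time grid."""

    grid: np.ndarray
    med: np.ndarray  # (n_grid, n_markers)
    mad: np.ndarray
    marker_names: list[str]
    period: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mad < 0):
            raise ValueError("mad must be nonnegative")

    def med_at(self, t, marker: str) -> np.ndarray:
        j = self.marker_names.index(marker)
        return np.interp(np.asarray(t, float) % self.period, self.grid,
                         self.med[:, j], period=self.period)

    def mad_at(self, t, marker: str) -> np.ndarray:
        j = self.marker_names.index(marker)
        return np.interp(np.asarray(t, float) % self.period, self.grid,
                         self.mad[:, j], period=self.period)


# ---------------------------------------------------------------------------
# preprocessing and embedding
# ---------------------------------------------------------------------------

def marker_columns(raw: pd.DataFrame) -> list[str]:
    """Marker columns of a snapshot table (everything but metadata/hidden)."""
    return [c for c in raw.columns
            if c not in META_COLUMNS and not c.startswith("__")]

def preprocess(raw: pd.DataFrame, markers: list[str] | None = None) -> MarkerMatrix:
    """Log10-transform and z-score marker intensities.

    Nonpositive raw intensities are floored to the smallest positive value
    of the same marker before taking logs (background-subtracted data can
    contain zeros).  Raises on markers with zero variance.
    """
    markers = markers or marker_columns(raw)
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    X = raw[markers].to_numpy(dtype=float).copy()
    for j, name in enumerate(markers):
        col = X[:, j]
        pos = col > 0
        if not pos.any():
            raise ValueError(f"marker {name!r} has no positive intensities")
        col[~pos] = col[pos].min()
        X[:, j] = np.log10(col)
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population SD: two distinct cells give z = +/-1
    if np.any(std < 1e-12):
        bad = [markers[j] for j in np.where(std < 1e-12)[0]]
        raise ValueError(f"zero-variance marker(s): {bad}")
    cell_ids = (raw["cell_id"].to_numpy() if "cell_id" in raw.columns
                else np.arange(len(raw)))
    return MarkerMatrix((X - mean) / std, list(markers), cell_ids)


def cmd_embed(m: MarkerMatrix | np.ndarray) -> np.ndarray:
    """Classical multidimensional scaling to two dimensions.

    Equivalent to eigendecomposition of the double-centred squared
    Euclidean distance matrix, computed as a thin SVD of the cell-centred
    data matrix (the Gram matrix of centred coordinates *is* the
    double-centred ``-D**2/2``).  Deterministic sign convention: within each
    component, the first coordinate of nonnegligible magnitude is positive.
    """
    X = m.values if isinstance(m, MarkerMatrix) else np.asarray(m, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    if S.size < 2 or S[1] ** 2 <= 1e-12 * max(1.0, S[0] ** 2):
        raise ValueError("top-2 CMD eigenvalues are not both positive "
                         "(degenerate configuration)")
    coords = U[:, :2] * S[:2]
    for j in range(2):
        col = coords[:, j]
        nz = np.where(np.abs(col) > 1e-9 * np.abs(col).max())[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    return coords


def fit_circle(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares (Kasa) circle fit; exact on noiseless circles."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x, y = coords[:, 0], coords[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("collinear points: circle fit is degenerate")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise ValueError("degenerate circle fit (nonpositive radius)")
    return np.array([cx, cy]), float(np.sqrt(r2))


def _binned_circular_median(theta, values, n_bins=60, smooth=5):
    """Per-angle-bin medians with circular moving-average smoothing."""
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    idx = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    med = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            med[b] = np.median(values[sel])
    if np.isnan(med).any():  # fill empty bins by circular interpolation
        good = ~np.isnan(med)
        centers = (edges[:-1] + edges[1:]) / 2
        med = np.interp(centers, centers[good], med[good], period=2 * np.pi)
    kernel = np.ones(smooth) / smooth
    pad = smooth // 2
    ext = np.concatenate([med[-pad:], med, med[:pad]])
    return np.convolve(ext, kernel, mode="valid"), edges


def _find_alias_column(names: list[str], aliases: tuple[str, ...]) -> str | None:
    lowered = {n.lower().replace(" ", "").replace("_", ""): n for n in names}
    for a in aliases:
        key = a.replace(" ", "").replace("_", "")
        if key in lowered:
            return lowered[key]
    return None


def angles(
    coords: np.ndarray,
    circle: tuple[np.ndarray, float],
    markers: MarkerMatrix | None = None,
    orientation_override: bool | None = None,
) -> CircularEmbedding:
    """Per-cell angles on the fitted circle with deterministic orientation.

    The rotational direction is fixed so that, along increasing angle, the
    binned-median peak of cyclin A precedes that of cyclin B (their forward
    circular gap is shorter than half a turn).  Pass
    ``orientation_override`` (True = mirror) when cyclin columns are absent.
    The angular origin is left untouched; rotate it to the M/G1 boundary
    with :meth:`CircularEmbedding.with_zero` once boundaries are known.
    """
    center, radius = circle
    coords = np.asarray(coords, dtype=float)
    raw = np.mod(np.arctan2(coords[:, 1] - center[1], coords[:, 0] - center[0]),
                 2 * np.pi)
    if orientation_override is not None:
        flip = bool(orientation_override)
    else:
        if markers is None:
            raise ValueError("markers required to fix orientation "
                             "(or pass orientation_override)")
        ca = _find_alias_column(markers.marker_names, _CYCLIN_A_ALIASES)
        cb = _find_alias_column(markers.marker_names, _CYCLIN_B_ALIASES)
        if ca is None or cb is None:
            raise ValueError("cyclin A/B columns not found and no "
                             "orientation_override supplied")
        sm_a, edges = _binned_circular_median(raw, markers.column(ca))
        sm_b, _ = _binned_circular_median(raw, markers.column(cb))
        centers = (edges[:-1] + edges[1:]) / 2
        peak_a = centers[np.argmax(sm_a)]
        peak_b = centers[np.argmax(sm_b)]
        flip = ((peak_b - peak_a) % (2 * np.pi)) > np.pi
    theta = np.mod(-raw, 2 * np.pi) if flip else raw
    return CircularEmbedding(coords=coords, center=np.asarray(center, float),
                             radius=float(radius), angle=theta, flip=flip)


# ---------------------------------------------------------------------------
# time inference
# ---------------------------------------------------------------------------

def _sorted_order(emb: CircularEmbedding) -> np.ndarray:
    # stable sort: ties broken by cell order (documented)
    return np.argsort(emb.angle, kind="stable")


def ergodic_times(emb: CircularEmbedding, T: float = 24.0) -> PseudotimeAssignment:
    """Equidistant times on sorted angles (uniform time marginal)."""
    n = emb.angle.size
    if n < 2:
        raise ValueError("need at least 2 cells")
    order = _sorted_order(emb)
    times = np.empty(n)
    times[order] = np.arange(n) * T / n
    return PseudotimeAssignment(time=times, T=T,
                                sorted_angles=emb.angle[order],
                                sorted_times=np.arange(n) * T / n)


def kafri_time(r, N: int, T: float = 24.0):
    """Exponential-age time of rank ``r`` among ``N`` cells:
    ``t = T * log2(2N / (2N - r))``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 2 * N):
        raise ValueError("rank must satisfy 0 <= r < 2N")
    return T * np.log2(2.0 * N / (2.0 * N - r))


def kafri_times(emb: CircularEmbedding, T: float = 24.0) -> PseudotimeAssignment:
    """Non-ergodic times from the age density of a doubling population.

    The cell of rank ``r`` along the oriented angle (``r`` cells younger)
    gets ``t = T log2(2N/(2N - r))``; monotone in ``r`` with ``t(0) = 0``
    and ``t -> T`` as ``r -> N``.
    """
    n = emb.angle.size
    if n < 2:
        raise ValueError("need at least 2 cells")
    order = _sorted_order(emb)
    st = np.asarray(kafri_time(np.arange(n), n, T))
    times = np.empty(n)
    times[order] = st
    return PseudotimeAssignment(time=times, T=T,
                                sorted_angles=emb.angle[order], sorted_times=st)


def default_window(n: int) -> int:
    w = max(51, round(n / 50))
    w = min(w, n)
    return w if w % 2 == 1 else w - 1


def moving_stats(
    values: MarkerMatrix | np.ndarray,
    pt: PseudotimeAssignment,
    window: int | None = None,
    n_grid: int = 100,
    marker_names: list[str] | None = None,
) -> MarkerTrajectory:
    """Circular moving median and moving MAD along pseudo-time.

    Cells are sorted by pseudo-time; at each of ``n_grid`` equally spaced
    grid times the ``window`` nearest cells in circular order contribute.
    ``values`` may be a :class:`MarkerMatrix` or any cells x markers array
    (e.g. raw intensities for model training).
    """
    if isinstance(values, MarkerMatrix):
        marker_names = values.marker_names
        X = values.values
    else:
        X = np.asarray(values, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        marker_names = marker_names or [f"m{j}" for j in range(X.shape[1])]
    n = X.shape[0]
    if pt.time.size != n:
        raise ValueError("pseudotime/value size mismatch")
    window = default_window(n) if window is None else window
    if window > n:
        raise ValueError(f"window {window} exceeds number of cells {n}")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    order = np.argsort(pt.time, kind="stable")
    ts = pt.time[order]
    Xs = X[order]
    grid = np.arange(n_grid) * pt.T / n_grid
    half = window // 2
    med = np.empty((n_grid, X.shape[1]))
    mad = np.empty_like(med)
    for g, t in enumerate(grid):
        c = np.searchsorted(ts, t)
        idx = np.arange(c - half, c + half + 1) % n
        w = Xs[idx]
        m = np.median(w, axis=0)
        med[g] = m
        mad[g] = np.median(np.abs(w - m), axis=0)
    return MarkerTrajectory(grid=grid, med=med, mad=mad,
                            marker_names=list(marker_names), period=pt.T)


# ---------------------------------------------------------------------------
# boundaries and robustness
# ---------------------------------------------------------------------------

def phase_boundaries(
    emb: CircularEmbedding,
    n_bins: int = 50,
    smooth_window: int = 5,
    min_relief: float = 0.4,
) -> np.ndarray:
    """Angles of the two deepest minima separating the two largest modes.

    Builds a circular histogram of angles, smooths it with a circular
    moving average, and locates the two largest local maxima; the returned
    boundaries are the lowest bins on the two arcs between them.  Returns
    an empty array for unimodal or near-uniform distributions (arrested
    populations), leaving phase annotation to the caller.
    """
    counts, edges = np.histogram(emb.angle, bins=n_bins, range=(0, 2 * np.pi))
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    ext = np.concatenate([counts[-pad:].astype(float), counts.astype(float),
                          counts[:pad].astype(float)])
    sm = np.convolve(ext, kernel, mode="valid")
    if (sm.max() - sm.min()) < min_relief * max(sm.mean(), 1.0):
        return np.empty(0)  # near-uniform: no stable minima
    prev = np.roll(sm, 1)
    nxt = np.roll(sm, -1)
    maxima = np.where((sm > prev) & (sm >= nxt))[0]
    if maxima.size < 2:
        return np.empty(0)  # unimodal
    top2 = maxima[np.argsort(sm[maxima])[-2:]]
    i, j = np.sort(top2)
    centers = (edges[:-1] + edges[1:]) / 2
    arc1 = np.arange(i, j + 1)                      # i -> j
    arc2 = np.concatenate([np.arange(j, n_bins), np.arange(0, i + 1)])  # j -> i
    b1 = centers[arc1[np.argmin(sm[arc1])]]
    b2 = centers[arc2[np.argmin(sm[arc2])]]
    return np.sort(np.array([b1, b2]))


def mg1_angle(emb: CircularEmbedding, markers: MarkerMatrix,
              boundaries: np.ndarray | None = None) -> float:
    """M/G1 transition angle: the point of minimum total cyclin expression.

    When two histogram boundaries are available the one with the lower
    summed cyclin level is labelled M/G1; otherwise the global minimum of
    the smoothed cyclin sum is used (robust for distributions without two
    clear modes).
    """
    cyc_cols = [n for n in markers.marker_names
                if _find_alias_column([n], _CYCLIN_ALIASES)]
    if not cyc_cols:
        raise ValueError("no cyclin columns found for M/G1 annotation")
    total = np.zeros(markers.n_cells)
    for n in cyc_cols:
        total += markers.column(n)
    sm, edges = _binned_circular_median(emb.angle, total)
    centers = (edges[:-1] + edges[1:]) / 2
    if boundaries is not None and len(boundaries) == 2:
        vals = np.interp(boundaries, centers, sm, period=2 * np.pi)
        return float(boundaries[np.argmin(vals)])
    return float(centers[np.argmin(sm)])


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def procrustes_transform(
    source: np.ndarray,
    target: np.ndarray,
    source_center: np.ndarray | None = None,
    target_center: np.ndarray | None = None,
):
    """Similarity transform (rotation/reflection + scale) between frames.

    Finds ``scale`` and orthogonal ``R`` minimising
    ``|| scale * (source - source_center) @ R - (target - target_center) ||``
    and returns ``(apply, residual_rms)`` where ``apply`` maps arbitrary
    points into the target frame.  Centers default to the point means.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    sc = source.mean(axis=0) if source_center is None else np.asarray(source_center)
    tc = target.mean(axis=0) if target_center is None else np.asarray(target_center)
    A = source - sc
    B = target - tc
    R, s = orthogonal_procrustes(A, B)
    scale = s / (A * A).sum()

    def apply(X: np.ndarray) -> np.ndarray:
        return scale * (np.asarray(X, float) - sc) @ R + tc

    residual = float(np.sqrt(np.mean(np.sum((apply(source) - target) ** 2, axis=1))))
    return apply, residual


def _aligned_loo_trajectory(mm, full_coords, ref_emb, pt_T, window, n_grid, drop):
    sub = mm.drop(drop)
    coords = cmd_embed(sub)
    apply_tf, _ = procrustes_transform(coords, full_coords)
    aligned = apply_tf(coords)
    theta = ref_emb.angle_of(aligned)
    order = np.argsort(theta, kind="stable")
    times = np.empty(theta.size)
    times[order] = np.arange(theta.size) * pt_T / theta.size
    pt = PseudotimeAssignment(time=times, T=pt_T,
                              sorted_angles=theta[order],
                              sorted_times=np.arange(theta.size) * pt_T / theta.size)
    return moving_stats(sub, pt, window=window, n_grid=n_grid)


def loo_marker_robustness(
    raw: pd.DataFrame,
    T: float = 24.0,
    window: int | None = None,
    n_grid: int = 100,
    pairing: str = "per-marker",
    orientation_override: bool | None = None,
) -> pd.DataFrame:
    """Leave-one-marker-out robustness of the embedding (paired t-tests).

    For every marker, the data are re-embedded without it (aligned back to
    the full-embedding frame by Procrustes so angle origins are shared),
    movMMAD is recomputed for the remaining markers on the shared grid, and
    a paired t-test compares the pooled movMMAD values against those from
    the full embedding.  ``pairing='per-marker'`` (default) pairs per-marker
    mean movMMAD values; ``'per-point'`` pairs every (marker, grid-point)
    value, which has more power but is anti-conservative because
    neighbouring grid points share moving windows (null simulations show an
    inflated type-I rate).  P-values are BH-adjusted across markers.
    """
    if pairing not in ("per-point", "per-marker"):
        raise ValueError("pairing must be 'per-point' or 'per-marker'")
    mm = preprocess(raw)
    if len(mm.marker_names) < 3:
        raise ValueError("need at least 3 markers")
    full_coords = cmd_embed(mm)
    circle = fit_circle(full_coords)
    emb = angles(full_coords, circle, mm,
                 orientation_override=orientation_override)
    pt = ergodic_times(emb, T)
    window = default_window(mm.n_cells) if window is None else window
    full_traj = moving_stats(mm, pt, window=window, n_grid=n_grid)
    rows = []
    for name in mm.marker_names:
        loo = _aligned_loo_trajectory(mm, full_coords, emb, T, window, n_grid, name)
        keep = [i for i, n in enumerate(full_traj.marker_names) if n != name]
        a = full_traj.mad[:, keep]
        b = loo.mad
        if pairing == "per-marker":
            a, b = a.mean(axis=0), b.mean(axis=0)
        res = stats.ttest_rel(a.ravel(), b.ravel())
        rows.append({"marker": name, "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def circular_corr(a, b) -> float:
    """Fisher-Lee circular correlation between two angle samples.

    Computed in O(n) via trigonometric sum identities; invariant to
    independent rotations of either sample and to sign-preserving
    reparameterisations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1-D samples, n >= 3")
    n = a.size

    def pair_cos_sum(u):
        # sum_{i<j} cos(u_i - u_j) = (|sum e^{iu}|^2 - n) / 2
        z = np.exp(1j * u).sum()
        return (np.abs(z) ** 2 - n) / 2.0

    num = 0.5 * (pair_cos_sum(a - b) - pair_cos_sum(a + b))
    npairs = n * (n - 1) / 2.0
    den_a = 0.5 * (npairs - pair_cos_sum(2 * a))
    den_b = 0.5 * (npairs - pair_cos_sum(2 * b))
    if den_a <= 0 or den_b <= 0:
        return 0.0
    return float(num / np.sqrt(den_a * den_b))
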
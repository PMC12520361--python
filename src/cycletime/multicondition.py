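"""Arrest-angle estimation on the untreated reference frame.

Treated (arrested) populations are unimodal in embedding space, so they
cannot be ordered on their own.  Instead, all untreated cells are
repeatedly co-embedded with small disjoint subsets of treated cells; the
untreated portion of each joint embedding is aligned back to the reference
frame by orthogonal Procrustes, the same transform is applied to the
treated cells, and the pooled treated angles yield an arrest mode that can
be read off the untreated angle-to-time map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import i1, iv

from .pseudotime import (
    CircularEmbedding,
    MarkerMatrix,
    PseudotimeAssignment,
    cmd_embed,
    fit_circle,
    procrustes_transform,
)

__all__ = [
    "ArrestEstimate",
    "partition_treated",
    "joint_embed_angles",
    "arrest_mode",
    "arrest_time",
    "estimate_arrest",
]


@dataclass
class ArrestEstimate:
    condition: str
    arrest_angle: float     # radians, reference frame
    arrest_time: float      # hours on the untreated map
    dispersion: float       # circular SD, radians
    n_cells: int
    phase_label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.arrest_angle < 2 * math.pi:
            raise ValueError("arrest_angle outside [0, 2*pi)")


def partition_treated(cell_ids, fraction: float = 0.05, seed: int = 0):
    """Seeded disjoint partition into ``ceil(1/fraction)`` near-equal subsets."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ids = np.asarray(cell_ids)
    n_subsets = math.ceil(1.0 / fraction)
    if ids.size < n_subsets:
        raise ValueError(f"cannot split {ids.size} cells into {n_subsets} "
                         "nonempty subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    return [ids[perm[k::n_subsets]] for k in range(n_subsets)]


def joint_embed_angles(
    untreated: MarkerMatrix,
    treated_subset: MarkerMatrix,
    reference: CircularEmbedding,
    max_residual: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Angles of treated cells in the untreated reference frame.

    Runs CMD on the concatenated matrix, aligns the untreated portion to
    ``reference.coords`` by a similarity Procrustes about the fitted circle
    centres, applies the same transform to the treated cells and returns
    their oriented angles plus the untreated median angular drift.

    Raises when the Procrustes residual exceeds ``max_residual`` times the
    reference radius (frame instability).
    """
    if untreated.marker_names != treated_subset.marker_names:
        raise ValueError("untreated and treated matrices must share markers")
    n_u = untreated.n_cells
    X = np.vstack([untreated.values, treated_subset.values])
    coords = cmd_embed(X)
    joint_center, _ = fit_circle(coords[:n_u])
    apply_tf, residual = procrustes_transform(
        coords[:n_u], reference.coords,
        source_center=joint_center, target_center=reference.center)
    if residual > max_residual * reference.radius:
        raise RuntimeError(
            f"Procrustes residual {residual:.3g} exceeds "
            f"{max_residual:.2f} x reference radius (frame instability)")
    drift = np.abs(_wrap_pi(reference.angle_of(apply_tf(coords[:n_u]))
                            - reference.angle))
    treated_angles = reference.angle_of(apply_tf(coords[n_u:]))
    return treated_angles, float(np.median(drift))


def _wrap_pi(x):
    return (x + np.pi) % (2 * np.pi) - np.pi


def _vonmises_kappa_mle(R: float) -> float:
    """Approximate max-likelihood concentration from resultant length."""
    if R < 1e-9:
        return 1e-9
    if R >= 1 - 1e-9:
        return 1e9
    if R < 0.53:
        return 2 * R + R ** 3 + 5 * R ** 5 / 6
    if R < 0.85:
        return -0.4 + 1.39 * R + 0.43 / (1 - R)
    return 1.0 / (R ** 3 - 4 * R ** 2 + 3 * R)


def silverman_kappa(angles: np.ndarray) -> float:
    """Circular plug-in kernel concentration (Taylor's rule of thumb)."""
    z = np.exp(1j * angles)
    R = np.abs(z.mean())
    kap = min(_vonmises_kappa_mle(R), 1e6)
    n = angles.size
    num = 3.0 * n * kap ** 2 * iv(2, 2 * kap)
    den = 4.0 * np.sqrt(np.pi) * i1(kap) ** 2
    if den <= 0 or not np.isfinite(num) or num <= 0:
        return max(kap, 1.0)
    return float(num / den) ** 0.4


def arrest_mode(
    angles: np.ndarray,
    kappa: float | None = None,
    n_grid: int = 2048,
    bimodal_ratio: float = 0.8,
) -> tuple[float, float]:
    """Mode and circular SD of an angle sample via a von Mises KDE.

    The kernel concentration defaults to the circular Silverman rule.
    Warns when a second local maximum of the density comes within
    ``bimodal_ratio`` of the global one (ambiguous mode).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 50:
        raise ValueError("need at least 50 angles")
    kappa = silverman_kappa(angles) if kappa is None else kappa
    grid = np.arange(n_grid) * 2 * np.pi / n_grid
    # log-sum-exp-free: density up to a constant
    dens = np.exp(kappa * (np.cos(grid[:, None] - angles[None, :]) - 1.0)).sum(axis=1)
    mode = float(grid[np.argmax(dens)])
    if (dens.max() - dens.min()) < 0.05 * dens.max():
        warnings.warn("angle density is nearly flat: arrest mode is "
                      "ambiguous", RuntimeWarning)
    prev, nxt = np.roll(dens, 1), np.roll(dens, -1)
    maxima = np.where((dens > prev) & (dens >= nxt))[0]
    if maxima.size >= 2:
        top = np.sort(dens[maxima])[::-1]
        if top[1] / top[0] > bimodal_ratio:
            warnings.warn("two near-equal density maxima: arrest mode is "
                          "ambiguous", RuntimeWarning)
    R = np.abs(np.exp(1j * angles).mean())
    circ_sd = float(np.sqrt(max(-2.0 * np.log(max(R, 1e-300)), 0.0)))
    return mode, circ_sd


def arrest_time(
    mode: float,
    pt_map: PseudotimeAssignment,
    condition: str = "",
    dispersion: float = 0.0,
    n_cells: int = 0,
) -> ArrestEstimate:
    """Read the arrest mode off the untreated angle-to-time map."""
    t = float(pt_map.time_at_angle(mode % (2 * np.pi))[0])
    label = ""
    if pt_map.boundaries:
        mg1 = pt_map.boundaries.get("M/G1", (0.0, 0.0))[1]
        rel = (t - mg1) % pt_map.T
        label = "early G1" if rel < 0.25 * pt_map.T else ""
    return ArrestEstimate(condition=condition, arrest_angle=mode % (2 * np.pi),
                          arrest_time=t, dispersion=dispersion,
                          n_cells=n_cells, phase_label=label)


def estimate_arrest(
    untreated: MarkerMatrix,
    treated: MarkerMatrix,
    reference: CircularEmbedding,
    pt_map: PseudotimeAssignment,
    condition: str,
    fraction: float = 0.05,
    seed: int = 0,
) -> tuple[ArrestEstimate, np.ndarray, float]:
    """Full arrest estimation: partition, co-embed, pool angles, find mode.

    Returns the estimate, the pooled per-cell treated angles (ordered as in
    ``treated``), and the median untreated angular drift across subsets.
    """
    subsets = partition_treated(np.arange(treated.n_cells), fraction, seed)
    pooled = np.empty(treated.n_cells)
    drifts = []
    for idx in subsets:
        sub = MarkerMatrix(treated.values[idx], treated.marker_names,
                           treated.cell_ids[idx])
        ang, drift = joint_embed_angles(untreated, sub, reference)
        pooled[idx] = ang
        drifts.append(drift)
    mode, disp = arrest_mode(pooled)
    est = arrest_time(mode, pt_map, condition=condition, dispersion=disp,
                      n_cells=treated.n_cells)
    return est, pooled, float(np.median(drifts))
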
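"""Ensemble observables of the coarse-grained GQ-multimer simulations.

Turns sampled ensembles into the quantities of interest: the fraction of
bonded (stacked) junctions with block-averaged errors, junction-angle
(beta) histograms and their two-basis mixture decomposition, the
chance-bonding rate of the attraction-free reference ensemble, and the
fraction of configurations bent along a semicircular arc (U-turn test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mc import SimulationEnsemble

__all__ = [
    "AngleHistogram",
    "MixtureDecomposition",
    "bonded_fraction",
    "beta_histogram",
    "mixture_weight",
    "chance_bonding_rate",
    "bend_fraction",
    "fit_circle_3d",
]

DEFAULT_BIN_WIDTH = 2.0  # degrees; resolves the ~15 degree stacked peak


@dataclass(frozen=True)
class AngleHistogram:
    """Normalized per-degree density of the junction angle beta on [0, 180]."""

    bin_edges: np.ndarray  # degrees, len nbins+1
    density: np.ndarray  # per degree, len nbins
    n_samples: int

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if edges.ndim != 1 or dens.shape != (edges.size - 1,):
            raise ValueError("bin_edges and density shapes are inconsistent")
        if np.any(dens < 0):
            raise ValueError("density must be non-negative")
        widths = np.diff(edges)
        total = float(np.sum(dens * widths))
        if self.n_samples > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 (got {total})")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", dens)

    def same_binning(self, other: "AngleHistogram") -> bool:
        return (self.bin_edges.size == other.bin_edges.size
                and bool(np.allclose(self.bin_edges, other.bin_edges)))

    @classmethod
    def from_samples(cls, angles_deg, bin_width: float = DEFAULT_BIN_WIDTH):
        angles = np.asarray(angles_deg, dtype=float).ravel()
        edges = np.arange(0.0, 180.0 + bin_width, bin_width)
        if edges[-1] < 180.0:
            edges = np.append(edges, 180.0)
        counts, edges = np.histogram(angles, bins=edges)
        widths = np.diff(edges)
        total = counts.sum()
        dens = counts / (total * widths) if total else np.zeros_like(widths)
        return cls(edges, dens, int(total))


@dataclass(frozen=True)
class MixtureDecomposition:
    """Weight of the first (stacked) basis in a two-basis decomposition."""

    p: float
    residual_norm: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _require_multimer(ensemble: SimulationEnsemble, minimum: int = 2) -> None:
    if ensemble.n_units < minimum:
        raise ValueError(f"observable requires a chain of >= {minimum} units")


def bonded_fraction(ensemble: SimulationEnsemble,
                    n_blocks: int = 10) -> tuple[float, float]:
    """Mean fraction of bonded junctions with a block-averaged standard error.

    Averages the bond indicator over all junctions and snapshots; the error
    estimate splits the (time-ordered, correlated) snapshot series into
    ``n_blocks`` contiguous blocks and takes the standard error of the
    block means.
    """
    _require_multimer(ensemble)
    per_snap = ensemble.bond_matrix.mean(axis=1)
    mean = float(per_snap.mean())
    blocks = np.array_split(per_snap, n_blocks)
    bm = np.array([b.mean() for b in blocks if b.size])
    stderr = float(bm.std(ddof=1) / math.sqrt(len(bm))) if len(bm) > 1 else float("nan")
    return mean, stderr


def beta_histogram(ensemble: SimulationEnsemble,
                   bin_width: float = DEFAULT_BIN_WIDTH) -> AngleHistogram:
    """Histogram of the angle between consecutive unit axes, pooled over
    all junctions and snapshots."""
    _require_multimer(ensemble)
    return AngleHistogram.from_samples(ensemble.junction_angles(), bin_width)


def mixture_weight(mid: AngleHistogram, low: AngleHistogram,
                   high: AngleHistogram) -> MixtureDecomposition:
    """Decompose ``mid`` as p*low + (1-p)*high in the least-squares sense.

    Closed-form projection p = <mid - high, low - high> / ||low - high||^2
    on the bin densities (uniform bin weights), clipped to [0, 1].  For the
    square-well model the conditional in-well and out-of-well angle
    distributions are temperature-independent, so the weight of the low-T*
    basis estimates the bonded fraction of the mid-T* ensemble.
    """
    if not (mid.same_binning(low) and mid.same_binning(high)):
        raise ValueError("histograms must share identical binning")
    d = low.density - high.density
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("basis histograms are identical; weight is undefined")
    p = float((mid.density - high.density) @ d) / denom
    p = min(max(p, 0.0), 1.0)
    resid = mid.density - (p * low.density + (1.0 - p) * high.density)
    return MixtureDecomposition(p, float(np.linalg.norm(resid)))


def chance_bonding_rate(ensemble: SimulationEnsemble) -> float:
    """Fraction of junction samples whose geometry satisfies the bond
    criterion, for an ensemble sampled without attraction (T* = +inf).

    This is the probability of bonding "by chance" in the beads-on-a-string
    reference state; it anchors the calibration of the stacking-well range.
    """
    if not math.isinf(ensemble.params.T_star):
        raise ValueError("chance-bonding rate is defined for T* = +inf ensembles")
    _require_multimer(ensemble)
    return float(ensemble.bond_matrix.mean())


def fit_circle_3d(points: np.ndarray):
    """Least-squares circle through >= 3 points in 3D.

    Fits the best plane through the centroid (PCA), projects, and solves
    the algebraic (Kasa) circle fit in-plane.  Returns a dict with center,
    radius, plane normal, rms of the radial residuals and the subtended
    angle (degrees) spanned by the points around the fitted center.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    normal = vt[2]
    u, v = vt[0], vt[1]
    x = q @ u
    y = q @ v
    # Kasa fit: minimize sum((x-a)^2 + (y-b)^2 - r^2)^2, linear in (a, b, c)
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x**2 + y**2
    (a, b, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    radius = math.sqrt(max(c + a * a + b * b, 0.0))
    center = centroid + a * u + b * v
    radial = np.hypot(x - a, y - b)
    rms = float(np.sqrt(np.mean((radial - radius) ** 2)))
    ang = np.unwrap(np.arctan2(y - b, x - a))
    subtended = float(np.degrees(np.max(ang) - np.min(ang)))
    return {"center": center, "radius": float(radius), "normal": normal,
            "rms": rms, "subtended_deg": subtended}


def bend_fraction(ensemble: SimulationEnsemble, arc_radius: float,
                  turn_angle: float = 160.0, radius_tol: float = 0.25,
                  rms_tol: float = 0.08) -> float:
    """Fraction of snapshots bent along a semicircular arc (U-turn test).

    A snapshot counts as bent when the best-fit circle through the unit
    centers has (i) radius within ``radius_tol`` (relative) of
    ``arc_radius``, (ii) the unit centers advance monotonically in angle
    around the fitted center (a genuine arc, not a scatter), (iii) the
    subtended angle is >= ``turn_angle`` degrees, and (iv) the rms radial
    deviation is <= ``rms_tol`` * fitted radius.  All tolerances are
    explicit parameters: the bending criterion is under-determined by the
    large-scale physics, and the measured fraction depends strongly on the
    target radius, so the criterion must be stated rather than guessed.
    """
    _require_multimer(ensemble, minimum=3)
    if arc_radius <= 0:
        raise ValueError("arc_radius must be positive")
    count = 0
    S = ensemble.n_snapshots
    for t in range(S):
        fit = fit_circle_3d(ensemble.positions[t])
        if fit["radius"] == 0.0 or not np.isfinite(fit["radius"]):
            continue
        if (abs(fit["radius"] - arc_radius) > radius_tol * arc_radius
                or fit["subtended_deg"] < turn_angle
                or fit["rms"] > rms_tol * fit["radius"]):
            continue
        # ordered angular progression along the arc
        nrm = fit["normal"]
        e = (np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9
             else np.array([0.0, 1.0, 0.0]))
        u = e - np.dot(e, nrm) * nrm
        u /= np.linalg.norm(u)
        v = np.cross(nrm, u)
        q = ensemble.positions[t] - fit["center"]
        ang = np.unwrap(np.arctan2(q @ v, q @ u))
        gaps = np.diff(ang)
        if np.all(gaps > 0) or np.all(gaps < 0):
            count += 1
    return count / S
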
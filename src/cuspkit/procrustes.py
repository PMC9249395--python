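"""Generalized Procrustes analysis with sliding semilandmarks.

Superimposition removes translation (centering), size (unit centroid
size) and rotation (orthogonal Procrustes, reflections disallowed) from
each landmark configuration, iterating rotations against a consensus
until the consensus stabilises.  Semilandmarks, which carry no
point-to-point homology, may additionally slide along the tangent of
their outline curve so that they best correspond across specimens; the
displacement minimises either thin-plate-spline bending energy (default)
or Procrustes distance to the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from cuspkit.landmarks import CurveSlideSpec, LandmarkConfig

__all__ = [
    "AlignedShapes",
    "GPAConvergenceError",
    "centroid_size",
    "align_gpa",
    "slide_semilandmarks",
    "procrustes_distance",
    "bending_energy_matrix",
    "bending_energy",
]


class GPAConvergenceError(RuntimeError):
    pass


@dataclass
class AlignedShapes:
    """Procrustes-superimposed coordinates with per-specimen sizes."""

    procrustes_coords: np.ndarray   # (n, k, 2)
    centroid_sizes: np.ndarray      # (n,) in original units
    mean_shape: np.ndarray          # (k, 2) consensus
    n_iter_gpa: int
    slid: bool
    ids: Optional[List[str]] = None

    @property
    def n(self) -> int:
        return self.procrustes_coords.shape[0]

    @property
    def k(self) -> int:
        return self.procrustes_coords.shape[1]

    def flattened(self) -> np.ndarray:
        return self.procrustes_coords.reshape(self.n, -1)

    def to_frame(self):
        import pandas as pd

        n, k, _ = self.procrustes_coords.shape
        ids = self.ids if self.ids is not None else [str(i) for i in range(n)]
        rows = [(ids[i], j, *self.procrustes_coords[i, j])
                for i in range(n) for j in range(k)]
        return pd.DataFrame(rows, columns=["id", "landmark", "x", "y"])


def _as_coords(c) -> np.ndarray:
    if isinstance(c, LandmarkConfig):
        return np.asarray(c.coords, dtype=float)
    return np.asarray(c, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared landmark-to-centroid distances."""
    x = _as_coords(config)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 landmarks")
    centred = x - x.mean(axis=0)
    cs = float(np.sqrt((centred ** 2).sum()))
    if cs == 0.0:
        raise ValueError("all landmarks coincide: zero centroid size")
    return cs


def _unitize(x: np.ndarray, who: str = "") -> np.ndarray:
    """Center and scale to unit centroid size; reject rank-deficient shapes."""
    centred = x - x.mean(axis=0)
    cs = np.sqrt((centred ** 2).sum())
    if cs == 0:
        raise ValueError(f"degenerate configuration {who}: zero size")
    u = centred / cs
    if np.linalg.matrix_rank(u, tol=1e-12) < 2:
        raise ValueError(f"degenerate (collinear) configuration {who}")
    return u


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det +1) minimising ||x R - target||_F for centred x."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centred and scaled to unit centroid size, then *b* is
    rotated onto *a* (no reflection); the distance is the root sum of
    squared coordinate differences, sqrt(2 - 2*sum(singular values)) in
    closed form.
    """
    xa, xb = _unitize(_as_coords(a), "a"), _unitize(_as_coords(b), "b")
    if xa.shape != xb.shape:
        raise ValueError("configurations must share landmark count")
    r = _optimal_rotation(xb, xa)
    return float(np.sqrt(((xb @ r - xa) ** 2).sum()))


# ---------------------------------------------------------------------------
# thin-plate-spline bending energy

def bending_energy_matrix(ref: np.ndarray, ridge: float = 1e-10) -> np.ndarray:
    """Bending-energy matrix (k x k) of the TPS interpolant on *ref*.

    The quadratic form v' E v gives the bending energy of displacing the
    reference landmarks by v in one coordinate.  A tiny ridge keeps the
    kernel solve stable for nearly coincident points.
    """
    ref = np.asarray(ref, dtype=float)
    k = len(ref)
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(np.maximum(d2, 1e-300)), 0.0) * 0.5
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K + ridge * np.eye(k)
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.inv(L)
    E = Linv[:k, :k]
    return (E + E.T) / 2.0


def bending_energy(ref: np.ndarray, target: np.ndarray,
                   E: Optional[np.ndarray] = None) -> float:
    """TPS bending energy of the deformation taking *ref* onto *target*."""
    if E is None:
        E = bending_energy_matrix(ref)
    v = np.asarray(target, dtype=float) - np.asarray(ref, dtype=float)
    return float(np.einsum("ic,ij,jc->", v, E, v))


# ---------------------------------------------------------------------------
# semilandmark sliding

def _slide_one(x: np.ndarray, consensus: np.ndarray, curves: CurveSlideSpec,
               mode: str, E: Optional[np.ndarray]) -> np.ndarray:
    """Slide one specimen's semilandmarks toward the consensus.

    Displacements are restricted to each semilandmark's tangent (the
    chord between its curve neighbours) and jointly minimise either the
    TPS bending energy of the consensus-to-specimen deformation or the
    squared Procrustes distance to the consensus.  Each offset is bounded
    by half the distance to the nearer neighbour (fold-over guard); when
    the bound binds, the whole offset vector is shrunk so the objective,
    convex along that ray, still decreases.
    """
    rows = curves.rows
    m = len(rows)
    if m == 0:
        return x.copy()
    before, slid, after = rows[:, 0], rows[:, 1], rows[:, 2]
    chord = x[after] - x[before]
    nrm = np.linalg.norm(chord, axis=1)
    if np.any(nrm == 0):
        bad = slid[nrm == 0][0]
        raise ValueError(f"degenerate tangent at semilandmark {bad}")
    tang = chord / nrm[:, None]

    v = x - consensus                       # (k, 2)
    if mode == "procrustes-distance":
        # independent 1D quadratic per slider: remove tangential deviation
        d = -np.einsum("mc,mc->m", v[slid], tang)
    elif mode == "bending-energy":
        if E is None:
            E = bending_energy_matrix(consensus)
        # A d = -b with A = sum_c T_c' E T_c, b = sum_c T_c' E v_c
        Es = E[np.ix_(slid, slid)]          # (m, m)
        A = Es * (tang @ tang.T)
        b = np.einsum("mj,jc,mc->m", E[slid, :], v, tang)
        A = A + 1e-12 * np.eye(m)
        d = -np.linalg.solve(A, b)
    else:
        raise ValueError(f"unknown sliding mode {mode!r}")

    # fold-over guard: |d_j| <= half distance to the nearer neighbour
    lim = 0.5 * np.minimum(np.linalg.norm(x[slid] - x[before], axis=1),
                           np.linalg.norm(x[after] - x[slid], axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(np.abs(d) > 0, lim / np.abs(d), np.inf)
    alpha = min(1.0, float(ratios.min()))
    out = x.copy()
    out[slid] += alpha * d[:, None] * tang
    return out


def slide_semilandmarks(shapes: np.ndarray, curves: CurveSlideSpec,
                        consensus: np.ndarray, mode: str = "bending-energy"
                        ) -> np.ndarray:
    """Slide semilandmarks of every specimen against the consensus.

    ``shapes`` is (n, k, 2), already superimposed.  Fixed landmarks never
    move.  Returns the adjusted array (specimens are not re-normalised
    here; the GPA loop does that).
    """
    shapes = np.asarray(shapes, dtype=float)
    E = bending_energy_matrix(consensus) if mode == "bending-energy" else None
    return np.stack([_slide_one(x, consensus, curves, mode, E) for x in shapes])


# ---------------------------------------------------------------------------
# generalized Procrustes analysis

def align_gpa(shapes, curves: Optional[CurveSlideSpec] = None,
              tol: float = 1e-10, max_iter: int = 100,
              slide_mode: str = "bending-energy",
              n_slide_iter: int = 5,
              tangent_project: bool = False,
              ids: Optional[Sequence[str]] = None) -> AlignedShapes:
    """Generalized Procrustes superimposition, optionally with sliding.

    ``shapes`` is an (n, k, 2) array, a list of LandmarkConfig, or a list
    of (k, 2) arrays.  Each configuration is centred and scaled to unit
    centroid size, then iteratively rotated onto the consensus; when
    ``curves`` is given, semilandmark sliding is interleaved during the
    first ``n_slide_iter`` outer iterations (each pass strictly reduces
    its objective; capping the passes keeps the slid positions from
    drifting along their curves), after which plain GPA iterates to
    convergence.  Deterministic; converges when the consensus moves less
    than ``tol`` (root sum of squares) between iterations.
    """
    if isinstance(shapes, np.ndarray) and shapes.ndim == 3:
        arrs = [shapes[i] for i in range(shapes.shape[0])]
    else:
        arrs = [_as_coords(s) for s in shapes]
        if ids is None and shapes and isinstance(shapes[0], LandmarkConfig):
            ids = [s.id for s in shapes]
    n = len(arrs)
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = arrs[0].shape[0]
    if k < 3:
        raise ValueError("GPA needs at least 3 landmarks")
    if any(a.shape != (k, 2) for a in arrs):
        raise ValueError("all configurations must share landmark count")

    sizes = np.array([centroid_size(a) for a in arrs])
    names = ids if ids is not None else [str(i) for i in range(n)]
    X = np.stack([_unitize(a, who=str(names[i])) for i, a in enumerate(arrs)])

    # initial consensus: first shape, then mean of rotated shapes
    consensus = X[0].copy()
    n_done = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        if curves is not None and curves.n_sliders and it <= n_slide_iter:
            X = slide_semilandmarks(X, curves, consensus, mode=slide_mode)
            for i in range(n):
                X[i] = _unitize(X[i], who=str(names[i]))
                X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        new_consensus = _unitize(new_consensus, who="consensus")
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        n_done = it
        if delta < tol:
            break
    else:
        raise GPAConvergenceError(
            f"GPA did not converge in {max_iter} iterations (delta={delta:.3g})")

    # final rotation pass onto the converged consensus
    for i in range(n):
        X[i] = X[i] @ _optimal_rotation(X[i], consensus)
    mean_shape = X.mean(axis=0)

    if tangent_project:
        m = consensus.reshape(-1)
        m = m / np.linalg.norm(m)
        flat = X.reshape(n, -1)
        coefs = flat @ m
        flat = flat - np.outer(coefs - 1.0, m)
        X = flat.reshape(n, k, 2)
        mean_shape = X.mean(axis=0)

    return AlignedShapes(
        procrustes_coords=X, centroid_sizes=sizes, mean_shape=mean_shape,
        n_iter_gpa=n_done, slid=curves is not None and curves.n_sliders > 0,
        ids=list(names))
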
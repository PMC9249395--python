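"""Plotting extras: PCA scatter, size distributions, TPS warp grids.

The warp grid visualises the thin-plate-spline deformation taking the
consensus shape to a target shape (e.g. the configuration at a PC
extreme), drawn as a deformed reference grid in the tradition of
D'Arcy Thompson transformation diagrams.
"""

from __future__ import annotations

from typing import Optional

import numpy as np


def _tps_interpolator(src: np.ndarray, dst: np.ndarray):
    """Return a callable mapping (m, 2) points by the TPS from src to dst."""
    k = len(src)
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(np.maximum(d2, 1e-300)), 0.0) * 0.5
    Q = np.column_stack([np.ones(k), src])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K + 1e-10 * np.eye(k)
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = dst
    W = np.linalg.solve(L, rhs)

    def f(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        d2p = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            U = np.where(d2p > 0, d2p * np.log(np.maximum(d2p, 1e-300)), 0.0) * 0.5
        return U @ W[:k] + np.column_stack([np.ones(len(pts)), pts]) @ W[k:]

    return f


def warp_grid(ax, reference: np.ndarray, target: np.ndarray,
              n_grid: int = 18, pad: float = 0.15, color: str = "0.6"):
    """Draw the TPS-deformed grid from *reference* to *target* on *ax*,
    with the target landmarks overplotted."""
    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    f = _tps_interpolator(reference, target)
    span = np.ptp(reference, axis=0)
    lo = reference.min(axis=0) - pad * span
    hi = reference.max(axis=0) + pad * span
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    dense = 60
    for x in xs:
        line = np.column_stack([np.full(dense, x), np.linspace(lo[1], hi[1], dense)])
        w = f(line)
        ax.plot(w[:, 0], w[:, 1], color=color, lw=0.5)
    for y in ys:
        line = np.column_stack([np.linspace(lo[0], hi[0], dense), np.full(dense, y)])
        w = f(line)
        ax.plot(w[:, 0], w[:, 1], color=color, lw=0.5)
    ax.plot(target[:, 0], target[:, 1], "k.", ms=4)
    ax.set_aspect("equal")
    ax.set_axis_off()


def pc_extreme_shape(pca, aligned, component: int = 0, sd: float = 2.0,
                     sign: float = 1.0) -> np.ndarray:
    """Consensus shape displaced along one PC by ``sd`` score SDs."""
    score_sd = pca.scores[:, component].std(ddof=1)
    disp = sign * sd * score_sd * pca.loadings[:, component]
    return aligned.mean_shape + disp.reshape(aligned.mean_shape.shape)


def plot_pca(ax, pca, meta=None, colors: Optional[dict] = None):
    """Scatter of the first two PC scores, coloured by treatment."""
    colors = colors or {"DMSO": "tab:gray", "IWR": "tab:red", "CHIR": "tab:blue"}
    sc = pca.scores
    if meta is not None:
        import pandas as pd

        mf = meta if isinstance(meta, pd.DataFrame) else None
        groups = None
        if mf is not None:
            groups = mf["treatment"].astype(str).to_numpy()
        if groups is None and pca.level == "sample-mean":
            groups = [i.split("/")[0] for i in pca.ids]
        for g in dict.fromkeys(groups):
            m = np.array([gg == g for gg in groups])
            ax.scatter(sc[m, 0], sc[m, 1], label=g, s=20,
                       color=colors.get(g, None))
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(sc[:, 0], sc[:, 1], s=20)
    ax.set_xlabel(f"PC1 ({pca.var_prop[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca.var_prop[1]:.1f}%)")
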
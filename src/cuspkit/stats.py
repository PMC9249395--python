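"""Statistics on aligned shapes and centroid sizes.

The workhorse is a sequential (type-I) sums-of-squares linear model on a
multivariate response — Procrustes-aligned coordinates flattened to one
row per tooth, or scalar centroid size — with the factors ``treatment``
and ``sample`` (samples coded nested within treatment as fixed effects).
Significance comes from residual randomization (RRPP): for each term the
residuals of the reduced model containing all preceding terms are
permuted and the term's SS recomputed.  With 3 treatments, 23 samples
and 138 teeth this yields the df decomposition 2 / 20 / 115.

Also here: PCA of shape space (tooth level or sample-mean level),
centroid-size group summaries with Tukey HSD contrasts, a pairwise
variance F-test on PC scores, and a chi-square test on cusp-count
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from cuspkit.procrustes import AlignedShapes

__all__ = [
    "ShapeLMResult",
    "PCAResult",
    "SizeStats",
    "procrustes_anova",
    "pca_shapes",
    "size_model",
    "variance_ftest",
    "chisq_proportions",
]


@dataclass
class ShapeLMResult:
    """Sequential-SS ANOVA table with permutation p-values."""

    terms: List[str]
    df: List[int]
    SS: List[float]
    R2: List[float]
    F: List[float]
    p_perm: List[float]
    df_res: int
    SS_res: float
    SS_total: float
    n_perm: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, d, ss, r2, f, p) for t, d, ss, r2, f, p in
                zip(self.terms, self.df, self.SS, self.R2, self.F, self.p_perm)]
        rows.append(("Residuals", self.df_res, self.SS_res,
                     self.SS_res / self.SS_total if self.SS_total else 0.0,
                     np.nan, np.nan))
        return pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"])


@dataclass
class PCAResult:
    scores: np.ndarray          # (n, ncomp)
    var_prop: np.ndarray        # percent variance per component
    loadings: np.ndarray        # (p, ncomp), columns orthonormal
    level: str                  # 'tooth' or 'sample-mean'
    ids: List[str] = field(default_factory=list)


@dataclass
class SizeStats:
    group_means: pd.Series
    percent_change: pd.Series   # vs control (DMSO)
    anova: ShapeLMResult
    tukey: pd.DataFrame


def _dummies(labels: Sequence) -> np.ndarray:
    """Full-rank treatment-contrast dummies (first level dropped)."""
    labels = pd.Categorical(labels)
    d = pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float)
    return d


def _response_matrix(aligned) -> np.ndarray:
    if isinstance(aligned, AlignedShapes):
        return aligned.flattened()
    y = np.asarray(aligned, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    elif y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    return y


def _meta_frame(meta) -> pd.DataFrame:
    if isinstance(meta, pd.DataFrame):
        return meta
    return pd.DataFrame(
        [(m.id, m.sample_id, m.treatment, m.side, m.tooth_position)
         for m in meta],
        columns=["id", "sample_id", "treatment", "side", "tooth_position"])


def procrustes_anova(aligned, meta,
                     formula: Sequence[str] = ("treatment", "sample"),
                     n_perm: int = 999, seed: Optional[int] = None
                     ) -> ShapeLMResult:
    """Sequential-SS linear model on shape or size with RRPP p-values.

    ``aligned`` may be AlignedShapes, an (n, p) or (n, k, 2) array, or a
    length-n vector of centroid sizes.  ``formula`` lists the factors in
    entry order; ``sample`` is always coded nested within treatment
    (sample identities are unique to a treatment in this design).  The
    observed SS, R2, F and df do not depend on ``n_perm``.
    """
    Y = _response_matrix(aligned)
    mf = _meta_frame(meta)
    n = Y.shape[0]
    if len(mf) != n:
        raise ValueError("metadata length does not match response rows")

    factor_cols = {
        "treatment": mf["treatment"].astype(str).to_numpy(),
        "sample": (mf["treatment"].astype(str) + "/" +
                   mf["sample_id"].astype(str)).to_numpy(),
    }
    for f in formula:
        if f not in factor_cols:
            raise ValueError(f"unknown factor {f!r}")
        if len(set(factor_cols[f])) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")

    # nested sequence of design matrices, intercept first; orthonormal
    # column bases via SVD (designs with nested factors are rank-deficient
    # in dummy coding)
    def basis(X):
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        return u[:, s > 1e-9 * s[0]]

    X = np.ones((n, 1))
    Qs = [basis(X)]
    ranks = [1]
    for f in formula:
        X = np.column_stack([X, _dummies(factor_cols[f])])
        q = basis(X)
        rank = q.shape[1]
        if rank <= ranks[-1]:
            raise ValueError(f"singular design at factor {f!r}")
        Qs.append(q)
        ranks.append(rank)

    fits = [q @ (q.T @ Y) for q in Qs]
    SS_total = float(((Y - fits[0]) ** 2).sum())
    if SS_total <= 1e-24 * max(1.0, float((Y ** 2).sum())):
        SS_total = 0.0
    SS = [float(((fits[i + 1] - fits[i]) ** 2).sum())
          for i in range(len(formula))]
    df = [ranks[i + 1] - ranks[i] for i in range(len(formula))]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    SS_res = float(((Y - fits[-1]) ** 2).sum())
    F = [(SS[i] / df[i]) / (SS_res / df_res) for i in range(len(formula))]
    R2 = [(SS[i] / SS_total) if SS_total > 0 else 0.0 for i in range(len(formula))]

    # RRPP: permute reduced-model residuals term by term
    p_perm: List[float] = []
    rng = np.random.default_rng(seed)
    for i in range(len(formula)):
        if SS_total == 0:
            p_perm.append(1.0)
            continue
        fit_red = fits[i]
        resid = Y - fit_red
        q_full_i, q_red_i = Qs[i + 1], Qs[i]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Ystar = fit_red + resid[perm]
            ss_star = (float((np.linalg.norm(q_full_i.T @ Ystar)) ** 2)
                       - float((np.linalg.norm(q_red_i.T @ Ystar)) ** 2))
            if ss_star >= SS[i] - 1e-12:
                count += 1
        p_perm.append((count + 1) / (n_perm + 1))

    return ShapeLMResult(list(formula), df, SS, R2, F, p_perm,
                         df_res, SS_res, SS_total, n_perm, seed)


def pca_shapes(aligned, meta=None, level: str = "sample-mean") -> PCAResult:
    """PCA of flattened aligned coordinates.

    ``level='sample-mean'`` first averages the teeth of each sample
    (requires metadata); ``level='tooth'`` uses every tooth.  Percent
    variance per component sums to 100; each component's sign is fixed
    by making its largest-magnitude loading positive.
    """
    Y = _response_matrix(aligned)
    ids: List[str]
    if level == "sample-mean":
        if meta is None:
            raise ValueError("sample-mean PCA needs metadata")
        mf = _meta_frame(meta)
        key = mf["treatment"].astype(str) + "/" + mf["sample_id"].astype(str)
        df = pd.DataFrame(Y)
        df["_key"] = key.to_numpy()
        g = df.groupby("_key", sort=True).mean()
        ids = list(g.index)
        Y = g.to_numpy()
    elif level == "tooth":
        if isinstance(aligned, AlignedShapes) and aligned.ids:
            ids = list(aligned.ids)
        else:
            ids = [str(i) for i in range(Y.shape[0])]
    else:
        raise ValueError("level must be 'tooth' or 'sample-mean'")
    n = Y.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 observations")
    Yc = Y - Y.mean(axis=0)
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    ncomp = int((s > 1e-12 * max(s[0], 1e-300)).sum())
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    scores = u * s
    loadings = vt.T
    # deterministic sign convention
    for j in range(ncomp):
        i0 = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i0, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    var = s ** 2
    var_prop = 100.0 * var / var.sum()
    return PCAResult(scores, var_prop, loadings, level, ids)


def size_model(cs: np.ndarray, meta, control: str = "DMSO",
               n_perm: int = 999, seed: Optional[int] = None) -> SizeStats:
    """Centroid-size analysis: nested ANOVA, Tukey HSD, percent change.

    Percent change of each treatment is relative to the control group
    mean: (mean_T - mean_ctrl) / mean_ctrl * 100.
    """
    cs = np.asarray(cs, dtype=float)
    mf = _meta_frame(meta)
    treat = mf["treatment"].astype(str)
    if control not in set(treat):
        raise ValueError(f"control group {control!r} missing")
    anova = procrustes_anova(cs, mf, n_perm=n_perm, seed=seed)
    means = pd.Series(cs).groupby(treat.to_numpy()).mean()
    pct = (means - means[control]) / means[control] * 100.0
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(cs, treat.to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return SizeStats(means, pct, anova, tukey)


def variance_ftest(scores: np.ndarray, meta, pair: Tuple[str, str]
                   ) -> Tuple[float, int, int, float]:
    """Two-sided F-test comparing PC-score variances of two groups.

    Group order is fixed as given (control first), so F < 1 indicates
    inflated variance in the second (treatment) group.  Returns
    (F, df1, df2, p).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    mf = _meta_frame(meta)
    treat = mf["treatment"].astype(str).to_numpy()
    ga = scores[treat == pair[0]]
    gb = scores[treat == pair[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = ga.var(ddof=1), gb.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    F = va / vb
    df1, df2 = len(ga) - 1, len(gb) - 1
    cdf = sps.f.cdf(F, df1, df2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(F), df1, df2, float(min(p, 1.0))


def chisq_proportions(table: np.ndarray, correction: bool = False
                      ) -> Tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table (no continuity correction
    by default).  Returns (chi2, df, p)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res[0]), int(res[2]), float(res[1])
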
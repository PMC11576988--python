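"""Validation analytics over per-task score matrices.

When a battery of tasks is scored per participant, these routines assess
how the tasks relate: a sparse pairwise Pearson correlation matrix (scores
are missing for participants who skipped a task), complete-linkage
hierarchical clustering of the tasks, exploratory factor analysis with a
varimax rotation (factor count by the Kaiser criterion), and a
Schmid-Leiman transformation of an oblique solution to quantify the
second-order general factor: the share of variance a single g factor
explains across the battery, 100 * ss_g / n_tasks where ss_g is the sum of
squared g loadings.  A battery whose scores fractionate cleanly into
domains has a small g share.

Factor extraction is minimum-residual (minres) by default, with
principal-axis available; rotations (varimax, promax) and the
Schmid-Leiman orthogonalization follow the standard published algorithms.

Two regression effect-size helpers round the module off: the printed form
of Cohen's f-squared, (1 - R^2)/R^2, with the conventional R^2/(1 - R^2)
behind a flag, and beta-over-SD effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform

__all__ = [
    "FactorSolution",
    "pairwise_correlation", "hierarchical_clusters", "kaiser_nfactors",
    "factor_analysis_varimax", "schmid_leiman_g", "g_variance_pct",
    "cohens_f2", "effect_size_sd",
]


# ---------------------------------------------------------------------------
# sparse correlation and clustering

def pairwise_correlation(scores: pd.DataFrame,
                         min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of a participants x tasks
    score matrix with missing entries.

    Each pair of tasks is correlated over the participants observed on
    both; pairs with fewer than ``min_overlap`` shared observations are
    left missing (NaN).  The diagonal is 1.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    if scores.shape[1] < 2:
        raise ValueError("need at least two tasks")
    tasks = list(scores.columns)
    k = len(tasks)
    corr = np.eye(k)
    x = scores.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    for a in range(k):
        for b in range(a + 1, k):
            both = obs[:, a] & obs[:, b]
            n = int(both.sum())
            if n < min_overlap:
                corr[a, b] = corr[b, a] = np.nan
                continue
            xa, xb = x[both, a], x[both, b]
            sa, sb = xa.std(), xb.std()
            if sa < 1e-15 or sb < 1e-15:
                corr[a, b] = corr[b, a] = np.nan
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            corr[a, b] = corr[b, a] = r
    return pd.DataFrame(corr, index=tasks, columns=tasks)


def hierarchical_clusters(corr: pd.DataFrame, n_clusters: int | None = None,
                          height: float | None = None
                          ) -> tuple[pd.Series, np.ndarray]:
    """Complete-linkage agglomerative clustering of tasks at distance 1 - r.

    Cut either to ``n_clusters`` groups or at dissimilarity ``height``.
    Tasks are processed in name order, which fixes tie-breaking.  Returns
    the cluster label per task and the scipy linkage matrix.
    """
    if (n_clusters is None) == (height is None):
        raise ValueError("give exactly one of n_clusters or height")
    if corr.isna().to_numpy().any():
        raise ValueError("correlation matrix has missing entries; "
                         "impute or restrict to observed pairs first")
    order = sorted(corr.columns)
    c = corr.loc[order, order].to_numpy()
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="complete")
    if n_clusters is not None:
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(z, t=height, criterion="distance")
    return pd.Series(labels, index=order, name="cluster"), z


# ---------------------------------------------------------------------------
# factor analysis

@dataclass
class FactorSolution:
    """First-order loadings plus (optionally) the Schmid-Leiman g fields.

    ``pct_g`` is 100 * ss_g / n_tasks: the percentage of total battery
    variance carried by the general factor.
    """

    loadings: pd.DataFrame          # tasks x factors
    rotation: str
    eigenvalues: np.ndarray
    n_factors: int
    g_loadings: pd.Series | None = None
    ss_g: float | None = None
    pct_g: float | None = None
    factor_corr: np.ndarray | None = None


def _check_corr(corr: pd.DataFrame | np.ndarray) -> np.ndarray:
    c = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.isnan(c).any():
        raise ValueError("correlation matrix has missing entries")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return (c + c.T) / 2.0


def kaiser_nfactors(corr: pd.DataFrame | np.ndarray) -> int:
    """Number of factors under the Kaiser criterion: eigenvalues of the
    correlation matrix strictly greater than 1 (an identity matrix, whose
    eigenvalues are all exactly 1, yields 0)."""
    c = _check_corr(corr)
    return int(np.sum(np.linalg.eigvalsh(c) > 1.0))


def _eig_loadings(r_reduced: np.ndarray, k: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(r_reduced)
    top = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[top], 0.0, None)
    return vecs[:, top] * np.sqrt(lam)


def _smc(c: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, the usual communality start."""
    try:
        inv = np.linalg.inv(c)
        smc = 1.0 - 1.0 / np.diag(inv)
        return np.clip(smc, 0.0, 0.999)
    except np.linalg.LinAlgError:
        return np.full(c.shape[0], 0.5)


def _extract_minres(c: np.ndarray, k: int) -> np.ndarray:
    """Minimum-residual extraction: choose uniquenesses psi to minimise the
    off-diagonal residuals of c - LL', with L the rank-k eigenapproximation
    of c - diag(psi)."""
    p = c.shape[0]
    mask = ~np.eye(p, dtype=bool)

    def objective(psi):
        loadings = _eig_loadings(c - np.diag(psi), k)
        resid = c - loadings @ loadings.T
        return float(np.sum(resid[mask] ** 2))

    psi0 = 1.0 - _smc(c)
    res = minimize(objective, psi0, method="L-BFGS-B",
                   bounds=[(0.005, 1.0)] * p,
                   options={"maxiter": 1000})
    if not res.success and res.fun > 1e-4:
        warnings.warn(f"minres extraction did not fully converge: "
                      f"{res.message}", stacklevel=2)
    return _eig_loadings(c - np.diag(res.x), k)


def _extract_principal_axis(c: np.ndarray, k: int,
                            max_iter: int = 100, tol: float = 1e-6
                            ) -> np.ndarray:
    """Iterated principal-axis factoring with SMC start."""
    h = _smc(c)
    loadings = None
    for _ in range(max_iter):
        r = c.copy()
        np.fill_diagonal(r, h)
        loadings = _eig_loadings(r, k)
        h_new = np.clip(np.sum(loadings ** 2, axis=1), 0.0, 0.999)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    r = c.copy()
    np.fill_diagonal(r, h)
    return _eig_loadings(r, k)


def _varimax(loadings: np.ndarray, normalize: bool = True,
             max_iter: int = 1000, tol: float = 1e-6
             ) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalised varimax rotation; returns (rotated, rotation)."""
    x = loadings.copy()
    p, k = x.shape
    if k < 2:
        return x, np.eye(k)
    if normalize:
        norms = np.sqrt(np.sum(x ** 2, axis=1, keepdims=True))
        norms[norms == 0] = 1.0
        x = x / norms
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        xr = x @ rot
        u, s, vt = np.linalg.svd(
            x.T @ (xr ** 3 - xr @ np.diag(np.sum(xr ** 2, axis=0)) / p))
        rot = u @ vt
        var_new = float(np.sum(s))
        if var_new < var_old * (1.0 + tol):
            break
        var_old = var_new
    out = x @ rot
    if normalize:
        out = out * norms
    return out, rot


def _column_signs(loadings: np.ndarray) -> np.ndarray:
    """Per-factor sign making the largest-magnitude loading positive."""
    signs = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            signs[j] = -1.0
    return signs


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip factor signs so each column's largest-magnitude loading is
    positive (determinism across platforms)."""
    return loadings * _column_signs(loadings)


def _promax(loadings: np.ndarray, power: int = 4
            ) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation of an (already varimax-rotated) loading
    matrix; returns (pattern, factor correlation Phi)."""
    v, _ = _varimax(loadings)
    p, k = v.shape
    if k < 2:
        return v, np.eye(k)
    target = v * np.abs(v) ** (power - 1)
    u, *_ = np.linalg.lstsq(v, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u @ np.diag(np.sqrt(d))
    pattern = v @ u
    ui = np.linalg.inv(u)
    phi = ui @ ui.T
    return pattern, phi


def factor_analysis_varimax(corr: pd.DataFrame, n_factors: int,
                            method: str = "minres") -> FactorSolution:
    """Common-factor extraction from a correlation matrix followed by a
    varimax rotation.  ``method`` is ``"minres"`` (default) or
    ``"principal_axis"``.  Column signs are fixed so each factor's
    largest-magnitude loading is positive."""
    c = _check_corr(corr)
    p = c.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("need 1 <= n_factors < n_tasks")
    if method == "minres":
        raw = _extract_minres(c, n_factors)
    elif method == "principal_axis":
        raw = _extract_principal_axis(c, n_factors)
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    rotated, _ = _varimax(raw)
    rotated = _fix_signs(rotated)
    tasks = (list(corr.columns) if isinstance(corr, pd.DataFrame)
             else [f"task{i}" for i in range(p)])
    cols = [f"F{j + 1}" for j in range(n_factors)]
    return FactorSolution(
        loadings=pd.DataFrame(rotated, index=tasks, columns=cols),
        rotation="varimax",
        eigenvalues=np.sort(np.linalg.eigvalsh(c))[::-1],
        n_factors=n_factors)


def schmid_leiman_g(corr: pd.DataFrame, n_factors: int,
                    method: str = "minres") -> FactorSolution:
    """Schmid-Leiman orthogonalization: general-factor loadings from a
    hierarchical factor model.

    An oblique (promax) first-order solution is factored at second order
    (one factor on the factor correlation matrix); each task's g loading is
    its first-order pattern times the second-order loadings, and the group
    factors are residualised accordingly.  ``ss_g`` is the sum of squared
    g loadings and ``pct_g = 100 * ss_g / n_tasks``.
    """
    c = _check_corr(corr)
    p = c.shape[0]
    if n_factors < 2:
        raise ValueError("Schmid-Leiman requires at least 2 first-order "
                         "factors")
    if method == "minres":
        raw = _extract_minres(c, n_factors)
    else:
        raw = _extract_principal_axis(c, n_factors)
    pattern, phi = _promax(raw)
    signs = _column_signs(pattern)
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)   # keep Lambda Phi Lambda' unchanged
    cond = np.linalg.cond(phi)
    if cond > 1e8:
        warnings.warn(f"factor correlation matrix near-singular "
                      f"(cond={cond:.2g})", stacklevel=2)
    # second-order: one general factor over the first-order factors
    gamma = _extract_minres(phi, 1).ravel()
    if gamma.sum() < 0:
        gamma = -gamma
    g_loadings = pattern @ gamma
    ss_g = float(np.sum(g_loadings ** 2))
    tasks = (list(corr.columns) if isinstance(corr, pd.DataFrame)
             else [f"task{i}" for i in range(p)])
    cols = [f"F{j + 1}" for j in range(n_factors)]
    return FactorSolution(
        loadings=pd.DataFrame(pattern, index=tasks, columns=cols),
        rotation="promax",
        eigenvalues=np.sort(np.linalg.eigvalsh(c))[::-1],
        n_factors=n_factors,
        g_loadings=pd.Series(g_loadings, index=tasks, name="g"),
        ss_g=ss_g,
        pct_g=g_variance_pct(ss_g, p),
        factor_corr=phi)


def g_variance_pct(ss_g: float, n_tasks: int) -> float:
    """Percentage of battery variance explained by the general factor:
    100 * ss_g / n_tasks."""
    if ss_g < 0:
        raise ValueError("ss_g must be nonnegative")
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    return 100.0 * ss_g / n_tasks


# ---------------------------------------------------------------------------
# regression effect sizes

def cohens_f2(r_squared: float, conventional: bool = False) -> float:
    """Cohen's f-squared effect size from a regression R^2.

    By default uses the form (1 - R^2)/R^2; ``conventional=True`` gives the
    textbook R^2/(1 - R^2).
    """
    if not 0 < r_squared <= 1:
        raise ValueError("r_squared must lie in (0, 1]")
    if conventional:
        if r_squared == 1:
            raise ValueError("conventional f2 undefined at R^2 = 1")
        return r_squared / (1.0 - r_squared)
    return (1.0 - r_squared) / r_squared


def effect_size_sd(beta: float, outcome_sd: float) -> float:
    """Regression coefficient expressed in outcome-SD units."""
    if outcome_sd <= 0:
        raise ValueError("outcome_sd must be positive")
    return beta / outcome_sd
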
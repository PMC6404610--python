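"""Ordination and multivariate testing on Bray-Curtis dissimilarities.

Bray-Curtis is computed on (shifted) expression profiles, non-metric
multidimensional scaling minimizes Kruskal stress-1 by alternating
isotonic regression with Guttman (SMACOF) configuration updates, and
PERMANOVA partitions the Gower-centered distance matrix among crossed
factors with sequential sums of squares and free permutation of sample
labels (the standard adonis behavior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from coexnet.preprocess import ExpressionMatrix


def bray_curtis(expr: ExpressionMatrix | pd.DataFrame, shift: bool = True) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples.

    d(a, b) = sum_g |x_ga - x_gb| / sum_g (x_ga + x_gb).  Expression
    residuals can be negative, so with ``shift=True`` the matrix is
    first shifted by its global minimum so the smallest value is 0; this
    preserves the rank structure of sample differences.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    values = data.to_numpy(dtype=float).T  # samples x genes
    if shift and values.min() < 0:
        values = values - values.min()
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values (use shift=True)")
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = data.columns[np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero sample vector(s): {list(bad)}")
    d = squareform(pdist(values, metric="braycurtis"))
    out = pd.DataFrame(d, index=data.columns, columns=data.columns)
    out.attrs["metric_name"] = "bray-curtis"
    return out


@dataclass
class OrdinationResult:
    """nMDS configuration with Kruskal stress-1 diagnostics."""

    scores: pd.DataFrame  # samples x k, centered
    stress: float
    k: int
    converged: bool
    n_restarts_used: int
    stress_history: list[float]  # per-iteration stress of the best run


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def _nmds_single(
    d: np.ndarray, k: int, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    n = d.shape[0]
    triu = np.triu_indices(n, 1)
    diss = d[triu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)
    config = init.copy()
    history: list[float] = []
    prev = np.inf
    converged = False
    best_config = config
    for _ in range(max_iter):
        dist = pdist(config)
        disp = iso.fit_transform(diss[order], dist[order])
        disparities = np.empty_like(dist)
        disparities[order] = disp
        # normalize so the stress denominator stays comparable across iterations
        scale = np.sqrt(np.sum(dist**2) / max(np.sum(disparities**2), 1e-300))
        disparities *= scale
        stress = _stress1(dist, disparities)
        if stress > prev + 1e-12:
            break  # keep the previous (better) configuration
        history.append(stress)
        best_config = config.copy()
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform with unit weights
        full_disp = squareform(disparities)
        full_dist = squareform(dist)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(full_dist > 0, full_disp / full_dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        config = (b @ config) / n
    final = history[-1] if history else _stress1(pdist(best_config), disparities)
    return best_config, final, converged, history


def nmds(
    d: pd.DataFrame,
    k: int = 5,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix into ``k`` dimensions.

    Runs ``n_restarts`` starts (a metric principal-coordinates start
    plus random starts) and returns the configuration with the lowest
    Kruskal stress-1.  Within a run the recorded stress sequence is
    non-increasing; the returned scores are centered.
    """
    values = d.to_numpy(dtype=float)
    n = values.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    rng = np.random.default_rng(seed)

    # principal-coordinates (classical MDS) start
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (values**2) @ j
    evals, evecs = np.linalg.eigh(g)
    idx = np.argsort(evals)[::-1][:k]
    pcoa = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 0.0))

    inits = [pcoa] + [rng.standard_normal((n, k)) for _ in range(max(n_restarts - 1, 0))]
    best = None
    for init in inits:
        config, stress, converged, history = _nmds_single(values, k, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (config, stress, converged, history)
    config, stress, converged, history = best
    config = config - config.mean(axis=0)
    scores = pd.DataFrame(
        config, index=d.index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        scores=scores, stress=stress, k=k, converged=converged,
        n_restarts_used=len(inits), stress_history=history,
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-300)
    q = q[:, keep]
    return q @ q.T


def permanova(
    d: pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    factors: tuple[str, ...] = ("population", "temperature"),
    interaction: bool = True,
) -> pd.DataFrame:
    """PERMANOVA with sequential (Type-I) partitioning of crossed factors.

    Partitions the Gower-centered distance matrix among the factors (and
    their interaction, for two factors) in the stated order; pseudo-F
    per term uses the residual mean square, and p-values come from free
    permutation of sample labels: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta = metadata.loc[d.index]
    for f in factors:
        if meta[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    n = len(meta)
    g = _gower_center(d.to_numpy(dtype=float))

    dummies = [
        pd.get_dummies(meta[f].astype("category"), drop_first=True, dtype=float).to_numpy()
        for f in factors
    ]
    terms: list[tuple[str, np.ndarray]] = list(zip(factors, dummies))
    if interaction and len(factors) == 2:
        inter = np.einsum("ij,ik->ijk", dummies[0], dummies[1]).reshape(n, -1)
        terms.append((f"{factors[0]}:{factors[1]}", inter))

    intercept = np.ones((n, 1))
    hats = []
    x = intercept
    h_prev = _hat(x)
    dfs = []
    for _, cols in terms:
        x = np.hstack([x, cols])
        h = _hat(x)
        hats.append((h_prev, h))
        dfs.append(int(round(np.trace(h - h_prev))))
        h_prev = h
    h_full = h_prev
    df_resid = n - int(round(np.trace(h_full)))
    resid_proj = np.eye(n) - h_full

    def term_ss(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([np.sum((h - h0) * gmat) for h0, h in hats])
        return ss, float(np.sum(resid_proj * gmat))

    ss_obs, ss_res = term_ss(g)
    ss_total = float(np.trace(g))
    ms_res = ss_res / df_resid
    f_obs = (ss_obs / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_rp = term_ss(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_rp / df_resid)
        exceed += f_p >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for (name, _), ss, df, f, p in zip(terms, ss_obs, dfs, f_obs, pvals):
        rows.append({"term": name, "SS": ss, "df": df, "F": f,
                     "R2": ss / ss_total, "p": p})
    rows.append({"term": "Residual", "SS": ss_res, "df": df_resid,
                 "F": np.nan, "R2": ss_res / ss_total, "p": np.nan})
    rows.append({"term": "Total", "SS": ss_total, "df": n - 1,
                 "F": np.nan, "R2": 1.0, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    table.attrs["n_permutations"] = n_perm
    table.attrs["rng_seed"] = seed
    return table
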
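"""Count preprocessing: normalization, filtering, VST, surrogate variables.

The pipeline order is fixed: median-of-ratios size-factor normalization,
variance filtering on the variance-stabilized scale, then estimation and
regression-based removal of latent (surrogate) variables from the
residual expression matrix.  Every step appends itself to the
:class:`ExpressionMatrix` transform log so downstream artifacts are
self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples expression with transform provenance."""

    data: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def with_data(self, data: pd.DataFrame, step: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data=data, transform_log=[*self.transform_log, step], metadata=self.metadata
        )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (DESeq-style).

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median over reference genes of the ratio of
    its count to the gene's geometric mean.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    ref = (values > 0).all(axis=1)
    if not ref.any():
        nonzero_per_sample = (values > 0).sum(axis=0)
        worst = counts.columns[np.argsort(nonzero_per_sample)][:3]
        raise ValueError(
            "no gene has nonzero counts in all samples; samples with the "
            f"fewest expressed genes: {list(worst)}"
        )
    log_ref = np.log(values[ref])
    log_gm = log_ref.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ref - log_gm, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def vst(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    dialect: str = "log2",
    dispersion: float | None = None,
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Variance-stabilizing transform of normalized counts.

    ``log2`` (default): log2(count/factor + 1).  ``anscombe``: an
    NB-motivated shift log2(count/factor + 1/(2*alpha)) using the
    supplied ``dispersion`` alpha, which stabilizes variance to first
    order for overdispersed counts with large means.
    """
    if factors is None:
        factors = size_factors(counts)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    norm = counts / factors
    if dialect == "log2":
        data = np.log2(norm + 1.0)
        step = "vst:log2(norm+1)"
    elif dialect == "anscombe":
        if dispersion is None or dispersion <= 0:
            raise ValueError("anscombe dialect requires a positive dispersion")
        data = np.log2(norm + 1.0 / (2.0 * dispersion))
        step = f"vst:log2(norm+1/(2*{dispersion}))"
    else:
        raise ValueError(f"unknown vst dialect: {dialect!r}")
    return ExpressionMatrix(
        data=data,
        transform_log=["normalize:median-of-ratios", step],
        metadata=metadata,
    )


def filter_low_variance(expr: ExpressionMatrix, drop_fraction: float = 0.40) -> ExpressionMatrix:
    """Drop the ``drop_fraction`` of genes with lowest variance.

    Retains the ceil((1 - drop_fraction) * G) genes of highest variance
    across all samples, preserving input gene order; ties at the cutoff
    are resolved by stable gene order.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    variances = expr.data.var(axis=1, ddof=1).to_numpy()
    n_keep = math.ceil((1.0 - drop_fraction) * len(variances))
    order = np.argsort(-variances, kind="stable")
    keep = np.sort(order[:n_keep])
    data = expr.data.iloc[keep]
    return expr.with_data(data, f"filter_low_variance:drop={drop_fraction}")


def _design_matrix(
    metadata: pd.DataFrame, include_interaction: bool = True
) -> np.ndarray:
    pop = pd.get_dummies(metadata["population"], drop_first=True, dtype=float)
    temp = pd.get_dummies(
        metadata["temperature"].astype("category"), drop_first=True, dtype=float
    )
    cols = [np.ones((len(metadata), 1)), pop.to_numpy(), temp.to_numpy()]
    if include_interaction:
        inter = np.einsum("ij,ik->ijk", pop.to_numpy(), temp.to_numpy())
        cols.append(inter.reshape(len(metadata), -1))
    return np.hstack(cols)


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of every gene (rows) regressed on the design (samples x p)."""
    q, _ = np.linalg.qr(design)
    return values - (values @ q) @ q.T


@dataclass
class SurrogateVariables:
    """Estimated latent factors in sample space (orthonormal columns)."""

    sv: pd.DataFrame  # samples x n_sv
    singular_values: np.ndarray
    n_sv: int
    meaningful: bool  # False when the residual matrix is (near) zero


def estimate_surrogate_variables(
    expr: ExpressionMatrix,
    metadata: pd.DataFrame | None = None,
    n_sv: int | str = "auto",
    include_interaction: bool = True,
    n_permutations: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
    weight_by_design_p: bool = True,
) -> SurrogateVariables:
    """Estimate latent batch-like factors from residual expression.

    Each gene is regressed on population + temperature (+ interaction);
    the top sample-space singular vectors of the residual matrix are the
    surrogate variables.  With ``weight_by_design_p`` (default), genes
    are importance-weighted by their design-model p-value before the
    SVD, so genes strongly driven by the biological design contribute
    little to the latent-factor estimate — without this, the shared
    replicate noise of large coexpression modules masquerades as a
    surrogate variable and its removal bleeds correlation across
    modules.  With ``n_sv="auto"`` the number of components is chosen
    by permutation parallel analysis: keep component k when its singular
    value exceeds the ``quantile`` percentile of singular values
    obtained after independently permuting each gene's residuals.
    """
    from scipy import stats as _stats

    meta = metadata if metadata is not None else expr.metadata
    if meta is None:
        raise ValueError("sample metadata is required")
    if not {"population", "temperature"} <= set(meta.columns):
        raise ValueError("metadata must contain population and temperature")
    meta = meta.loc[expr.samples]
    design = _design_matrix(meta, include_interaction)
    model_df = np.linalg.matrix_rank(design)
    n_samples = len(meta)
    max_sv = n_samples - model_df
    if isinstance(n_sv, int) and n_sv >= max_sv:
        raise ValueError(
            f"n_sv={n_sv} must be < n_samples - model df = {max_sv}"
        )

    values = expr.data.to_numpy(dtype=float)
    resid = _residualize(values, design)
    if weight_by_design_p:
        centered = values - values.mean(axis=1, keepdims=True)
        sst = np.sum(centered**2, axis=1)
        sse = np.sum(resid**2, axis=1)
        df1, df2 = model_df - 1, n_samples - model_df
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((sst - sse) / df1) / np.where(sse > 0, sse / df2, np.nan)
        pvals = np.where(np.isfinite(f), _stats.f.sf(f, df1, df2), 0.0)
        resid = resid * np.sqrt(np.maximum(pvals, 0.0))[:, None]
    u, s, vt = np.linalg.svd(resid, full_matrices=False)

    scale = np.abs(resid).max()
    meaningful = bool(s[0] > 1e-10 * max(scale, 1.0)) and scale > 1e-12

    if n_sv == "auto":
        rng = np.random.default_rng(seed)
        perm_s = np.empty((n_permutations, len(s)))
        for b in range(n_permutations):
            shuffled = resid.copy()
            # permute each gene's residual profile independently
            idx = np.argsort(rng.random(shuffled.shape), axis=1)
            shuffled = np.take_along_axis(shuffled, idx, axis=1)
            perm_s[b] = np.linalg.svd(shuffled, compute_uv=False)
        threshold = np.quantile(perm_s, quantile, axis=0)
        keep = int(np.sum(s > threshold))
        keep = min(keep, max_sv - 1) if max_sv > 1 else 0
    else:
        keep = int(n_sv)

    if not meaningful:
        keep = 0

    # second step: rebuild each factor from the raw (unresidualized)
    # expression of the genes most associated with it, recovering any
    # component of the latent factor that is aligned with the design
    components = []
    if keep:
        raw = values - values.mean(axis=1, keepdims=True)
        resid_norm = np.sqrt((resid**2).sum(axis=1))
        for k in range(keep):
            v = vt[k]
            with np.errstate(invalid="ignore"):
                assoc = np.abs(resid @ v) / np.where(resid_norm > 0, resid_norm, np.nan)
            n_top = max(50, int(0.1 * len(assoc)))
            top = np.argsort(np.nan_to_num(assoc))[-n_top:]
            _, _, vt_top = np.linalg.svd(raw[top], full_matrices=False)
            direction = vt_top[0]
            if direction @ v < 0:
                direction = -direction
            components.append(direction)
        q, _ = np.linalg.qr(np.column_stack(components))
        # keep orientation aligned with the initial estimates
        for k in range(keep):
            if q[:, k] @ components[k] < 0:
                q[:, k] = -q[:, k]
        sv_matrix = q
    else:
        sv_matrix = np.empty((n_samples, 0))

    sv = pd.DataFrame(
        sv_matrix, index=expr.samples,
        columns=[f"SV{k + 1}" for k in range(keep)],
    )
    return SurrogateVariables(
        sv=sv, singular_values=s[: max(keep, 1)], n_sv=keep, meaningful=meaningful
    )


def remove_latent_effects(expr: ExpressionMatrix, sv: pd.DataFrame | np.ndarray) -> ExpressionMatrix:
    """Regress each gene on the surrogate variables and keep residuals.

    The per-gene intercept is retained, so grand means are preserved;
    re-regressing the output on ``sv`` yields coefficients ~ 0.
    All-zero SV columns are dropped (removing nothing); a rank-deficient
    remainder is rejected.
    """
    sv_arr = np.asarray(sv, dtype=float)
    if sv_arr.ndim == 1:
        sv_arr = sv_arr[:, None]
    if sv_arr.shape[0] != expr.data.shape[1]:
        raise ValueError("surrogate-variable rows must match sample count")
    nonzero = np.abs(sv_arr).max(axis=0) > 0
    sv_arr = sv_arr[:, nonzero]
    if sv_arr.shape[1] == 0:
        return expr.with_data(expr.data.copy(), "remove_latent_effects:none")
    design = np.hstack([np.ones((sv_arr.shape[0], 1)), sv_arr])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("surrogate-variable matrix is rank deficient")
    values = expr.data.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    fitted = (design @ beta).T
    intercept = beta[0][:, None]
    resid = values - fitted + intercept
    data = pd.DataFrame(resid, index=expr.genes, columns=expr.samples)
    return expr.with_data(data, f"remove_latent_effects:k={sv_arr.shape[1]}")
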
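"""Resampling-based module stability filtering.

Candidate modules from the full network are validated by rebuilding the
network on many subsampled datasets (a fixed number of replicates drawn
from every treatment cell).  A resampled module that captures at least
10% of a full-network module credits its overlapping genes to that
module; genes credited in at least 70% of resamples keep their label,
everything else is unassigned.  Surviving modules with eigengene
correlation above 0.9 are merged, and modules that fall below the
minimum size are dissolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexnet.network import CutParameters, _relabel_by_size, build_network_modules
from coexnet.preprocess import ExpressionMatrix
from coexnet.simulate import UNASSIGNED

_EPS = 1e-9  # guards >= comparisons against float error in fraction*size


@dataclass
class ResamplePlan:
    """Sample subsets for each resampled network."""

    sample_ids: list[list[str]]
    replicates_kept_per_cell: int
    rng_seed: int

    @property
    def n_resamples(self) -> int:
        return len(self.sample_ids)


def make_resample_plan(
    metadata: pd.DataFrame,
    n_resamples: int = 100,
    kept_per_cell: int = 4,
    seed: int = 0,
) -> ResamplePlan:
    """Draw ``kept_per_cell`` replicates per treatment cell, uniformly
    without replacement, independently across cells and resamples."""
    rng = np.random.default_rng(seed)
    cells = metadata.groupby(["population", "temperature"], observed=True)
    for key, group in cells:
        if len(group) < kept_per_cell:
            raise ValueError(
                f"treatment cell {key} has {len(group)} replicates; "
                f"cannot keep {kept_per_cell}"
            )
    plans: list[list[str]] = []
    for _ in range(n_resamples):
        chosen: list[str] = []
        for _, group in cells:
            ids = np.sort(group.index.to_numpy())
            chosen.extend(rng.choice(ids, size=kept_per_cell, replace=False))
        plans.append(sorted(chosen))
    return ResamplePlan(sample_ids=plans, replicates_kept_per_cell=kept_per_cell,
                        rng_seed=seed)


def significant_groups(
    resampled: pd.Series,
    full: pd.Series,
    min_fraction: float = 0.10,
) -> dict[int, set]:
    """Genes credited to each full-network module by one resample.

    For each resampled module r and full module f: if the overlap holds
    at least ``min_fraction`` of f's genes, every gene in the overlap is
    credited to f.  One resampled module may credit several full
    modules; unassigned labels never match.
    """
    if not resampled.index.equals(full.index):
        resampled = resampled.reindex(full.index, fill_value=UNASSIGNED)
    credits: dict[int, set] = {}
    full_sizes = full[full != UNASSIGNED].value_counts()
    cross = pd.crosstab(resampled, full)
    for f in full_sizes.index:
        if f not in cross.columns:
            continue
        threshold = min_fraction * full_sizes[f]
        col = cross[f].drop(index=UNASSIGNED, errors="ignore")
        good_r = col.index[col + _EPS >= threshold]
        if len(good_r) == 0:
            continue
        mask = (full == f) & resampled.isin(good_r)
        credits[int(f)] = set(full.index[mask])
    return credits


def apply_retention(
    credit_counts: pd.Series,
    full: pd.Series,
    n_resamples: int,
    threshold: float = 0.70,
) -> tuple[pd.Series, pd.DataFrame]:
    """Keep a gene's full-network label iff it was credited to that label
    in at least ``threshold`` of the resamples.

    ``credit_counts`` gives, per gene, the number of resamples in which
    the gene fell in a significant group of its own full-network module.
    Returns the filtered assignment and a retention table.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    counts = credit_counts.reindex(full.index, fill_value=0).astype(int)
    retained = counts + _EPS >= threshold * n_resamples
    labels = full.where((full != UNASSIGNED) & retained, UNASSIGNED).astype(int)
    table = pd.DataFrame(
        {
            "full_module": full,
            "credits": counts,
            "retention_fraction": counts / n_resamples,
            "final_label": labels,
        }
    )
    return labels, table


def count_credits(
    credit_sets: list[dict[int, set]], full: pd.Series
) -> pd.Series:
    """Number of resamples crediting each gene to its full-network module."""
    counts = pd.Series(0, index=full.index, dtype=int)
    for credits in credit_sets:
        for module, genes in credits.items():
            idx = full.index.intersection(list(genes))
            idx = idx[full.loc[idx] == module]
            counts.loc[idx] += 1
    return counts


def merge_correlated_modules(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    r_threshold: float = 0.9,
    iterate: bool = True,
) -> pd.Series:
    """Merge modules whose eigengenes correlate above ``r_threshold``.

    Modules are grouped by single-linkage chaining on the thresholded
    eigengene-correlation graph (connected components); each component
    becomes one module.  Because merging changes eigengenes, the
    procedure recomputes them and repeats until no pair exceeds the
    threshold (``iterate=False`` performs a single pass).
    """
    from coexnet.eigengene import module_eigengene  # local import: avoid cycle

    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    labels = labels.copy()
    while True:
        sizes = labels[labels != UNASSIGNED].value_counts()
        # singleton modules have no principal component; they are left to
        # the minimum-size purge downstream
        modules = sorted(sizes.index[sizes >= 2])
        if len(modules) < 2:
            break
        eig = pd.DataFrame(
            {
                m: module_eigengene(data, labels.index[labels == m]).scores
                for m in modules
            }
        )
        r = eig.corr()
        adj = (r > r_threshold) & ~np.eye(len(modules), dtype=bool)
        if not adj.to_numpy().any():
            break
        # connected components by union-find
        parent = {m: m for m in modules}

        def find(m):
            while parent[m] != m:
                parent[m] = parent[parent[m]]
                m = parent[m]
            return m

        for i, mi in enumerate(modules):
            for mj in np.asarray(modules)[np.asarray(adj.iloc[i])]:
                ri, rj = find(mi), find(int(mj))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
        labels = labels.map(lambda m: find(m) if m != UNASSIGNED else UNASSIGNED)
        if not iterate:
            break
    return _relabel_by_size(labels)


def enforce_min_size(labels: pd.Series, min_size: int = 30) -> pd.Series:
    """Dissolve modules with fewer than ``min_size`` genes and renumber
    the survivors by decreasing size."""
    counts = labels[labels != UNASSIGNED].value_counts()
    small = counts.index[counts < min_size]
    labels = labels.where(~labels.isin(small), UNASSIGNED).astype(int)
    return _relabel_by_size(labels)


@dataclass
class StabilityResult:
    """Final assignment plus the audit trail of the stability filter."""

    labels: pd.Series
    retention: pd.DataFrame
    plan: ResamplePlan
    full_labels: pd.Series
    resampled_labels: list[pd.Series] = field(repr=False, default_factory=list)


def run_stability(
    expr: ExpressionMatrix | pd.DataFrame,
    full_labels: pd.Series,
    metadata: pd.DataFrame,
    beta: float = 5.0,
    cut_params: CutParameters | None = None,
    n_resamples: int = 100,
    kept_per_cell: int = 4,
    min_fraction: float = 0.10,
    retention_threshold: float = 0.70,
    merge_r: float = 0.9,
    min_size: int = 30,
    seed: int = 0,
    keep_resampled_labels: bool = False,
) -> StabilityResult:
    """Full stability procedure around an existing full-network assignment.

    Rebuilds the network on each subsample with the same parameters as
    the full network, credits genes through significant groups, applies
    the retention threshold, merges correlated eigengenes, and enforces
    the minimum module size.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    cut_params = cut_params or CutParameters()
    plan = make_resample_plan(metadata, n_resamples, kept_per_cell, seed)
    credit_sets: list[dict[int, set]] = []
    kept_labels: list[pd.Series] = []
    for ids in plan.sample_ids:
        sub = data.loc[:, ids]
        sub_labels = build_network_modules(sub, beta=beta, params=cut_params)
        credit_sets.append(significant_groups(sub_labels, full_labels, min_fraction))
        if keep_resampled_labels:
            kept_labels.append(sub_labels)
    counts = count_credits(credit_sets, full_labels)
    labels, retention = apply_retention(
        counts, full_labels, plan.n_resamples, retention_threshold
    )
    labels = merge_correlated_modules(data, labels, r_threshold=merge_r)
    labels = enforce_min_size(labels, min_size)
    retention["final_label"] = labels
    return StabilityResult(
        labels=labels, retention=retention, plan=plan,
        full_labels=full_labels, resampled_labels=kept_labels,
    )
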
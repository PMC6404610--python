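"""Signed weighted coexpression network construction and module detection.

The network follows the WGCNA recipe: a signed adjacency
a_ij = ((1 + cor_ij)/2)^beta, the topological overlap matrix (TOM),
average-linkage hierarchical clustering of the TOM dissimilarity, and a
dynamic hybrid tree cut into candidate modules with a PAM-like second
stage that can assign leftover genes across branch boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from coexnet.preprocess import ExpressionMatrix
from coexnet.simulate import UNASSIGNED


def signed_adjacency(
    expr: ExpressionMatrix | pd.DataFrame, beta: float = 5.0
) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + r_ij)/2)^beta with Pearson r.

    Anticorrelated genes map toward 0, perfectly correlated pairs to 1.
    Genes with zero variance have undefined correlation and are
    rejected by name.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    if data.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(data.index[np.flatnonzero(sd == 0)][:10])
        raise ValueError(f"zero-variance gene(s): {bad}")
    r = np.corrcoef(values)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    a = np.clip(a, 0.0, 1.0)
    a = (a + a.T) / 2.0
    out = pd.DataFrame(a, index=data.index, columns=data.index)
    out.attrs["beta"] = beta
    out.attrs["signed"] = True
    return out


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a [0,1] adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and connectivity k_i = sum_{u != i} a_iu;
    TOM_ii = 1.  A vanishing denominator (isolated pair) yields 0.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1) - np.diag(a)
    # l_ij excludes u = i and u = j; diag(a) = 1 contributes a_ij twice
    l = a @ a - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 1e-12, (l + a) / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def cluster_average(diss: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a dissimilarity matrix.

    Returns a SciPy linkage matrix; average linkage guarantees
    non-decreasing merge heights.
    """
    d = diss.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric with a zero diagonal")
    return linkage(squareform(d, checks=False), method="average")


@dataclass
class CutParameters:
    """Dynamic tree cut parameters (WGCNA naming)."""

    cut_height: float = 0.905
    deep_split: int = 2
    min_cluster_size: int = 30
    pam_respects_hybrid: bool = False
    pam_stage: bool = True
    pam_max_dist: float | None = None  # defaults to cut_height

    def validate(self) -> None:
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must lie in (0, 1]")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be in 0..4")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def _node_members(z: np.ndarray, n: int) -> list[list[int]]:
    """Leaf sets for every internal node of a linkage matrix."""
    members: list[list[int]] = [[i] for i in range(n)]
    for left, right, _, _ in z:
        members.append(members[int(left)] + members[int(right)])
    return members


def _subtree_heights(z: np.ndarray, n: int) -> list[np.ndarray]:
    """Sorted internal merge heights for every node's subtree."""
    heights: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    for i, (left, right, h, _) in enumerate(z):
        merged = np.concatenate([heights[int(left)], heights[int(right)], [h]])
        merged.sort()
        heights.append(merged)
    return heights


def _split_criteria(params: CutParameters) -> tuple[float, float]:
    # deep_split 0..4 maps to progressively permissive core-scatter and
    # gap requirements on the normalized height scale (the dynamic
    # hybrid convention: scatter in [0.64, 0.96], gap = (1-scatter)*3/4)
    max_core_scatter = 0.64 + 0.08 * params.deep_split
    min_gap = (1.0 - max_core_scatter) * 0.75
    return max_core_scatter, min_gap


class _Splitter:
    """Recursive dynamic-hybrid branch splitting.

    A merge node is split into its two children when both children are
    at least ``min_cluster_size``, both have a tight core (mean height
    of the lowest ``min_cluster_size - 1`` internal merges below the
    deep-split-dependent core-scatter limit) and both are separated
    from the joining height by at least the minimum gap.  Heights are
    normalized so the 5th percentile of merge heights maps to 0 and the
    cut height to 1.
    """

    def __init__(self, z: np.ndarray, n: int, members: list[list[int]],
                 params: CutParameters):
        self.z, self.n, self.members, self.params = z, n, members, params
        self.heights = _subtree_heights(z, n)
        h = z[:, 2]
        low = float(np.quantile(h, 0.05)) if len(h) else 0.0
        span = max(params.cut_height - low, 1e-12)
        self._low, self._span = low, span
        self.max_core_scatter, self.min_gap = _split_criteria(params)

    def _u(self, h: float) -> float:
        return (h - self._low) / self._span

    def _core_scatter(self, node: int) -> float:
        if node < self.n:
            return 0.0
        core = self.heights[node][: max(self.params.min_cluster_size - 1, 1)]
        return self._u(float(core.mean()))

    def _qualifies(self, child: int, join_height: float) -> bool:
        if len(self.members[child]) < self.params.min_cluster_size:
            return False
        scatter = self._core_scatter(child)
        gap = self._u(join_height) - scatter
        return scatter <= self.max_core_scatter and gap >= self.min_gap

    def split(self, node: int) -> list[list[int]]:
        if node < self.n:
            return [self.members[node]]
        left, right, height, _ = self.z[node - self.n]
        left, right = int(left), int(right)
        if self._qualifies(left, height) and self._qualifies(right, height):
            return self.split(left) + self.split(right)
        # trim small side branches (later unassigned or PAM-rescued) and
        # keep descending the main branch
        min_size = self.params.min_cluster_size
        sizes = (len(self.members[left]), len(self.members[right]))
        if sizes[0] < min_size and sizes[1] >= min_size:
            return [self.members[left]] + self.split(right)
        if sizes[1] < min_size and sizes[0] >= min_size:
            return [self.members[right]] + self.split(left)
        return [self.members[node]]


def dynamic_tree_cut(
    z: np.ndarray,
    diss: pd.DataFrame,
    params: CutParameters | None = None,
) -> pd.Series:
    """Dynamic hybrid tree cut of an average-linkage dendrogram.

    Stage 1 cuts the tree at ``cut_height`` and recursively splits
    branches whose sub-branches are each at least ``min_cluster_size``
    and separated by a height gap controlled by ``deep_split`` (larger
    deep_split = more, smaller clusters).  Branches below the minimum
    size are left unassigned.  Stage 2 (PAM-like, enabled when
    ``pam_stage`` and ``pam_respects_hybrid`` is false) assigns each
    unlabeled gene to the module with the smallest average dissimilarity,
    provided that average is at most ``pam_max_dist`` (default: the cut
    height); ties break toward the lower module label.  Final labels are
    positive integers ordered by decreasing module size, 0 = unassigned.
    """
    params = params or CutParameters()
    params.validate()
    n = diss.shape[0]
    members = _node_members(z, n)
    d = diss.to_numpy(dtype=float)

    # maximal nodes with merge height <= cut_height form the static cut
    flat = fcluster(z, t=params.cut_height, criterion="distance")
    branches: dict[int, list[int]] = {}
    for i, c in enumerate(flat):
        branches.setdefault(int(c), []).append(i)

    # map static branches back to tree nodes so deep-split can recurse
    node_of_branch: dict[frozenset, int] = {}
    for node, mem in enumerate(members):
        node_of_branch.setdefault(frozenset(mem), node)

    splitter = _Splitter(z, n, members, params)
    clusters: list[list[int]] = []
    for mem in branches.values():
        node = node_of_branch.get(frozenset(mem))
        if node is None or params.deep_split == 0:
            clusters.append(mem)
        else:
            clusters.extend(splitter.split(node))

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for mem in clusters:
        if len(mem) >= params.min_cluster_size:
            labels[mem] = next_label
            next_label += 1

    if params.pam_stage and not params.pam_respects_hybrid and next_label > 1:
        max_dist = params.pam_max_dist if params.pam_max_dist is not None else params.cut_height
        module_ids = list(range(1, next_label))
        module_masks = [labels == m for m in module_ids]
        unlabeled = np.flatnonzero(labels == 0)
        if len(unlabeled):
            avg = np.stack(
                [d[np.ix_(unlabeled, mask.nonzero()[0])].mean(axis=1) for mask in module_masks],
                axis=1,
            )
            best = np.argmin(avg, axis=1)  # argmin takes the lowest label on ties
            best_dist = avg[np.arange(len(unlabeled)), best]
            ok = best_dist <= max_dist
            labels[unlabeled[ok]] = np.asarray(module_ids)[best[ok]]

    return _relabel_by_size(pd.Series(labels, index=diss.index, name="module"))


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Renumber modules by decreasing size (ties: lower old label first)."""
    counts = labels[labels != UNASSIGNED].value_counts()
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping).astype(int)


def build_network_modules(
    expr: ExpressionMatrix | pd.DataFrame,
    beta: float = 5.0,
    params: CutParameters | None = None,
) -> pd.Series:
    """Convenience: adjacency -> TOM -> UPGMA -> dynamic tree cut."""
    a = signed_adjacency(expr, beta=beta)
    tom = topological_overlap(a)
    diss = 1.0 - tom
    np.fill_diagonal(diss.values, 0.0)
    z = cluster_average(diss)
    return dynamic_tree_cut(z, diss, params)
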
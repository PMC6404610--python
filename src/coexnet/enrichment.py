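"""Gene-set enrichment: homolog expansion, one-tailed Fisher tests, BH FDR.

Gene sets (e.g. transcription-factor ChIP targets or hsp families) are
tested for over-representation in each module with the upper-tail
hypergeometric (one-tailed Fisher exact) test against a universe of
testable genes, and FDR is controlled within each collection by
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from coexnet.simulate import UNASSIGNED


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe."""

    name: str
    sets: dict[str, set] = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def restricted(self, universe: set) -> "GeneSetCollection":
        """Intersect every set with ``universe`` (empty sets are kept,
        flagged by their zero size rather than silently dropped)."""
        return GeneSetCollection(
            name=self.name,
            sets={k: v & universe for k, v in self.sets.items()},
            universe=set(universe),
        )


def expand_homologs(
    collection: GeneSetCollection,
    homolog_map: pd.DataFrame,
    expressed_genes=None,
) -> GeneSetCollection:
    """Map gene sets through a (possibly one-to-many) homolog table.

    ``homolog_map`` has two columns: source-species id, target-species
    id.  Every set member is replaced by the union of all its mapped
    target genes (a source gene with several homologs contributes all of
    them; unmapped genes drop out).  The universe becomes all mapped
    target genes, intersected with ``expressed_genes`` when given.
    """
    if homolog_map.empty:
        raise ValueError("homolog map is empty")
    src_col, tgt_col = homolog_map.columns[:2]
    pairs = homolog_map[[src_col, tgt_col]].drop_duplicates()
    mapping: dict[str, set] = {}
    for src, tgt in pairs.itertuples(index=False):
        mapping.setdefault(src, set()).add(tgt)
    universe = set().union(*mapping.values()) if mapping else set()
    if expressed_genes is not None:
        universe &= set(expressed_genes)
    sets = {
        name: set().union(*(mapping.get(g, set()) for g in members)) & universe
        if members
        else set()
        for name, members in collection.sets.items()
    }
    return GeneSetCollection(name=collection.name, sets=sets, universe=universe)


def _upper_tail_p(a: np.ndarray, universe: np.ndarray, set_size: np.ndarray,
                  module_size: np.ndarray) -> np.ndarray:
    """P(overlap >= a) under the hypergeometric null (vectorized)."""
    return stats.hypergeom.sf(np.asarray(a) - 1, universe, set_size, module_size)


def fisher_enrichment(
    module: set, geneset: set, universe: set
) -> tuple[float, float]:
    """One-tailed (over-representation) Fisher exact test.

    The 2x2 table is (in module & in set, in module & not, not module &
    in set, neither); p is the upper-tail hypergeometric sum and the
    odds ratio is (a*d)/(b*c), infinite when b*c = 0 with a*d > 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    if not module <= universe or not geneset <= universe:
        raise ValueError("module and gene set must be subsets of the universe")
    a = len(module & geneset)
    b = len(module) - a
    c = len(geneset) - a
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    p = float(_upper_tail_p(a, len(universe), len(geneset), len(module)))
    return odds, min(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_all(
    labels: pd.Series,
    collections: list[GeneSetCollection],
    universe: set | None = None,
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Fisher enrichment of every (module, set) pair.

    The universe defaults to the genes carrying a label (the testable,
    expressed genes); BH FDR is applied within each collection across
    all its (module, set) tests.
    """
    module_ids = sorted(set(labels[labels != UNASSIGNED]))
    if not module_ids:
        raise ValueError("no modules in the assignment")
    if universe is None:
        universe = set(labels.index)
    modules: dict[str, set] = {
        str(m): set(labels.index[labels == m]) & universe for m in module_ids
    }
    if include_unassigned:
        modules["unassigned"] = set(labels.index[labels == UNASSIGNED]) & universe

    frames = []
    for coll in collections:
        rows = []
        for set_name, members in coll.sets.items():
            members = members & universe
            for mod_name, mod_genes in modules.items():
                a = len(mod_genes & members)
                b = len(mod_genes) - a
                c = len(members) - a
                d = len(universe) - a - b - c
                if b * c == 0:
                    odds = np.inf if a * d > 0 else np.nan
                else:
                    odds = (a * d) / (b * c)
                rows.append(
                    {
                        "collection": coll.name, "set": set_name, "module": mod_name,
                        "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds,
                        "set_size": len(members), "module_size": len(mod_genes),
                        "universe_size": len(universe),
                    }
                )
        frame = pd.DataFrame(rows)
        frame["p"] = np.minimum(
            _upper_tail_p(
                frame["a"].to_numpy(), frame["universe_size"].to_numpy(),
                frame["set_size"].to_numpy(), frame["module_size"].to_numpy(),
            ),
            1.0,
        )
        frame["q"] = bh_fdr(frame["p"].to_numpy())
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
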
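"""Module eigengenes and their statistical characterization.

The eigengene of a module is the first principal component of the
module's standardized expression: a one-number-per-sample summary whose
variance-explained quantifies how coherent the module is.  Eigengenes
are then tested for an ancestral environmental response (t-test within
the ancestor), for population / temperature / interaction effects
(two-way fixed-effects ANOVA), pairwise population differences (Tukey
HSD on the ANOVA residual mean square) and finally classified into
reaction-norm categories from the significance pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from coexnet.preprocess import ExpressionMatrix
from coexnet.simulate import UNASSIGNED, Category


@dataclass
class EigengeneRow:
    """First principal component of one module."""

    scores: pd.Series  # unit norm (up to orientation sign)
    pct_variance_pc1: float
    pct_variance_pc2: float
    orientation_sign: int


def module_eigengene(
    expr: ExpressionMatrix | pd.DataFrame, genes
) -> EigengeneRow:
    """Eigengene of the gene set: PC1 sample scores of standardized rows.

    Each gene is centered and scaled to unit variance before the SVD, so
    the variance explained is comparable across modules.  The sign is
    oriented so the eigengene correlates positively with the module's
    mean standardized expression (deterministic on recomputation).
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    sub = data.loc[list(genes)]
    if sub.shape[0] < 2:
        raise ValueError("a module needs at least 2 genes for an eigengene")
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("all genes in the module are constant")
    if (sd == 0).any():
        bad = list(sub.index[np.flatnonzero(sd == 0)][:10])
        raise ValueError(f"constant gene(s) in module: {bad}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    total = float(np.sum(s**2))
    pc1 = 100.0 * float(s[0] ** 2) / total
    pc2 = 100.0 * float(s[1] ** 2) / total if len(s) > 1 else 0.0
    scores = vt[0]
    mean_profile = z.mean(axis=0)
    r = float(np.dot(scores, mean_profile))
    sign = 1
    if r < 0 or (r == 0 and scores[np.flatnonzero(scores)[0]] < 0 if np.any(scores) else False):
        sign = -1
    return EigengeneRow(
        scores=pd.Series(sign * scores, index=sub.columns, name="eigengene"),
        pct_variance_pc1=pc1,
        pct_variance_pc2=pc2,
        orientation_sign=sign,
    )


def ancestor_ttest(
    eigengene: pd.Series,
    metadata: pd.DataFrame,
    population: str = "ancestor",
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """t-test of eigengene expression between environments in one
    population (by default the ancestor).

    Returns (t, df, two-sided p); ``equal_var=True`` gives the pooled
    Student's t, ``False`` the Welch variant.  The sign convention is
    low-temperature group minus high-temperature group.
    """
    meta = metadata.loc[eigengene.index]
    anc = meta[meta["population"] == population]
    temps = sorted(anc["temperature"].unique())
    if len(temps) != 2:
        raise ValueError(f"population {population!r} must span two temperatures")
    groups = [eigengene.loc[anc.index[anc["temperature"] == t]] for t in temps]
    for t, g in zip(temps, groups):
        if len(g) < 2:
            raise ValueError(f"temperature group {t} has fewer than 2 samples")
    res = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
    if equal_var:
        df = len(groups[0]) + len(groups[1]) - 2
    else:
        df = float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA of one eigengene."""

    table: pd.DataFrame  # index: temperature, population, interaction, residual
    degenerate: bool = False

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


def eigengene_anova(eigengene: pd.Series, metadata: pd.DataFrame) -> AnovaResult:
    """Population x temperature ANOVA with interaction (balanced design).

    Sums of squares are computed from cell means (Type-I, identical to
    Type-III on the balanced design assumed here).  A zero residual sum
    of squares is flagged degenerate and reported with p = 0.
    """
    meta = metadata.loc[eigengene.index]
    y = eigengene.to_numpy(dtype=float)
    pops = sorted(meta["population"].unique())
    temps = sorted(meta["temperature"].unique())
    cell_counts = meta.groupby(["population", "temperature"], observed=True).size()
    if len(cell_counts) != len(pops) * len(temps) or cell_counts.nunique() != 1:
        raise ValueError("a balanced, fully crossed design is required")
    n_per_cell = int(cell_counts.iloc[0])

    grand = y.mean()
    pop_means = {p: y[(meta["population"] == p).to_numpy()].mean() for p in pops}
    temp_means = {t: y[(meta["temperature"] == t).to_numpy()].mean() for t in temps}
    cell_means = {
        (p, t): y[((meta["population"] == p) & (meta["temperature"] == t)).to_numpy()].mean()
        for p in pops
        for t in temps
    }
    n = len(y)
    ss_pop = n_per_cell * len(temps) * sum((pop_means[p] - grand) ** 2 for p in pops)
    ss_temp = n_per_cell * len(pops) * sum((temp_means[t] - grand) ** 2 for t in temps)
    ss_int = n_per_cell * sum(
        (cell_means[(p, t)] - pop_means[p] - temp_means[t] + grand) ** 2
        for p in pops
        for t in temps
    )
    fitted = np.array(
        [cell_means[(p, t)] for p, t in zip(meta["population"], meta["temperature"])]
    )
    ss_resid = float(np.sum((y - fitted) ** 2))

    df_pop = len(pops) - 1
    df_temp = len(temps) - 1
    df_int = df_pop * df_temp
    df_resid = n - len(pops) * len(temps)

    degenerate = ss_resid <= 1e-12 * max(float(np.sum((y - grand) ** 2)), 1e-300)
    rows = {}
    for name, ss, df in (
        ("temperature", ss_temp, df_temp),
        ("population", ss_pop, df_pop),
        ("interaction", ss_int, df_int),
    ):
        if degenerate:
            f = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / df) / (ss_resid / df_resid)
            p = float(stats.f.sf(f, df, df_resid))
        rows[name] = {"SS": ss, "df_num": df, "df_den": df_resid, "F": f, "p": p}
    rows["residual"] = {
        "SS": ss_resid, "df_num": df_resid, "df_den": np.nan, "F": np.nan, "p": np.nan
    }
    return AnovaResult(table=pd.DataFrame(rows).T, degenerate=degenerate)


@dataclass
class TukeyResult:
    """Pairwise population comparisons with compact letter display."""

    comparisons: pd.DataFrame  # (group1, group2, estimate, p_adj, significant)
    letters: dict[str, str]
    alpha: float


def tukey_hsd(
    eigengene: pd.Series,
    metadata: pd.DataFrame,
    anova: AnovaResult | None = None,
    factor: str = "population",
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey HSD over factor levels using the two-way ANOVA residual MS.

    Adjusted p-values come from the studentized-range distribution with
    the ANOVA residual df; groups pooled across the other factor
    (balanced design).  The compact letter display assigns a letter to
    every maximal clique of the non-significance graph, so two levels
    share a letter iff their adjusted p exceeds ``alpha``.
    """
    meta = metadata.loc[eigengene.index]
    if anova is None:
        anova = eigengene_anova(eigengene, meta)
    ms_resid = float(anova.table.loc["residual", "SS"]) / float(
        anova.table.loc["residual", "df_num"]
    )
    df_resid = float(anova.table.loc["residual", "df_num"])
    levels = sorted(meta[factor].unique())
    k = len(levels)
    groups = {lv: eigengene.loc[meta.index[meta[factor] == lv]] for lv in levels}
    sizes = {lv: len(g) for lv, g in groups.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError("balanced groups are required for Tukey HSD")
    n_per = next(iter(sizes.values()))
    se = np.sqrt(ms_resid / n_per)

    rows = []
    ns_graph = nx.Graph()
    ns_graph.add_nodes_from(levels)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(groups[a].mean() - groups[b].mean())
            if ms_resid <= 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_resid))
            p_adj = min(max(p_adj, 0.0), 1.0)
            sig = p_adj < alpha
            rows.append(
                {"group1": a, "group2": b, "estimate": diff, "p_adj": p_adj,
                 "significant": sig}
            )
            if not sig:
                ns_graph.add_edge(a, b)

    means = {lv: float(groups[lv].mean()) for lv in levels}
    cliques = sorted(
        (sorted(c, key=lambda lv: means[lv]) for c in nx.find_cliques(ns_graph)),
        key=lambda c: min(means[lv] for lv in c),
    )
    letters: dict[str, str] = {lv: "" for lv in levels}
    for letter_i, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_i)
        for lv in clique:
            letters[lv] += letter
    return TukeyResult(
        comparisons=pd.DataFrame(rows), letters=letters, alpha=alpha
    )


def classify_reaction_norm(anova: AnovaResult, alpha: float = 0.05) -> Category:
    """Reaction-norm category from the ANOVA significance pattern.

    interaction significant -> EVOLVED_PLASTICITY (evolved and/or
    divergent plasticity); else temperature + population -> DIVERGENT
    BASELINE; temperature only -> SHARED_PLASTICITY; population only ->
    NON_PLASTIC_DIVERGENCE; nothing -> NULL (no signal).
    """
    p_int = anova.p("interaction")
    p_temp = anova.p("temperature")
    p_pop = anova.p("population")
    if p_int < alpha:
        return Category.EVOLVED_PLASTICITY
    if p_temp < alpha and p_pop < alpha:
        return Category.DIVERGENT_BASELINE
    if p_temp < alpha:
        return Category.SHARED_PLASTICITY
    if p_pop < alpha:
        return Category.NON_PLASTIC_DIVERGENCE
    return Category.NULL


def eigengene_table(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    ancestor: str = "ancestor",
    include_unassigned: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full per-module statistical summary.

    Returns ``(stats, eigengenes, tukey_letters)``: a long-format table
    with one row per module x effect carrying F, dfs, p, the PC1/PC2
    variance percentages, the ancestor t-test and the reaction-norm
    category; the eigengene score matrix (modules x samples); and the
    compact-letter display for modules with a significant population
    effect.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    module_ids = sorted(set(labels[labels != UNASSIGNED]))
    groups: list[tuple[str, pd.Index]] = [
        (str(m), labels.index[labels == m]) for m in module_ids
    ]
    if include_unassigned and (labels == UNASSIGNED).sum() >= 2:
        groups.append(("unassigned", labels.index[labels == UNASSIGNED]))

    stat_rows = []
    letter_rows = []
    scores = {}
    for name, genes in groups:
        row = module_eigengene(data, genes)
        scores[name] = row.scores
        anova = eigengene_anova(row.scores, metadata)
        category = classify_reaction_norm(anova, alpha)
        t, df_t, p_t = ancestor_ttest(row.scores, metadata, population=ancestor)
        for effect in ("temperature", "population", "interaction"):
            stat_rows.append(
                {
                    "module": name,
                    "n_genes": len(genes),
                    "pct_var_pc1": row.pct_variance_pc1,
                    "pct_var_pc2": row.pct_variance_pc2,
                    "effect": effect,
                    "F": anova.f(effect),
                    "df_num": int(anova.table.loc[effect, "df_num"]),
                    "df_den": int(anova.table.loc[effect, "df_den"]),
                    "p": anova.p(effect),
                    "ancestor_t": t,
                    "ancestor_df": df_t,
                    "ancestor_p": p_t,
                    "category": category.value,
                }
            )
        if anova.p("population") < alpha:
            tukey = tukey_hsd(row.scores, metadata, anova=anova, alpha=alpha)
            for pop, letter in tukey.letters.items():
                letter_rows.append({"module": name, "population": pop, "letters": letter})

    stats_df = pd.DataFrame(stat_rows)
    eig_df = pd.DataFrame(scores).T
    eig_df.index.name = "module"
    letters_df = pd.DataFrame(letter_rows, columns=["module", "population", "letters"])
    return stats_df, eig_df, letters_df
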
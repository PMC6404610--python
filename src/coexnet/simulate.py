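"""Negative-binomial count simulator with planted coexpression modules.

The generator emulates the structure of an experimental-evolution
transcriptomics study: four populations (an ancestor, an unselected
control, and heat- and oxidative-stress selected lines) assayed at two
rearing temperatures (20 and 30 degrees C) with replicate RNA-seq
libraries per treatment cell.  Each planted module is driven by a latent
"eigengene" whose mean over treatment cells follows one of the canonical
reaction-norm archetypes (shared plasticity, divergent baseline,
evolved/divergent plasticity, non-plastic divergence, or null).  Module
genes load on that latent profile on the log scale, latent batch factors
load on every gene, and counts are drawn from a negative binomial after
scaling by a per-sample library-size factor.

Effect sizes are expressed in replicate-standard-deviation units: the
latent eigengene receives unit-variance normal replicate noise before
any per-gene noise, so a temperature effect of 2 means the 30-degree
cells sit two replicate SDs above the 20-degree cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

#: Module label reserved for genes that belong to no module.
UNASSIGNED = 0

POPULATIONS = ("ancestor", "control", "heat", "oxidative")
TEMPERATURES = (20, 30)


class Category(str, Enum):
    """Reaction-norm archetypes for a planted module's eigengene."""

    SHARED_PLASTICITY = "SHARED_PLASTICITY"
    DIVERGENT_BASELINE = "DIVERGENT_BASELINE"
    EVOLVED_PLASTICITY = "EVOLVED_PLASTICITY"
    NON_PLASTIC_DIVERGENCE = "NON_PLASTIC_DIVERGENCE"
    NULL = "NULL"


@dataclass
class ModuleSpec:
    """Specification of one planted module.

    Effects are additive on the latent eigengene: the cell mean is
    ``temperature_effect * I[30C] + population_effects[pop] +
    interaction_effects[(pop, temp)]`` and each sample adds standard
    normal replicate noise.  ``loading_mean``/``loading_sd`` control the
    per-gene loading on the eigengene; ``within_module_noise_sd`` is the
    per-gene log-scale noise around the loaded profile.
    """

    size: int
    category: Category = Category.NULL
    temperature_effect: float = 0.0
    population_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    loading_mean: float = 0.8
    loading_sd: float = 0.1
    within_module_noise_sd: float = 0.6

    def validate(self) -> None:
        if self.size < 1:
            raise ValueError(f"module size must be >= 1, got {self.size}")
        if not 0 < self.loading_mean <= 1:
            raise ValueError("loading_mean must lie in (0, 1]")
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be non-negative")
        if self.within_module_noise_sd <= 0:
            raise ValueError("within_module_noise_sd must be positive")
        has_pop = any(v != 0 for v in self.population_effects.values())
        has_int = any(v != 0 for v in self.interaction_effects.values())
        if self.category is Category.NULL:
            if self.temperature_effect != 0 or has_pop or has_int:
                raise ValueError("NULL module must have all effects zero")
        if self.category is Category.SHARED_PLASTICITY:
            if has_pop or has_int:
                raise ValueError(
                    "SHARED_PLASTICITY requires zero population and "
                    "interaction effects"
                )
            if self.temperature_effect == 0:
                raise ValueError(
                    "SHARED_PLASTICITY requires a nonzero temperature effect"
                )


def module_archetype(category: Category | str, size: int, effect: float = 2.0,
                     **overrides) -> ModuleSpec:
    """Build a :class:`ModuleSpec` following a canonical archetype.

    The archetypes mirror the qualitative reaction-norm patterns seen in
    evolve-and-resequence expression studies:

    * ``SHARED_PLASTICITY`` — temperature response only, identical in
      all populations.
    * ``DIVERGENT_BASELINE`` — the ancestral temperature response is
      retained but one selected line shifts its baseline expression.
    * ``EVOLVED_PLASTICITY`` — the two stress-selected lines respond to
      temperature in opposite directions (the empirical signature of
      independently evolved plasticity), with no shared temperature
      main effect.
    * ``NON_PLASTIC_DIVERGENCE`` — a population shift with no
      temperature response.
    * ``NULL`` — no treatment structure (background-like module).

    ``effect`` is in replicate-SD units and sets the dominant effect of
    the archetype.
    """
    category = Category(category)
    spec: ModuleSpec
    if category is Category.SHARED_PLASTICITY:
        spec = ModuleSpec(size=size, category=category, temperature_effect=effect)
    elif category is Category.DIVERGENT_BASELINE:
        # baseline divergence dominates the retained plastic response
        # (population F well above temperature F, as in evolved lines)
        spec = ModuleSpec(
            size=size, category=category, temperature_effect=0.75 * effect,
            population_effects={"oxidative": 1.5 * effect},
        )
    elif category is Category.EVOLVED_PLASTICITY:
        spec = ModuleSpec(
            size=size, category=category,
            interaction_effects={("heat", 30): effect, ("oxidative", 30): -effect},
        )
    elif category is Category.NON_PLASTIC_DIVERGENCE:
        spec = ModuleSpec(
            size=size, category=category,
            population_effects={"heat": effect},
        )
    else:
        spec = ModuleSpec(size=size, category=Category.NULL)
    for key, value in overrides.items():
        setattr(spec, key, value)
    spec.validate()
    return spec


def default_study_design(
    seed: int = 0, n_background_genes: int = 800, effect: float = 2.0
) -> "SimulationDesign":
    """The canonical simulated study: 4 populations x 2 temperatures x 6
    replicates with five planted modules spanning the reaction-norm
    taxonomy plus background genes.

    The planted latent profiles are deliberately non-collinear, the way
    distinct coexpression modules are in real transcriptomes: one module
    up- and one down-regulated by heat, a divergent-baseline module in
    the oxidative line, an evolved-plasticity module whose stress lines
    respond in opposite directions, and a non-plastic divergence
    confined to the control line.
    """
    return SimulationDesign(
        modules=[
            module_archetype(Category.SHARED_PLASTICITY, 400, effect=effect),
            module_archetype(Category.SHARED_PLASTICITY, 350, effect=-effect),
            module_archetype(Category.DIVERGENT_BASELINE, 250, effect=effect),
            module_archetype(Category.EVOLVED_PLASTICITY, 150, effect=effect),
            module_archetype(
                Category.NON_PLASTIC_DIVERGENCE, 50, effect=effect,
                population_effects={"control": effect},
            ),
        ],
        n_background_genes=n_background_genes,
        rng_seed=seed,
    )


@dataclass
class SimulationDesign:
    """Full description of a simulated study.

    ``library_size_range`` is a pair of multiplicative factors; each
    sample's factor is drawn uniformly from it.  ``nb_dispersion`` is the
    negative-binomial dispersion alpha (variance = mu + alpha * mu^2).
    """

    modules: list[ModuleSpec]
    n_background_genes: int = 800
    n_populations: int = 4
    n_temperatures: int = 2
    n_replicates: int = 6
    library_size_range: tuple[float, float] = (0.7, 1.4)
    nb_dispersion: float = 0.05
    n_batch_factors: int = 2
    batch_effect_sd: float = 0.5
    background_noise_sd: float = 0.6
    base_log_mean: float = 5.5
    base_log_sd: float = 1.0
    rng_seed: int = 0

    @property
    def populations(self) -> tuple[str, ...]:
        return POPULATIONS[: self.n_populations]

    @property
    def temperatures(self) -> tuple[int, ...]:
        return TEMPERATURES[: self.n_temperatures]

    @property
    def n_samples(self) -> int:
        return self.n_populations * self.n_temperatures * self.n_replicates

    def validate(self) -> None:
        if not self.modules:
            raise ValueError("design must contain at least one module")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be non-negative")
        if not 1 <= self.n_populations <= len(POPULATIONS):
            raise ValueError(f"n_populations must be in 1..{len(POPULATIONS)}")
        if not 1 <= self.n_temperatures <= len(TEMPERATURES):
            raise ValueError(f"n_temperatures must be in 1..{len(TEMPERATURES)}")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be 0 < lo <= hi")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be non-negative")
        for spec in self.modules:
            spec.validate()


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated count matrix."""

    gene_labels: pd.Series  # gene -> module id (UNASSIGNED for background)
    module_categories: dict[int, Category]
    batch_factors: pd.DataFrame  # samples x batch factors
    eigengene_targets: pd.DataFrame  # module id x treatment cell means
    latent_eigengenes: pd.DataFrame  # module id x sample realized values


def _substream(seed: int, *name) -> np.random.Generator:
    """Named RNG substream: draws for one purpose never perturb another."""
    tag = zlib.crc32("/".join(str(part) for part in name).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _sample_table(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for pop in design.populations:
        for temp in design.temperatures:
            for rep in range(1, design.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{pop}_{temp}_r{rep}",
                        "population": pop,
                        "temperature": temp,
                        "replicate": rep,
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["population"] = pd.Categorical(meta["population"], categories=design.populations)
    return meta


def _cell_mean(spec: ModuleSpec, pop: str, temp: int, hot: int) -> float:
    value = spec.temperature_effect * (temp == hot)
    value += spec.population_effects.get(pop, 0.0)
    value += spec.interaction_effects.get((pop, temp), 0.0)
    return value


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    # negative binomial with var = mu + alpha mu^2: n = 1/alpha, p = n/(n+mu)
    n = 1.0 / alpha
    p = n / (n + np.maximum(mean, 1e-12))
    return rng.negative_binomial(n, p)


def simulate_counts(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate a count matrix with planted modules.

    Returns ``(counts, metadata, truth)`` where ``counts`` is a genes x
    samples integer DataFrame, ``metadata`` has one row per sample with
    population / temperature / replicate, and ``truth`` carries the
    planted labels, categories, batch factors and latent eigengenes.

    The simulation is deterministic given ``design.rng_seed``, and each
    module, the batch factors, the background genes and the library
    sizes use independent named RNG substreams, so adding a module to the
    design does not perturb the draws of the others.
    """
    design.validate()
    meta = _sample_table(design)
    n_samples = len(meta)
    hot = max(design.temperatures)

    lib_rng = _substream(design.rng_seed, "library")
    lo, hi = design.library_size_range
    lib_factors = lib_rng.uniform(lo, hi, size=n_samples)

    batch_rng = _substream(design.rng_seed, "batch")
    batch = batch_rng.standard_normal((n_samples, design.n_batch_factors))
    batch_df = pd.DataFrame(
        batch, index=meta.index,
        columns=[f"batch{b + 1}" for b in range(design.n_batch_factors)],
    )

    gene_ids: list[str] = []
    labels: list[int] = []
    log_expr_blocks: list[np.ndarray] = []
    eigengene_rows = {}
    target_rows = {}
    categories: dict[int, Category] = {}

    cells = [(pop, temp) for pop in design.populations for temp in design.temperatures]

    for m, spec in enumerate(design.modules, start=1):
        rng = _substream(design.rng_seed, "module", m)
        cell_means = {cell: _cell_mean(spec, *cell, hot) for cell in cells}
        e = np.array(
            [cell_means[(row.population, row.temperature)] for row in meta.itertuples()]
        )
        e = e + rng.standard_normal(n_samples)  # replicate noise, SD 1
        eigengene_rows[m] = e
        target_rows[m] = pd.Series(
            {f"{pop}_{temp}": cell_means[(pop, temp)] for pop, temp in cells}
        )
        categories[m] = spec.category

        loadings = spec.loading_mean + spec.loading_sd * rng.standard_normal(spec.size)
        mu0 = design.base_log_mean + design.base_log_sd * rng.standard_normal(spec.size)
        w = design.batch_effect_sd * rng.standard_normal(
            (spec.size, design.n_batch_factors)
        )
        eps = spec.within_module_noise_sd * rng.standard_normal((spec.size, n_samples))
        log_expr = mu0[:, None] + loadings[:, None] * e[None, :] + w @ batch.T + eps
        log_expr_blocks.append(log_expr)
        gene_ids.extend(f"M{m}_g{j + 1}" for j in range(spec.size))
        labels.extend([m] * spec.size)

    if design.n_background_genes:
        rng = _substream(design.rng_seed, "background")
        g = design.n_background_genes
        mu0 = design.base_log_mean + design.base_log_sd * rng.standard_normal(g)
        w = design.batch_effect_sd * rng.standard_normal((g, design.n_batch_factors))
        eps = design.background_noise_sd * rng.standard_normal((g, n_samples))
        log_expr_blocks.append(mu0[:, None] + w @ batch.T + eps)
        gene_ids.extend(f"BG_g{j + 1}" for j in range(g))
        labels.extend([UNASSIGNED] * g)

    log_expr = np.vstack(log_expr_blocks)
    mean = np.exp(log_expr) * lib_factors[None, :]
    counts = np.empty_like(mean, dtype=np.int64)
    offset = 0
    for m, spec in enumerate(design.modules, start=1):
        rng = _substream(design.rng_seed, "counts", m)
        counts[offset : offset + spec.size] = _nb_draw(
            rng, mean[offset : offset + spec.size], design.nb_dispersion
        )
        offset += spec.size
    if design.n_background_genes:
        rng = _substream(design.rng_seed, "counts", "background")
        counts[offset:] = _nb_draw(rng, mean[offset:], design.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta.index)
    truth = SimulationTruth(
        gene_labels=pd.Series(labels, index=gene_ids, name="module"),
        module_categories=categories,
        batch_factors=batch_df,
        eigengene_targets=pd.DataFrame(target_rows).T,
        latent_eigengenes=pd.DataFrame(
            eigengene_rows, index=meta.index
        ).T.rename_axis("module"),
    )
    return counts_df, meta, truth


@dataclass
class RecoveryReport:
    """Agreement between an inferred module assignment and planted truth."""

    ari: float
    per_module: pd.DataFrame  # planted module -> best match, precision, recall
    background_unassigned_fraction: float
    n_genes_compared: int


def evaluate_recovery(inferred: pd.Series, truth: SimulationTruth) -> RecoveryReport:
    """Score an inferred assignment against the planted labels.

    The adjusted Rand index is computed over genes assigned to a module
    (label > 0) in *both* partitions; per-planted-module precision and
    recall use the best-overlapping inferred module; background recovery
    is the fraction of planted-background genes left unassigned (genes
    dropped upstream, e.g. by variance filtering, count as unassigned).
    """
    common = truth.gene_labels.index.intersection(inferred.index)
    if len(common) == 0:
        raise ValueError("inferred assignment shares no genes with the truth")
    true_all = truth.gene_labels
    # Genes absent from the inferred assignment were dropped upstream.
    inf_all = inferred.reindex(true_all.index, fill_value=UNASSIGNED).astype(int)

    both = (true_all > 0) & (inf_all > 0)
    ari = (
        float(adjusted_rand_score(true_all[both], inf_all[both]))
        if both.sum() >= 2
        else 0.0
    )

    rows = []
    for m in sorted(set(true_all[true_all > 0])):
        members = true_all.index[true_all == m]
        inf_members = inf_all.loc[members]
        assigned = inf_members[inf_members > 0]
        if len(assigned) == 0:
            rows.append({"module": m, "best_match": UNASSIGNED,
                         "precision": 0.0, "recall": 0.0})
            continue
        best = assigned.value_counts().idxmax()
        overlap = int((assigned == best).sum())
        best_size = int((inf_all == best).sum())
        rows.append(
            {
                "module": m,
                "best_match": int(best),
                "precision": overlap / best_size,
                "recall": overlap / len(members),
            }
        )
    per_module = pd.DataFrame(rows).set_index("module")

    bg = true_all.index[true_all == UNASSIGNED]
    bg_frac = float((inf_all.loc[bg] == UNASSIGNED).mean()) if len(bg) else float("nan")
    return RecoveryReport(
        ari=ari,
        per_module=per_module,
        background_unassigned_fraction=bg_frac,
        n_genes_compared=int(both.sum()),
    )
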
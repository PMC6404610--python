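"""Pipeline orchestration: config, validation, staged artifacts.

A single global seed deterministically derives per-stage seeds (by
hashing the stage name), so any stage can be re-run in isolation and the
end-to-end run is bit-reproducible for a fixed config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from coexnet import io
from coexnet.eigengene import eigengene_table
from coexnet.enrichment import enrich_all
from coexnet.network import CutParameters, build_network_modules
from coexnet.ordination import bray_curtis, nmds, permanova
from coexnet.preprocess import (
    estimate_surrogate_variables,
    filter_low_variance,
    remove_latent_effects,
    size_factors,
    vst,
)
from coexnet.stability import run_stability


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    counts: str = ""
    metadata: str = ""
    gene_sets: list[str] = field(default_factory=list)
    homolog_map: str = ""
    output_dir: str = "results/pipeline"
    drop_fraction: float = 0.40
    vst_dialect: str = "log2"
    n_sv: int | str = "auto"
    beta: float = 5.0
    cut_height: float = 0.905
    deep_split: int = 2
    min_size: int = 30
    n_resamples: int = 100
    kept_per_cell: int = 4
    min_fraction: float = 0.10
    retention_threshold: float = 0.70
    merge_r: float = 0.9
    n_perm: int = 1000
    nmds_k: int = 5
    nmds_restarts: int = 20
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (zlib.crc32(f"{stage}:{self.seed}".encode()) ^ self.seed) % (2**31)


def validate_inputs(counts: pd.DataFrame, metadata: pd.DataFrame) -> list[dict]:
    """Schema checks; returns a list of {level, message} findings."""
    issues: list[dict] = []

    def err(msg):
        issues.append({"level": "error", "message": msg})

    def warn(msg):
        issues.append({"level": "warning", "message": msg})

    only_counts = set(counts.columns) - set(metadata.index)
    only_meta = set(metadata.index) - set(counts.columns)
    for s in sorted(only_counts):
        err(f"sample {s!r} present in counts but missing from metadata")
    for s in sorted(only_meta):
        err(f"sample {s!r} present in metadata but missing from counts")
    if counts.index.has_duplicates:
        err("duplicate gene ids in counts")
    numeric = counts.select_dtypes("number")
    if numeric.shape != counts.shape:
        err("counts contain non-numeric columns")
    else:
        neg = counts.lt(0)
        if neg.any().any():
            gene = neg.any(axis=1).idxmax()
            sample = neg.loc[gene].idxmax()
            err(f"negative count at gene {gene!r}, sample {sample!r}")
        if not (counts.to_numpy() % 1 == 0).all():
            warn("counts contain non-integer values")
    missing_cols = {"population", "temperature"} - set(metadata.columns)
    if missing_cols:
        err(f"metadata is missing columns: {sorted(missing_cols)}")
    elif not only_meta and not only_counts:
        cells = metadata.groupby(["population", "temperature"], observed=True).size()
        if (cells < 2).any():
            warn("some treatment cells have fewer than 2 replicates")
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute preprocess -> ordination -> network -> stability ->
    eigengene -> enrichment, writing each stage's TSV artifacts and a
    manifest; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "artifacts": {}}

    counts = io.read_counts(config.counts)
    metadata = io.read_metadata(config.metadata)
    issues = validate_inputs(counts, metadata)
    errors = [i for i in issues if i["level"] == "error"]
    if errors:
        raise ValueError(
            "input validation failed: " + "; ".join(i["message"] for i in errors)
        )
    metadata = metadata.loc[counts.columns]

    def save(name: str, frame: pd.DataFrame, index_label: str) -> None:
        path = out / name
        frame.rename_axis(index_label).to_csv(path, sep="\t")
        manifest["artifacts"][name] = str(path)

    # --- preprocess
    factors = size_factors(counts)
    expr = vst(counts, factors, dialect=config.vst_dialect, metadata=metadata)
    expr = filter_low_variance(expr, config.drop_fraction)
    sva = estimate_surrogate_variables(
        expr, metadata, n_sv=config.n_sv, seed=config.stage_seed("sva")
    )
    if sva.n_sv:
        expr = remove_latent_effects(expr, sva.sv)
    save("expression_residual.tsv", expr.data, "gene")
    save("surrogate_variables.tsv", sva.sv, "sample_id")

    # --- ordination
    d = bray_curtis(expr)
    ord_res = nmds(
        d, k=config.nmds_k, n_restarts=config.nmds_restarts,
        seed=config.stage_seed("nmds"),
    )
    save("nmds_scores.tsv", ord_res.scores, "sample_id")
    perm = permanova(d, metadata, n_perm=config.n_perm,
                     seed=config.stage_seed("permanova"))
    save("permanova.tsv", perm, "term")
    manifest["nmds_stress"] = ord_res.stress

    # --- network + stability
    cut = CutParameters(
        cut_height=config.cut_height, deep_split=config.deep_split,
        min_cluster_size=config.min_size,
    )
    full_labels = build_network_modules(expr, beta=config.beta, params=cut)
    save("modules_full_network.tsv", full_labels.to_frame(), "gene")
    stab = run_stability(
        expr, full_labels, metadata,
        beta=config.beta, cut_params=cut,
        n_resamples=config.n_resamples, kept_per_cell=config.kept_per_cell,
        min_fraction=config.min_fraction,
        retention_threshold=config.retention_threshold,
        merge_r=config.merge_r, min_size=config.min_size,
        seed=config.stage_seed("stability"),
    )
    save("modules_final.tsv", stab.labels.to_frame(), "gene")
    save("retention.tsv", stab.retention, "gene")
    (out / "resample_plan.json").write_text(
        json.dumps(
            {
                "replicates_kept_per_cell": stab.plan.replicates_kept_per_cell,
                "rng_seed": stab.plan.rng_seed,
                "sample_ids": stab.plan.sample_ids,
            },
            indent=1,
        )
    )
    manifest["artifacts"]["resample_plan.json"] = str(out / "resample_plan.json")

    # --- eigengene statistics
    stats_df, eig_df, letters_df = eigengene_table(
        expr, stab.labels, metadata, alpha=config.alpha
    )
    save("eigengene_stats.tsv", stats_df.set_index("module"), "module")
    save("eigengenes.tsv", eig_df, "module")
    save("tukey_letters.tsv", letters_df.set_index(letters_df.columns[0])
         if len(letters_df) else letters_df, "module")

    # --- enrichment
    if config.gene_sets:
        collections = [io.read_gmt(p) for p in config.gene_sets]
        if config.homolog_map:
            homolog = io.read_homolog_map(config.homolog_map)
            from coexnet.enrichment import expand_homologs

            collections = [
                expand_homologs(c, homolog, expressed_genes=set(stab.labels.index))
                for c in collections
            ]
        table = enrich_all(stab.labels, collections)
        save("enrichment.tsv", table.set_index("collection"), "collection")

    (out / "config_echo.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
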
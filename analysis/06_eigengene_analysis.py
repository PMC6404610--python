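#!/usr/bin/env python
"""Characterize the stable modules: eigengene (PC1) per module with
variance explained, ancestor-environment t-test, population x
temperature ANOVA, Tukey HSD letters, and reaction-norm category."""

import argparse
from pathlib import Path

import pandas as pd

import coexnet as cx
from coexnet import io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--expr", type=Path,
                        default=Path("results/preprocess/expression_residual.tsv"))
    parser.add_argument("--labels", type=Path,
                        default=Path("results/stability/modules_final.tsv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/eigengene"))
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    expr = pd.read_csv(args.expr, sep="\t", index_col=0)
    meta = io.read_metadata(args.data_dir / "metadata.tsv")
    labels = io.read_labels(args.labels)

    stats_df, eig_df, letters_df = cx.eigengene_table(
        expr, labels, meta, alpha=args.alpha
    )

    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stats_df.to_csv(out / "eigengene_stats.tsv", sep="\t", index=False)
    eig_df.rename_axis("module").to_csv(out / "eigengenes.tsv", sep="\t")
    letters_df.to_csv(out / "tukey_letters.tsv", sep="\t", index=False)

    summary = stats_df.drop_duplicates("module")[
        ["module", "n_genes", "pct_var_pc1", "ancestor_t", "ancestor_p",
         "category"]
    ].round(3)
    print("module summary (PC1 variance %, ancestor t-test, category):")
    print(summary.to_string(index=False))
    if len(letters_df):
        print("Tukey compact letters (modules with a population effect):")
        print(letters_df.pivot(index="module", columns="population",
                               values="letters").to_string())


if __name__ == "__main__":
    main()
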
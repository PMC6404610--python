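#!/usr/bin/env python
"""Test the recovered modules for enrichment of the planted gene sets
(one-tailed Fisher exact, BH FDR within the collection).  On synthetic
data the planted GMT plays the role the transcription-factor-target and
hsp collections play on real data; an optional homolog map is expanded
one-to-many before testing."""

import argparse
from pathlib import Path

import coexnet as cx
from coexnet import io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--labels", type=Path,
                        default=Path("results/stability/modules_final.tsv"))
    parser.add_argument("--homolog-map", type=Path, default=None)
    parser.add_argument("--out-dir", type=Path, default=Path("results/enrichment"))
    args = parser.parse_args()

    labels = io.read_labels(args.labels)
    collection = io.read_gmt(args.data_dir / "planted_modules.gmt")
    if args.homolog_map:
        table = io.read_homolog_map(args.homolog_map)
        collection = cx.expand_homologs(collection, table,
                                        expressed_genes=set(labels.index))

    result = cx.enrich_all(labels, [collection])

    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    sig = result[result["q"] < 0.05].sort_values("q")
    print(f"{len(result)} (module, set) tests; {len(sig)} significant at "
          f"FDR < 0.05")
    cols = ["set", "module", "a", "set_size", "module_size", "odds_ratio", "q"]
    print(sig[cols].to_string(index=False))


if __name__ == "__main__":
    main()
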
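#!/usr/bin/env python
"""Screen genes for phenotype-characteristic genotypic patterns.

Stage 1 of the two-stage approach: per gene, greedily accumulate patterns
that are rare (< 10%) in phenotype-negative subjects until they cover a
majority of phenotype-positive subjects; assess by label permutation with
Benjamini-Hochberg control across genes, and emit gene weights for the
neural-net stage.
"""
import argparse
from pathlib import Path

import pandas as pd

from sidefx import io
from sidefx.pipeline import phenotype_labels
from sidefx.screen import ScreenConfig, screen_all


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results"))
    ap.add_argument("--phenotype", default="GSIDE",
                    help="GSIDE, S, SEX, AUTO, NEURO, CARDIO or a cluster name")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--permutations", type=int, default=999)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    vectors = io.read_gene_vectors(args.indir)
    profiles = pd.read_csv(args.indir / "profiles.tsv", sep="\t",
                           index_col="subject_id")
    labels = phenotype_labels(profiles, args.phenotype).reindex(vectors.index)
    keep = labels.notna()
    res = screen_all(vectors.loc[keep], labels[keep].to_numpy(dtype=bool),
                     ScreenConfig(seed=args.seed, n_permutations=args.permutations))
    args.out.mkdir(parents=True, exist_ok=True)
    tab = res.table.copy()
    tab["patterns"] = tab["patterns"].map(lambda p: ",".join(map(str, p)))
    tab.to_csv(args.out / "screen.tsv", sep="\t", index=False)
    res.gene_weights.rename_axis("gene_id").to_csv(
        args.out / "gene_weights.tsv", sep="\t")

    sig = res.table[res.table.significant]
    print(f"phenotype {args.phenotype}: cases {labels[keep].mean():.1%} of {int(keep.sum())}")
    if len(sig):
        print(f"flagged genes at FDR {res.config.fdr_level}: "
              f"{sorted(set(sig.gene_id))}")
    else:
        print("no gene reached significance at the stated FDR "
              "(expected when genotypes carry no phenotype signal)")
    if res.excluded:
        print(f"excluded genes: {res.excluded}")


if __name__ == "__main__":
    main()
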
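#!/usr/bin/env python
"""Diversity and ordination of the two groups.

Alpha diversity per sample (richness, Shannon H', Pielou, Chao1) with
rank-sum group tests, Bray-Curtis PCoA, and PERMANOVA adjusted for the
age and sex covariates (entered before the group term).
"""

import json
import os

import pandas as pd

from viromeprofiler import community_ecology as ce, group_comparison as gcmp

OUT = os.path.join("results", "analysis")
DATA = os.path.join(OUT, "data")


def main() -> None:
    rel = pd.read_csv(os.path.join(OUT, "abundance_relative.tsv"), sep="\t", index_col=0)
    metadata = pd.read_csv(os.path.join(DATA, "metadata.tsv"), sep="\t", index_col=0)
    groups = metadata["group"]

    div = ce.diversity_table(rel)
    div.to_csv(os.path.join(OUT, "diversity.tsv"), sep="\t")
    for metric in ("richness", "shannon_H"):
        x = div.loc[groups == "control", metric].dropna()
        y = div.loc[groups == "case", metric].dropna()
        _, p = gcmp.wilcoxon_rank_sum(x, y)
        print(f"{metric}: control median {x.median():.3g} vs case {y.median():.3g} "
              f"(rank-sum p = {p:.2g})")

    dist = ce.bray_curtis(rel)
    ordination = ce.pcoa(dist)
    pd.DataFrame(
        ordination.coordinates[:, :4],
        index=ordination.sample_ids,
        columns=[f"PCo{i+1}" for i in range(min(4, ordination.coordinates.shape[1]))],
    ).to_csv(os.path.join(OUT, "pcoa_coords.tsv"), sep="\t")
    pct = 100 * ordination.proportion_explained[:2]
    print(f"PCoA axes 1-2 explain {pct[0]:.1f}% + {pct[1]:.1f}% of variance")

    perma = ce.permanova(dist, metadata, "group", covariates=("age", "sex"),
                         n_perm=999, seed=0)
    with open(os.path.join(OUT, "permanova.json"), "w") as fh:
        json.dump(perma, fh, indent=1)
    print(f"PERMANOVA (age+sex adjusted): pseudo-F = {perma['pseudo_F']:.2f}, "
          f"p = {perma['p_value']:.3g}")


if __name__ == "__main__":
    main()
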
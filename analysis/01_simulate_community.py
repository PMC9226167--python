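#!/usr/bin/env python
"""Generate the synthetic two-group gut-virome community used by all
downstream analysis steps.

Emulates the study design at desk scale: two groups of 24 samples (the
size of the VLP sub-cohort), ordinary phage lineages, a nine-marker-gene
phage family with three subfamilies, Crassvirales-like genomes, bacterial
hosts carrying prophages and CRISPR arrays, and a planted control-vs-case
prevalence differential on one lineage plus a global richness differential
favouring controls.  Writes FASTA/TSV/JSON inputs under
results/analysis/data/.
"""

import os
import sys

from viromeprofiler import synthetic_community as sc

OUTDIR = os.path.join("results", "analysis", "data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def build_spec(seed: int) -> sc.CommunitySpec:
    return sc.CommunitySpec(
        seed=seed,
        n_phage_genomes=24,
        n_host_genomes=6,
        n_samples_per_group=24,
        marker_family_spec=sc.MarkerFamilySpec(genomes_per_subfamily=(3, 3, 3)),
        n_crass_genomes=2,
        prophage_fraction=0.15,
        richness_differential=(0.9, 0.7),
        planted_effects={
            "lin_0": sc.PlantedEffect(0.9, 0.1, 1.0),   # control-associated
            "marker_family_beta": sc.PlantedEffect(0.4, 0.8, 1.5),  # case-associated
        },
    )


def main() -> None:
    spec = build_spec(SEED)
    bundle = sc.generate_community(spec)
    alignments = sc.generate_alignments(bundle)
    paths = sc.write_bundle(bundle, OUTDIR)
    sc.write_alignments(alignments, os.path.join(OUTDIR, "alignments.tsv"))
    n_phage = sum(1 for r in bundle.truth["roles"].values() if r == "phage")
    n_host = sum(1 for r in bundle.truth["roles"].values() if r == "bacterial")
    print(f"community: {n_phage} phage + {n_host} bacterial contigs, "
          f"{len(bundle.metadata)} samples, seed {SEED}")
    print(f"planted lineages: {sorted(set(bundle.truth['lineage_of'].values()))}")
    print(f"alignment records: {len(alignments.records)}")
    print(f"wrote {len(paths) + 1} files to {OUTDIR}")


if __name__ == "__main__":
    main()
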
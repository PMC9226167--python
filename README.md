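# viromeprofiler

Profiling human gut viromes from assembled metagenomes: who is there, how
abundant, who do they infect, and how do two participant groups differ.

Bulk (whole-genome shotgun) and VLP (virus-like particle) gut metagenomes
yield contigs of mixed origin. This package implements the computational
chain a virome study runs downstream of assembly and upstream annotation:

- **Triage** — classify contigs phage vs. bacterial from upstream-tool
  evidence (sorter categories 1–6, viral-finder score/p, taxonomic
  annotation), with the *prophage exception* that keeps integrated phages
  in the bacterial set; detect circular short contigs by identical
  terminal ends; deduplicate at ≥ 90% identity.
- **Clustering** — all-vs-all protein search (Smith–Waterman, BLOSUM62,
  bit score = (λ·S − ln K)/ln 2 with λ = 0.267, K = 0.041, threshold 50
  bits) → protein clusters (PCs) → viral clusters (VCs) by shared PC
  content: edge weight −log₁₀(P_hyper(shared ≥ k) · n(n−1)/2), Markov
  clustering at inflation 1.5. VCs are approximately genus-level;
  singletons are one-member VCs.
- **Abundance** — alignment records filtered at ≥ 90% identity, contig
  counts zeroed below 75% horizontal coverage, RPKM =
  count / (len/10³) / (lib/10⁶), summed per VC, closed to relative
  abundance; prevalence bins (individual < 10% of samples,
  core-like > 30%).
- **Ecology** — richness, Shannon H′ (nats), Pielou J = H/ln S, Chao1;
  Bray–Curtis β-diversity with classical-scaling PCoA; PERMANOVA with
  sequential covariate adjustment; Spearman + Benjamini–Hochberg.
- **Host linkage** — three routes merged with provenance: CRISPR
  protospacer matches (≤ 1 substitution, both strands), prophage-contig
  taxonomy propagation, and unanimous host family among co-clustered
  reference phages; multi-phylum host ranges flagged.
- **Marker lineages** — a nine-gene phage family rule (every marker
  ≥ 50 bits on contigs ≥ 30 kb; a relaxed four-structural-gene mode for
  fragmented assemblies), subfamily delineation by average-linkage
  clustering of shared-PC profiles, the two-marker Crassvirales rule
  (terminase + polymerase, ≥ 350-residue alignments, ≥ 70 kb), and
  prophage boundary extraction from multi-sample read-depth profiles.
- **Group statistics** — Fisher exact prevalence tests, Wilcoxon rank-sum
  abundance tests, BH adjustment; a validation seam for externally
  computed bias-corrected compositional (ANCOM-BC style) results.

Because the cohort's sequencing data are under restricted access, the
package ships a **synthetic community generator** (`synthetic_community`)
that emulates the study's data structure with planted ground truth —
phage lineages, a marker-gene family with subfamilies, prophages, CRISPR
arrays, two-group abundance designs — so every stage is testable and the
whole pipeline runs end to end in seconds.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a seeded
synthetic community (two groups × 24 samples, 35 phage + 6 bacterial
contigs) and write tables under `results/analysis/`:

```bash
python analysis/01_simulate_community.py   # seeded inputs
python analysis/02_triage_contigs.py
python analysis/03_cluster_genomes.py
python analysis/04_profile_abundance.py
python analysis/05_community_ecology.py
python analysis/06_link_hosts.py
python analysis/07_marker_lineages.py
python analysis/08_compare_groups.py
```

Selected output (seed 1):

```
572 proteins -> 431 hits >= 50 bits -> 321 PCs
35 contigs -> 16 VCs (2 singletons)
richness: control median 14 vs case 11 (rank-sum p = 2.5e-07)
PERMANOVA (age+sex adjusted): pseudo-F = 2.34, p = 0.003
spacer-route recovery vs planted truth: precision 1.00, recall 1.00
family members (9/9 markers, >=30 kb): 9 of 35 contigs
subfamily sizes: {'alpha': 3, 'beta': 3, 'gamma': 3}
prophage boundary demo: extracted a 68,665 bp genome at [100,000, 168,665)
top-ranked unit by q: VC_4 (q = 5.9e-07, direction 'control') — planted effect recovered
```

The planted richness differential (inclusion 0.9 vs 0.7) surfaces as the
control/case richness gap; the planted control-associated lineage is the
top differentially prevalent VC; the nine marker-family genomes recover
their three planted subfamilies exactly; and the depth-profile extractor
reads the integrated genome length off the coverage trough.

The same stages are scriptable via the thin CLI
(`viromeprofiler synth|triage|cluster|abundance|compare|run`), e.g.

```bash
viromeprofiler run --config config.yaml
```

which executes triage → cluster → abundance → ecology/host/lineage →
compare from a YAML config and writes a manifest of output hashes,
thresholds, and wall-clock per stage.

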
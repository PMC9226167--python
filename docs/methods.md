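# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## Triage

A contig enters the phage set when any of three clauses fires: (i) the
genome-architecture sorter placed it in category 1, 2, 4 or 5; (ii) the
machine-learning viral finder scored it above 0.9 with p < 0.05; (iii) it
is in an ambiguous sorter category (3 or 6), the finder scored it above
0.7 with p < 0.05, *and* its superkingdom annotation is "Viruses" or
"unclassified". Contigs annotated as eukaryotic viruses are then removed.
A contig is bacterial when annotated "Bacteria" — with the prophage
exception: a category 4/5/6 contig that is both phage-positive and
bacterial-annotated stays in *both* sets, because integrated prophages are
the evidence base for one of the host-linkage routes. Absent evidence
fails its clause rather than erroring; real upstream feature tables are
sparse. The rule is a pure function and records an ordered trace of the
clauses that fired.

Circularity is detected only among short contigs (1,500–5,000 bp, the
range not retained by the long-contig rule) as an exact terminal direct
repeat of ≥ 20 bp. The repeat length is configurable; 20 bp is long
enough that chance hits are negligible (4²⁰ ≫ any genome size here) and
short enough to catch assembler overlaps.

Deduplication removes a contig iff it aligns to a strictly longer
retained contig (length ties broken by lexicographically earlier id) at
≥ 90% identity over ≥ 95% of its own length. Containment is computed by
bounded semi-global alignment (edlib HW mode, edit distance capped at
(1 − identity)·length for fast rejection) of the full shorter contig and,
failing that, of its central 95% window; a sampled-k-mer prescreen skips
hopeless pairs. The 95% span is an assumption exposed as `min_span`. The
procedure processes contigs longest-first, which makes it input-order
invariant and idempotent.

## Protein and viral clustering

Homology is scored by local alignment under BLOSUM62 with affine gaps
(BLAST convention gap open 11 / extend 1: a length-g gap costs 11 + g;
in Biopython terms open = −12, extend = −1) and converted to bits with
the ungapped Karlin–Altschul constants λ = 0.267 nats/unit, K = 0.041:
bits = (λ·S − ln K)/ln 2. The 50-bit decision cleanly separates clear
homologs from unrelated proteins; matching BLAST's gapped statistics
exactly (E-values, composition adjustment) is not attempted. The
all-vs-all search uses a shared-4-mer prefilter (≥ 8 common 4-mers);
two unrelated ~300-aa proteins share < 1 common 4-mer in expectation
while homologs at any divergence the 50-bit threshold can still accept
share dozens, so the prefilter does not change the hit set in the regime
that matters (`prefilter_k=None` forces the exhaustive search).

Protein clusters are connected components of the ≥ 50-bit hit graph —
deterministic and adequate because all downstream use is shared-PC
content. Viral clusters use the significance of PC overlap between two
contigs: sim = −log₁₀(P_hyper(shared ≥ k | set sizes, universe) ·
n(n−1)/2), an edge iff sim ≥ 1, refined by Markov clustering (expansion
= matrix square, inflation 1.5, column renormalisation, convergence
ε = 10⁻⁶, ≤ 200 iterations, values < 10⁻⁹ pruned). Self-loops are set to
the maximum edge weight and similarity values are capped at 300 before
MCL (−log₁₀ of an underflowed p-value is infinite). The iteration
schedule is fixed, so clustering is deterministic; contigs with no edge
become singleton VCs; ids are assigned by sorting clusters on their
smallest member.

The shared-PC fraction between two contigs is 100·|A∩B|/|A∪B| over their
PC sets — the quantity subfamily delineation clusters on.

## Abundance

Pipeline order is fixed: identity filter → coverage zeroing → RPKM → VC
aggregation → relative abundance. "Less than" thresholds are strict, so
identity exactly 0.90 and coverage exactly 0.75 are kept. Horizontal
coverage is the union length of alignment intervals over the contig
length (coordinates 0-based half-open throughout; a converter is provided
for 1-based inclusive input). Library size defaults to the per-sample
total of identity-filtered, coverage-zeroed mapped reads; a flag accepts
externally supplied totals (e.g. all QC reads) since both conventions are
defensible. The coverage filter is applied uniformly — richness,
evenness, and every downstream statistic see the same filtered table.

## Ecology

Shannon H′ uses natural log (the convention of the R ecology stack; base
is a flag); Pielou J = H/ln S is undefined for S ≤ 1 and flagged None.
Chao1 = S + F₁²/(2F₂) with the bias-corrected S + F₁(F₁−1)/2 fallback
when no doubletons exist; on non-count data it degrades to S. PCoA is
classical scaling (double-centre −½·J·D²·J, eigh, coordinates
eigvec·√eigval on positive eigenvalues, axes by descending eigenvalue);
negative eigenvalues are dropped with a warning, no Cailliez correction.
PERMANOVA partitions the Gower-centred distance matrix sequentially
(Type I): covariates (numeric passthrough, categoricals one-hot) enter
before the group term; pseudo-F = (SS_group/df_group)/(SS_res/df_res);
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) by permutation of raw group
labels only, covariates staying attached to samples. scikit-bio's
covariate-free PERMANOVA serves as a cross-check in the tests, not as
the implementation (it has no sequential covariate support).

## Host linkage

Simplified CRISPR array detection seeds on exact 20-mers recurring at
gaps of 41–105 bp (repeat 23–55 + spacer 18–50), chains ≥ 3 occurrences,
extends repeat boundaries by strict consensus (every copy identical), and
reports the spacers between consecutive repeat copies, requiring them
pairwise distinct. The reported repeat is the maximal exactly conserved
core; copies differing outside that core are tolerated at the seeding
stage but their deviant columns are left to the spacers. Array quality
scoring of the full published detectors is out of scope — downstream
computation consumes spacers only.

Protospacer matching is Hamming (no indels, matching short-protospacer
practice) on both strands with ≤ 1 substitution by default; "fewer than
2 mismatches" is read literally as ≤ 1, with the flag allowing ≤ 2 for
sensitivity analyses. Spacers shorter than 18 nt are searched with a
warning. The prophage route propagates a prophage-contig's taxon to every
VC containing it; the reference route emits a family-level link only on
unanimous host family among co-clustered reference phages (unanimity
below family rank is not required — family only). Merged predictions are
deduplicated by (VC, taxon, rank) with routes pooled; a VC whose
predictions span > 1 phylum is flagged multi-phylum.

## Marker lineages

Family membership: contig length ≥ 30,000 bp and a ≥ 50-bit hit for
every one of the nine markers (four structural: terminase large subunit,
portal, Clp protease, major capsid; three replication/transcription:
DNA polymerase I, SNF2-like helicase, VRR-NUC nuclease; two of unknown
function). Relaxed mode — built for fragmented external assemblies —
requires only the four structural markers and waives the length rule.
Membership is monotone in the protein set. The shipped marker proteins
are synthetic stand-ins (random sequences, 210–550 aa): the procedure
depends only on homology structure, and the marker set is configurable so
real gene sequences can be dropped in.

Subfamilies: the pairwise shared-PC-percentage matrix is treated as a
per-genome profile; Euclidean distances between profiles, average-linkage
hierarchical clustering, dendrogram cut at k (a required user parameter —
no automatic selection); labels assigned by cluster size descending, ties
by smallest member, making the labelling order-invariant. The 10%/20%/40%
gene-sharing context thresholds for family/subfamily/genus are reported
as diagnostics, not gates; the operative gate is the marker rule.

Crassvirales: both the terminase and polymerase queries must hit ≥ 50
bits with alignment length ≥ 350 and the contig must be ≥ 70 kb. The 350
threshold is conventionally quoted in bp although the search is
protein-space; the unit flag (default residues, `nt` divides by 3) makes
the interpretation explicit.

Prophage boundaries: informative samples have mean flank depth ≥ 5× and
mean candidate-region depth ≤ 0.1× the flank mean (both flags); their
depth vectors are averaged, median-smoothed over 21 bp, and the interval
is delimited by the outermost positions below half the flank mean. The
window and half-height crossing are package choices; on noise-free step
profiles the boundaries are exact (the 21-bp median shifts a clean step
by zero positions), and under Poisson depth noise they stay within tens
of bp of the true attachment sites.

## Group statistics

Fisher exact tests are two-sided by the probability-mass method (sum of
hypergeometric probabilities ≤ the observed table's, with float slack) —
scipy's implementation, cross-checked in the tests against explicit
enumeration over all admissible tables. Sidedness is a flag since the
convention is not universal. Wilcoxon rank-sum uses exact enumeration for
min(n, m) ≤ 25 without ties — the boundary chosen so 24-per-group designs
take the exact path — and the tie/continuity-corrected normal
approximation otherwise. BH adjustment is the standard step-up
q_(i) = min_{j≥i} min(1, p_(j)·m/j), identical to statsmodels' `fdr_bh`;
it is monotone in p-rank and dominates p, but is *not* idempotent (no
step-up q-value transform is), so only those two properties are asserted.
The ANCOM-BC seam validates and ingests externally computed result tables
(unit, lfc, se, q) — the bias-corrected estimator is a published external
method and is not recomputed.

## The synthetic community generator

The generator emulates, at desk scale, the data structure the analysis
consumes: two groups labelled control/case (default 24 samples each, the
VLP sub-cohort size); ordinary phage lineages sharing ~80% of a 12–17
protein core repertoire at 2% divergence (the planted VCs); a marker
family whose subfamilies descend from per-subfamily ancestors (0.35
substitutions/site from the family seeds) with members at 0.05 within,
plus subfamily-private accessory repertoires that create the shared-PC
structure the subfamily cut recovers; ≥ 70 kb genomes carrying the two
Crassvirales queries; bacterial hosts with planted prophages (15% of
phages by default) and CRISPR arrays whose spacers are phage substrings
with 0–3 planned interior substitutions; and a log-normal (μ = 2, σ = 1)
lineage abundance model with per-lineage prevalence effects and a
per-group VC inclusion probability (default 0.9 vs 0.7) as the richness
differential.

Reads are never simulated: alignment records are generated directly
(tiles of 300 bp at stride 250, Poisson read counts proportional to
planted abundance at 2 reads/abundance-unit per tile), because every
in-scope computation consumes alignments. A configurable fraction of
records carries identity < 0.90 to exercise the identity filter, and
sparse low-coverage records on absent contigs exercise the 75% zeroing.
Protein divergence is i.i.d. substitution with a uniform replacement
alphabet and no indels, keeping score expectations tractable. CRISPR
boundary columns are redrawn so no column flanking a repeat is constant
across copies, which makes strict-consensus array detection exactly
recoverable — a deliberate idealisation.

What the generator does **not** emulate — sequencing error profiles,
assembly fragmentation and chimerism, strain-level micro-diversity,
compositional coupling between phage and host abundances, indel
evolution, real CRISPR repeat families — bounds what passing tests show:
they demonstrate the *procedures* are correct against planted truth under
the stated statistical structure, not that the upstream tools' outputs on
real data have these properties.

Determinism: one integer seed; every draw flows through a named substream
(CRC32-keyed `SeedSequence`), so identical specs give byte-identical
bundles and adding a draw to one component never perturbs another.

## Pipeline

Stages run in fixed order (triage → cluster → abundance → ecology / host
/ lineage → compare) from a validated YAML/JSON config (unknown keys are
errors naming the key; disabled dependencies are errors). The clustered
phage set is the pure-phage calls: dual-status prophage contigs stay
bacterial so they cannot absorb their own integrated free phages at
dedup, and they contribute through the prophage linkage route. Every run
writes a manifest with the config snapshot, per-stage output SHA-256
hashes, thresholds, and wall-clock. Stages are deterministic and
re-executed on re-run (state is in memory); the manifest marks a stage
`cached` when its outputs were already byte-identical, which doubles as
the reproducibility check. All outputs are TSV/JSON.

## Problem sizes

The demo and test configurations use 8–35 phage genomes, 3–6 hosts, 6–24
samples per group, 3×3 marker families, and 100–200 seed replicates for
calibration checks; the full suite runs in under a minute and the demo
pipeline in ~15 s on one CPU. These sizes were chosen so planted effects
are recoverable with comfortable statistical margins while keeping the
artifact seconds-fast.

## Known limitations

- Bit scores are not BLAST-comparable beyond the ≥ 50-bit decision.
- Array detection reports the maximal exactly conserved repeat core;
  heavily degenerate repeats (> 1 mismatch between copies near the
  boundaries) shift spacer boundaries.
- PERMANOVA permutes raw labels (not residuals); with strong covariate
  effects the permutation distribution is approximate.
- Chao1 on RPKM (non-count) data degrades to observed richness.
- The ANCOM-BC estimator itself is external; only its result tables are
  validated and ingested.
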
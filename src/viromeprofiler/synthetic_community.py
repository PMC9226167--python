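"""Deterministic synthetic gut-virome communities with planted ground truth.

The generator emulates the data structure a bulk/VLP virome study works
with after assembly and upstream annotation: phage and bacterial contigs,
per-contig ORF protein sets, upstream-tool triage features, CRISPR arrays,
prophages inserted into host contigs, a marker-gene phage family with
subfamily structure, and a two-group (control vs. case) abundance design
with planted prevalence/abundance effects.  Reads are never simulated:
alignment records and depth vectors are generated directly, because all
downstream computation consumes alignments, not reads.

Every stochastic draw flows from one integer seed through named substreams
(:mod:`viromeprofiler._rng`), so identical specs yield byte-identical
bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._rng import substream

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "MarkerFamilySpec",
    "CrisprPlan",
    "PlantedEffect",
    "CommunitySpec",
    "CommunityBundle",
    "AlignmentSet",
    "load_family_markers",
    "load_crass_markers",
    "diverge_protein",
    "generate_marker_family",
    "generate_community",
    "generate_alignments",
    "realize_presence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# The four structural genes of the nine-gene family core; the relaxed
# classification mode (for incomplete assemblies) requires only these.
STRUCTURAL_MARKERS = (
    "terminase_large_subunit",
    "portal_protein",
    "clp_protease",
    "major_capsid_protein",
)

SUBFAMILY_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


def load_family_markers() -> Dict[str, str]:
    """The nine synthetic seed marker proteins shipped with the package."""
    return _load_fixture("synthetic_family_markers.faa")


def load_crass_markers() -> Dict[str, str]:
    """Synthetic terminase/polymerase queries for the Crassvirales rule."""
    return _load_fixture("synthetic_crass_markers.faa")


def _load_fixture(name: str) -> Dict[str, str]:
    ref = resources.files("viromeprofiler.data").joinpath(name)
    with ref.open() as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# Spec types


@dataclass(frozen=True)
class MarkerFamilySpec:
    """Design of the planted marker-gene phage family.

    Each subfamily descends from its own ancestor (derived from the family
    seed markers at ``between_divergence`` substitutions/site); members
    diverge from that ancestor at ``within_divergence``.  Subfamilies also
    carry private accessory-protein repertoires, which is what separates
    them in shared-protein-cluster space (the marker genes themselves stay
    mutually homologous across the family).
    """

    genomes_per_subfamily: Tuple[int, ...] = (3, 3, 3)
    within_divergence: float = 0.05
    between_divergence: float = 0.35
    n_accessory: int = 12
    length_range: Tuple[int, int] = (31_000, 60_000)

    def validate(self) -> None:
        if not self.genomes_per_subfamily or any(
            n < 1 for n in self.genomes_per_subfamily
        ):
            raise ValueError("marker_family_spec.genomes_per_subfamily: counts must be >= 1")
        for name in ("within_divergence", "between_divergence"):
            val = getattr(self, name)
            if not 0.0 <= val <= 0.5:
                raise ValueError(f"marker_family_spec.{name}: must be in [0, 0.5]")


@dataclass(frozen=True)
class CrisprPlan:
    """One planted CRISPR array: spacers in ``host`` targeting ``phage``."""

    host_index: int
    phage_index: int
    n_spacers: int = 3
    mismatches: Tuple[int, ...] = (0, 0, 0)

    def validate(self, n_hosts: int, n_phages: int) -> None:
        if not 0 <= self.host_index < n_hosts:
            raise ValueError("crispr_spacer_plan.host_index: out of range")
        if not 0 <= self.phage_index < n_phages:
            raise ValueError("crispr_spacer_plan.phage_index: out of range")
        if self.n_spacers < 2:
            raise ValueError("crispr_spacer_plan.n_spacers: must be >= 2 (>=3 repeat copies)")
        if len(self.mismatches) != self.n_spacers:
            raise ValueError("crispr_spacer_plan.mismatches: one entry per spacer")
        if any(m not in (0, 1, 2, 3) for m in self.mismatches):
            raise ValueError("crispr_spacer_plan.mismatches: entries must be in {0,1,2,3}")


@dataclass(frozen=True)
class PlantedEffect:
    """Group differential for one phage lineage (prevalence and abundance)."""

    prevalence_control: float = 0.9
    prevalence_case: float = 0.9
    abundance_multiplier_case: float = 1.0

    def validate(self, label: str) -> None:
        for name in ("prevalence_control", "prevalence_case"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"planted_effects[{label}].{name}: must be in [0, 1]")
        if self.abundance_multiplier_case <= 0:
            raise ValueError(
                f"planted_effects[{label}].abundance_multiplier_case: must be > 0"
            )


@dataclass(frozen=True)
class CommunitySpec:
    """Full design of a synthetic two-group community.

    Defaults emulate the study structure at desk scale: two groups of 24
    samples (the size of the cohort's VLP sub-cohort), ordinary phage
    lineages of 2-3 members, a 3x3 marker family (divergence 0.05 within /
    0.35 between subfamilies), a 15% prophage fraction, log-normal lineage
    abundances, and a planted richness differential favouring controls.
    """

    n_phage_genomes: int = 24
    n_host_genomes: int = 6
    n_samples_per_group: int = 24
    phage_length_range: Tuple[int, int] = (15_000, 50_000)
    phages_per_lineage: int = 2
    marker_family_spec: MarkerFamilySpec = field(default_factory=MarkerFamilySpec)
    n_crass_genomes: int = 2
    prophage_fraction: float = 0.15
    crispr_spacer_plan: Tuple[CrisprPlan, ...] = (
        CrisprPlan(0, 0, 3, (0, 0, 0)),
        CrisprPlan(1, 2, 3, (0, 1, 0)),
        CrisprPlan(2, 4, 2, (1, 0)),
    )
    abundance_mu: Tuple[float, float] = (2.0, 2.0)  # log-normal mean (control, case)
    abundance_sigma: Tuple[float, float] = (1.0, 1.0)
    planted_effects: Mapping[str, PlantedEffect] = field(default_factory=dict)
    richness_differential: Tuple[float, float] = (0.9, 0.7)  # inclusion prob per group
    host_length_range: Tuple[int, int] = (30_000, 60_000)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_phage_genomes", "n_host_genomes", "n_samples_per_group",
                     "phages_per_lineage"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: must be >= 1")
        for name in ("phage_length_range", "host_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name}: invalid interval")
        if not 0.0 <= self.prophage_fraction <= 1.0:
            raise ValueError("prophage_fraction: must be in [0, 1]")
        for p in self.richness_differential:
            if not 0.0 < p <= 1.0:
                raise ValueError("richness_differential: probabilities must be in (0, 1]")
        self.marker_family_spec.validate()
        for plan in self.crispr_spacer_plan:
            plan.validate(self.n_host_genomes, self.n_phage_genomes)
        for label, eff in self.planted_effects.items():
            eff.validate(label)


# ---------------------------------------------------------------------------
# Bundle types


@dataclass
class ContigRecord:
    """A nucleotide contig with provenance and optional prophage interval."""

    id: str
    sequence: str
    sample_id: str
    circular: bool = False
    prophage_interval: Optional[Tuple[int, int]] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TriageFeatures:
    """Per-contig evidence from upstream tools, consumed by the triage rule."""

    contig_id: str
    sorter_category: Optional[int] = None
    finder_score: Optional[float] = None
    finder_p: Optional[float] = None
    annotation_superkingdom: Optional[str] = None
    annotation_is_eukaryotic_virus: bool = False

    @property
    def is_prophage_category(self) -> bool:
        return self.sorter_category in (4, 5, 6)


@dataclass
class CrisprArrayTruth:
    host_contig: str
    target_phage: str
    repeat: str
    spacers: List[str]
    planned_mismatches: List[int]
    start: int  # position of the first repeat copy in the host contig
    end: int


@dataclass
class CommunityBundle:
    """Generated contigs, proteins, upstream features, and planted truth."""

    spec: CommunitySpec
    contigs: List[ContigRecord]
    proteins: Dict[str, Dict[str, str]]  # contig id -> {protein id -> sequence}
    triage_features: List[TriageFeatures]
    crispr_arrays: List[CrisprArrayTruth]
    truth: Dict[str, object]
    metadata: pd.DataFrame  # sample, group, covariates
    planted_abundance: pd.DataFrame  # samples x phage contigs

    def contig(self, contig_id: str) -> ContigRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass
class AlignmentSet:
    """PAF-like alignment records plus on-demand per-base depth vectors."""

    records: pd.DataFrame  # contig_id, start, end, n_reads, identity, sample_id
    contig_lengths: Dict[str, int]

    def depth(self, contig_id: str, sample_id: str) -> np.ndarray:
        length = self.contig_lengths[contig_id]
        sub = self.records[
            (self.records.contig_id == contig_id)
            & (self.records.sample_id == sample_id)
        ]
        vec = np.zeros(length)
        for start, end, n_reads in zip(sub.start, sub.end, sub.n_reads):
            vec[start:end] += n_reads
        return vec


# ---------------------------------------------------------------------------
# Sequence helpers


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


def diverge_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at ``rate`` per site (no indels).

    Substituted positions receive one of the 19 other residues uniformly,
    keeping bit-score expectations analytically tractable.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError(f"divergence rate must be in [0, 0.5], got {rate}")
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        alphabet = np.array(list(AMINO_ACIDS))
        for i in np.nonzero(hit)[0]:
            choices = alphabet[alphabet != arr[i]]
            arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def _substitute_dna(
    seq: str,
    n_subs: int,
    rng: np.random.Generator,
    interior_only: bool = False,
) -> str:
    arr = list(seq)
    if n_subs == 0:
        return seq
    lo, hi = (1, len(arr) - 1) if interior_only else (0, len(arr))
    positions = rng.choice(np.arange(lo, hi), size=n_subs, replace=False)
    for pos in positions:
        options = [b for b in NUCLEOTIDES if b != arr[pos]]
        arr[pos] = options[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Marker family generation


def generate_marker_family(
    n_per_subfamily: Sequence[int],
    divergence: float,
    seed: int,
    between_divergence: float = 0.35,
    n_accessory: int = 12,
    length_range: Tuple[int, int] = (31_000, 60_000),
    id_prefix: str = "markerphage",
) -> Tuple[List[ContigRecord], Dict[str, Dict[str, str]], Dict[str, str]]:
    """Generate marker-family genomes carrying the nine-gene core.

    Returns ``(contigs, proteins, subfamily_labels)``.  Every genome carries
    one diverged homolog of each of the nine seed markers, exceeds 30 kb,
    and additionally carries subfamily-private accessory proteins that give
    the subfamilies their shared-PC structure.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError(f"divergence must be in [0, 0.5], got {divergence}")
    seeds = load_family_markers()
    rng = substream(seed, "marker_family")
    contigs: List[ContigRecord] = []
    proteins: Dict[str, Dict[str, str]] = {}
    labels: Dict[str, str] = {}
    for sub_idx, n_genomes in enumerate(n_per_subfamily):
        sub_name = SUBFAMILY_NAMES[sub_idx % len(SUBFAMILY_NAMES)]
        ancestors = {
            name: diverge_protein(seq, between_divergence, rng)
            for name, seq in seeds.items()
        }
        accessory = {
            f"acc_{sub_name}_{k}": _random_protein(rng, int(rng.integers(150, 400)))
            for k in range(n_accessory)
        }
        for g in range(n_genomes):
            cid = f"{id_prefix}_{sub_name}_{g}"
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            contigs.append(
                ContigRecord(id=cid, sequence=_random_dna(rng, length), sample_id="synthetic")
            )
            prots: Dict[str, str] = {}
            orf = 0
            for name, anc in ancestors.items():
                prots[f"{cid}_{orf}"] = diverge_protein(anc, divergence, rng)
                orf += 1
            keep = rng.random(len(accessory)) < 0.85
            for (acc_name, acc_seq), kept in zip(accessory.items(), keep):
                if kept:
                    prots[f"{cid}_{orf}"] = diverge_protein(acc_seq, divergence, rng)
                    orf += 1
            for _ in range(2):  # private proteins
                prots[f"{cid}_{orf}"] = _random_protein(rng, int(rng.integers(150, 300)))
                orf += 1
            proteins[cid] = prots
            labels[cid] = sub_name
    return contigs, proteins, labels


# ---------------------------------------------------------------------------
# Community generation


def _marker_order(cid: str, proteins: Mapping[str, str]) -> List[str]:
    return sorted(proteins, key=lambda p: int(p.rsplit("_", 1)[1]))


_HOST_TAXA = [
    ("Firmicutes", "Clostridiales", "Lachnospiraceae", "Blautia", "Blautia obeum"),
    ("Firmicutes", "Clostridiales", "Lachnospiraceae", "Roseburia", "Roseburia intestinalis"),
    ("Bacteroidetes", "Bacteroidales", "Bacteroidaceae", "Bacteroides", "Bacteroides fragilis"),
    ("Firmicutes", "Lactobacillales", "Streptococcaceae", "Streptococcus", "Streptococcus thermophilus"),
    ("Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium longum"),
    ("Proteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", "Escherichia coli"),
]


def _host_taxonomy(i: int) -> Dict[str, str]:
    phylum, order, fam, genus, species = _HOST_TAXA[i % len(_HOST_TAXA)]
    return {
        "phylum": phylum,
        "order": order,
        "family": fam,
        "genus": genus,
        "species": species,
    }


def _plant_crispr_array(
    host_seq: str,
    phage_seq: str,
    plan: CrisprPlan,
    rng: np.random.Generator,
    insert_at: int,
) -> Tuple[str, CrisprArrayTruth, List[str]]:
    """Insert one CRISPR array into ``host_seq`` at ``insert_at``.

    Repeat copies are exact; spacers are phage substrings carrying the
    planned number of substitutions.  Boundary columns are resampled so no
    column immediately flanking a repeat is constant across copies - this
    keeps simplified array detection exactly recoverable.
    """
    repeat_len = int(rng.integers(28, 36))
    repeat = _random_dna(rng, repeat_len)
    spacer_len = 32
    max_start = len(phage_seq) - spacer_len
    # Redraw protospacer positions until the columns flanking the repeat
    # copies are not constant across copies (including the host bases at the
    # insertion point); planned mismatches go to interior positions only, so
    # boundary columns always equal the protospacer's.  This keeps strict
    # consensus-extension array detection exactly recoverable.
    for _ in range(100):
        spacers: List[str] = []
        protospacers: List[str] = []
        for k in range(plan.n_spacers):
            start = int(rng.integers(0, max_start))
            proto = phage_seq[start : start + spacer_len]
            protospacers.append(proto)
            spacers.append(
                _substitute_dna(proto, plan.mismatches[k], rng, interior_only=True)
            )
        firsts = [s[0] for s in spacers] + [host_seq[insert_at]]
        lasts = [s[-1] for s in spacers] + [host_seq[insert_at - 1]]
        if len(set(firsts)) > 1 and len(set(lasts)) > 1 and len(set(spacers)) == len(spacers):
            break
    array = repeat + "".join(s + repeat for s in spacers)
    new_seq = host_seq[:insert_at] + array + host_seq[insert_at:]
    truth = CrisprArrayTruth(
        host_contig="",  # filled by caller
        target_phage="",
        repeat=repeat,
        spacers=spacers,
        planned_mismatches=list(plan.mismatches),
        start=insert_at,
        end=insert_at + len(array),
    )
    return new_seq, truth, protospacers


def generate_community(spec: CommunitySpec) -> CommunityBundle:
    """Generate a full synthetic community with planted ground truth.

    The truth dict records, for every generated contig, its role and
    lineage, the planted VC partition, marker-family labels, host links,
    prophage intervals, and the per-lineage group effects, so downstream
    recovery tests never need to recompute what was planted.
    """
    spec.validate()
    seed = spec.seed

    # --- phage genomes, grouped into lineages (planted VCs)
    rng_ph = substream(seed, "phage_seq")
    rng_prot = substream(seed, "phage_proteins")
    n_ordinary = spec.n_phage_genomes
    lineage_of: Dict[str, str] = {}
    contigs: List[ContigRecord] = []
    proteins: Dict[str, Dict[str, str]] = {}

    n_lineages = max(1, n_ordinary // spec.phages_per_lineage)
    lineage_cores = {}
    for li in range(n_lineages):
        n_core = int(rng_prot.integers(12, 18))
        lineage_cores[f"lin_{li}"] = {
            f"core_{li}_{k}": _random_protein(rng_prot, int(rng_prot.integers(150, 400)))
            for k in range(n_core)
        }
    for i in range(n_ordinary):
        lin = f"lin_{i % n_lineages}"
        cid = f"phage_{i:03d}"
        length = int(rng_ph.integers(*spec.phage_length_range))
        contigs.append(ContigRecord(cid, _random_dna(rng_ph, length), "synthetic"))
        lineage_of[cid] = lin
        core = lineage_cores[lin]
        prots: Dict[str, str] = {}
        orf = 0
        keep = rng_prot.random(len(core)) < 0.8
        for (name, seq), kept in zip(core.items(), keep):
            if kept:
                prots[f"{cid}_{orf}"] = diverge_protein(seq, 0.02, rng_prot)
                orf += 1
        for _ in range(3):
            prots[f"{cid}_{orf}"] = _random_protein(rng_prot, int(rng_prot.integers(120, 300)))
            orf += 1
        proteins[cid] = prots

    # --- marker family genomes
    fam = spec.marker_family_spec
    fam_contigs, fam_proteins, fam_labels = generate_marker_family(
        fam.genomes_per_subfamily,
        fam.within_divergence,
        seed,
        between_divergence=fam.between_divergence,
        n_accessory=fam.n_accessory,
        length_range=fam.length_range,
    )
    contigs.extend(fam_contigs)
    proteins.update(fam_proteins)
    for cid, sub in fam_labels.items():
        lineage_of[cid] = f"marker_family_{sub}"

    # --- Crassvirales-like genomes
    rng_crass = substream(seed, "crass")
    crass_markers = load_crass_markers()
    crass_ids: List[str] = []
    for i in range(spec.n_crass_genomes):
        cid = f"crassphage_{i}"
        length = int(rng_crass.integers(75_000, 95_000))
        contigs.append(ContigRecord(cid, _random_dna(rng_crass, length), "synthetic"))
        prots = {
            f"{cid}_0": diverge_protein(crass_markers["crass_terminase"], 0.1, rng_crass),
            f"{cid}_1": diverge_protein(crass_markers["crass_polymerase"], 0.1, rng_crass),
        }
        for k in range(2, 8):
            prots[f"{cid}_{k}"] = _random_protein(rng_crass, int(rng_crass.integers(150, 350)))
        proteins[cid] = prots
        lineage_of[cid] = "crassvirales"
        crass_ids.append(cid)

    phage_ids = [c.id for c in contigs]

    # --- host genomes with planted prophages and CRISPR arrays
    rng_host = substream(seed, "host_seq")
    rng_crispr = substream(seed, "crispr")
    n_prophages = int(round(spec.prophage_fraction * len(phage_ids)))
    prophage_phages = sorted(
        rng_host.choice(phage_ids, size=min(n_prophages, len(phage_ids)), replace=False)
    )
    host_contigs: List[ContigRecord] = []
    host_taxa: Dict[str, Dict[str, str]] = {}
    crispr_truth: List[CrisprArrayTruth] = []
    protospacer_truth: List[Dict[str, object]] = []
    prophage_host_of: Dict[str, str] = {}
    plans_by_host: Dict[int, List[CrisprPlan]] = {}
    for plan in spec.crispr_spacer_plan:
        plans_by_host.setdefault(plan.host_index, []).append(plan)
    for h in range(spec.n_host_genomes):
        hid = f"host_{h:03d}"
        length = int(rng_host.integers(*spec.host_length_range))
        seq = _random_dna(rng_host, length)
        # CRISPR arrays go into the first third; prophage after them.
        arrays_end = 0
        for plan in plans_by_host.get(h, []):
            target = phage_ids[plan.phage_index]
            target_seq = next(c.sequence for c in contigs if c.id == target)
            insert_at = int(rng_crispr.integers(arrays_end + 100, arrays_end + len(seq) // 6))
            seq, truth, protos = _plant_crispr_array(seq, target_seq, plan, rng_crispr, insert_at)
            truth.host_contig = hid
            truth.target_phage = target
            crispr_truth.append(truth)
            arrays_end = truth.end
            for spacer, proto, mm in zip(truth.spacers, protos, truth.planned_mismatches):
                protospacer_truth.append(
                    {
                        "host_contig": hid,
                        "target_phage": target,
                        "spacer": spacer,
                        "planned_mismatches": mm,
                    }
                )
        prophage_interval = None
        if h < len(prophage_phages):
            pid = prophage_phages[h]
            pseq = next(c.sequence for c in contigs if c.id == pid)
            pos = int(rng_host.integers(max(arrays_end + 200, len(seq) // 3), len(seq) - 100))
            seq = seq[:pos] + pseq + seq[pos:]
            prophage_interval = (pos, pos + len(pseq))
            prophage_host_of[pid] = hid
        host_contigs.append(
            ContigRecord(hid, seq, "synthetic", prophage_interval=prophage_interval)
        )
        host_taxa[hid] = _host_taxonomy(h)
    contigs.extend(host_contigs)

    # --- triage features consistent with truth
    rng_triage = substream(seed, "triage")
    features: List[TriageFeatures] = []
    for c in contigs:
        if c.id.startswith("host"):
            category = None
            if c.prophage_interval is not None:
                category = int(rng_triage.choice([4, 5]))
            features.append(
                TriageFeatures(
                    contig_id=c.id,
                    sorter_category=category,
                    annotation_superkingdom="Bacteria",
                )
            )
        else:
            style = rng_triage.random()
            if style < 0.6:
                features.append(
                    TriageFeatures(c.id, sorter_category=int(rng_triage.choice([1, 2])))
                )
            elif style < 0.85:
                features.append(
                    TriageFeatures(
                        c.id,
                        finder_score=float(rng_triage.uniform(0.91, 0.999)),
                        finder_p=float(rng_triage.uniform(1e-5, 0.04)),
                    )
                )
            else:
                features.append(
                    TriageFeatures(
                        c.id,
                        sorter_category=int(rng_triage.choice([3, 6])),
                        finder_score=float(rng_triage.uniform(0.71, 0.89)),
                        finder_p=float(rng_triage.uniform(1e-5, 0.04)),
                        annotation_superkingdom="Viruses",
                    )
                )

    # --- sample metadata
    rng_meta = substream(seed, "metadata")
    samples = []
    for g, group in enumerate(("control", "case")):
        for i in range(spec.n_samples_per_group):
            samples.append(
                {
                    "sample": f"S{g}{i:03d}",
                    "group": group,
                    "age": int(rng_meta.integers(25, 70)),
                    "sex": str(rng_meta.choice(["F", "M"])),
                }
            )
    metadata = pd.DataFrame(samples).set_index("sample")

    # --- planted per-sample abundance for phage contigs
    rng_ab = substream(seed, "abundance")
    lineages = sorted(set(lineage_of.values()))
    incl = dict(zip(("control", "case"), spec.richness_differential))
    mu = dict(zip(("control", "case"), spec.abundance_mu))
    sigma = dict(zip(("control", "case"), spec.abundance_sigma))
    abundance = pd.DataFrame(0.0, index=metadata.index, columns=sorted(phage_ids))
    for lin in lineages:
        members = sorted(c for c, l in lineage_of.items() if l == lin)
        effect = spec.planted_effects.get(lin, PlantedEffect(1.0, 1.0, 1.0))
        for sample, row in metadata.iterrows():
            group = row["group"]
            prev = (
                effect.prevalence_control if group == "control" else effect.prevalence_case
            )
            if rng_ab.random() >= prev * incl[group]:
                continue
            base = float(rng_ab.lognormal(mu[group], sigma[group]))
            if group == "case":
                base *= effect.abundance_multiplier_case
            weights = rng_ab.dirichlet(np.ones(len(members)) * 5.0)
            for m, w in zip(members, weights):
                abundance.loc[sample, m] = base * w

    truth: Dict[str, object] = {
        "roles": {
            c.id: ("bacterial" if c.id.startswith("host") else "phage") for c in contigs
        },
        "lineage_of": lineage_of,
        "vc_partition": {
            lin: sorted(c for c, l in lineage_of.items() if l == lin) for lin in lineages
        },
        "marker_family_members": sorted(fam_labels),
        "subfamily_labels": fam_labels,
        "crassvirales_members": crass_ids,
        "prophage_intervals": {
            c.id: list(c.prophage_interval)
            for c in host_contigs
            if c.prophage_interval is not None
        },
        "prophage_host_of": prophage_host_of,
        "host_taxa": host_taxa,
        "protospacers": protospacer_truth,
        "planted_effects": {k: asdict(v) for k, v in spec.planted_effects.items()},
        "richness_differential": list(spec.richness_differential),
    }

    return CommunityBundle(
        spec=spec,
        contigs=contigs,
        proteins=proteins,
        triage_features=features,
        crispr_arrays=crispr_truth,
        truth=truth,
        metadata=metadata,
        planted_abundance=abundance,
    )


def realize_presence(bundle: CommunityBundle) -> pd.DataFrame:
    """Planted presence/absence of each lineage per sample (samples x lineages)."""
    lineage_of = bundle.truth["lineage_of"]
    lineages = sorted(set(lineage_of.values()))
    out = pd.DataFrame(False, index=bundle.planted_abundance.index, columns=lineages)
    for contig, lin in lineage_of.items():
        out[lin] |= bundle.planted_abundance[contig] > 0
    return out


# ---------------------------------------------------------------------------
# Alignment generation


def generate_alignments(
    bundle: CommunityBundle,
    reads_per_unit: float = 2.0,
    record_span: int = 300,
    record_stride: int = 250,
    contaminant_fraction: float = 0.05,
    noise_record_rate: float = 0.1,
    seed: Optional[int] = None,
) -> AlignmentSet:
    """Generate PAF-like alignment records consistent with planted abundance.

    Present contig x sample pairs are tiled with overlapping records
    (stride < span, so horizontal coverage is ~100%), each carrying a
    Poisson read count proportional to the planted abundance - summed reads
    per contig are therefore proportional to planted abundance up to
    Poisson noise.  A ``contaminant_fraction`` of records receives identity
    below 0.90 (drawn extra, at random positions) to exercise the identity
    filter, and a small rate of sparse low-coverage records is added to
    absent pairs to exercise the 75% horizontal-coverage zeroing.
    """
    if seed is None:
        seed = bundle.spec.seed
    rng = substream(seed, "alignments")
    lengths = {c.id: c.length for c in bundle.contigs}
    phage_cols = list(bundle.planted_abundance.columns)
    unknown = [c for c in phage_cols if c not in lengths]
    if unknown:
        raise KeyError(f"unknown contig ids in abundance profile: {unknown}")
    rows: List[Tuple[str, int, int, int, float, str]] = []
    contam_ratio = (
        contaminant_fraction / (1.0 - contaminant_fraction)
        if contaminant_fraction < 1.0
        else 1.0
    )
    for sample in bundle.planted_abundance.index:
        for cid in phage_cols:
            a = bundle.planted_abundance.loc[sample, cid]
            L = lengths[cid]
            if a > 0:
                lam = max(a * reads_per_unit, 0.2)
                starts = np.arange(0, max(L - record_span, 1), record_stride)
                counts = rng.poisson(lam, size=len(starts))
                for s, nr in zip(starts, counts):
                    if nr == 0:
                        continue
                    e = min(s + record_span, L)
                    rows.append((cid, int(s), int(e), int(nr), float(rng.uniform(0.92, 1.0)), sample))
                n_contam = rng.poisson(contam_ratio * max(int((counts > 0).sum()), 1))
                for _ in range(n_contam):
                    s = int(rng.integers(0, max(L - record_span, 1)))
                    e = min(s + record_span, L)
                    rows.append((cid, s, e, int(rng.integers(1, 4)), float(rng.uniform(0.70, 0.899)), sample))
            elif rng.random() < noise_record_rate:
                # sparse spurious mapping: high identity but low coverage
                for _ in range(int(rng.integers(1, 4))):
                    s = int(rng.integers(0, max(L - record_span, 1)))
                    e = min(s + record_span, L)
                    rows.append((cid, s, e, int(rng.integers(1, 3)), float(rng.uniform(0.92, 1.0)), sample))
    records = pd.DataFrame(
        rows, columns=["contig_id", "start", "end", "n_reads", "identity", "sample_id"]
    )
    return AlignmentSet(records=records, contig_lengths=lengths)


# ---------------------------------------------------------------------------
# Writers (plain-text external interface)


def write_bundle(bundle: CommunityBundle, outdir) -> Dict[str, str]:
    """Write the bundle to FASTA/TSV/JSON files; returns {name: path}."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(_p("contigs.fasta"), "w") as fh:
        for c in bundle.contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")
    with open(_p("proteins.faa"), "w") as fh:
        for cid in sorted(bundle.proteins):
            for pid in sorted(bundle.proteins[cid], key=lambda p: int(p.rsplit("_", 1)[1])):
                fh.write(f">{pid}\n{bundle.proteins[cid][pid]}\n")
    feat_rows = []
    for f in bundle.triage_features:
        feat_rows.append(
            {
                "contig_id": f.contig_id,
                "sorter_category": f.sorter_category,
                "finder_score": f.finder_score,
                "finder_p": f.finder_p,
                "annotation_superkingdom": f.annotation_superkingdom,
                "annotation_is_eukaryotic_virus": f.annotation_is_eukaryotic_virus,
            }
        )
    pd.DataFrame(feat_rows).to_csv(_p("triage_features.tsv"), sep="\t", index=False)
    bundle.metadata.to_csv(_p("metadata.tsv"), sep="\t")
    bundle.planted_abundance.to_csv(_p("planted_abundance.tsv"), sep="\t")
    with open(_p("truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=1, default=str)
    return paths


def write_alignments(alignments: AlignmentSet, path) -> None:
    alignments.records.to_csv(path, sep="\t", index=False)
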
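"""Marker-gene lineage classification and prophage boundary extraction.

A candidate phage family is delineated by a nine-gene core: a contig is a
family member iff it is long enough (>= 30 kb) and carries a homolog of
every marker at >= 50 bits.  A relaxed mode - used to scan fragmented
external assemblies - requires only the four structural markers
(terminase, portal, Clp protease, major capsid).  Subfamilies are cut from
average-linkage hierarchical clustering of the pairwise shared-protein-
cluster profile.  A separate two-marker rule (terminase + polymerase hits
with long alignments on >= 70 kb contigs) identifies Crassvirales phages.
Prophage boundaries are read off multi-sample depth profiles: in samples
where the host is abundant but the phage absent, the integrated region is
a depth trough whose half-height crossings mark the attachment sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import median_filter
from scipy.spatial.distance import pdist

from .genome_clustering import ScoringParams, score_homology, shared_pc_fraction_matrix
from .synthetic_community import STRUCTURAL_MARKERS, SUBFAMILY_NAMES

__all__ = [
    "MarkerGeneSet",
    "LineageAssignment",
    "DepthProfile",
    "classify_family",
    "assign_subfamilies",
    "classify_crassvirales",
    "extract_prophage_boundaries",
    "lineage_prevalence",
]


@dataclass(frozen=True)
class MarkerGeneSet:
    """A named set of marker proteins with the membership thresholds."""

    name: str
    markers: Mapping[str, str]  # marker name -> protein sequence
    required: Optional[Tuple[str, ...]] = None  # None: all markers required
    min_bits: float = 50.0
    min_contig_len: int = 30_000

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("empty marker set")
        req = self.required_markers
        unknown = [m for m in req if m not in self.markers]
        if unknown:
            raise ValueError(f"required markers not in set: {unknown}")

    @property
    def required_markers(self) -> Tuple[str, ...]:
        return tuple(self.markers) if self.required is None else self.required


@dataclass
class LineageAssignment:
    contig_id: str
    family: bool
    subfamily: str = "unassigned"
    marker_hits: Dict[str, float] = field(default_factory=dict)  # marker -> best bits


def _best_bits(
    marker_seq: str,
    proteins: Mapping[str, str],
    params: ScoringParams,
    min_aln_len: Optional[int] = None,
) -> Tuple[float, Optional[int]]:
    """Best bit score (and its alignment length) of a marker vs contig ORFs."""
    best, best_len = 0.0, None
    for pid in sorted(proteins):
        hit = score_homology(
            marker_seq,
            proteins[pid],
            params,
            query_id="marker",
            subject_id=pid,
            with_alignment_length=min_aln_len is not None,
        )
        if hit is not None and hit.bit_score > best:
            best, best_len = hit.bit_score, hit.alignment_length
    return best, best_len


def classify_family(
    contig_id: str,
    contig_length: int,
    proteins: Mapping[str, str],
    markers: MarkerGeneSet,
    relaxed: bool = False,
    params: Optional[ScoringParams] = None,
) -> LineageAssignment:
    """Family membership by the marker-core rule.

    Strict mode requires a >= ``min_bits`` hit for every marker in the set
    and contig length >= ``min_contig_len``.  Relaxed mode (for incomplete
    assemblies) requires only the four structural markers and waives the
    length rule.  Membership is monotone: extra protein hits can never
    remove it.
    """
    params = params or ScoringParams(bit_threshold=markers.min_bits)
    required = (
        tuple(m for m in STRUCTURAL_MARKERS if m in markers.markers)
        if relaxed
        else markers.required_markers
    )
    if relaxed and not required:
        raise ValueError("relaxed mode: marker set has no structural markers")
    hits: Dict[str, float] = {}
    for name in sorted(markers.markers):
        bits, _ = _best_bits(markers.markers[name], proteins, params)
        if bits >= markers.min_bits:
            hits[name] = bits
    member = all(name in hits for name in required)
    if not relaxed:
        member = member and contig_length >= markers.min_contig_len
    return LineageAssignment(contig_id, member, "unassigned", hits)


def assign_subfamilies(
    member_ids: Sequence[str],
    pc_membership: Mapping[str, set],
    k: int = 3,
) -> Dict[str, str]:
    """Cut family members into ``k`` subfamilies by shared-PC profile.

    The pairwise shared-PC-percentage matrix is treated as a per-genome
    profile; genomes are clustered by average-linkage on the Euclidean
    distances between matrix rows and the dendrogram is cut into ``k``
    clusters.  Labels (alpha, beta, gamma, ...) are assigned by cluster
    size descending (ties by smallest member id), so the labelling is
    deterministic and order-invariant.  ``k`` is a user choice - no
    automatic selection is attempted.
    """
    ids = sorted(member_ids)
    if len(ids) < k:
        raise ValueError(f"need >= {k} family members, got {len(ids)}")
    if k == 1:
        return {cid: SUBFAMILY_NAMES[0] for cid in ids}
    profile = shared_pc_fraction_matrix(ids, pc_membership)
    Z = linkage(pdist(profile, metric="euclidean"), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    clusters: Dict[int, List[str]] = {}
    for cid, label in zip(ids, raw):
        clusters.setdefault(int(label), []).append(cid)
    ordered = sorted(clusters.values(), key=lambda m: (-len(m), min(m)))
    out: Dict[str, str] = {}
    for rank, members in enumerate(ordered):
        name = SUBFAMILY_NAMES[rank] if rank < len(SUBFAMILY_NAMES) else f"sub{rank}"
        for cid in members:
            out[cid] = name
    return out


def classify_crassvirales(
    contig_id: str,
    contig_length: int,
    proteins: Mapping[str, str],
    terminase: str,
    polymerase: str,
    min_bits: float = 50.0,
    min_alignment: int = 350,
    alignment_unit: str = "residues",
    min_contig_len: int = 70_000,
    params: Optional[ScoringParams] = None,
) -> bool:
    """Two-marker Crassvirales rule.

    Flag iff BOTH the terminase and the polymerase query hit at
    >= ``min_bits`` with alignment length >= ``min_alignment`` and the
    contig is >= ``min_contig_len``.  The 350 threshold is conventionally
    quoted in bp although the search is protein-space; the unit flag
    (``residues`` default, or ``nt`` which divides the threshold by 3)
    makes the interpretation explicit.
    """
    if alignment_unit not in ("residues", "nt"):
        raise ValueError("alignment_unit must be 'residues' or 'nt'")
    threshold = min_alignment if alignment_unit == "residues" else int(np.ceil(min_alignment / 3))
    if contig_length < min_contig_len:
        return False
    params = params or ScoringParams(bit_threshold=min_bits)
    for query in (terminase, polymerase):
        bits, aln_len = _best_bits(query, proteins, params, min_aln_len=threshold)
        if bits < min_bits or aln_len is None or aln_len < threshold:
            return False
    return True


# ---------------------------------------------------------------------------
# Prophage boundaries from depth


@dataclass
class DepthProfile:
    """Per-sample read depth along one (prophage-carrying) contig."""

    contig_id: str
    depths: Mapping[str, np.ndarray]  # sample -> per-base depth
    flank_intervals: Sequence[Tuple[int, int]]  # host-gene flanks
    candidate_interval: Tuple[int, int]  # rough phage region to interrogate

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.depths.values()}
        if len(lengths) > 1:
            raise ValueError("depth vectors differ in length")


def extract_prophage_boundaries(
    profile: DepthProfile,
    host_min_depth: float = 5.0,
    phage_max_ratio: float = 0.1,
    smooth_window: int = 21,
) -> Tuple[Tuple[int, int], int]:
    """Prophage interval from samples where the host is present, phage absent.

    Informative samples have mean flank depth >= ``host_min_depth`` and
    mean depth in the candidate region <= ``phage_max_ratio`` times the
    flank mean.  Their depth vectors are averaged, median-smoothed
    (``smooth_window`` bp), and the boundaries are the outermost positions
    where the smoothed depth drops below half the flank mean.  Returns the
    0-based half-open interval and its length; exact on noise-free step
    profiles.
    """
    cand_lo, cand_hi = profile.candidate_interval
    informative: List[np.ndarray] = []
    flank_means: List[float] = []
    for sample in sorted(profile.depths):
        depth = np.asarray(profile.depths[sample], dtype=float)
        flank_vals = np.concatenate([depth[s:e] for s, e in profile.flank_intervals])
        flank_mean = float(flank_vals.mean())
        cand_mean = float(depth[cand_lo:cand_hi].mean())
        if flank_mean >= host_min_depth and cand_mean <= phage_max_ratio * flank_mean:
            informative.append(depth)
            flank_means.append(flank_mean)
    if not informative:
        raise ValueError("no discriminating sample")
    pooled = np.mean(informative, axis=0)
    smoothed = median_filter(pooled, size=smooth_window, mode="nearest")
    half = np.mean(flank_means) / 2.0
    below = np.nonzero(smoothed < half)[0]
    if below.size == 0:
        raise ValueError("no discriminating sample")
    start, end = int(below[0]), int(below[-1]) + 1
    return (start, end), end - start


def lineage_prevalence(
    lineage_of_unit: Mapping[str, str],
    abundance: pd.DataFrame,  # samples x units (filtered abundance)
    metadata: pd.DataFrame,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-lineage per-group presence counts.

    A lineage is present in a sample when any of its member units has
    non-zero filtered abundance there.  Returns lineages x groups counts
    plus group sizes, ready for prevalence tests.
    """
    groups = metadata.loc[abundance.index, group_col]
    lineages = sorted(set(lineage_of_unit.values()))
    if not lineages:
        cols = [f"{p}_{g}" for g in sorted(groups.unique()) for p in ("present", "n")]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="lineage"))
    presence = pd.DataFrame(False, index=abundance.index, columns=lineages)
    for unit, lin in lineage_of_unit.items():
        if unit in abundance.columns:
            presence[lin] |= abundance[unit] > 0
    rows = []
    for lin in lineages:
        row = {"lineage": lin}
        for level in sorted(groups.unique()):
            members = presence.loc[groups == level, lin]
            row[f"present_{level}"] = int(members.sum())
            row[f"n_{level}"] = int(len(members))
        rows.append(row)
    return pd.DataFrame(rows).set_index("lineage")
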
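"""Phage-host linkage: CRISPR protospacers, prophages, reference co-clustering.

Three independent evidence routes predict which bacterial taxon a viral
cluster infects:

* **spacer** - a CRISPR spacer from a bacterial contig (or an external
  spacer catalogue) matches a phage contig with at most one substitution
  ("less than 2 mismatches"), on either strand;
* **prophage** - a VC contains a bacterial contig carrying an integrated
  prophage, so the VC inherits that contig's taxon;
* **reference** - a VC co-clusters characterised reference phages whose
  hosts all fall in one bacterial family (unanimity required).

Predictions are merged per VC with provenance; VCs (or single contigs)
with spacer evidence from more than one phylum are flagged as putative
broad-host-range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple
import warnings

import numpy as np
import pandas as pd

from .synthetic_community import ContigRecord

__all__ = [
    "SpacerRecord",
    "ProtospacerHit",
    "HostPrediction",
    "detect_crispr_arrays",
    "match_protospacers",
    "prophage_vc_links",
    "refseq_cocluster_links",
    "merge_host_predictions",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpacerRecord:
    """A CRISPR spacer with its source contig/genome and (known) taxonomy."""

    spacer_id: str
    sequence: str
    source_id: str
    taxonomy: Mapping[str, str] = field(default_factory=dict)  # rank -> name

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.spacer_id}: spacer must be a non-empty ACGT string")


@dataclass(frozen=True)
class ProtospacerHit:
    spacer_id: str
    contig_id: str
    position: int  # 0-based start on the forward strand
    strand: str  # "+" | "-"
    mismatches: int


@dataclass(frozen=True)
class HostPrediction:
    vc_id: str
    taxon: str
    rank: str
    route: str  # "spacer" | "prophage" | "reference"
    evidence_ids: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# CRISPR array detection (simplified)


def detect_crispr_arrays(
    contig: ContigRecord,
    min_copies: int = 3,
    repeat_range: Tuple[int, int] = (23, 55),
    spacer_range: Tuple[int, int] = (18, 50),
    seed_k: int = 20,
) -> List[SpacerRecord]:
    """Find CRISPR arrays and return their spacers.

    Simplified detector: an array is >= ``min_copies`` repeat copies
    (23-55 bp) separated by non-identical spacers (18-50 bp).  Candidate
    arrays are seeded by exact ``seed_k``-mers recurring at compatible
    intervals; repeat boundaries are then extended by strict consensus
    (every copy identical), so the repeat reported is the maximal exactly
    conserved core.  Array quality scoring of the full published detectors
    is out of scope - downstream computation consumes spacers only.
    """
    seq = contig.sequence
    n = len(seq)
    rep_min, rep_max = repeat_range
    sp_min, sp_max = spacer_range
    gap_min, gap_max = rep_min + sp_min, rep_max + sp_max
    if n < seed_k * min_copies:
        return []
    positions: Dict[str, List[int]] = {}
    for i in range(n - seed_k + 1):
        positions.setdefault(seq[i : i + seed_k], []).append(i)
    claimed_until = -1
    spacers: List[SpacerRecord] = []
    # scan left to right; the first seed of an array claims it
    for i in range(n - seed_k + 1):
        if i <= claimed_until:
            continue
        occ = positions[seq[i : i + seed_k]]
        if len(occ) < min_copies:
            continue
        chain = [i]
        for p in occ:
            if p > chain[-1] and gap_min <= p - chain[-1] <= gap_max:
                chain.append(p)
        if len(chain) < min_copies:
            continue
        # extend repeat boundaries by strict consensus across all copies
        left = 0
        while all(c - left - 1 >= 0 for c in chain) and len(
            {seq[c - left - 1] for c in chain}
        ) == 1:
            left += 1
            if (chain[1] - chain[0]) - (seed_k + left) < sp_min:
                break
        right = 0
        while all(c + seed_k + right < n for c in chain) and len(
            {seq[c + seed_k + right] for c in chain}
        ) == 1:
            right += 1
            if (chain[1] - chain[0]) - (seed_k + left + right) < sp_min:
                break
        rep_len = seed_k + left + right
        if not rep_min <= rep_len <= rep_max:
            continue
        starts = [c - left for c in chain]
        gaps = [starts[k + 1] - (starts[k] + rep_len) for k in range(len(starts) - 1)]
        if any(not sp_min <= g <= sp_max for g in gaps):
            continue
        seqs = [seq[starts[k] + rep_len : starts[k + 1]] for k in range(len(starts) - 1)]
        if len(set(seqs)) != len(seqs):
            continue  # spacers must be non-identical
        for k, sp in enumerate(seqs):
            spacers.append(
                SpacerRecord(
                    spacer_id=f"{contig.id}_array{starts[0]}_sp{k}",
                    sequence=sp,
                    source_id=contig.id,
                )
            )
        claimed_until = starts[-1] + rep_len
    return spacers


# ---------------------------------------------------------------------------
# Protospacer matching


def _hamming_hits(spacer: str, target: str, max_mismatches: int) -> List[Tuple[int, int]]:
    """(position, mismatches) of all windows within the Hamming budget."""
    m, n = len(spacer), len(target)
    if n < m:
        return []
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    s = np.frombuffer(spacer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != s).sum(axis=1)
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mismatches)[0]]


def match_protospacers(
    spacers: Sequence[SpacerRecord],
    phage_contigs: Sequence[ContigRecord],
    max_mismatches: int = 1,
) -> List[ProtospacerHit]:
    """All protospacer matches of each spacer against each phage contig.

    A hit is any position on either strand where the spacer matches with at
    most ``max_mismatches`` substitutions (Hamming distance; indels are not
    considered, matching short-protospacer practice).  Positions are
    0-based on the forward strand of the contig.  Spacers shorter than
    18 nt are searched anyway, with a warning.
    """
    hits: List[ProtospacerHit] = []
    for sp in spacers:
        if len(sp.sequence) < 18:
            warnings.warn(
                f"spacer {sp.spacer_id} shorter than 18 nt; matches may be spurious"
            )
        rc = reverse_complement(sp.sequence)
        for contig in phage_contigs:
            for pos, mm in _hamming_hits(sp.sequence, contig.sequence, max_mismatches):
                hits.append(ProtospacerHit(sp.spacer_id, contig.id, pos, "+", mm))
            for pos, mm in _hamming_hits(rc, contig.sequence, max_mismatches):
                hits.append(ProtospacerHit(sp.spacer_id, contig.id, pos, "-", mm))
    return hits


def spacer_vc_links(
    hits: Sequence[ProtospacerHit],
    vc_of_contig: Mapping[str, str],
    taxonomy_of_spacer_source: Mapping[str, Mapping[str, str]],
    spacer_sources: Mapping[str, str],
    rank: str = "phylum",
) -> List[HostPrediction]:
    """Turn protospacer hits into VC-level host predictions at ``rank``."""
    preds: Dict[Tuple[str, str], List[str]] = {}
    for hit in hits:
        vc = vc_of_contig.get(hit.contig_id)
        if vc is None:
            continue
        source = spacer_sources.get(hit.spacer_id)
        taxonomy = taxonomy_of_spacer_source.get(source, {})
        taxon = taxonomy.get(rank)
        if taxon is None:
            continue
        preds.setdefault((vc, taxon), []).append(hit.spacer_id)
    return [
        HostPrediction(vc, taxon, rank, "spacer", tuple(sorted(set(ev))))
        for (vc, taxon), ev in sorted(preds.items())
    ]


# ---------------------------------------------------------------------------
# Prophage and reference routes


def prophage_vc_links(
    vc_members: Mapping[str, Iterable[str]],
    prophage_taxa: Mapping[str, Mapping[str, str]],
    rank: str = "genus",
) -> List[HostPrediction]:
    """Every VC containing a prophage contig inherits that contig's taxon.

    ``prophage_taxa`` maps prophage-flagged (bacterial) contig ids to their
    taxonomy; any such contig that is a member of a VC links the whole VC.
    """
    preds: List[HostPrediction] = []
    for vc_id in sorted(vc_members):
        for member in sorted(vc_members[vc_id]):
            taxonomy = prophage_taxa.get(member)
            if taxonomy is None:
                continue
            taxon = taxonomy.get(rank) or taxonomy.get("species")
            if taxon is None:
                continue
            preds.append(HostPrediction(vc_id, taxon, rank, "prophage", (member,)))
    return preds


def refseq_cocluster_links(
    vc_members: Mapping[str, Iterable[str]],
    reference_hosts: Mapping[str, str],  # reference genome id -> host family
) -> List[HostPrediction]:
    """Family-level links from characterised phages co-clustered in a VC.

    A link is emitted only when every reference member of the VC infects
    the same bacterial family (unanimity); VCs with no reference members,
    or with references split across families, yield nothing.
    """
    preds: List[HostPrediction] = []
    for vc_id in sorted(vc_members):
        refs = sorted(m for m in vc_members[vc_id] if m in reference_hosts)
        if not refs:
            continue
        families = {reference_hosts[r] for r in refs}
        if len(families) == 1:
            preds.append(
                HostPrediction(vc_id, families.pop(), "family", "reference", tuple(refs))
            )
    return preds


# ---------------------------------------------------------------------------
# Merge


def merge_host_predictions(
    predictions: Sequence[HostPrediction],
    phylum_of_taxon: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Merge all routes into a per-VC host table with a multi-phylum flag.

    Predictions are deduplicated by (vc, taxon, rank) with evidence pooled
    across routes; a VC is flagged multi-phylum when its predictions span
    more than one phylum.  ``phylum_of_taxon`` maps non-phylum taxon names
    to their phylum; taxa at rank "phylum" map to themselves, and unmapped
    taxa do not contribute to the flag.
    """
    if not predictions:
        return pd.DataFrame(
            columns=["vc_id", "taxon", "rank", "routes", "evidence_ids", "multi_phylum"]
        )
    phylum_of_taxon = phylum_of_taxon or {}
    merged: Dict[Tuple[str, str, str], Dict[str, Set[str]]] = {}
    for pred in predictions:
        key = (pred.vc_id, pred.taxon, pred.rank)
        entry = merged.setdefault(key, {"routes": set(), "evidence": set()})
        entry["routes"].add(pred.route)
        entry["evidence"].update(pred.evidence_ids)
    phyla_per_vc: Dict[str, Set[str]] = {}
    for (vc, taxon, rank), _ in merged.items():
        phylum = taxon if rank == "phylum" else phylum_of_taxon.get(taxon)
        if phylum is not None:
            phyla_per_vc.setdefault(vc, set()).add(phylum)
    rows = []
    for (vc, taxon, rank), entry in sorted(merged.items()):
        rows.append(
            {
                "vc_id": vc,
                "taxon": taxon,
                "rank": rank,
                "routes": ",".join(sorted(entry["routes"])),
                "evidence_ids": ",".join(sorted(entry["evidence"])),
                "multi_phylum": len(phyla_per_vc.get(vc, set())) > 1,
            }
        )
    return pd.DataFrame(rows)
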
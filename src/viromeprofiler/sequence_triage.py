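"""Viral/bacterial contig triage, circularity detection, and deduplication.

Upstream tools (a genome-architecture sorter with categories 1-6, a
machine-learning viral finder with score/p-value, and a taxonomic contig
annotator) produce the per-contig evidence; this module applies the
decision rule combining them:

* sorter category 1, 2, 4 or 5 -> phage;
* finder score > 0.9 with p < 0.05 -> phage;
* sorter category 3 or 6 AND finder score > 0.7 with p < 0.05 AND
  superkingdom annotation "Viruses" or "unclassified" -> phage;
* contigs annotated as eukaryotic viruses are then removed;
* superkingdom "Bacteria" -> bacterial, except that a contig already
  called phage stays bacterial only when it is a prophage (category
  4/5/6) - the prophage exception that keeps integrated phages available
  for host linkage.

Circular contigs are recognised among short contigs (1.5-5 kb) by an
exact terminal direct repeat; deduplication removes contigs contained at
>= 90% identity in a longer retained contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .synthetic_community import ContigRecord, TriageFeatures

__all__ = [
    "ContigRecord",
    "TriageFeatures",
    "TriageResult",
    "detect_circular",
    "classify_viral",
    "deduplicate",
]

PHAGE_CATEGORIES = frozenset({1, 2, 4, 5})
AMBIGUOUS_CATEGORIES = frozenset({3, 6})
PROPHAGE_CATEGORIES = frozenset({4, 5, 6})


@dataclass
class TriageResult:
    """Outcome of the viral/bacterial decision rule with its trace.

    A contig may be both phage and bacterial only through the prophage
    exception; ``reasons`` records the ordered rule clauses that fired.
    """

    contig_id: str
    phage: bool
    bacterial: bool
    reasons: List[str] = field(default_factory=list)


def detect_circular(
    contig: ContigRecord,
    min_len: int = 1500,
    max_len: int = 5000,
    min_repeat: int = 20,
) -> bool:
    """True iff the contig is short (in ``[min_len, max_len)``) and carries
    an exact terminal direct repeat of at least ``min_repeat`` bp.

    Assemblers leave such identical terminal ends on circular genomes;
    contigs at or above ``max_len`` are retained by the long-contig rule
    instead and are never flagged here.
    """
    if not contig.sequence:
        raise ValueError(f"{contig.id}: empty sequence")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    n = contig.length
    if not (min_len <= n < max_len):
        return False
    seq = contig.sequence
    limit = n // 2
    if limit < min_repeat:
        return False
    # longest exact prefix == suffix overlap up to half the contig
    for k in range(limit, min_repeat - 1, -1):
        if seq[:k] == seq[-k:]:
            return True
    return False


def classify_viral(features: TriageFeatures) -> TriageResult:
    """Apply the phage/bacterial decision rule to one contig's evidence.

    Pure function; absent evidence fails its clause rather than erroring,
    because real upstream feature tables are sparse.
    """
    reasons: List[str] = []
    cat = features.sorter_category
    score = features.finder_score
    pval = features.finder_p
    kingdom = features.annotation_superkingdom

    phage = False
    if cat in PHAGE_CATEGORIES:
        phage = True
        reasons.append(f"sorter category {cat} in {{1,2,4,5}} -> phage")
    if not phage and score is not None and pval is not None and score > 0.9 and pval < 0.05:
        phage = True
        reasons.append(f"finder score {score:.3g} > 0.9 with p {pval:.3g} < 0.05 -> phage")
    if (
        not phage
        and cat in AMBIGUOUS_CATEGORIES
        and score is not None
        and pval is not None
        and score > 0.7
        and pval < 0.05
        and kingdom in ("Viruses", "unclassified")
    ):
        phage = True
        reasons.append(
            f"sorter category {cat} with finder score {score:.3g} > 0.7, "
            f"p {pval:.3g} < 0.05 and superkingdom {kingdom!r} -> phage"
        )
    if phage and features.annotation_is_eukaryotic_virus:
        phage = False
        reasons.append("annotated as eukaryotic virus -> removed from phage set")

    bacterial = False
    if kingdom == "Bacteria":
        if not phage:
            bacterial = True
            reasons.append("superkingdom Bacteria -> bacterial")
        elif cat in PROPHAGE_CATEGORIES:
            bacterial = True
            reasons.append(
                f"prophage exception: category {cat} contig kept in both phage "
                "and bacterial sets"
            )
        else:
            reasons.append("superkingdom Bacteria but already phage (non-prophage) -> not bacterial")
    if not reasons:
        reasons.append("no clause fired -> neither phage nor bacterial")
    return TriageResult(features.contig_id, phage, bacterial, reasons)


def _containment_identity(shorter: str, longer: str, min_identity: float) -> float:
    """Identity of the best semi-global placement of ``shorter`` in ``longer``.

    edlib HW mode aligns the whole shorter sequence into the longer one;
    identity is 1 - edit_distance / len(shorter).  The search is bounded at
    the edit distance the identity threshold allows, so hopeless pairs are
    rejected quickly; returns 0.0 when the bound is exceeded.
    """
    max_dist = int((1.0 - min_identity) * len(shorter)) + 1
    res = edlib.align(shorter, longer, mode="HW", task="distance", k=max_dist)
    if res["editDistance"] < 0:  # bound exceeded
        return 0.0
    return 1.0 - res["editDistance"] / len(shorter)


def _kmer_prescreen(shorter: str, longer: str, k: int = 20, n_probes: int = 50) -> bool:
    """Cheap containment prescreen: do sampled k-mers of ``shorter`` occur
    in ``longer``?  At >= 90% identity a k-mer survives with probability
    ~0.9^20, so several of 50 probes match; unrelated sequences match none.
    """
    if len(shorter) <= k:
        return True
    step = max(1, (len(shorter) - k) // n_probes)
    found = 0
    for i in range(0, len(shorter) - k, step):
        if shorter[i : i + k] in longer:
            found += 1
            if found >= 2:
                return True
    return False


def deduplicate(
    contigs: Sequence[ContigRecord],
    min_identity: float = 90.0,
    min_span: float = 0.95,
) -> Tuple[List[ContigRecord], Dict[str, str]]:
    """Remove contigs contained in a longer retained contig.

    A contig is removed iff it aligns to a strictly longer retained contig
    (ties broken by lexicographically earlier id) at >= ``min_identity``
    percent identity over >= ``min_span`` of its own length.  Containment
    is tested by semi-global alignment of the whole shorter contig and,
    failing that, of its central ``min_span`` window.  The result is
    independent of input order; the duplicate map records which
    representative absorbed each removed contig.
    """
    if not 0.0 < min_identity <= 100.0:
        raise ValueError("min_identity must be in (0, 100]")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes}")
    threshold = min_identity / 100.0
    # Process longest first so representatives are always at least as long
    # as anything they absorb; ties by id for order-invariance.
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    retained: List[ContigRecord] = []
    duplicate_map: Dict[str, str] = {}
    for contig in ordered:
        absorbed_by = None
        trim = int(round(contig.length * (1.0 - min_span) / 2.0))
        core = contig.sequence[trim : contig.length - trim] if trim else contig.sequence
        for rep in retained:
            if rep.length <= contig.length and not (
                rep.length == contig.length and rep.id < contig.id
            ):
                continue
            if not _kmer_prescreen(contig.sequence, rep.sequence):
                continue
            if _containment_identity(contig.sequence, rep.sequence, threshold) >= threshold:
                absorbed_by = rep.id
                break
            if trim and _containment_identity(core, rep.sequence, threshold) >= threshold:
                absorbed_by = rep.id
                break
        if absorbed_by is None:
            retained.append(contig)
        else:
            duplicate_map[contig.id] = absorbed_by
    retained.sort(key=lambda c: c.id)
    return retained, duplicate_map
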
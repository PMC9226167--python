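"""Independent brute-force oracles used to check the implementation.

These deliberately re-derive results by the most direct method available
(full dynamic programming, per-position marking, exhaustive enumeration)
and share no code with the library paths they validate.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def smith_waterman_affine(
    a: str, b: str, gap_open: float = 12.0, gap_extend: float = 1.0
) -> float:
    """Full-matrix local alignment score with affine gaps (Gotoh).

    ``gap_open`` is the cost of the first gap residue (matching the
    convention where a length-g gap costs gap_open + (g-1)*gap_extend).
    """
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def semiglobal_edit_distance(query: str, target: str) -> int:
    """Minimum edit distance of ``query`` against any substring of
    ``target`` (full DP; the oracle for containment identity)."""
    m = len(query)
    prev = [0] * (len(target) + 1)  # free leading gaps in target
    for i in range(1, m + 1):
        cur = [i] + [0] * len(target)
        for j in range(1, len(target) + 1):
            cost = 0 if query[i - 1] == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free trailing gaps in target


def sliding_hamming_hits(
    spacer: str, target: str, max_mismatches: int
) -> List[Tuple[int, int]]:
    """All (position, mismatches) by per-window character comparison."""
    out = []
    m = len(spacer)
    for i in range(len(target) - m + 1):
        mm = sum(1 for x, y in zip(spacer, target[i : i + m]) if x != y)
        if mm <= max_mismatches:
            out.append((i, mm))
    return out


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def fisher_two_sided_enumerate(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of all admissible tables.

    Fixed margins; sums hypergeometric probabilities of every table whose
    probability is <= the observed one (with relative slack for float ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(lo, hi + 1):
        p_x = hypergeom.pmf(x, n, c1, r1)
        if p_x <= p_obs * (1 + 1e-7):
            total += p_x
    return min(total, 1.0)


def coverage_by_marking(intervals: Sequence[Tuple[int, int]], length: int) -> float:
    """Horizontal coverage by per-position marking."""
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    return covered.mean() if length else 0.0


def hypergeom_tail_exact(
    shared: int, universe: int, size_a: int, size_b: int
) -> float:
    """P(X >= shared) by summing pmf terms (independent of sf)."""
    return float(
        sum(
            hypergeom.pmf(x, universe, size_a, size_b)
            for x in range(shared, min(size_a, size_b) + 1)
        )
    )


def brute_force_abundance(
    records, contig_lengths: Dict[str, int], vc_of: Dict[str, str],
    min_identity: float = 0.90, min_coverage: float = 0.75,
) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Recompute the whole abundance pipeline record by record.

    Returns nested dicts: layer -> sample -> unit -> value, for layers
    ``counts`` (contig), ``rpkm`` (contig) and ``vc_relative`` (VC).
    """
    samples = sorted(set(records["sample_id"]))
    contigs = sorted(contig_lengths)
    counts: Dict[str, Dict[str, float]] = {s: {c: 0.0 for c in contigs} for s in samples}
    for s in samples:
        for c in contigs:
            rows = [
                (int(r.start), int(r.end), int(r.n_reads))
                for r in records.itertuples()
                if r.sample_id == s and r.contig_id == c and r.identity >= min_identity
            ]
            cov = coverage_by_marking([(x, y) for x, y, _ in rows], contig_lengths[c])
            if cov >= min_coverage:
                counts[s][c] = float(sum(n for _, _, n in rows))
    rpkm: Dict[str, Dict[str, float]] = {}
    for s in samples:
        lib = sum(counts[s].values())
        rpkm[s] = {
            c: (
                counts[s][c] / (contig_lengths[c] / 1e3) / (lib / 1e6)
                if lib > 0
                else 0.0
            )
            for c in contigs
        }
    vcs = sorted(set(vc_of.values()))
    vc_rel: Dict[str, Dict[str, float]] = {}
    for s in samples:
        agg = {v: 0.0 for v in vcs}
        for c in contigs:
            agg[vc_of[c]] += rpkm[s][c]
        total = sum(agg.values())
        vc_rel[s] = {v: (agg[v] / total if total > 0 else 0.0) for v in vcs}
    return {"counts": counts, "rpkm": rpkm, "vc_relative": vc_rel}
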
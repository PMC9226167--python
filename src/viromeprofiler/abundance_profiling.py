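"""Coverage-filtered abundance profiling: alignments -> per-VC abundance.

The pipeline order is fixed and mirrors standard virome practice:

1. drop alignment records below 90% identity (spurious mappings);
2. compute horizontal coverage per contig x sample and zero the read
   counts of pairs covered over less than 75% of the contig (presence
   filter - low-coverage "hits" are read recruitment to shared genes, not
   evidence the virus is present);
3. normalise to RPKM (reads per kilobase per million mapped reads);
4. sum per viral cluster;
5. close to relative abundance per sample.

All coordinates are 0-based half-open.  "Less than" thresholds are
strict: identity exactly 0.90 and coverage exactly 0.75 are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "filter_identity",
    "horizontal_coverage",
    "compute_depth",
    "counts_with_coverage_zeroing",
    "rpkm",
    "aggregate_by_vc",
    "relative_abundance",
    "prevalence_bins",
    "ranked_abundance_curve",
    "profile_abundance",
]

RECORD_COLUMNS = ["contig_id", "start", "end", "n_reads", "identity", "sample_id"]


@dataclass
class AbundanceMatrix:
    """A sample x unit table with its layer tag and coverage provenance."""

    values: pd.DataFrame  # index: samples, columns: units
    layer: str  # "counts" | "rpkm" | "relative"
    coverage_mask: Optional[pd.DataFrame] = None  # sample x contig coverage fraction

    def __post_init__(self) -> None:
        if self.layer not in ("counts", "rpkm", "relative"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "relative":
            totals = self.values.sum(axis=1)
            bad = totals[(totals > 0) & (np.abs(totals - 1.0) > 1e-9)]
            if len(bad):
                raise ValueError("relative layer rows must sum to 1")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"alignment records missing columns: {missing}")


def filter_identity(records: pd.DataFrame, min_identity: float = 0.90) -> pd.DataFrame:
    """Keep records with identity >= ``min_identity`` (boundary inclusive)."""
    _check_records(records)
    ident = records["identity"]
    if len(records) and ((ident < 0) | (ident > 1)).any():
        bad = records.loc[(ident < 0) | (ident > 1)].index[:5].tolist()
        raise ValueError(f"identity outside [0, 1] at rows {bad}")
    return records[ident >= min_identity].reset_index(drop=True)


def horizontal_coverage(
    intervals: Iterable[Tuple[int, int]], contig_len: int
) -> float:
    """Fraction of contig positions covered by >= 1 interval (union length)."""
    merged_len = 0
    current_start = current_end = None
    for start, end in sorted(intervals):
        if start < 0 or end > contig_len or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) invalid for contig of length {contig_len}"
            )
        if current_start is None:
            current_start, current_end = start, end
        elif start <= current_end:
            current_end = max(current_end, end)
        else:
            merged_len += current_end - current_start
            current_start, current_end = start, end
    if current_start is not None:
        merged_len += current_end - current_start
    return merged_len / contig_len


def compute_depth(records: pd.DataFrame, contig_len: int) -> np.ndarray:
    """Per-base depth vector from records of one contig (+sample)."""
    vec = np.zeros(contig_len)
    for start, end, n_reads in zip(records["start"], records["end"], records["n_reads"]):
        if start < 0 or end > contig_len:
            raise ValueError(f"interval [{start}, {end}) exceeds contig length {contig_len}")
        vec[start:end] += n_reads
    return vec


def counts_with_coverage_zeroing(
    records: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    threshold: float = 0.75,
    samples: Optional[Sequence[str]] = None,
    contigs: Optional[Sequence[str]] = None,
) -> AbundanceMatrix:
    """Per contig x sample read counts, zeroed where coverage < ``threshold``.

    Records should already be identity-filtered.  The coverage mask (the
    horizontal-coverage fraction of every contig x sample cell) is retained
    so zeroed cells stay auditable.
    """
    _check_records(records)
    if samples is None:
        samples = sorted(records["sample_id"].unique())
    if contigs is None:
        contigs = sorted(contig_lengths)
    unknown = set(records["contig_id"]) - set(contig_lengths)
    if unknown:
        raise KeyError(f"records reference contigs without lengths: {sorted(unknown)[:5]}")
    counts = pd.DataFrame(0.0, index=list(samples), columns=list(contigs))
    mask = pd.DataFrame(0.0, index=list(samples), columns=list(contigs))
    for (sample, contig), sub in records.groupby(["sample_id", "contig_id"]):
        cov = horizontal_coverage(
            list(zip(sub["start"], sub["end"])), contig_lengths[contig]
        )
        mask.loc[sample, contig] = cov
        counts.loc[sample, contig] = sub["n_reads"].sum() if cov >= threshold else 0.0
    return AbundanceMatrix(values=counts, layer="counts", coverage_mask=mask)


def rpkm(
    counts: AbundanceMatrix,
    contig_lengths: Mapping[str, int],
    library_sizes: Optional[Mapping[str, float]] = None,
) -> AbundanceMatrix:
    """Reads per kilobase per million mapped reads.

    ``library_sizes`` defaults to each sample's total (identity-filtered,
    coverage-zeroed) mapped reads; pass totals from the full QC read set to
    use the alternative convention.
    """
    if counts.layer != "counts":
        raise ValueError("rpkm expects the counts layer")
    values = counts.values
    if library_sizes is None:
        library_sizes = values.sum(axis=1).to_dict()
    lengths = np.array([contig_lengths[c] for c in values.columns], dtype=float)
    out = values.copy().astype(float)
    for sample in values.index:
        lib = float(library_sizes[sample])
        if lib == 0:
            if values.loc[sample].sum() > 0:
                raise ValueError(f"library_size is 0 for sample {sample} with nonzero counts")
            continue
        out.loc[sample] = values.loc[sample] / (lengths / 1e3) / (lib / 1e6)
    return AbundanceMatrix(values=out, layer="rpkm", coverage_mask=counts.coverage_mask)


def aggregate_by_vc(
    matrix: AbundanceMatrix, vc_of_contig: Mapping[str, str]
) -> AbundanceMatrix:
    """Sum contig columns into their viral clusters (totals conserved)."""
    missing = [c for c in matrix.values.columns if c not in vc_of_contig]
    if missing:
        raise KeyError(f"contigs without VC assignment: {missing}")
    grouped = matrix.values.T.groupby(
        [vc_of_contig[c] for c in matrix.values.columns]
    ).sum().T
    grouped = grouped[sorted(grouped.columns)]
    return AbundanceMatrix(values=grouped, layer=matrix.layer, coverage_mask=matrix.coverage_mask)


def relative_abundance(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Close each sample's row to sum 1; all-zero rows stay zero (warned)."""
    totals = matrix.values.sum(axis=1)
    zero_rows = totals[totals == 0].index.tolist()
    if zero_rows:
        warnings.warn(f"samples with zero total abundance left at zero: {zero_rows}")
    out = matrix.values.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return AbundanceMatrix(values=out, layer="relative", coverage_mask=matrix.coverage_mask)


def prevalence_bins(
    relative: AbundanceMatrix, low: float = 0.10, high: float = 0.30
) -> pd.DataFrame:
    """Per-unit prevalence (fraction of samples with value > 0) and bin.

    Bins follow the individual / intermediate / core-like convention:
    units seen in fewer than ``low`` of samples are individual-specific,
    those above ``high`` are core-like.
    """
    prevalence = (relative.values > 0).mean(axis=0)
    # individual: strictly below `low`; core-like: strictly above `high`
    bins = np.select(
        [prevalence < low, prevalence > high], ["individual", "core-like"], "intermediate"
    )
    return pd.DataFrame(
        {"prevalence": prevalence, "bin": bins}, index=relative.values.columns
    )


def ranked_abundance_curve(sample_row: pd.Series) -> np.ndarray:
    """Cumulative fraction over units sorted by descending abundance.

    Ties are broken by unit id; the curve is non-decreasing and ends at 1
    when the row has positive total.
    """
    total = sample_row.sum()
    ordered = sample_row.sort_index().sort_values(ascending=False, kind="stable")
    if total == 0:
        return np.zeros(len(ordered))
    return np.cumsum(ordered.to_numpy()) / total


def profile_abundance(
    records: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    vc_of_contig: Mapping[str, str],
    min_identity: float = 0.90,
    min_coverage: float = 0.75,
    library_sizes: Optional[Mapping[str, float]] = None,
    samples: Optional[Sequence[str]] = None,
) -> Dict[str, AbundanceMatrix]:
    """Run the full fixed-order pipeline; returns all layers.

    Returns a dict with keys ``counts`` (contig level), ``rpkm`` (contig
    level), ``vc_rpkm`` and ``vc_relative``.
    """
    filtered = filter_identity(records, min_identity)
    counts = counts_with_coverage_zeroing(
        filtered, contig_lengths, threshold=min_coverage, samples=samples
    )
    rpkm_layer = rpkm(counts, contig_lengths, library_sizes)
    vc_rpkm = aggregate_by_vc(rpkm_layer, vc_of_contig)
    vc_rel = relative_abundance(vc_rpkm)
    return {
        "counts": counts,
        "rpkm": rpkm_layer,
        "vc_rpkm": vc_rpkm,
        "vc_relative": vc_rel,
    }
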
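"""Readers/writers for the plain-text interchange formats.

Everything is TSV/FASTA/JSON for diffability; alignment coordinates are
0-based half-open throughout, with a converter for 1-based inclusive
input.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import pandas as pd
from Bio import SeqIO

from .synthetic_community import ContigRecord, TriageFeatures

__all__ = [
    "read_contigs_fasta",
    "read_proteins_fasta",
    "read_triage_features",
    "read_alignments",
    "from_one_based_inclusive",
    "write_contigs_fasta",
]


def read_contigs_fasta(path, sample_id: str = "unknown") -> List[ContigRecord]:
    return [
        ContigRecord(rec.id, str(rec.seq).upper(), sample_id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_contigs_fasta(contigs, path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")


def read_proteins_fasta(path) -> Dict[str, Dict[str, str]]:
    """Protein FASTA with ids ``<contig>_<orf_index>`` -> nested dict."""
    out: Dict[str, Dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        contig = rec.id.rsplit("_", 1)[0]
        out.setdefault(contig, {})[rec.id] = str(rec.seq)
    return out


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_triage_features(path) -> List[TriageFeatures]:
    df = pd.read_csv(path, sep="\t")
    features = []
    for _, row in df.iterrows():
        cat = row.get("sorter_category")
        features.append(
            TriageFeatures(
                contig_id=row["contig_id"],
                sorter_category=int(cat) if pd.notna(cat) else None,
                finder_score=_opt_float(row.get("finder_score")),
                finder_p=_opt_float(row.get("finder_p")),
                annotation_superkingdom=(
                    row["annotation_superkingdom"]
                    if pd.notna(row.get("annotation_superkingdom"))
                    else None
                ),
                annotation_is_eukaryotic_virus=bool(
                    row.get("annotation_is_eukaryotic_virus", False)
                ),
            )
        )
    return features


def read_alignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"contig_id", "start", "end", "n_reads", "identity", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    return df


def from_one_based_inclusive(df: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive start/end columns to 0-based half-open."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return out
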
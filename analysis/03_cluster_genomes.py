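#!/usr/bin/env python
"""Form protein clusters and viral clusters from the phage ORF set.

All-vs-all local-alignment protein search at >= 50 bits, PCs as connected
components of the hit graph, then VCs by hypergeometric shared-PC
significance with Markov clustering; singletons become one-member VCs.
"""

import os

import pandas as pd
from Bio import SeqIO

from viromeprofiler import genome_clustering as gc, io

DATA = os.path.join("results", "analysis", "data")
OUT = os.path.join("results", "analysis")


def main() -> None:
    retained = {rec.id for rec in SeqIO.parse(os.path.join(OUT, "phage_contigs.fasta"), "fasta")}
    by_contig = io.read_proteins_fasta(os.path.join(DATA, "proteins.faa"))
    proteins = {
        pid: seq
        for cid in retained
        for pid, seq in by_contig.get(cid, {}).items()
    }
    hits = gc.all_vs_all_hits(proteins)
    pcs = gc.build_protein_clusters(hits, proteins)
    membership = gc.pc_membership_from_clusters(
        pcs, {pid: pid.rsplit("_", 1)[0] for pid in proteins}
    )
    for cid in retained:
        membership.setdefault(cid, set())
    vcs = gc.build_viral_clusters(membership, universe=len(pcs))

    pd.DataFrame(
        [(h.query_id, h.subject_id, h.raw_score, round(h.bit_score, 2)) for h in hits],
        columns=["query", "subject", "raw", "bits"],
    ).to_csv(os.path.join(OUT, "hits.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(pc.pc_id, pid) for pc in pcs for pid in sorted(pc.members)],
        columns=["pc_id", "protein_id"],
    ).to_csv(os.path.join(OUT, "pcs.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(vc.vc_id, cid, vc.singleton) for vc in vcs for cid in sorted(vc.members)],
        columns=["vc_id", "contig_id", "singleton"],
    ).to_csv(os.path.join(OUT, "vcs.tsv"), sep="\t", index=False)
    n_single = sum(vc.singleton for vc in vcs)
    print(f"{len(proteins)} proteins -> {len(hits)} hits >= 50 bits -> {len(pcs)} PCs")
    print(f"{len(retained)} contigs -> {len(vcs)} VCs ({n_single} singletons)")


if __name__ == "__main__":
    main()
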
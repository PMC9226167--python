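#!/usr/bin/env python
"""Predict VC hosts by CRISPR protospacers and prophage taxonomy.

Detects CRISPR arrays on bacterial contigs, matches their spacers against
phage contigs (<= 1 mismatch, both strands), propagates prophage-contig
taxonomy to VCs, merges both routes, and flags multi-phylum host ranges.
Evaluates the spacer route against the generator's planted truth.
"""

import json
import os

import pandas as pd
from Bio import SeqIO

from viromeprofiler import host_linkage as hl, io

OUT = os.path.join("results", "analysis")
DATA = os.path.join(OUT, "data")


def main() -> None:
    contigs = io.read_contigs_fasta(os.path.join(DATA, "contigs.fasta"))
    triage = pd.read_csv(os.path.join(OUT, "triage_results.tsv"), sep="\t")
    vc_table = pd.read_csv(os.path.join(OUT, "vcs.tsv"), sep="\t")
    vc_of = dict(zip(vc_table.contig_id, vc_table.vc_id))
    truth = json.load(open(os.path.join(DATA, "truth.json")))

    bacterial_ids = set(triage.loc[triage.bacterial, "contig_id"])
    bacterial = [c for c in contigs if c.id in bacterial_ids]
    phages = [c for c in contigs if c.id in vc_of]

    spacers = [sp for b in bacterial for sp in hl.detect_crispr_arrays(b)]
    hits = hl.match_protospacers(spacers, phages, max_mismatches=1)
    host_taxa = truth["host_taxa"]
    spacer_links = hl.spacer_vc_links(
        hits, vc_of, host_taxa, {sp.spacer_id: sp.source_id for sp in spacers}
    )
    vc_members = {}
    for cid, vc in vc_of.items():
        vc_members.setdefault(vc, set()).add(cid)
    prophage_taxa = {
        phage: host_taxa[host] for phage, host in truth["prophage_host_of"].items()
    }
    prophage_links = hl.prophage_vc_links(vc_members, prophage_taxa)
    phylum_of = {
        taxa[rank]: taxa["phylum"]
        for taxa in host_taxa.values()
        for rank in ("phylum", "family", "genus", "species")
    }
    merged = hl.merge_host_predictions(spacer_links + prophage_links, phylum_of)
    merged.to_csv(os.path.join(OUT, "host_predictions.tsv"), sep="\t", index=False)

    source_of = {sp.spacer_id: sp.source_id for sp in spacers}
    got = {(source_of[h.spacer_id], h.contig_id) for h in hits}
    planted = {
        (r["host_contig"], r["target_phage"])
        for r in truth["protospacers"]
        if r["planned_mismatches"] <= 1
    }
    tp = len(got & planted)
    print(f"{len(spacers)} spacers from {len(bacterial)} bacterial contigs; "
          f"{len(hits)} protospacer hits")
    print(f"spacer-route recovery vs planted truth: precision "
          f"{tp / len(got) if got else 0:.2f}, recall {tp / len(planted) if planted else 0:.2f}")
    print(f"host predictions: {len(merged)} rows over "
          f"{merged.vc_id.nunique() if len(merged) else 0} VCs "
          f"({int(merged.multi_phylum.sum()) if len(merged) else 0} multi-phylum rows)")


if __name__ == "__main__":
    main()
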
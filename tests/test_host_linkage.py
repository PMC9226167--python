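"""CRISPR array detection, protospacer matching, and the three host-linkage
routes with their merge."""

import numpy as np
import pytest

from viromeprofiler import host_linkage as hl
from viromeprofiler._rng import substream
from viromeprofiler.synthetic_community import ContigRecord

from _oracles import revcomp, sliding_hamming_hits


def _random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# detect_crispr_arrays


def _build_array(rng, repeat_len=30, spacer_len=32, n_spacers=3):
    repeat = _random_dna(rng, repeat_len)
    spacers = [_random_dna(rng, spacer_len) for _ in range(n_spacers)]
    # ensure boundary columns are not constant across copies
    while len({s[0] for s in spacers}) == 1 or len({s[-1] for s in spacers}) == 1:
        spacers = [_random_dna(rng, spacer_len) for _ in range(n_spacers)]
    array = repeat + "".join(s + repeat for s in spacers)
    return repeat, spacers, array


def test_constructed_array_recovered_exactly():
    rng = substream(1, "array_exact")
    repeat, spacers, array = _build_array(rng)
    seq = _random_dna(rng, 500) + array + _random_dna(rng, 500)
    found = hl.detect_crispr_arrays(ContigRecord("h", seq, "s"))
    assert [sp.sequence for sp in found] == spacers


def test_two_repeat_copies_are_not_an_array():
    rng = substream(2, "array_short")
    repeat = _random_dna(rng, 30)
    spacer = _random_dna(rng, 32)
    seq = _random_dna(rng, 300) + repeat + spacer + repeat + _random_dna(rng, 300)
    assert hl.detect_crispr_arrays(ContigRecord("h", seq, "s")) == []


def test_identical_spacers_rejected():
    rng = substream(3, "array_identical")
    repeat = _random_dna(rng, 30)
    spacer = _random_dna(rng, 32)
    seq = repeat + spacer + repeat + spacer + repeat
    assert hl.detect_crispr_arrays(ContigRecord("h", seq, "s")) == []


def test_planted_arrays_recovered_from_bundle(small_bundle):
    """Truth closure: every planted array's spacers come back verbatim."""
    hosts = [c for c in small_bundle.contigs if c.id.startswith("host")]
    recovered = {
        (sp.source_id, sp.sequence)
        for host in hosts
        for sp in hl.detect_crispr_arrays(host)
    }
    planted = {
        (rec["host_contig"], rec["spacer"]) for rec in small_bundle.truth["protospacers"]
    }
    assert planted == recovered


# ---------------------------------------------------------------------------
# match_protospacers


def test_exact_spacer_hit_at_planted_coordinate():
    rng = substream(4, "match_exact")
    target = _random_dna(rng, 2000)
    spacer = target[700:732]
    hits = hl.match_protospacers(
        [hl.SpacerRecord("sp", spacer, "h")], [ContigRecord("p", target, "s")]
    )
    forward = [h for h in hits if h.strand == "+"]
    assert any(h.position == 700 and h.mismatches == 0 for h in forward)


def test_two_substitutions_rejected_at_default_threshold():
    rng = substream(5, "match_2mm")
    target = _random_dna(rng, 2000)
    spacer = list(target[500:532])
    for pos in (5, 20):
        spacer[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[pos]]
    hits = hl.match_protospacers(
        [hl.SpacerRecord("sp", "".join(spacer), "h")], [ContigRecord("p", target, "s")]
    )
    assert not any(h.position == 500 for h in hits)
    relaxed = hl.match_protospacers(
        [hl.SpacerRecord("sp", "".join(spacer), "h")],
        [ContigRecord("p", target, "s")],
        max_mismatches=2,
    )
    assert any(h.position == 500 and h.mismatches == 2 for h in relaxed)


def test_matcher_equals_sliding_hamming_oracle():
    """Hit sets identical to a brute-force sliding-window Hamming scan."""
    rng = substream(6, "match_oracle")
    contigs = [ContigRecord(f"p{i}", _random_dna(rng, 400), "s") for i in range(5)]
    spacers = []
    for k in range(30):
        if k % 3 == 0:  # planted with 0-2 substitutions
            src = contigs[int(rng.integers(0, 5))]
            start = int(rng.integers(0, len(src.sequence) - 30))
            sp = list(src.sequence[start : start + 30])
            for pos in rng.choice(30, size=int(rng.integers(0, 3)), replace=False):
                sp[pos] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(sp)
        else:
            seq = _random_dna(rng, 30)
        spacers.append(hl.SpacerRecord(f"sp{k}", seq, "h"))
    got = {
        (h.spacer_id, h.contig_id, h.position, h.strand, h.mismatches)
        for h in hl.match_protospacers(spacers, contigs, max_mismatches=1)
    }
    expected = set()
    for sp in spacers:
        for contig in contigs:
            for pos, mm in sliding_hamming_hits(sp.sequence, contig.sequence, 1):
                expected.add((sp.spacer_id, contig.id, pos, "+", mm))
            for pos, mm in sliding_hamming_hits(revcomp(sp.sequence), contig.sequence, 1):
                expected.add((sp.spacer_id, contig.id, pos, "-", mm))
    assert got == expected


def test_matching_is_strand_symmetric():
    rng = substream(7, "match_strand")
    target = _random_dna(rng, 1000)
    spacer = target[200:230]
    fwd = hl.match_protospacers(
        [hl.SpacerRecord("sp", spacer, "h")], [ContigRecord("p", target, "s")]
    )
    rc = hl.match_protospacers(
        [hl.SpacerRecord("sp", revcomp(spacer), "h")],
        [ContigRecord("p", revcomp(target), "s")],
    )
    assert {(h.position, h.mismatches) for h in fwd if h.strand == "+"} == {
        (len(target) - 30 - h.position, h.mismatches) for h in rc if h.strand == "+"
    }


def test_short_spacer_warns_but_is_searched():
    rng = substream(8, "match_short")
    target = _random_dna(rng, 200)
    spacer = target[50:66]  # 16 nt
    with pytest.warns(UserWarning, match="shorter than 18"):
        hits = hl.match_protospacers(
            [hl.SpacerRecord("sp", spacer, "h")], [ContigRecord("p", target, "s")]
        )
    assert any(h.position == 50 for h in hits)


def test_invalid_spacer_sequence_rejected():
    with pytest.raises(ValueError, match="ACGT"):
        hl.SpacerRecord("sp", "ACGTN", "h")


# ---------------------------------------------------------------------------
# linkage routes


def test_prophage_route_propagates_taxon():
    vcs = {"VC_0": {"phageA", "prophageB"}, "VC_1": {"phageC"}}
    taxa = {"prophageB": {"phylum": "Bacteroidetes", "genus": "Bacteroides",
                          "species": "Bacteroides fragilis"}}
    preds = hl.prophage_vc_links(vcs, taxa, rank="species")
    assert len(preds) == 1
    assert preds[0].vc_id == "VC_0" and preds[0].taxon == "Bacteroides fragilis"
    assert preds[0].route == "prophage"


def test_reference_route_requires_unanimity():
    vcs = {"VC_0": {"p1", "ref1", "ref2"}, "VC_1": {"p2", "ref3", "ref4"}, "VC_2": {"p3"}}
    hosts = {"ref1": "Streptococcaceae", "ref2": "Streptococcaceae",
             "ref3": "Streptococcaceae", "ref4": "Lachnospiraceae"}
    preds = hl.refseq_cocluster_links(vcs, hosts)
    assert [(p.vc_id, p.taxon, p.rank) for p in preds] == [
        ("VC_0", "Streptococcaceae", "family")
    ]


def test_merge_flags_multi_phylum_and_dedups():
    preds = [
        hl.HostPrediction("VC_0", "Firmicutes", "phylum", "spacer", ("sp1",)),
        hl.HostPrediction("VC_0", "Firmicutes", "phylum", "prophage", ("c1",)),
        hl.HostPrediction("VC_1", "Firmicutes", "phylum", "spacer", ("sp2",)),
        hl.HostPrediction("VC_1", "Bacteroidetes", "phylum", "spacer", ("sp3",)),
    ]
    merged = hl.merge_host_predictions(preds)
    vc0 = merged[merged.vc_id == "VC_0"]
    assert len(vc0) == 1 and vc0.iloc[0]["routes"] == "prophage,spacer"
    assert not vc0.iloc[0]["multi_phylum"]
    vc1 = merged[merged.vc_id == "VC_1"]
    assert len(vc1) == 2 and vc1["multi_phylum"].all()


def test_merge_of_empty_input_is_empty():
    merged = hl.merge_host_predictions([])
    assert merged.empty


def test_planted_links_recovered_with_perfect_precision(small_bundle):
    """Spacer route on the bundle: every planted host-phage pair recovered
    (recall 1.0) and nothing else (precision 1.0); planted 2-mismatch
    decoys are excluded at the default threshold."""
    hosts = [c for c in small_bundle.contigs if c.id.startswith("host")]
    phages = [c for c in small_bundle.contigs if not c.id.startswith("host")]
    spacers = [sp for h in hosts for sp in hl.detect_crispr_arrays(h)]
    rng = substream(9, "decoys")
    decoys = []
    for k, phage in enumerate(phages[:3]):
        start = int(rng.integers(0, phage.length - 32))
        sp = list(phage.sequence[start : start + 32])
        for pos in rng.choice(np.arange(1, 31), size=2, replace=False):
            sp[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sp[pos]]
        decoys.append(hl.SpacerRecord(f"decoy{k}", "".join(sp), "decoy_host"))
    hits = hl.match_protospacers(spacers + decoys, phages, max_mismatches=1)
    got_pairs = set()
    source_of = {sp.spacer_id: sp.source_id for sp in spacers + decoys}
    for h in hits:
        got_pairs.add((source_of[h.spacer_id], h.contig_id))
    planted_pairs = {
        (rec["host_contig"], rec["target_phage"])
        for rec in small_bundle.truth["protospacers"]
        if rec["planned_mismatches"] <= 1
    }
    assert got_pairs == planted_pairs  # recall and precision 1.0, no decoys
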
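"""Nine-gene family classification, subfamily delineation, the Crassvirales
two-marker rule, and prophage boundary extraction from depth profiles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from viromeprofiler import lineage_markers as lm
from viromeprofiler import synthetic_community as sc
from viromeprofiler._rng import substream


@pytest.fixture(scope="module")
def family_markers():
    return lm.MarkerGeneSet("family_core", sc.load_family_markers())


@pytest.fixture(scope="module")
def one_family_genome():
    contigs, proteins, _ = sc.generate_marker_family((1,), 0.1, seed=31)
    cid = contigs[0].id
    return cid, contigs[0].length, proteins[cid]


# ---------------------------------------------------------------------------
# classify_family


def test_generated_genome_is_family_member(one_family_genome, family_markers):
    cid, length, proteins = one_family_genome
    res = lm.classify_family(cid, length, proteins, family_markers)
    assert res.family and len(res.marker_hits) == 9


def test_deleting_terminase_breaks_strict_but_not_relaxed(one_family_genome, family_markers):
    cid, length, proteins = one_family_genome
    # ORFs are emitted marker-first in seed order; drop the terminase homolog
    terminase_orf = f"{cid}_0"
    without = {p: s for p, s in proteins.items() if p != terminase_orf}
    strict = lm.classify_family(cid, length, without, family_markers)
    assert not strict.family
    relaxed = lm.classify_family(cid, length, without, family_markers, relaxed=True)
    assert not relaxed.family  # terminase is one of the four structural genes
    # dropping a non-structural marker instead: relaxed mode tolerates it
    polymerase_orf = f"{cid}_4"
    without_pol = {p: s for p, s in proteins.items() if p != polymerase_orf}
    assert not lm.classify_family(cid, length, without_pol, family_markers).family
    assert lm.classify_family(cid, length, without_pol, family_markers, relaxed=True).family


def test_short_contig_fails_length_rule(one_family_genome, family_markers):
    cid, _, proteins = one_family_genome
    res = lm.classify_family(cid, 20_000, proteins, family_markers)
    assert not res.family
    assert len(res.marker_hits) == 9  # markers all present; length is the gate


def test_membership_is_monotone_in_protein_set(one_family_genome, family_markers):
    cid, length, proteins = one_family_genome
    rng = substream(1, "extra_protein")
    extra = dict(proteins)
    extra[f"{cid}_999"] = "".join(
        np.array(list(sc.AMINO_ACIDS))[rng.integers(0, 20, size=200)]
    )
    assert lm.classify_family(cid, length, extra, family_markers).family


def test_empty_marker_set_errors():
    with pytest.raises(ValueError, match="empty"):
        lm.MarkerGeneSet("x", {})


# ---------------------------------------------------------------------------
# assign_subfamilies


def test_planted_subfamilies_recovered(marker_family_pcs):
    labels = marker_family_pcs["labels"]
    membership = marker_family_pcs["membership"]
    ids = sorted(labels)
    assigned = lm.assign_subfamilies(ids, membership, k=3)
    ari = adjusted_rand_score([labels[c] for c in ids], [assigned[c] for c in ids])
    assert ari == 1.0


def test_k1_gives_single_label(marker_family_pcs):
    ids = sorted(marker_family_pcs["labels"])
    assigned = lm.assign_subfamilies(ids, marker_family_pcs["membership"], k=1)
    assert set(assigned.values()) == {"alpha"}


def test_assignment_is_input_order_invariant(marker_family_pcs):
    membership = marker_family_pcs["membership"]
    ids = sorted(marker_family_pcs["labels"])
    base = lm.assign_subfamilies(ids, membership, k=3)
    assert lm.assign_subfamilies(list(reversed(ids)), membership, k=3) == base


def test_duplicate_profiles_share_a_label(marker_family_pcs):
    membership = dict(marker_family_pcs["membership"])
    ids = sorted(marker_family_pcs["labels"])
    membership["clone"] = set(membership[ids[0]])
    assigned = lm.assign_subfamilies(ids + ["clone"], membership, k=3)
    assert assigned["clone"] == assigned[ids[0]]


def test_too_few_members_errors(marker_family_pcs):
    ids = sorted(marker_family_pcs["labels"])[:2]
    with pytest.raises(ValueError, match="members"):
        lm.assign_subfamilies(ids, marker_family_pcs["membership"], k=3)


# ---------------------------------------------------------------------------
# classify_crassvirales


@pytest.fixture(scope="module")
def crass_like_proteins():
    rng = substream(2, "crass_test")
    markers = sc.load_crass_markers()
    return {
        "c_0": sc.diverge_protein(markers["crass_terminase"], 0.1, rng),
        "c_1": sc.diverge_protein(markers["crass_polymerase"], 0.1, rng),
    }


def test_both_markers_and_length_flag_crassvirales(crass_like_proteins):
    markers = sc.load_crass_markers()
    assert lm.classify_crassvirales(
        "c", 80_000, crass_like_proteins,
        markers["crass_terminase"], markers["crass_polymerase"],
    )


def test_short_contig_not_flagged(crass_like_proteins):
    markers = sc.load_crass_markers()
    assert not lm.classify_crassvirales(
        "c", 60_000, crass_like_proteins,
        markers["crass_terminase"], markers["crass_polymerase"],
    )


def test_single_marker_not_flagged(crass_like_proteins):
    markers = sc.load_crass_markers()
    only_terminase = {"c_0": crass_like_proteins["c_0"]}
    assert not lm.classify_crassvirales(
        "c", 80_000, only_terminase,
        markers["crass_terminase"], markers["crass_polymerase"],
    )


def test_crassvirales_closed_loop_on_bundle(small_bundle):
    markers = sc.load_crass_markers()
    lengths = {c.id: c.length for c in small_bundle.contigs}
    flagged = [
        cid
        for cid in small_bundle.truth["lineage_of"]
        if lm.classify_crassvirales(
            cid, lengths[cid], small_bundle.proteins[cid],
            markers["crass_terminase"], markers["crass_polymerase"],
        )
    ]
    assert sorted(flagged) == sorted(small_bundle.truth["crassvirales_members"])


# ---------------------------------------------------------------------------
# extract_prophage_boundaries


def _step_profile(length, start, end, flank_depth=20.0, n_samples=3):
    depths = {}
    for i in range(n_samples):
        d = np.full(length, flank_depth)
        d[start:end] = 0.0
        depths[f"s{i}"] = d
    return lm.DepthProfile(
        "contig",
        depths,
        flank_intervals=[(0, max(start - 1000, 1)), (min(end + 1000, length), length)],
        candidate_interval=(start, end),
    )


def test_step_profile_extracts_exact_interval():
    """Noise-free step profile: the recovered genome length is exactly the
    planted 68,665 bp."""
    profile = _step_profile(205_884, 100_000, 168_665)
    interval, length = lm.extract_prophage_boundaries(profile)
    assert interval == (100_000, 168_665) and length == 68_665


def test_uniform_depth_has_no_discriminating_sample():
    depths = {"s0": np.full(50_000, 20.0)}
    profile = lm.DepthProfile(
        "c", depths, flank_intervals=[(0, 10_000)], candidate_interval=(15_000, 40_000)
    )
    with pytest.raises(ValueError, match="no discriminating sample"):
        lm.extract_prophage_boundaries(profile)


def test_boundaries_stable_under_poisson_noise():
    """Across 20 noisy seeds, boundaries stay within +/-50 bp of truth."""
    L, a, b = 120_000, 30_000, 90_000
    for seed in range(20):
        rng = substream(seed, "boundary_noise")
        d = rng.poisson(20.0, size=L).astype(float)
        d[a:b] = rng.poisson(0.3, size=b - a)
        profile = lm.DepthProfile(
            "c", {"s": d}, flank_intervals=[(0, 25_000), (95_000, L)],
            candidate_interval=(a, b),
        )
        (lo, hi), _ = lm.extract_prophage_boundaries(profile)
        assert abs(lo - a) <= 50 and abs(hi - b) <= 50


# ---------------------------------------------------------------------------
# lineage_prevalence


def test_prevalence_counts_bounded_by_group_sizes(small_bundle, small_alignments):
    from viromeprofiler import abundance_profiling as ap

    lengths = {c.id: c.length for c in small_bundle.contigs if not c.id.startswith("host")}
    vc_of = {cid: small_bundle.truth["lineage_of"][cid] for cid in lengths}
    layers = ap.profile_abundance(small_alignments.records, lengths, vc_of)
    lineage_of_unit = {lin: lin for lin in set(vc_of.values())}
    table = lm.lineage_prevalence(
        lineage_of_unit, layers["vc_relative"].values, small_bundle.metadata
    )
    n = small_bundle.spec.n_samples_per_group
    assert (table["present_control"] <= n).all() and (table["present_case"] <= n).all()
    assert (table[["n_control", "n_case"]] == n).all().all()


def test_absent_lineage_counts_zero(small_bundle):
    import pandas as pd

    abundance = pd.DataFrame(
        0.0, index=small_bundle.metadata.index, columns=["VC_X"]
    )
    table = lm.lineage_prevalence({"VC_X": "ghost"}, abundance, small_bundle.metadata)
    assert table.loc["ghost", ["present_control", "present_case"]].sum() == 0
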
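import warnings

import pytest

from viromeprofiler import genome_clustering as gc
from viromeprofiler import synthetic_community as sc


@pytest.fixture(scope="session")
def small_spec() -> sc.CommunitySpec:
    """A small but complete community design shared across tests."""
    return sc.CommunitySpec(
        seed=42,
        n_phage_genomes=8,
        n_host_genomes=3,
        n_samples_per_group=6,
        marker_family_spec=sc.MarkerFamilySpec(genomes_per_subfamily=(2, 2, 2)),
        n_crass_genomes=1,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec) -> sc.CommunityBundle:
    return sc.generate_community(small_spec)


@pytest.fixture(scope="session")
def small_alignments(small_bundle) -> sc.AlignmentSet:
    return sc.generate_alignments(small_bundle)


@pytest.fixture(scope="session")
def marker_family_pcs():
    """PC membership + subfamily truth for a planted 3x3 marker family.

    Divergence 0.05 within / 0.35 between subfamilies; the all-vs-all
    protein search is the expensive step, so it is computed once.
    """
    contigs, proteins, labels = sc.generate_marker_family((3, 3, 3), 0.05, seed=7)
    flat = {pid: s for prots in proteins.values() for pid, s in prots.items()}
    hits = gc.all_vs_all_hits(flat)
    pcs = gc.build_protein_clusters(hits, flat)
    membership = gc.pc_membership_from_clusters(
        pcs, {pid: pid.rsplit("_", 1)[0] for pid in flat}
    )
    return {
        "contigs": contigs,
        "proteins": proteins,
        "labels": labels,
        "membership": membership,
        "n_pcs": len(pcs),
    }


@pytest.fixture(autouse=True)
def _quiet_zero_row_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="samples with zero total abundance")
        yield
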
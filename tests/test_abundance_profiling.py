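"""Identity filter, coverage zeroing, RPKM, VC aggregation, closure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from viromeprofiler import abundance_profiling as ap
from viromeprofiler._rng import substream

from _oracles import brute_force_abundance, coverage_by_marking


def _records(rows):
    return pd.DataFrame(rows, columns=ap.RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# filter_identity


def test_identity_boundary_is_inclusive():
    records = _records(
        [
            ("c", 0, 100, 5, 0.90, "s"),
            ("c", 0, 100, 5, 0.899, "s"),
            ("c", 0, 100, 5, 1.0, "s"),
        ]
    )
    kept = ap.filter_identity(records)
    assert list(kept.identity) == [0.90, 1.0]


def test_empty_input_passes_through():
    assert len(ap.filter_identity(_records([]))) == 0


def test_identity_outside_unit_interval_errors():
    with pytest.raises(ValueError, match="identity"):
        ap.filter_identity(_records([("c", 0, 100, 5, 1.2, "s")]))


# ---------------------------------------------------------------------------
# horizontal_coverage


def test_union_arithmetic():
    assert ap.horizontal_coverage([(0, 50), (40, 80)], 100) == pytest.approx(0.80)


def test_no_records_means_zero_coverage():
    assert ap.horizontal_coverage([], 100) == 0.0


def test_interval_exceeding_contig_errors():
    with pytest.raises(ValueError):
        ap.horizontal_coverage([(50, 150)], 100)


@given(
    st.lists(
        st.tuples(st.integers(0, 198), st.integers(1, 60)).map(
            lambda t: (t[0], min(t[0] + t[1], 200))
        ),
        max_size=15,
    )
)
@settings(deadline=None, derandomize=True)
def test_coverage_union_property(intervals):
    """Union coverage equals per-position marking for arbitrary interval sets."""
    assert ap.horizontal_coverage(intervals, 200) == pytest.approx(
        coverage_by_marking(intervals, 200)
    )


def test_coverage_matches_marking_oracle():
    for seed in range(100):
        rng = substream(seed, "coverage_oracle")
        length = int(rng.integers(50, 500))
        n = int(rng.integers(0, 20))
        intervals = []
        for _ in range(n):
            s = int(rng.integers(0, length - 1))
            e = int(rng.integers(s + 1, length + 1))
            intervals.append((s, e))
        assert ap.horizontal_coverage(intervals, length) == pytest.approx(
            coverage_by_marking(intervals, length)
        )


# ---------------------------------------------------------------------------
# counts_with_coverage_zeroing


@pytest.mark.parametrize(
    "end,expected",
    [(80, 40.0), (70, 0.0), (75, 40.0)],  # coverage 0.80 / 0.70 / exactly 0.75
)
def test_coverage_zeroing_boundaries(end, expected):
    records = _records([("c", 0, end, 40, 0.95, "s")])
    out = ap.counts_with_coverage_zeroing(records, {"c": 100})
    assert out.values.loc["s", "c"] == expected
    assert out.coverage_mask.loc["s", "c"] == pytest.approx(end / 100)


# ---------------------------------------------------------------------------
# rpkm


def test_rpkm_arithmetic():
    counts = ap.AbundanceMatrix(
        pd.DataFrame({"c": [10.0]}, index=["s"]), layer="counts"
    )
    out = ap.rpkm(counts, {"c": 2000}, {"s": 1_000_000})
    assert out.values.loc["s", "c"] == pytest.approx(5.0)


def test_rpkm_zero_counts_and_library_scaling():
    counts = ap.AbundanceMatrix(
        pd.DataFrame({"c": [0.0, 8.0]}, index=["s1", "s2"]), layer="counts"
    )
    single = ap.rpkm(counts, {"c": 1000}, {"s1": 1e6, "s2": 1e6})
    double = ap.rpkm(counts, {"c": 1000}, {"s1": 2e6, "s2": 2e6})
    assert single.values.loc["s1", "c"] == 0.0
    assert single.values.loc["s2", "c"] == pytest.approx(2 * double.values.loc["s2", "c"])


def test_rpkm_zero_library_with_counts_errors():
    counts = ap.AbundanceMatrix(pd.DataFrame({"c": [5.0]}, index=["s"]), layer="counts")
    with pytest.raises(ValueError, match="library_size"):
        ap.rpkm(counts, {"c": 1000}, {"s": 0})


# ---------------------------------------------------------------------------
# aggregate_by_vc / relative_abundance


def test_vc_aggregation_sums_and_conserves():
    matrix = ap.AbundanceMatrix(
        pd.DataFrame({"c1": [5.0], "c2": [3.0], "c3": [2.0]}, index=["s"]), layer="rpkm"
    )
    vc_of = {"c1": "VC_0", "c2": "VC_0", "c3": "VC_1"}
    out = ap.aggregate_by_vc(matrix, vc_of)
    assert out.values.loc["s", "VC_0"] == pytest.approx(8.0)
    assert out.values.loc["s", "VC_1"] == pytest.approx(2.0)  # singleton unchanged
    assert out.values.to_numpy().sum() == pytest.approx(matrix.values.to_numpy().sum())


def test_unassigned_contig_errors_with_ids():
    matrix = ap.AbundanceMatrix(pd.DataFrame({"c1": [5.0]}, index=["s"]), layer="rpkm")
    with pytest.raises(KeyError, match="c1"):
        ap.aggregate_by_vc(matrix, {})


def test_relative_abundance_closure_and_zero_rows():
    matrix = ap.AbundanceMatrix(
        pd.DataFrame({"a": [4.0, 0.0], "b": [6.0, 0.0]}, index=["s1", "s2"]), layer="rpkm"
    )
    with pytest.warns(UserWarning, match="zero total"):
        rel = ap.relative_abundance(matrix)
    assert list(rel.values.loc["s1"]) == pytest.approx([0.4, 0.6])
    assert list(rel.values.loc["s2"]) == [0.0, 0.0]


def test_relative_abundance_column_permutation_invariant():
    values = pd.DataFrame({"a": [4.0], "b": [6.0], "c": [10.0]}, index=["s"])
    rel = ap.relative_abundance(ap.AbundanceMatrix(values, layer="rpkm"))
    rel_perm = ap.relative_abundance(
        ap.AbundanceMatrix(values[["c", "a", "b"]], layer="rpkm")
    )
    for col in "abc":
        assert rel.values.loc["s", col] == rel_perm.values.loc["s", col]


# ---------------------------------------------------------------------------
# prevalence bins & ranked-abundance curves


def test_prevalence_bins_follow_study_cutoffs():
    n_samples = 196
    data = pd.DataFrame(
        0.0, index=[f"s{i}" for i in range(n_samples)], columns=["rare", "core", "all"]
    )
    data.iloc[:19, 0] = 0.1  # 19/196 < 10% -> individual
    data.iloc[:60, 1] = 0.1  # 60/196 > 30% -> core-like
    data.iloc[:, 2] = 0.1
    rel = ap.AbundanceMatrix(data.div(data.sum(axis=1), axis=0), layer="relative")
    bins = ap.prevalence_bins(rel)
    assert bins.loc["rare", "bin"] == "individual"
    assert bins.loc["core", "bin"] == "core-like"
    assert bins.loc["all", "prevalence"] == 1.0


def test_ranked_abundance_curve_cumulates():
    row = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2}, name="s")
    assert list(ap.ranked_abundance_curve(row)) == pytest.approx([0.5, 0.8, 1.0])
    single = pd.Series({"a": 7.0}, name="s")
    assert list(ap.ranked_abundance_curve(single)) == [1.0]
    permuted = row[["c", "a", "b"]]
    assert list(ap.ranked_abundance_curve(permuted)) == pytest.approx([0.5, 0.8, 1.0])


# ---------------------------------------------------------------------------
# end-to-end


def test_pipeline_matches_brute_force_recomputation():
    """Full fixed-order pipeline equals a record-by-record recomputation on
    a random instance of up to 20 contigs x 6 samples."""
    rng = substream(21, "pipeline_oracle")
    contigs = {f"c{i:02d}": int(rng.integers(500, 2000)) for i in range(20)}
    vc_of = {c: f"VC_{i % 7}" for i, c in enumerate(sorted(contigs))}
    samples = [f"s{j}" for j in range(6)]
    rows = []
    for s in samples:
        for c, length in contigs.items():
            for _ in range(int(rng.integers(0, 12))):
                start = int(rng.integers(0, length - 50))
                end = int(rng.integers(start + 1, length + 1))
                rows.append(
                    (c, start, end, int(rng.integers(1, 20)), float(rng.uniform(0.7, 1.0)), s)
                )
    records = _records(rows)
    layers = ap.profile_abundance(records, contigs, vc_of, samples=samples)
    oracle = brute_force_abundance(records, contigs, vc_of)
    for s in samples:
        for c in contigs:
            assert layers["counts"].values.loc[s, c] == pytest.approx(oracle["counts"][s][c])
            assert layers["rpkm"].values.loc[s, c] == pytest.approx(oracle["rpkm"][s][c])
        for vc in set(vc_of.values()):
            assert layers["vc_relative"].values.loc[s, vc] == pytest.approx(
                oracle["vc_relative"][s][vc]
            )


def test_planted_abundance_recovered_from_alignments(small_bundle, small_alignments):
    """Recovered VC relative abundances track the planted abundances
    (mean per-sample Spearman rho >= 0.9 at default noise)."""
    bundle = small_bundle
    lengths = {c.id: c.length for c in bundle.contigs if not c.id.startswith("host")}
    vc_of = {cid: bundle.truth["lineage_of"][cid] for cid in lengths}
    layers = ap.profile_abundance(small_alignments.records, lengths, vc_of)
    rel = layers["vc_relative"].values
    planted = pd.DataFrame(0.0, index=rel.index, columns=sorted(set(vc_of.values())))
    for cid, lin in vc_of.items():
        planted[lin] += bundle.planted_abundance[cid]
    rhos = []
    for s in rel.index:
        if planted.loc[s].sum() > 0:
            rhos.append(spearmanr(planted.loc[s], rel.loc[s, planted.columns]).statistic)
    assert np.mean(rhos) >= 0.9
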
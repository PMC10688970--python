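"""Fragment counting, CPM/CPKM scaling, z-scores, and binned tracks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germtag.quant import (
    BedParseError,
    FragmentLibrary,
    binned_coverage,
    count_overlaps,
    cpkm,
    cpm,
    genotype_zscores,
    load_fragments,
    log2_bin_ratio,
    score_table,
    transposon_scores,
)

SIZES = {"2L": 100_000, "X": 50_000}


def make_lib(frags, label="lib", sizes=SIZES, library_size=None):
    df = pd.DataFrame(frags, columns=["chrom", "start", "end"])
    return FragmentLibrary(
        label=label,
        fragments=df,
        chrom_sizes=sizes,
        library_size=-1 if library_size is None else library_size,
    )


def brute_force_counts(frags: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Independent all-pairs overlap oracle (half-open, ≥1 bp)."""
    counts = np.zeros(len(intervals), dtype=int)
    for i, iv in enumerate(intervals.itertuples()):
        for fr in frags.itertuples():
            if fr.chrom == iv.chrom and fr.start < iv.end and fr.end > iv.start:
                counts[i] += 1
    return counts


class TestLoadFragments:
    def test_valid_records_define_library_size(self):
        bed = "2L\t10\t60\n2L\t500\t900\nX\t5\t55\n"
        lib = load_fragments(bed, "a", SIZES)
        assert len(lib) == 3 and lib.library_size == 3

    def test_empty_input_gives_empty_library(self):
        lib = load_fragments("\n", "a", SIZES)
        assert lib.library_size == 0
        with pytest.raises(ValueError):
            binned_coverage(lib)

    def test_out_of_bounds_rejected_and_counted(self):
        bed = "2L\t10\t60\nX\t49_990\t50_100\nchrUn\t0\t50\n".replace("_", "")
        lib = load_fragments(bed, "a", SIZES)
        assert len(lib) == 1 and lib.n_rejected == 2

    def test_malformed_line_reports_number(self):
        with pytest.raises(BedParseError, match="line 2"):
            load_fragments("2L\t1\t2\n2L\tnope\t5\n", "a", SIZES)


class TestCountOverlaps:
    def test_no_fragments_all_zero(self):
        lib = make_lib([])
        iv = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [100]})
        assert count_overlaps(lib, iv).tolist() == [0]

    def test_half_open_abutment_not_counted(self):
        lib = make_lib([("2L", 100, 200)])
        iv = pd.DataFrame(
            {"chrom": ["2L", "2L", "2L"], "start": [200, 0, 199], "end": [300, 100, 300]}
        )
        assert count_overlaps(lib, iv).tolist() == [0, 0, 1]

    def test_fragment_counted_in_every_overlapped_interval(self):
        lib = make_lib([("2L", 150, 260)])
        iv = pd.DataFrame({"chrom": ["2L", "2L"], "start": [100, 250], "end": [200, 400]})
        assert count_overlaps(lib, iv).tolist() == [1, 1]

    def test_random_fixture_matches_brute_force(self, rng):
        frags = pd.DataFrame(
            {
                "chrom": rng.choice(["2L", "X"], 1000),
                "start": rng.integers(0, 49_000, 1000),
            }
        )
        frags["end"] = frags["start"] + rng.integers(1, 1000, 1000)
        iv = pd.DataFrame(
            {"chrom": rng.choice(["2L", "X"], 50), "start": rng.integers(0, 49_000, 50)}
        )
        iv["end"] = iv["start"] + rng.integers(1, 2000, 50)
        lib = make_lib(frags.to_numpy().tolist())
        np.testing.assert_array_equal(count_overlaps(lib, iv), brute_force_counts(frags, iv))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        frags=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=0, max_size=60
        ),
        ivs=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=1, max_size=10
        ),
    )
    def test_property_matches_brute_force(self, frags, ivs):
        fdf = pd.DataFrame(
            [("2L", s, s + l) for s, l in frags], columns=["chrom", "start", "end"]
        )
        idf = pd.DataFrame(
            [("2L", s, s + l) for s, l in ivs], columns=["chrom", "start", "end"]
        )
        lib = make_lib(fdf.to_numpy().tolist())
        np.testing.assert_array_equal(count_overlaps(lib, idf), brute_force_counts(fdf, idf))


class TestScaling:
    def test_cpm_examples_exact(self):
        assert cpm(10, 1_000_000) == 10.0
        assert cpm(0, 1_000_000) == 0.0
        assert cpm(7, 350_000) == 20.0

    def test_cpm_zero_library_errors(self):
        with pytest.raises(ValueError):
            cpm(5, 0)

    def test_cpkm_examples_exact(self):
        assert cpkm(10, 1_000_000, 2_000) == 5.0
        assert cpkm(0, 1_000_000, 2_000) == 0.0
        assert cpkm(3, 500_000, 250) == 24.0

    def test_cpkm_zero_length_errors(self):
        with pytest.raises(ValueError):
            cpkm(3, 500_000, 0)

    def test_cpkm_invariant_under_joint_rescaling(self, rng):
        raw = rng.integers(0, 100, 20)
        base = cpkm(raw, 1_000_000, 500)
        np.testing.assert_allclose(cpkm(raw * 3, 3_000_000, 500), base)

    def test_cpm_column_sums_for_disjoint_cover(self, rng):
        # disjoint intervals jointly containing every fragment
        iv = pd.DataFrame(
            {"chrom": "2L", "start": np.arange(0, 100_000, 1000), "end": np.arange(1000, 101_000, 1000)}
        )
        starts = rng.integers(0, 99_000, 500)
        frags = [("2L", int(s), int(s) + 1) for s in starts]
        lib = make_lib(frags)
        total = cpm(count_overlaps(lib, iv), lib.library_size).sum()
        assert total == pytest.approx(1_000_000.0)


class TestGenotypeZscores:
    def test_zero_variance_triple_is_zero(self):
        t = pd.DataFrame({"bam": [5.0], "aly": [5.0], "wildtype": [5.0]})
        assert genotype_zscores(t).iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_hand_computed_case(self):
        t = pd.DataFrame({"bam": [0.0], "aly": [0.0], "wildtype": [3.0]})
        z = genotype_zscores(t).iloc[0].round(3)
        assert z.tolist() == [-0.707, -0.707, 1.414]

    def test_rows_sum_to_zero(self, rng):
        t = pd.DataFrame(rng.random((50, 3)), columns=["bam", "aly", "wildtype"])
        np.testing.assert_allclose(genotype_zscores(t).sum(axis=1), 0.0, atol=1e-9)

    def test_invariant_under_affine_transform(self, rng):
        t = pd.DataFrame(rng.random((20, 3)), columns=["bam", "aly", "wildtype"])
        z0 = genotype_zscores(t)
        z1 = genotype_zscores(t * 3.7 + 11.0)
        np.testing.assert_allclose(z0.to_numpy(), z1.to_numpy(), atol=1e-9)

    def test_missing_label_errors(self):
        with pytest.raises(KeyError, match="wildtype"):
            genotype_zscores(pd.DataFrame({"bam": [1.0], "aly": [2.0]}))


class TestTransposonScores:
    def test_formula_instance(self):
        sizes = {"TE1_consensus": 5_000}
        frags = [("TE1_consensus", i * 10, i * 10 + 50) for i in range(25)]
        lib = make_lib(frags, sizes=sizes, library_size=1_000_000)
        out = transposon_scores(lib, {"TE1_consensus": 5_000})
        assert out.loc["TE1_consensus", "cpkm"] == 5.0

    def test_absent_consensus_scores_zero(self):
        sizes = {"TE1": 5_000, "TE2": 1_000}
        lib = make_lib([("TE1", 0, 100)], sizes=sizes, library_size=10)
        out = transposon_scores(lib, {"TE1": 5_000, "TE2": 1_000})
        assert out.loc["TE2", "raw"] == 0 and out.loc["TE2", "cpkm"] == 0.0

    def test_unknown_consensus_errors(self):
        lib = make_lib([("TE1", 0, 100)], sizes={"TE1": 5_000})
        with pytest.raises(KeyError, match="TE9"):
            transposon_scores(lib, {"TE9": 500})

    def test_raw_counts_bounded_by_library_size(self, rng):
        sizes = {f"TE{i}": 2_000 for i in range(5)}
        frags = [
            (f"TE{int(rng.integers(0, 5))}", int(s), int(s) + 100)
            for s in rng.integers(0, 1_900, 200)
        ]
        lib = make_lib(frags, sizes=sizes)
        out = transposon_scores(lib, pd.Series(sizes))
        assert out["raw"].sum() <= lib.library_size


class TestBinnedCoverage:
    def test_tiling_with_short_last_bin(self):
        lib = make_lib([("2L", 0, 10)], sizes={"2L": 45_000})
        track = binned_coverage(lib, bin_size=20_000)
        assert track.bins[["start", "end"]].to_numpy().tolist() == [
            [0, 20_000],
            [20_000, 40_000],
            [40_000, 45_000],
        ]

    def test_fragment_inside_one_bin_counts_once(self):
        lib = make_lib([("2L", 100, 300)], sizes={"2L": 45_000}, library_size=1_000_000)
        track = binned_coverage(lib, bin_size=20_000)
        assert track.chrom_values("2L").tolist() == [1.0, 0.0, 0.0]

    def test_boundary_spanning_fragment_counts_in_both_bins(self):
        lib = make_lib([("2L", 19_900, 20_100)], sizes={"2L": 45_000}, library_size=1_000_000)
        track = binned_coverage(lib, bin_size=20_000)
        assert track.chrom_values("2L").tolist() == [1.0, 1.0, 0.0]


class TestLog2BinRatio:
    def test_equal_tracks_give_zero(self):
        lib = make_lib([("2L", 0, 10), ("2L", 30_000, 30_100)], sizes={"2L": 45_000})
        t = binned_coverage(lib, bin_size=20_000)
        assert log2_bin_ratio(t, t, 1.0).bins["value"].tolist() == [0.0, 0.0, 0.0]

    def test_doubling_gives_one_without_pseudocount(self):
        a = make_lib([("2L", 0, 10)] * 4, sizes={"2L": 20_000}, library_size=100)
        b = make_lib([("2L", 0, 10)] * 2, sizes={"2L": 20_000}, library_size=100)
        ratio = log2_bin_ratio(binned_coverage(a), binned_coverage(b), pseudocount=0.0)
        assert ratio.bins["value"].tolist() == [1.0]

    def test_pseudocount_case(self):
        a = make_lib([], sizes={"2L": 20_000}, library_size=1_000_000)
        b = make_lib([("2L", 0, 10)] * 4, sizes={"2L": 20_000}, library_size=1_000_000)
        ratio = log2_bin_ratio(binned_coverage(a), binned_coverage(b), pseudocount=1.0)
        assert ratio.bins["value"].iloc[0] == pytest.approx(np.log2(1 / 5), abs=1e-9)

    def test_binning_mismatch_errors(self):
        a = binned_coverage(make_lib([("2L", 0, 10)], sizes={"2L": 45_000}), bin_size=20_000)
        b = binned_coverage(make_lib([("2L", 0, 10)], sizes={"2L": 45_000}), bin_size=10_000)
        with pytest.raises(ValueError, match="binned"):
            log2_bin_ratio(a, b)


def test_score_table_carries_annotation_and_adds_per_library_columns():
    lib1 = make_lib([("2L", 0, 100)], label="a", library_size=1_000_000)
    lib2 = make_lib([("2L", 50, 150), ("2L", 60, 160)], label="b", library_size=2_000_000)
    iv = pd.DataFrame({"gene_id": ["g1"], "chrom": ["2L"], "start": [0], "end": [100]})
    out = score_table([lib1, lib2], iv, lengths=True)
    assert out.loc[0, "raw_a"] == 1 and out.loc[0, "raw_b"] == 2
    assert out.loc[0, "cpm_a"] == 1.0 and out.loc[0, "cpm_b"] == 1.0
    assert out.loc[0, "cpkm_a"] == 10.0
    assert out.loc[0, "gene_id"] == "g1"
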
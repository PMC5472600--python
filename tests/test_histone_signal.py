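import numpy as np
import pandas as pd
import pytest

from mullersig import (average_tss_window, compute_histone_matrix,
                       count_window_tags, log2_transform, normalize_by_library,
                       quantile_normalize, subtract_input)
from mullersig.models import GeneModel, TagLibrary, WindowTrack

from conftest import random_instance
from oracles import brute_histone_matrix, naive_quantile_normalize


def lib(positions, chrom="chr1", sample_id="t"):
    return TagLibrary(sample_id, {chrom: np.asarray(positions)})


class TestCountWindowTags:
    def test_counts_match_interval_membership(self):
        tracks = count_window_tags(lib([100, 600, 1100]), {"chr1": 5000})
        track = tracks["chr1"]
        # brute-force membership for every window
        for i, s in enumerate(track.starts):
            expected = sum(1 for p in (100, 600, 1100) if s <= p < s + 1050)
            assert track.values[i] == expected
        assert track.values[0] == 2          # window [0, 1050) holds 100, 600
        assert track.values[2] == 3          # window [100, 1150) holds all three

    @pytest.mark.parametrize("pos", [1000, 1337, 3001])
    def test_interior_tag_hits_exactly_21_windows(self, pos):
        track = count_window_tags(lib([pos]), {"chr1": 5000})["chr1"]
        hit = np.nonzero(track.values)[0]
        expected = [i for i, s in enumerate(track.starts) if s <= pos < s + 1050]
        assert list(hit) == expected
        assert len(hit) == 21  # width/step = 1050/50

    def test_tagless_chrom_gives_zero_track(self):
        tracks = count_window_tags(lib([10]), {"chr1": 2000, "chr2": 2000})
        assert not tracks["chr2"].values.any()

    def test_empty_library_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            count_window_tags(TagLibrary("x", {}), {"chr1": 100})

    def test_tag_chrom_missing_from_lengths_is_error(self):
        with pytest.raises(ValueError, match="chr9"):
            count_window_tags(lib([10], chrom="chr9"), {"chr1": 100})


class TestTrackOps:
    def test_library_normalization_divides(self):
        t = WindowTrack("chr1", [2.0, 3.0, 0.0])
        assert list(normalize_by_library(t, 10).values) == [0.2, 0.3, 0.0]
        with pytest.raises(ValueError):
            normalize_by_library(t, 0)

    def test_duplicating_tags_leaves_normalized_track_unchanged(self, rng):
        pos = rng.integers(0, 4000, size=50)
        one = count_window_tags(lib(pos), {"chr1": 5000})["chr1"]
        three = count_window_tags(lib(np.repeat(pos, 3)), {"chr1": 5000})["chr1"]
        a = normalize_by_library(one, 50).values
        b = normalize_by_library(three, 150).values
        np.testing.assert_array_equal(a, b)

    def test_subtract_and_add_back_is_identity(self):
        t = WindowTrack("chr1", [0.3, 0.1])
        c = WindowTrack("chr1", [0.1, 0.2])
        d = subtract_input(t, c)
        np.testing.assert_allclose(d.values, [0.2, -0.1])
        np.testing.assert_allclose(d.values + c.values, t.values)

    def test_grid_mismatch_is_error(self):
        with pytest.raises(ValueError, match="grid"):
            subtract_input(WindowTrack("chr1", [1.0]), WindowTrack("chr1", [1.0, 2.0]))

    def test_log2_floor_and_monotonicity(self, rng):
        eps = 1e-9
        t = WindowTrack("chr1", [1.0 - eps, -5.0, 0.0])
        out = log2_transform(t, eps).values
        assert out[0] == pytest.approx(0.0)
        assert out[1] == out[2] == pytest.approx(np.log2(eps))
        v = rng.normal(size=200)
        o = log2_transform(WindowTrack("chr1", v), eps).values
        order = np.argsort(v)
        assert np.all(np.diff(o[order]) >= 0)
        with pytest.raises(ValueError):
            log2_transform(t, 0.0)


class TestAverageTssWindow:
    def test_constant_track_scores_constant(self):
        tracks = {"chr1": WindowTrack("chr1", np.full(100, 3.5))}
        genes = [GeneModel("a", "chr1", "+", 1000, 2000),
                 GeneModel("b", "chr1", "-", 2000, 3000)]
        scores, missing = average_tss_window(tracks, genes)
        assert not missing
        assert set(scores.index) == {"a", "b"}
        assert (scores == 3.5).all()

    def test_toy_center_selection(self):
        # three windows with centers 4975, 5025, 5075; TSS=50, flank=5000
        # covered interval [-4950, 5050] -> centers 4975 and 5025 -> mean 1.5
        track = WindowTrack("chr1", [1.0, 2.0, 4.0], start0=4450)
        scores, missing = average_tss_window(
            {"chr1": track}, [GeneModel("g", "chr1", "+", 50, 100)], flank=5000)
        assert scores["g"] == pytest.approx(1.5)

    def test_mirror_symmetry_for_minus_strand(self, rng):
        """Mirroring tags and gene about the chromosome midpoint preserves score."""
        L = 100_000
        pos = rng.integers(0, L, size=2000)
        ctrl = rng.integers(0, L, size=2000)
        tss = 41_003
        gene = GeneModel("g", "chr1", "+", tss, tss + 100)
        mirror_gene = GeneModel("g", "chr1", "-", L - tss - 100, L - tss)
        score, mirrored = [], []
        for tags, c_tags, g in [(pos, ctrl, gene),
                                (L - 1 - pos, L - 1 - ctrl, mirror_gene)]:
            pairs = [(TagLibrary("t", {"chr1": tags}),
                      TagLibrary("i", {"chr1": c_tags}))]
            norm, raw = compute_histone_matrix(pairs, [g], {"chr1": L})
            (score if g is gene else mirrored).append(raw.values.loc["g", "t"])
        assert score[0] == pytest.approx(mirrored[0], abs=1e-9)

    def test_gene_off_track_flagged_missing(self):
        tracks = {"chr1": WindowTrack("chr1", np.ones(10))}
        genes = [GeneModel("far", "chr1", "+", 900_000, 901_000),
                 GeneModel("off", "chr5", "+", 0, 10)]
        scores, missing = average_tss_window(tracks, genes)
        assert sorted(missing) == ["far", "off"] and scores.empty


class TestQuantileNormalize:
    def test_hand_example(self):
        df = pd.DataFrame({"A": [5.0, 3.0], "B": [2.0, 4.0]}, index=["g1", "g2"])
        out = quantile_normalize(df)
        # sorted-row means are [2.5, 4.5]
        assert list(out["A"]) == [4.5, 2.5]
        assert list(out["B"]) == [2.5, 4.5]

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"A": [1.0, 7.0, 3.0], "B": [1.0, 7.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_ties_get_mean_of_tied_reference_values(self):
        df = pd.DataFrame({"A": [1.0, 1.0, 9.0], "B": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["A"].iloc[0] == out["A"].iloc[1] == pytest.approx(ref[:2].mean())
        assert out["A"].iloc[2] == pytest.approx(ref[2])

    def test_contract_on_random_matrices(self, rng):
        from scipy.stats import spearmanr
        for _ in range(10):
            df = pd.DataFrame(rng.normal(size=(30, 4)))
            out = quantile_normalize(df)
            sorted_cols = np.sort(out.to_numpy(), axis=0)
            for j in range(1, 4):
                np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0],
                                           atol=1e-12)
            for c in df.columns:
                assert spearmanr(df[c], out[c]).statistic == pytest.approx(1.0)
            pd.testing.assert_frame_equal(quantile_normalize(out), out,
                                          check_exact=False, atol=1e-12)

    def test_agrees_with_naive_oracle(self, rng):
        df = pd.DataFrame(rng.integers(0, 6, size=(40, 3)).astype(float))
        pd.testing.assert_frame_equal(quantile_normalize(df),
                                      naive_quantile_normalize(df),
                                      check_exact=False, atol=1e-12)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"A": [1.0, np.nan], "B": [1.0, 2.0]}))


class TestComputeHistoneMatrix:
    def test_degenerate_identical_pairs_give_constant_matrix(self):
        pos = np.array([100, 500, 900])
        pairs = [(lib(pos, sample_id="t1"), lib(pos, sample_id="i1")),
                 (lib(pos, sample_id="t2"), lib(pos, sample_id="i2"))]
        genes = [GeneModel("g", "chr1", "+", 500, 600)]
        norm, raw = compute_histone_matrix(pairs, genes, {"chr1": 3000})
        assert np.allclose(raw.values.to_numpy(), np.log2(1e-9))
        assert np.allclose(norm.values.to_numpy(), np.log2(1e-9))

    def test_equals_brute_force_on_random_instance(self, rng):
        genes, pairs, chrom_lengths = random_instance(rng, n_genes=12, n_tags=300)
        norm, _ = compute_histone_matrix(pairs, genes, chrom_lengths)
        expected = brute_histone_matrix(pairs, genes, chrom_lengths)
        pd.testing.assert_frame_equal(norm.values, expected, check_exact=False,
                                      atol=1e-9, check_names=False)

    def test_duplicate_sample_id_rejected(self):
        pairs = [(lib([1], sample_id="t"), lib([2])),
                 (lib([3], sample_id="t"), lib([4]))]
        with pytest.raises(ValueError, match="duplicate"):
            compute_histone_matrix(pairs, [GeneModel("g", "chr1", "+", 0, 10)],
                                   {"chr1": 2000})
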
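"""Promoter scanning, permutation null and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbescan.motif import build_pwm
from nbescan.scan import (
    NullScoreDistribution,
    PromoterScanModel,
    PromoterWindow,
    average_profile,
    best_match_per_gene,
    build_null,
    compare_groups,
    empirical_pvalue,
    heatmap_matrix,
    positional_boxplot_stats,
    scan_windows,
)
from nbescan.simulate import PromoterSimConfig, simulate_promoters

from conftest import NBE, linear_scan_pvalue


def make_window(sequence, gene_id="g", group=None):
    return PromoterWindow(gene_id=gene_id, sequence=sequence, group=group)


@pytest.fixture(scope="module")
def small_null(pwm):
    windows = [make_window("ACGT" * 51, gene_id=f"w{i}") for i in range(5)]
    return build_null(windows, pwm, n=2000, seed=11)


class TestEmpiricalPvalue:
    def test_bounds(self):
        null = NullScoreDistribution(np.sort(np.arange(100.0)), "window_permute", 0)
        assert empirical_pvalue(-10.0, null) == 1.0
        assert empirical_pvalue(1e9, null) == pytest.approx(1 / 101)

    def test_max_score_with_large_null(self):
        null = NullScoreDistribution(np.zeros(100_000), "window_permute", 0)
        assert empirical_pvalue(1.0, null) == pytest.approx(9.9999e-6, rel=1e-4)

    def test_median_score(self):
        null = NullScoreDistribution(np.sort(np.arange(101.0)), "window_permute", 0)
        # 51 null scores >= 50 -> p = 52/102
        assert empirical_pvalue(50.0, null) == pytest.approx(52 / 102)

    def test_agrees_with_linear_scan_oracle(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=3000)
        null = NullScoreDistribution(np.sort(raw), "window_permute", 0)
        for score in rng.normal(size=50):
            assert empirical_pvalue(score, null) == linear_scan_pvalue(score, raw)

    @settings(max_examples=30, derandomize=True)
    @given(scores=st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    def test_monotone_in_score(self, scores):
        rng = np.random.default_rng(7)
        null = NullScoreDistribution(np.sort(rng.normal(size=500)),
                                     "window_permute", 0)
        ordered = sorted(scores)
        pvals = [empirical_pvalue(s, null) for s in ordered]
        assert all(p1 >= p2 for p1, p2 in zip(pvals, pvals[1:]))
        assert all(1 / 501 <= p <= 1 for p in pvals)


class TestBuildNull:
    def test_degenerate_all_a_windows(self, pwm):
        windows = [make_window("A" * 201)]
        null = build_null(windows, pwm, n=1000, seed=0)
        assert np.ptp(null.scores) == 0.0
        assert empirical_pvalue(null.scores[0] + 1.0, null) == pytest.approx(1 / 1001)

    def test_seed_reproducibility(self, pwm):
        windows = [make_window("ACGTACG" * 29, gene_id=f"w{i}") for i in range(3)]
        a = build_null(windows, pwm, n=1500, seed=42)
        b = build_null(windows, pwm, n=1500, seed=42)
        assert np.array_equal(a.scores, b.scores)
        c = build_null(windows, pwm, n=1500, seed=43)
        assert not np.array_equal(a.scores, c.scores)

    def test_composition_preserved_single_letter_windows(self, pwm):
        # windows containing only C and G can only yield CG k-mers
        windows = [make_window("CG" * 100)]
        null = build_null(windows, pwm, n=1000, seed=1)
        cg_scores = set()
        from itertools import product
        from nbescan.motif import encode
        for kmer in product("CG", repeat=7):
            codes = encode("".join(kmer))
            cg_scores.add(round(float(pwm.scores[np.arange(7), codes].sum()), 9))
        assert {round(float(s), 9) for s in null.scores} <= cg_scores

    def test_ambiguous_bases_excluded(self, pwm):
        windows = [make_window("ACGTNAC" * 29)]
        null = build_null(windows, pwm, n=1200, seed=2)
        assert np.all(np.isfinite(null.scores))
        assert null.n == 1200

    def test_validation(self, pwm):
        with pytest.raises(ValueError):
            build_null([], pwm, n=2000, seed=0)
        with pytest.raises(ValueError):
            build_null([make_window("A" * 201)], pwm, n=10, seed=0)
        with pytest.raises(ValueError):
            build_null([make_window("A" * 201)], pwm, n=2000, seed=0,
                       scheme="bogus")

    def test_kmer_shuffle_scheme(self, pwm):
        windows = [make_window("ACGTACG" * 29)]
        null = build_null(windows, pwm, n=1000, seed=3, scheme="kmer_shuffle")
        assert null.scheme == "kmer_shuffle"
        assert null.n == 1000


class TestScanWindows:
    def test_all_a_window_flat_track(self, pwm, small_null):
        track = scan_windows([make_window("A" * 201)], pwm, small_null)[0]
        # positions 4 and 7 of CUGAGGA are A; an all-A 7-mer hits 2 on-bases
        on, off = np.log2(0.85 / 0.25), np.log2(0.05 / 0.25)
        expected = 2 * on + 5 * off
        assert np.allclose(track.scores, expected)
        assert 7 * off < expected  # sanity on the closed forms

    def test_planted_consensus_is_argmax(self, pwm, small_null):
        seq = list("A" * 201)
        start = 25 + 50  # offset +25
        seq[start:start + 7] = "CTGAGGA"
        track = scan_windows([make_window("".join(seq))], pwm, small_null)[0]
        assert track.offsets[np.nanargmax(track.scores)] == 25

    def test_determinism_and_offsets(self, pwm, small_null):
        seq = ("ACGT" * 51)[:201]
        windows = [make_window(seq, gene_id="a"), make_window(seq, gene_id="b")]
        t1, t2 = scan_windows(windows, pwm, small_null)
        assert np.array_equal(t1.scores, t2.scores)
        assert np.array_equal(t1.pvalues, t2.pvalues)
        assert t1.offsets[0] == -50
        assert t1.offsets[-1] == 150 - 7 + 1
        assert t1.offsets.size == 201 - 7 + 1

    def test_ambiguous_positions_are_nan(self, pwm, small_null):
        seq = "A" * 100 + "N" + "A" * 100
        track = scan_windows([make_window(seq)], pwm, small_null)[0]
        nan_offsets = track.offsets[np.isnan(track.scores)]
        # every k-mer covering index 100 (offset +50) is unscoreable
        assert list(nan_offsets) == list(range(44, 51))
        assert np.isnan(track.pvalues[np.isnan(track.scores)]).all()

    def test_short_window_skipped(self, pwm, small_null):
        windows = [make_window("ACG", gene_id="short"),
                   make_window("ACGT" * 51, gene_id="ok")]
        tracks = scan_windows(windows, pwm, small_null)
        assert [t.gene_id for t in tracks] == ["ok"]


class TestBestMatch:
    def test_planted_and_tie_rule(self, pwm, small_null):
        seq = list("A" * 201)
        seq[60:67] = "CTGAGGA"
        seq[80:87] = "CTGAGGA"
        window = make_window("".join(seq))
        track = scan_windows([window], pwm, small_null)[0]
        # two identical maxima; 5'-most wins
        assert best_match_per_gene(track, window, region=(0, 50)) == "CTGAGGA"
        idx = np.nanargmax(track.scores[track.region_slice((0, 50))])
        assert track.offsets[track.region_slice((0, 50))][idx] == 10

    def test_all_a_window(self, pwm, small_null):
        window = make_window("A" * 201)
        track = scan_windows([window], pwm, small_null)[0]
        assert best_match_per_gene(track, window, region=(0, 50)) == "AAAAAAA"

    def test_unscoreable_region_warns_and_returns_none(self, pwm, small_null):
        window = make_window("A" * 95 + "N" * 60 + "A" * 46)
        track = scan_windows([window], pwm, small_null)[0]
        with pytest.warns(UserWarning):
            assert best_match_per_gene(track, window, region=(50, 100)) is None


class TestProfilesAndHeatmap:
    def test_single_track_profile_identity(self, pwm, small_null):
        track = scan_windows([make_window("ACGT" * 51)], pwm, small_null)[0]
        profile = average_profile([track])
        assert np.allclose(profile["mean_similarity_index"],
                           track.similarity_index, equal_nan=True)

    def test_embedded_motifs_localize_profile(self, pwm):
        config = PromoterSimConfig(n_paused=300, n_non_paused=0,
                                   embed_p_paused=0.8, seed=9)
        windows, _ = simulate_promoters(config)
        model = PromoterScanModel(windows, pwm)
        res = model.fit(null_n=5000, seed=10)
        profile = res.average_profile()
        argmax_offset = profile.loc[
            profile["mean_similarity_index"].idxmax(), "offset"]
        assert 20 <= argmax_offset <= 30

    def test_background_profile_is_flat(self, pwm):
        config = PromoterSimConfig(n_paused=400, n_non_paused=0,
                                   embed_p_paused=0.0, seed=12)
        windows, manifest = simulate_promoters(config)
        assert manifest == []
        res = PromoterScanModel(windows, pwm).fit(null_n=5000, seed=13)
        profile = res.average_profile()
        vals = profile["mean_similarity_index"].to_numpy()
        per_gene = np.stack([t.similarity_index for t in res.tracks])
        se = float(np.nanstd(per_gene) / np.sqrt(per_gene.shape[0]))
        # the range of ~195 per-offset means of 400 genes stays at the
        # Monte-Carlo noise scale (iid range of ~200 means is ~5.5 s.e.)
        assert np.ptp(vals) < 8 * se

    def test_heatmap_ordering_and_shape(self, pwm, small_null):
        heights = {"g1": 30, "g2": 10, "g3": 20}
        windows = []
        for gene, offset in heights.items():
            seq = list("A" * 201)
            # plant motifs with distinct mismatch counts for distinct heights
            mism = {"g1": 0, "g2": 2, "g3": 1}[gene]
            kmer = list("CTGAGGA")
            for j in range(mism):
                kmer[j] = "A" if kmer[j] != "A" else "C"
            seq[50 + 20:50 + 27] = "".join(kmer)
            windows.append(make_window("".join(seq), gene_id=gene))
        tracks = scan_windows(windows, pwm, small_null)
        ordered = heatmap_matrix(tracks, order="by_max_index")
        assert list(ordered.index) == ["g1", "g3", "g2"]
        as_input = heatmap_matrix(tracks, order="input")
        assert list(as_input.index) == ["g1", "g2", "g3"]
        assert ordered.shape == (3, 195)

    def test_boxplot_bins(self, pwm, small_null):
        seq = list("A" * 201)
        seq[75:82] = "CTGAGGA"  # offset +25
        windows = [make_window("".join(seq), gene_id=f"g{i}") for i in range(4)]
        tracks = scan_windows(windows, pwm, small_null)
        stats = positional_boxplot_stats(tracks)
        values = stats["values"]
        top = max(values, key=lambda c: values[c].mean())
        assert top in (20, 30)  # the 20+-5 and 30+-5 bins contain +25
        assert stats["adjacent_welch_p"][(20, 30)] == 1.0  # identical bins
        zero_width = positional_boxplot_stats(tracks, centers=[25],
                                              halfwidth=0)
        track_at_25 = tracks[0].similarity_index[
            tracks[0].offsets.tolist().index(25)]
        assert zero_width["values"][25][0] == pytest.approx(track_at_25)


class TestCompareGroups:
    def test_identical_groups(self, pwm, small_null):
        windows = [make_window("ACGT" * 51, gene_id=f"a{i}") for i in range(3)]
        tracks = scan_windows(windows, pwm, small_null)
        res = compare_groups({"x": tracks, "y": tracks})
        assert res.ks_statistic == 0.0
        assert res.ks_pvalue == pytest.approx(1.0)

    def test_label_swap_symmetry(self, pwm):
        config = PromoterSimConfig(n_paused=40, n_non_paused=40, seed=21)
        windows, _ = simulate_promoters(config)
        res = PromoterScanModel(windows, pwm).fit(null_n=2000, seed=22)
        fwd = res.compare_groups()
        by_group = {}
        for t in res.tracks:
            by_group.setdefault(t.group, []).append(t)
        swapped = compare_groups(
            {"non_paused": by_group["non_paused"],
             "paused": by_group["paused"]})
        assert swapped.ks_pvalue == pytest.approx(fwd.ks_pvalue)
        assert swapped.welch_t_pvalue == pytest.approx(fwd.welch_t_pvalue)

    def test_small_group_rejected(self, pwm, small_null):
        tracks = scan_windows([make_window("ACGT" * 51)], pwm, small_null)
        with pytest.raises(ValueError):
            compare_groups({"x": tracks, "y": tracks})

    def test_gap_detection_monotone_in_embedding_gap(self, pwm):
        """Stronger embed-probability gaps give smaller KS p-values."""
        pvals = []
        for gap_p in (0.1, 0.35, 0.6):
            config = PromoterSimConfig(
                n_paused=150, n_non_paused=150,
                embed_p_paused=gap_p, embed_p_non_paused=0.1, seed=31)
            windows, _ = simulate_promoters(config)
            res = PromoterScanModel(windows, pwm).fit(null_n=3000, seed=32)
            pvals.append(res.compare_groups().ks_pvalue)
        assert pvals[0] > pvals[1] > pvals[2]
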
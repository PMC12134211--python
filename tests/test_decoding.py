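"""Blob detection, round calling, trap classification, read counting."""

import numpy as np
import pandas as pd
import pytest

from poolscreen.barcodes import BarcodeSeq
from poolscreen.decoding import (
    CALL_AMBIGUOUS,
    CALL_NONE,
    DecodeParams,
    accumulate_mask,
    background_stats,
    call_round,
    classify_trap,
    compare_frequencies,
    count_amplicon_reads,
    decode_image_stack,
    decode_signal_table,
    detect_blob_mask,
    summarize_experiment,
)


class TestBackgroundStats:
    def test_recovers_gaussian_parameters(self, rng):
        x = rng.normal(100, 10, size=100_000)
        mu, sigma = background_stats(x)
        assert mu == pytest.approx(100, abs=0.3)
        assert sigma == pytest.approx(10, abs=0.3)

    def test_constant_pixels(self):
        with pytest.warns(UserWarning):
            mu, sigma = background_stats(np.full(200, 7.0))
        assert (mu, sigma) == (7.0, 0.0)

    def test_robust_to_bright_blob_tail(self, rng):
        """1% of pixels at 1e4 barely move the fitted background mean."""
        x = rng.normal(100, 10, size=100_000)
        x[:1000] = 1e4
        mu, _ = background_stats(x)
        assert mu == pytest.approx(100, abs=1.0)

    def test_requires_enough_pixels(self):
        with pytest.raises(ValueError):
            background_stats(np.zeros(50))


class TestMasks:
    def test_threshold_mask(self, rng):
        params = DecodeParams()
        img = rng.normal(100, 10, size=(20, 20))
        img[5:8, 5:8] = 100 + 20 * 10  # 20 sigma blob
        mask = detect_blob_mask(img, 100, 10, params)
        assert mask[5:8, 5:8].all()
        # expected false positives ~ npix * P(Z > 5) ~ 1e-4: none here
        assert mask.sum() == 9

    def test_all_below_threshold_empty(self):
        params = DecodeParams()
        assert not detect_blob_mask(np.full((10, 10), 50.0), 100, 10, params).any()

    @pytest.mark.parametrize("count,kept", [(7, True), (4, True), (3, False), (0, False)])
    def test_consensus_requires_half_of_rounds(self, count, kept):
        params = DecodeParams()
        masks = [np.array([[i < count]]) for i in range(7)]
        assert accumulate_mask(masks, params)[0, 0] == kept


class TestCallRound:
    params = DecodeParams(area_min_px=4)
    thr = [1.0, 1.0, 1.0, 1.0]

    def call(self, intensities, areas=(10, 10, 10, 10)):
        return call_round(intensities, areas, self.thr, self.params).call

    def test_single_surviving_channel(self):
        assert self.call([10, 0, 0, 0]) == 0

    def test_dominant_channel_wins(self):
        assert self.call([10, 4, 0, 0]) == 0  # 10 >= 2x4

    def test_near_tie_is_ambiguous(self):
        assert self.call([10, 6, 0, 0]) == CALL_AMBIGUOUS  # 10 < 12

    def test_no_survivors(self):
        assert self.call([0.5, 0.5, 0.5, 0.5]) == CALL_NONE

    def test_area_rule_voids_channel(self):
        assert self.call([10, 8, 0, 0], areas=(10, 2, 0, 0)) == 0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            self.call([-1, 0, 0, 0])


class TestClassifyTrap:
    def test_all_none_is_no_signal(self, codebook85):
        assert classify_trap([CALL_NONE] * 7, codebook85).category == "no_signal"

    def test_any_ambiguous_is_double(self, codebook85):
        calls = list(codebook85.codewords[0][:6]) + [CALL_AMBIGUOUS]
        assert classify_trap(calls, codebook85).category == "double_signal"

    def test_incomplete_word_unassigned(self, codebook85):
        calls = list(codebook85.codewords[0])
        calls[2] = CALL_NONE
        assert classify_trap(calls, codebook85).category == "unassigned"

    def test_exact_word_decoded(self, codebook85):
        d = classify_trap(list(codebook85.codewords[5]), codebook85)
        assert d.category == "decoded" and d.barcode_index == 5 and d.n_corrected == 0

    def test_precedence_ambiguous_beats_missing(self, codebook85):
        calls = [CALL_NONE, CALL_AMBIGUOUS] + list(codebook85.codewords[0][2:])
        assert classify_trap(calls, codebook85).category == "double_signal"


def test_decode_signal_table_matches_scalar_path(codebook_small, rng):
    """The vectorised table decoder agrees with the scalar
    call_round/classify_trap reference on random tables."""
    R, C = 7, 4
    n = 60
    rows = []
    for trap in range(n):
        for r in range(R):
            for c in range(C):
                rows.append({
                    "trap_id": trap, "round": r, "channel": c,
                    "total_intensity": float(rng.choice([0.0, 3.0, 8.0, 20.0, 50.0])),
                    "n_pixels": int(rng.choice([0, 2, 10])),
                })
    df = pd.DataFrame(rows)
    params = DecodeParams(area_min_px=4)
    thr = np.full(C, 5.0)
    fast = decode_signal_table(df, codebook_small, params, thresholds=thr)
    for d in fast:
        sub = df[df.trap_id == d.trap_id]
        calls = []
        for r in range(R):
            s = sub[sub["round"] == r].sort_values("channel")
            calls.append(call_round(s.total_intensity.to_numpy(),
                                    s.n_pixels.to_numpy(), thr, params).call)
        ref = classify_trap(calls, codebook_small, trap_id=d.trap_id)
        assert (d.category, d.barcode_id, d.n_corrected, d.round_calls) == (
            ref.category, ref.barcode_id, ref.n_corrected, ref.round_calls)


def test_decode_image_stack_recovers_clean_genotypes():
    from poolscreen.synthetic import GenotypingSimConfig, gen_genotyping

    cfg = GenotypingSimConfig(
        n_traps=40, occupancy_prob=1.0, p_no_signal=0.0, p_double_signal=0.0,
        p_round_error=0.0, trap_shape_px=(30, 14), seed=19,
    )
    tiles, gt = gen_genotyping(cfg, mode="image")
    occ = gt.traps[gt.traps.occupied]
    decodes = decode_image_stack(tiles, occ.trap_id.tolist(), gt.codebook)
    truth = occ.set_index("trap_id").barcode_id
    assert all(d.category == "decoded" and d.barcode_id == truth[d.trap_id] for d in decodes)


def test_summarize_experiment_counts_and_error():
    from poolscreen.synthetic import GenotypingSimConfig, gen_genotyping

    cfg = GenotypingSimConfig(n_traps=2000, n_barcodes=20, p_round_error=0.0, seed=23)
    signals, gt = gen_genotyping(cfg)
    decodes = decode_signal_table(signals, gt.codebook)
    s = summarize_experiment(decodes)
    truth_counts = gt.category_counts()
    # categories partition occupied traps; counts match construction
    assert (s.n_no_signal + s.n_double_signal + s.n_unassigned + s.n_decoded) == s.n_occupied
    assert s.n_no_signal == truth_counts.get("no_signal", 0)
    assert s.n_double_signal == truth_counts.get("double_signal", 0)
    assert s.n_decoded == truth_counts.get("normal", 0)  # p_round_error = 0
    assert s.per_round_error == 0.0


def test_summarize_experiment_needs_occupied_traps():
    with pytest.raises(ValueError):
        summarize_experiment([])


class TestAmpliconCounting:
    barcodes = [BarcodeSeq("b1", "ACGTACGTACGTACGTACGTACGTACGTAC"),
                BarcodeSeq("b2", "GGGGCCCCAAAATTTTGGGGCCCCAAAATT")]

    def test_exact_substring_counted(self):
        reads = ["TTT" + self.barcodes[0].seq + "GG"]
        counts = count_amplicon_reads(reads, self.barcodes)
        assert counts.loc["b1", "count"] == 1 and counts.loc["b2", "count"] == 0

    def test_single_mismatch_unmatched(self):
        nearly = "T" + self.barcodes[0].seq[1:]
        counts = count_amplicon_reads(["AA" + nearly + "CC"], self.barcodes)
        assert counts.loc["b1", "count"] == 0
        assert counts.loc["__unmatched__", "count"] == 1

    def test_multi_match_tallied_separately(self):
        read = self.barcodes[0].seq + self.barcodes[1].seq
        counts = count_amplicon_reads([read], self.barcodes)
        assert counts.loc["__multi__", "count"] == 1

    def test_reverse_complement_flag(self):
        from Bio.Seq import Seq

        rc = str(Seq(self.barcodes[0].seq).reverse_complement())
        assert count_amplicon_reads([rc], self.barcodes).loc["b1", "count"] == 0
        counts = count_amplicon_reads([rc], self.barcodes, include_reverse_complement=True)
        assert counts.loc["b1", "count"] == 1

    def test_generator_abundances_recovered_exactly(self):
        from poolscreen.barcodes import DesignParams, generate_candidates
        from poolscreen.synthetic import gen_amplicon

        bcs = generate_candidates(DesignParams(n_candidates=30, k=30, seed=31))
        reads, true_counts = gen_amplicon(bcs, n_reads=600, seed=4)
        counts = count_amplicon_reads(reads, bcs)
        for b in bcs:
            assert counts.loc[b.id, "count"] == true_counts[b.id]
        assert counts.loc["__unmatched__", "count"] == 0


class TestCompareFrequencies:
    def test_identical_counts_all_ratios_one(self):
        c = pd.Series([10, 20, 30], index=["a", "b", "c"])
        table, within = compare_frequencies(c, c.copy())
        np.testing.assert_allclose(table.ratio, 1.0)
        assert within == 3

    def test_absent_barcode_outside_twofold(self):
        insitu = pd.Series([0, 20, 30], index=["a", "b", "c"])
        ngs = pd.Series([10, 20, 30], index=["a", "b", "c"])
        table, within = compare_frequencies(insitu, ngs)
        assert table.loc["a", "ratio"] == 0.0
        assert within == 2

    def test_zero_ngs_flagged_nan_and_excluded(self):
        insitu = pd.Series([10, 20], index=["a", "b"])
        ngs = pd.Series([0, 30], index=["a", "b"])
        table, within = compare_frequencies(insitu, ngs)
        assert np.isnan(table.loc["a", "ratio"])
        assert within == 1

    def test_multinomial_subsampling_within_twofold(self, rng):
        """Two deep multinomial samples of one composition agree within
        two-fold for every barcode."""
        p = rng.dirichlet(np.full(40, 5.0))
        a = pd.Series(rng.multinomial(20_000, p), index=[f"b{i}" for i in range(40)])
        b = pd.Series(rng.multinomial(20_000, p), index=[f"b{i}" for i in range(40)])
        _, within = compare_frequencies(a, b)
        assert within == 40
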
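"""Codebook construction, single-error-correcting decoding, error budget."""

import itertools

import numpy as np
import pytest

from poolscreen.codebook import (
    Codebook,
    CodebookConstructionError,
    CodebookSpec,
    build_codebook,
    decode_word,
    decode_words,
    estimate_round_error,
    round_error_closed_form,
    simulate_misassignment,
)


def test_spec_rejects_infeasible_and_inconsistent():
    with pytest.raises(ValueError):
        CodebookSpec(n_codes=2**7 * 2, n_rounds=7, n_colors=2)  # > C^N: pigeonhole
    with pytest.raises(ValueError):
        CodebookSpec(min_distance=2, correction_radius=1)


def test_single_codeword_codebook_valid():
    cb = build_codebook(CodebookSpec(n_codes=1, seed=0))
    assert len(cb) == 1


def test_build_codebook_pairwise_distances_exhaustive(codebook85):
    """All C(85,2) = 3570 pairwise Hamming distances >= 3, checked by
    brute-force enumeration independent of the construction."""
    words = codebook85.codewords
    pairs = list(itertools.combinations(range(len(words)), 2))
    assert len(pairs) == 3570
    for i, j in pairs:
        assert int((words[i] != words[j]).sum()) >= 3


def test_build_codebook_deterministic():
    a = build_codebook(CodebookSpec(seed=4))
    b = build_codebook(CodebookSpec(seed=4))
    assert np.array_equal(a.codewords, b.codewords)


def test_build_codebook_infeasible_spec_errors():
    # distance N over a 2-letter alphabet admits only 2 codewords
    spec = CodebookSpec(n_codes=3, n_rounds=4, n_colors=2, min_distance=4,
                        correction_radius=1, seed=0)
    with pytest.raises(CodebookConstructionError):
        build_codebook(spec, max_rejections_per_slot=1000)


def test_decode_exact_match(codebook85):
    for i in (0, 42, 84):
        out = decode_word(codebook85.codewords[i], codebook85)
        assert out.decoded and out.index == i and out.n_corrected == 0


def test_decode_exhaustive_single_error_correction(codebook85):
    """Every one of the 85 x 7 x 3 = 1785 single-symbol corruptions
    decodes back to the original codeword."""
    C = codebook85.spec.n_colors
    n_cases = 0
    for i, word in enumerate(codebook85.codewords):
        for r in range(codebook85.spec.n_rounds):
            for wrong in range(C):
                if wrong == word[r]:
                    continue
                corrupted = word.copy()
                corrupted[r] = wrong
                out = decode_word(corrupted, codebook85)
                assert out.decoded and out.index == i and out.n_corrected == 1
                n_cases += 1
    assert n_cases == 1785


def test_decode_distance_two_unassigned(codebook85):
    """Words at distance >= 2 from every codeword are unassigned,
    confirmed against an exhaustive distance scan."""
    rng = np.random.default_rng(0)
    found = 0
    while found < 20:
        w = rng.integers(0, 4, size=7).astype(np.int16)
        d = (codebook85.codewords != w[None, :]).sum(axis=1)
        if d.min() >= 2:
            assert not decode_word(w, codebook85).decoded
            found += 1


def test_decode_missing_symbol_unassigned(codebook85):
    w = codebook85.codewords[0].copy()
    w[3] = -1
    assert not decode_word(w, codebook85).decoded


def test_decode_word_wrong_length_rejected(codebook85):
    with pytest.raises(ValueError):
        decode_word([0, 1, 2], codebook85)


def test_decode_words_matches_scalar(codebook85, rng):
    words = rng.integers(0, 4, size=(200, 7)).astype(np.int16)
    assigned, n_corr, decoded = decode_words(words, codebook85)
    for k in range(len(words)):
        out = decode_word(words[k], codebook85)
        assert decoded[k] == out.decoded
        if out.decoded:
            assert assigned[k] == out.index and n_corr[k] == out.n_corrected


def test_simulate_misassignment_zero_error(codebook85):
    b = simulate_misassignment(codebook85, 0.0, 10_000, seed=1)
    assert b.p_wrong == 0.0 and b.p_correct == 1.0


def test_simulate_misassignment_probabilities_sum_to_one(codebook85):
    b = simulate_misassignment(codebook85, 0.1, 50_000, seed=2)
    assert b.p_wrong + b.p_unassigned + b.p_correct == pytest.approx(1.0, abs=1e-15)


def test_simulate_misassignment_analytic_bound(codebook85):
    """p_wrong cannot exceed the probability of >= 2 round errors:
    1 - (1-p)^7 - 7p(1-p)^6 (about 0.0284 at p = 0.038)."""
    for p in (0.01, 0.038, 0.1, 0.2):
        n = 100_000
        b = simulate_misassignment(codebook85, p, n, seed=3)
        bound = 1 - (1 - p) ** 7 - 7 * p * (1 - p) ** 6
        se = np.sqrt(bound * (1 - bound) / n)
        assert b.p_wrong <= bound + 3 * se


def test_misassignment_monotone_in_round_error(codebook85):
    """p_wrong and p_unassigned are statistically non-decreasing in the
    per-round error rate on [0, 0.3]."""
    n = 60_000
    ps = [0.0, 0.05, 0.1, 0.2, 0.3]
    budgets = [simulate_misassignment(codebook85, p, n, seed=4) for p in ps]
    slack = 3 / np.sqrt(n)
    for lo, hi in zip(budgets, budgets[1:]):
        assert hi.p_wrong >= lo.p_wrong - slack
        assert hi.p_unassigned >= lo.p_unassigned - slack


def test_estimate_round_error_from_pairs():
    cw = [0, 1, 2, 3, 0, 1, 2]
    pairs = [(cw, cw)] * 9 + [([1, 1, 2, 3, 0, 1, 2], cw)]  # one corrected symbol
    assert estimate_round_error(pairs) == pytest.approx(1 / 70)
    assert estimate_round_error([(cw, cw)] * 5) == 0.0
    with pytest.raises(ValueError):
        estimate_round_error([])


def test_estimate_round_error_matches_conditional_closed_form(codebook85, rng):
    """Estimated per-round error from decoded traps converges to
    p/(1+6p) — the known downward bias from excluding non-decodable
    traps (about 0.0309 at p = 0.038)."""
    from poolscreen.codebook import corrupt_words

    p = 0.038
    n = 50_000
    true_idx = rng.integers(0, 85, size=n)
    observed = corrupt_words(codebook85.codewords[true_idx], p, 4, rng)
    assigned, n_corr, decoded = decode_words(observed, codebook85)
    est = estimate_round_error(n_corrected=n_corr[decoded], n_rounds=7)
    expect = round_error_closed_form(p)
    # 3 MC standard errors on the mean corrected-per-round fraction
    se = np.std(n_corr[decoded] / 7) / np.sqrt(decoded.sum())
    assert abs(est - expect) < 3 * se
    assert expect == pytest.approx(0.0309, abs=2e-4)


def test_codebook_json_roundtrip(tmp_path, codebook_small):
    path = tmp_path / "cb.json"
    codebook_small.to_json(path)
    back = Codebook.from_json(path)
    assert back.spec == codebook_small.spec
    # ids sorted on load; compare as mapping
    orig = {b: codebook_small.codeword_of(b).tolist() for b in codebook_small.ids}
    assert {b: back.codeword_of(b).tolist() for b in back.ids} == orig


def test_codebook_rejects_distance_violation():
    spec = CodebookSpec(n_codes=2, n_rounds=7, n_colors=4, min_distance=3)
    words = np.array([[0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0, 1]])
    with pytest.raises(ValueError):
        Codebook(words, spec)
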
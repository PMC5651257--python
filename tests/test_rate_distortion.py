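"""Gaussian rate-distortion, reverse water-filling and random codebooks."""

import numpy as np
import pytest

from morphocode import (
    codebook_size,
    decode,
    empirical_distortion,
    encode,
    lambda_for_rate,
    make_codebook,
    rate_of_distortion,
    rd_rate_single,
    reverse_waterfill,
    sample_prior,
)
from morphocode.rate_distortion import encode_decode_batch


def waterfill_oracle(variances, total_distortion):
    """Independent closed-form solve: sort the variances and find the
    piecewise-linear segment where sum_i min(lam, s_i) crosses D."""
    s = np.sort(np.asarray(variances, float))
    n = len(s)
    total = s.sum()
    if total_distortion >= total:
        return float(s.max()), 0.0
    below = 0.0
    for k in range(n):  # lam in segment [s[k-1], s[k]]
        active = n - k  # dims with variance >= lam
        lam = (total_distortion - below) / active
        if (k == 0 or lam >= s[k - 1]) and lam <= s[k]:
            coded = s > lam
            rate = 0.5 * np.sum(np.log2(s[coded] / lam)) if coded.any() else 0.0
            return float(lam), float(rate)
        below += s[k]
    raise AssertionError("oracle failed to bracket lam")


@pytest.mark.parametrize(
    "distortion, sigma2, expected",
    [
        (4.0, 4.0, 0.0),  # D = variance: one codeword suffices
        (1.0, 4.0, 1.0),  # D = variance/4: half log2(4)
        (8.0, 4.0, 0.0),  # D above the variance: zero rate
        (0.25, 4.0, 2.0),
    ],
)
def test_single_gaussian_rate(distortion, sigma2, expected):
    assert rd_rate_single(distortion, sigma2) == pytest.approx(expected)


def test_single_gaussian_rejects_nonpositive_distortion():
    with pytest.raises(ValueError):
        rd_rate_single(0.0, 1.0)


def test_waterfill_two_dim_hand_case():
    sol = reverse_waterfill([4.0, 1.0], 2.0)
    assert sol.lam == pytest.approx(1.0, rel=1e-9)
    np.testing.assert_allclose(sol.per_dim_distortion, [1.0, 1.0], rtol=1e-9)
    assert sol.rate_bits == pytest.approx(1.0, rel=1e-9)
    assert rate_of_distortion([4.0, 1.0], 2.0) == pytest.approx(1.0)


def test_waterfill_total_variance_boundary():
    sol = reverse_waterfill([4.0, 1.0, 0.5], 5.5)
    assert sol.rate_bits == 0.0
    assert sol.lam == pytest.approx(4.0)
    np.testing.assert_allclose(sol.per_dim_distortion, [4.0, 1.0, 0.5])


def test_waterfill_clamps_excess_distortion():
    sol = reverse_waterfill([1.0, 2.0], 10.0)
    assert sol.rate_bits == 0.0
    assert sol.total_distortion == pytest.approx(3.0)


def test_waterfill_matches_oracle_on_random_spectra():
    rng = np.random.default_rng(123)
    for _ in range(50):
        n = rng.integers(1, 11)
        var = rng.uniform(0.05, 5.0, size=n)
        d = rng.uniform(0.01, 0.999) * var.sum()
        sol = reverse_waterfill(var, d)
        lam_o, rate_o = waterfill_oracle(var, d)
        assert sol.total_distortion == pytest.approx(d, rel=1e-9)
        assert sol.lam == pytest.approx(lam_o, rel=1e-6)
        assert sol.rate_bits == pytest.approx(rate_o, rel=1e-6, abs=1e-9)


def test_single_variance_consistent_with_scalar_formula():
    for d in (0.1, 0.5, 2.0, 3.0):
        assert rate_of_distortion([2.0], d) == pytest.approx(
            rd_rate_single(d, 2.0), abs=1e-9
        )


def test_rate_curve_monotone_and_convex_in_distortion():
    var = [3.0, 1.5, 0.8, 0.2]
    grid = np.linspace(0.05, sum(var), 60)
    rates = np.array([rate_of_distortion(var, d) for d in grid])
    assert np.all(np.diff(rates) <= 1e-12)  # non-increasing
    second = np.diff(rates, 2)
    assert np.all(second >= -1e-9)  # convex


def test_lambda_for_rate_inverts_waterfill():
    sol = lambda_for_rate([4.0, 1.0], 1.0)
    assert sol.lam == pytest.approx(1.0, rel=1e-6)
    assert sol.total_distortion == pytest.approx(2.0, rel=1e-6)

    rng = np.random.default_rng(7)
    for _ in range(20):
        var = rng.uniform(0.1, 4.0, size=rng.integers(1, 8))
        r = rng.uniform(0.0, 12.0)
        sol = lambda_for_rate(var, r)
        if r == 0:
            np.testing.assert_allclose(sol.per_dim_distortion, var)
        else:
            assert rate_of_distortion(var, sol.total_distortion) == pytest.approx(
                r, abs=1e-6
            )


def test_lambda_for_zero_rate_returns_full_variance():
    sol = lambda_for_rate([2.0, 1.0, 0.1], 0.0)
    assert sol.rate_bits == 0.0
    np.testing.assert_allclose(sol.per_dim_distortion, [2.0, 1.0, 0.1])


def test_codebook_size_arithmetic():
    assert codebook_size(4) == 16
    assert codebook_size(8, block_size=2) == 2**16
    assert codebook_size(0) == 1


def test_zero_rate_codebook_is_single_zero_codeword(small_prior):
    cb = make_codebook(small_prior, 0)
    assert cb.size == 1
    assert not cb.codewords.any()
    np.testing.assert_array_equal(decode(0, cb), np.zeros(small_prior.n_modes))


def test_four_bit_codebook_has_sixteen_codewords(small_prior):
    cb = make_codebook(small_prior, 4, seed=3)
    assert cb.size == 16
    assert cb.codewords.shape == (16, small_prior.n_modes)


def test_codebook_deterministic_under_seed(small_prior):
    a = make_codebook(small_prior, 5, seed=11)
    b = make_codebook(small_prior, 5, seed=11)
    np.testing.assert_array_equal(a.codewords, b.codewords)
    assert a.lam == b.lam


def test_submerged_components_are_exactly_zero(small_prior):
    # at a low rate the water level exceeds the smallest variances
    cb = make_codebook(small_prior, 1, seed=2)
    submerged = small_prior.variances < cb.lam
    assert submerged.any(), "test needs at least one submerged dimension"
    assert not cb.codewords[:, submerged].any()
    # coded components are drawn N(0, sigma_i^2 - lam): check at a rate with
    # enough codewords for the sample variance to concentrate
    big = make_codebook(small_prior, 10, seed=4)
    target = np.clip(small_prior.variances - big.lam, 0.0, None)
    sample_var = big.codewords.var(axis=0, ddof=1)
    np.testing.assert_allclose(sample_var, target, rtol=0.2)


def test_codebook_size_cap(small_prior):
    with pytest.raises(ValueError, match="cap"):
        make_codebook(small_prior, 21)
    with pytest.raises(ValueError, match="cap"):
        make_codebook(small_prior, 11, block_size=2)


def test_encode_matches_brute_force(small_prior):
    cb = make_codebook(small_prior, 3, seed=5)
    rng = np.random.default_rng(6)
    for beta in sample_prior(small_prior, 25, rng):
        brute = int(np.argmin(np.sum((cb.codewords - beta) ** 2, axis=1)))
        assert encode(beta, cb) == brute


def test_encode_exact_codeword_and_ties(small_prior):
    cb = make_codebook(small_prior, 3, seed=5)
    assert encode(cb.codewords[5], cb) == 5
    # duplicated codewords: ties break toward the lowest index
    dup = cb.codewords.copy()
    dup[4] = dup[1]
    tied = type(cb)(
        rate_bits=3, block_size=1, lam=cb.lam, codewords=dup, seed=0,
        variances=cb.variances,
    )
    assert encode(dup[4], tied) == 1


def test_single_codeword_always_index_zero(small_prior):
    cb = make_codebook(small_prior, 0)
    assert encode(np.ones(small_prior.n_modes) * 9.9, cb) == 0


def test_decode_roundtrip_and_range(small_prior):
    cb = make_codebook(small_prior, 2, seed=8)
    for k in range(cb.size):
        assert encode(decode(k, cb), cb) == k
        np.testing.assert_array_equal(decode(k, cb), cb.codewords[k])
    with pytest.raises(IndexError):
        decode(cb.size, cb)


def test_batch_encoding_agrees_with_scalar_encode(small_prior):
    cb = make_codebook(small_prior, 4, seed=13)
    samples = sample_prior(small_prior, 40, seed=14)
    decoded = encode_decode_batch(samples, cb)
    for s, d in zip(samples, decoded):
        np.testing.assert_array_equal(d, cb.codewords[encode(s, cb)])


def test_distortion_zero_when_samples_are_codewords(small_prior):
    cb = make_codebook(small_prior, 3, seed=1)
    assert empirical_distortion(cb.codewords, cb) == 0.0


def test_zero_rate_distortion_equals_total_variance(small_prior):
    # a single mean codeword: expected distortion equals the variance
    cb = make_codebook(small_prior, 0)
    samples = sample_prior(small_prior, 20000, seed=3)
    d = empirical_distortion(samples, cb)
    assert d == pytest.approx(small_prior.total_variance, rel=0.05)


def test_empirical_distortion_respects_theoretical_lower_bound(small_prior):
    for rate in (1, 3, 5, 7):
        cb = make_codebook(small_prior, rate, seed=rate)
        samples = sample_prior(small_prior, 2000, seed=100 + rate)
        decoded = encode_decode_batch(samples, cb)
        sq = np.sum((samples - decoded) ** 2, axis=1)
        stderr = sq.std(ddof=1) / np.sqrt(len(sq))
        bound = lambda_for_rate(small_prior.variances, rate).total_distortion
        assert sq.mean() >= bound - 3 * stderr
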
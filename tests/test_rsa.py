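"""RDM construction, comparison, permutation inference, noise ceilings and
behavior correlation."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from capspace import rsa


@pytest.fixture()
def features(rng):
    return rng.standard_normal((6, 5))


# -- compute_rdm ---------------------------------------------------------


def test_rdm_identical_rows_all_zero():
    X = np.tile(np.arange(4.0), (5, 1))
    rdm = rsa.compute_rdm(X, "euclidean")
    assert np.allclose(rdm.matrix, 0.0)


def test_rdm_correlation_opposite_rows_is_two(rng):
    x = rng.standard_normal(6)
    X = np.stack([x, -x, x + rng.standard_normal(6) * 0.1])
    rdm = rsa.compute_rdm(X, "correlation_distance")
    assert rdm.matrix[0, 1] == pytest.approx(2.0)
    assert rdm.matrix.min() >= 0.0 and rdm.matrix.max() <= 2.0


def test_rdm_matches_brute_force_loop(rng):
    X = rng.standard_normal((4, 3))
    rdm = rsa.compute_rdm(X, "euclidean")
    for a in range(4):
        for b in range(4):
            expected = np.sqrt(((X[a] - X[b]) ** 2).sum())
            assert rdm.matrix[a, b] == pytest.approx(expected, abs=1e-12)


def test_rdm_zero_variance_row_raises(rng):
    X = rng.standard_normal((4, 5))
    X[2] = 3.14
    with pytest.raises(ValueError, match="2"):
        rsa.compute_rdm(X, "correlation_distance")


def test_rdm_too_few_conditions(rng):
    with pytest.raises(ValueError):
        rsa.compute_rdm(rng.standard_normal((2, 5)))


# -- compare_rdms --------------------------------------------------------


def test_compare_rdm_with_itself(features):
    rdm = rsa.compute_rdm(features)
    assert rsa.compare_rdms(rdm, rdm, "pearson").r == pytest.approx(1.0)
    assert rsa.compare_rdms(rdm, rdm, "spearman").r == pytest.approx(1.0)


def test_compare_constant_rdm_errors(features):
    rdm = rsa.compute_rdm(features)
    const = rsa.RDM(
        matrix=np.ones((6, 6)) - np.eye(6),
        metric="euclidean",
        condition_ids=rdm.condition_ids,
    )
    with pytest.raises(ValueError):
        rsa.compare_rdms(rdm, const, "pearson")


def test_compare_mismatched_conditions(features):
    a = rsa.compute_rdm(features, condition_ids=list("abcdef"))
    b = rsa.compute_rdm(features, condition_ids=list("abcdeg"))
    with pytest.raises(ValueError):
        rsa.compare_rdms(a, b)


def test_compare_matches_hand_rank_correlation(rng):
    """5-condition pair equals spearman of the 10 upper-triangle entries."""
    A = rng.standard_normal((5, 4))
    B = A + 0.5 * rng.standard_normal((5, 4))
    ra, rb = rsa.compute_rdm(A), rsa.compute_rdm(B)
    iu = np.triu_indices(5, k=1)
    expected = spearmanr(ra.matrix[iu], rb.matrix[iu]).statistic
    assert rsa.compare_rdms(ra, rb, "spearman").r == pytest.approx(expected)


def test_subset_rdm_equals_rdm_of_subset(rng):
    """Condition-subset RSA consistency: subsetting an RDM equals building
    the RDM from the subset's features."""
    X = rng.standard_normal((8, 5))
    idx = [1, 3, 4, 7]
    full = rsa.compute_rdm(X)
    sub = full.subset(idx)
    direct = rsa.compute_rdm(X[idx], condition_ids=sub.condition_ids)
    np.testing.assert_allclose(sub.matrix, direct.matrix, atol=1e-12)


# -- invariances ---------------------------------------------------------


def test_euclidean_rdm_invariant_to_translation_and_rotation(rng):
    X = rng.standard_normal((6, 4))
    base = rsa.compute_rdm(X).matrix
    shifted = rsa.compute_rdm(X + rng.standard_normal(4)).matrix
    np.testing.assert_allclose(shifted, base, atol=1e-9)
    Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
    rotated = rsa.compute_rdm(X @ Q).matrix
    np.testing.assert_allclose(rotated, base, atol=1e-9)


def test_correlation_rdm_invariant_to_row_shifts(rng):
    X = rng.standard_normal((5, 6))
    base = rsa.compute_rdm(X, "correlation_distance").matrix
    shifted = rsa.compute_rdm(
        X + rng.standard_normal(5)[:, None], "correlation_distance"
    ).matrix
    np.testing.assert_allclose(shifted, base, atol=1e-9)


# -- permutation test ----------------------------------------------------


def test_permutation_identity_reproduces_observed(features):
    rdm = rsa.compute_rdm(features)
    n = rdm.n_conditions
    perm = np.arange(n)
    shuffled = rdm.matrix[np.ix_(perm, perm)]
    np.testing.assert_array_equal(shuffled, rdm.matrix)


def test_permutation_p_at_minimum_for_identical_rdms(features):
    rdm = rsa.compute_rdm(features)
    res = rsa.permutation_test(rdm, rdm, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    # identical RDMs can only be matched by distance-preserving relabelings,
    # so p sits at (1 + #ties) / (n_perm + 1), near the minimum
    assert res.p_perm <= 5 / 100


def test_permutation_type_I_error_rate():
    """Under the null (independent geometries) the test rejects at ~alpha."""
    rng = np.random.default_rng(99)
    n_reps, alpha = 500, 0.05
    rejections = 0
    for _ in range(n_reps):
        A = rng.standard_normal((8, 4))
        B = rng.standard_normal((8, 4))
        res = rsa.permutation_test(
            rsa.compute_rdm(A), rsa.compute_rdm(B), n_perm=99, seed=rng
        )
        rejections += res.p_perm < alpha
    rate = rejections / n_reps
    assert abs(rate - alpha) <= 0.03


def test_permutation_rejects_bad_nperm(features):
    rdm = rsa.compute_rdm(features)
    with pytest.raises(ValueError):
        rsa.permutation_test(rdm, rdm, n_perm=0)


# -- noise ceiling -------------------------------------------------------


def test_noise_ceiling_identical_subjects(features):
    rdm = rsa.compute_rdm(features)
    nc = rsa.noise_ceiling([rdm] * 5)
    assert nc.upper == pytest.approx(1.0)
    assert nc.lower == pytest.approx(1.0)


def test_noise_ceiling_lower_below_upper(rng):
    """Heterogeneous subjects: leave-one-out mean degrades the fit."""
    base = rng.standard_normal((6, 5))
    rdms = [
        rsa.compute_rdm(base + 0.8 * rng.standard_normal((6, 5)))
        for _ in range(6)
    ]
    nc = rsa.noise_ceiling(rdms)
    assert nc.lower < nc.upper


def test_noise_ceiling_needs_three_subjects(features):
    rdm = rsa.compute_rdm(features)
    with pytest.raises(ValueError):
        rsa.noise_ceiling([rdm, rdm])


# -- behavior correlation ------------------------------------------------


def test_behavior_perfect_correlation(rng):
    sim = rng.uniform(0, 1, 12)
    df = rsa.behavior_correlation(sim, sim)
    assert df.loc[0, "r"] == pytest.approx(1.0)


def test_behavior_null_fdr_rate(rng):
    """Independent accuracies: FDR keeps the significant-ROI fraction near
    or below alpha."""
    n_reps, n_rois, alpha = 200, 10, 0.05
    frac = []
    for _ in range(n_reps):
        sim = rng.standard_normal((16, n_rois))
        acc = rng.uniform(0.5, 1.0, 16)
        df = rsa.behavior_correlation(sim, acc, alpha=alpha)
        frac.append(df["significant"].mean())
    assert np.mean(frac) <= alpha + 0.02


def test_behavior_input_validation(rng):
    with pytest.raises(ValueError):
        rsa.behavior_correlation(np.ones(5), rng.uniform(size=5))
    with pytest.raises(ValueError):
        rsa.behavior_correlation(rng.uniform(size=5), np.ones(5))
    with pytest.raises(ValueError):
        rsa.behavior_correlation(rng.uniform(size=3), rng.uniform(size=3))
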
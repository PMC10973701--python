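"""Planted-geometry activation simulator and GLM beta recovery."""

import numpy as np
import pytest

from capspace import rsa, stimuli, synthetic_brain as sb


@pytest.fixture(scope="module")
def target(request):
    rng = np.random.default_rng(42)
    return rsa.compute_rdm(rng.standard_normal((12, 8)), "correlation_distance")


def fidelity(patterns, target):
    obs = rsa.compute_rdm(patterns, "correlation_distance",
                          condition_ids=target.condition_ids)
    return rsa.compare_rdms(obs, target, "pearson").r


def test_embedding_reproduces_target_exactly(target, rng):
    """lam=1, no noise: the sample correlation RDM matches the target."""
    patterns = sb.simulate_region(target, n_voxels=40, lam=1.0, noise_sd=0.0, rng=rng)
    assert patterns.shape == (12, 40)
    obs = rsa.compute_rdm(patterns, "correlation_distance",
                          condition_ids=target.condition_ids)
    np.testing.assert_allclose(obs.matrix, target.matrix, atol=1e-8)
    assert fidelity(patterns, target) > 0.99


def test_embedding_distance_ordering(target, rng):
    """Pairwise dissimilarities of the constructed patterns reproduce the
    target ordering."""
    patterns = sb.simulate_region(target, 40, 1.0, 0.0, rng)
    obs = rsa.compute_rdm(patterns, "correlation_distance",
                          condition_ids=target.condition_ids)
    assert rsa.compare_rdms(obs, target, "spearman").r > 0.95


def test_lambda_zero_fidelity_centered_on_zero(target):
    rs = []
    for i in range(30):
        rng = np.random.default_rng(100 + i)
        rs.append(fidelity(sb.simulate_region(target, 40, 0.0, 0.0, rng), target))
    assert abs(np.mean(rs)) < 0.1


def test_fidelity_monotone_in_lambda_and_noise(target):
    """RDM recovery rises with the mixing weight and falls with noise."""
    def mean_fid(lam, noise):
        return np.mean(
            [
                fidelity(
                    sb.simulate_region(
                        target, 40, lam, noise, np.random.default_rng(i)
                    ),
                    target,
                )
                for i in range(15)
            ]
        )

    by_lam = [mean_fid(l, 0.2) for l in (0.0, 0.4, 0.8, 1.0)]
    assert all(b > a for a, b in zip(by_lam, by_lam[1:]))
    by_noise = [mean_fid(0.8, s) for s in (0.0, 0.5, 2.0)]
    assert all(b < a for a, b in zip(by_noise, by_noise[1:]))


def test_simulate_region_validation(target, rng):
    with pytest.raises(ValueError):
        sb.simulate_region(target, 40, 1.5, 0.0, rng)
    with pytest.raises(ValueError):
        sb.simulate_region(target, 5, 1.0, 0.0, rng)  # too few voxels


def test_non_embeddable_rdm_raises(rng):
    """A far-from-Euclidean dissimilarity pattern is rejected with a
    residual report."""
    n = 8
    m = np.full((n, n), 1.9)
    np.fill_diagonal(m, 0.0)
    bad = rsa.RDM(matrix=m, metric="correlation_distance",
                  condition_ids=tuple(range(n)))
    with pytest.raises(sb.EmbeddingError, match="residual"):
        sb.embed_rdm(bad, 40, rng)


def test_paradigm_scale_shapes(rng):
    """48-condition targets yield (48, n_voxels) activations."""
    feats = rng.standard_normal((48, 20))
    target = rsa.compute_rdm(feats, "correlation_distance")
    patterns = sb.simulate_region(target, 60, 0.7, 0.3, rng)
    assert patterns.shape == (48, 60)


# -- cohort --------------------------------------------------------------


def make_targets(n_cond=12, seed=5):
    rng = np.random.default_rng(seed)
    return {
        r: rsa.compute_rdm(rng.standard_normal((n_cond, 8)), "correlation_distance")
        for r in ("frontal", "dorsal")
    }


def test_cohort_reproducible():
    targets = make_targets()
    a = sb.simulate_cohort(4, targets, seed=3)
    b = sb.simulate_cohort(4, targets, seed=3)
    np.testing.assert_array_equal(a[1], b[1])
    for sa, sbj in zip(a[0], b[0]):
        for r in sa.regions:
            np.testing.assert_array_equal(sa.regions[r], sbj.regions[r])


def test_cohort_noiseless_ceiling_is_one():
    """Zero noise and no subject variation: noise ceiling = 1."""
    targets = make_targets()
    subjects, _, _ = sb.simulate_cohort(
        4, targets, per_region_lambda=1.0, noise_sd=0.0,
        subject_lambda_sd=0.0, seed=1,
    )
    rdms = [sb.subject_rdms(s)["frontal"] for s in subjects]
    nc = rsa.noise_ceiling(rdms)
    assert nc.upper == pytest.approx(1.0, abs=1e-6)
    assert nc.lower == pytest.approx(1.0, abs=1e-6)


def test_cohort_ceilings_bracket_model_fit():
    """At moderate SNR the true generating RDM's mean fit lies in or below
    the ceiling band."""
    targets = make_targets()
    subjects, _, _ = sb.simulate_cohort(
        10, targets, per_region_lambda=0.7, noise_sd=0.3, seed=2,
    )
    region = "frontal"
    rdms = [sb.subject_rdms(s)[region] for s in subjects]
    nc = rsa.noise_ceiling(rdms)
    fits = [rsa.compare_rdms(targets[region], r, "pearson").r for r in rdms]
    assert nc.lower <= np.mean(fits) <= nc.upper + 0.05


def test_behavior_correlates_with_planted_similarity():
    """Accuracy tracks planted similarity; no slope -> no correlation."""
    targets = make_targets()
    rs, rs_null = [], []
    for i in range(25):
        _, acc, man = sb.simulate_cohort(
            12, targets, per_region_lambda=0.6, subject_lambda_sd=0.25,
            noise_sd=0.3, seed=200 + i,
        )
        sims = np.array(man["similarities"])
        rs.append(np.corrcoef(sims, acc)[0, 1])
        _, acc0, man0 = sb.simulate_cohort(
            12, targets, per_region_lambda=0.6, subject_lambda_sd=0.25,
            noise_sd=0.3, behavior_slope=0.0, seed=500 + i,
        )
        rs_null.append(np.corrcoef(man0["similarities"], acc0)[0, 1])
    assert np.mean(rs) > 0.6
    assert abs(np.mean(rs_null)) < 0.2


def test_cohort_validation():
    with pytest.raises(ValueError):
        sb.simulate_cohort(2, make_targets())


def test_write_cohort(tmp_path):
    targets = make_targets()
    subjects, acc, man = sb.simulate_cohort(3, targets, seed=0)
    sb.write_cohort(subjects, acc, man, tmp_path)
    assert (tmp_path / "manifest.json").exists()
    assert len(list(tmp_path.glob("*_activation.tsv"))) == 3


# -- GLM -----------------------------------------------------------------


def test_glm_noiseless_recovery_exact():
    """OLS recovers the true betas to machine precision without noise."""
    paradigm = stimuli.build_paradigm(0)
    sim = sb.glm_from_paradigm(paradigm, stage="memory")
    _, err = sb.simulate_glm_and_recover(sim, np.random.default_rng(0))
    assert err < 1e-8


def test_glm_response_stage_and_tr_grid():
    paradigm = stimuli.build_paradigm(1)
    sim = sb.glm_from_paradigm(paradigm, stage="response")
    assert sim.TR == 2.0
    X = sb.glm_design_matrix(sim)
    assert X.shape[0] == int(sim.total_time // 2.0)
    assert X.shape[1] == 49  # intercept + one regressor per trial
    _, err = sb.simulate_glm_and_recover(sim, np.random.default_rng(0))
    assert err < 1e-8


def test_glm_error_scales_linearly_with_noise():
    """Doubling the noise sd doubles the median recovery error."""
    onsets = [np.array([10.0 * k + 2.0]) for k in range(6)]
    durations = [np.array([2.0])] * 6
    sim_lo = sb.GLMSim(onsets=onsets, durations=durations,
                       true_betas=np.ones(6), total_time=80.0, noise_sd=0.1)
    sim_hi = sb.GLMSim(onsets=onsets, durations=durations,
                       true_betas=np.ones(6), total_time=80.0, noise_sd=0.2)
    errs_lo, errs_hi = [], []
    for i in range(60):
        _, e1 = sb.simulate_glm_and_recover(sim_lo, np.random.default_rng(i))
        _, e2 = sb.simulate_glm_and_recover(sim_hi, np.random.default_rng(10_000 + i))
        errs_lo.append(e1)
        errs_hi.append(e2)
    ratio = np.median(errs_hi) / np.median(errs_lo)
    assert 1.5 < ratio < 2.5


def test_hrf_shape():
    t = np.arange(0, 32, 0.1)
    h = sb.double_gamma_hrf(t)
    assert h.max() == pytest.approx(1.0)
    assert t[h.argmax()] == pytest.approx(5.0, abs=1.5)  # peak near 5-6 s
    assert h[(t > 10) & (t < 25)].min() < 0  # undershoot present
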
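"""Style clusters, score boundaries (midpoint rule) and assignment."""

import numpy as np
import pytest

import fingertap as ft
from fingertap import calibration as cal
from fingertap.errors import CalibrationError


def test_two_blob_centers_recovered():
    rng = np.random.default_rng(12)
    blob1 = rng.normal((80.0, 1.5), 2.0, size=(50, 2))
    blob2 = rng.normal((30.0, 3.5), 2.0, size=(50, 2))
    c1, c2 = cal.fit_performance_clusters(np.vstack([blob1, blob2]), seed=0)
    # sampling-mean oracle
    assert np.linalg.norm(c1 - blob1.mean(axis=0)) < 1.0
    assert np.linalg.norm(c2 - blob2.mean(axis=0)) < 1.0


def test_cluster_fit_deterministic_under_seed():
    rng = np.random.default_rng(12)
    feats = np.vstack([rng.normal((80, 2.0), 2, size=(30, 2)),
                       rng.normal((40, 3.2), 2, size=(30, 2))])
    a = cal.fit_performance_clusters(feats, seed=5)
    b = cal.fit_performance_clusters(feats, seed=5)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_identical_points_rejected():
    with pytest.raises(CalibrationError):
        cal.fit_performance_clusters(np.tile([50.0, 2.0], (10, 1)), seed=0)


def test_boundaries_are_center_midpoints():
    # four clean groups at 4/3/2/1 -> centers recovered -> midpoints
    values = np.repeat([4.0, 3.0, 2.0, 1.0], 10)
    b = cal.fit_score_boundaries(values, seed=0)
    np.testing.assert_allclose(b, [3.5, 2.5, 1.5])


def test_boundaries_from_separated_gaussians():
    rng = np.random.default_rng(4)
    values = np.concatenate([rng.normal(c, 3.0, 40) for c in (90.0, 60.0, 35.0, 10.0)])
    b = cal.fit_score_boundaries(values, seed=1)
    np.testing.assert_allclose(b, [75.0, 47.5, 22.5], atol=3.0)


def test_boundaries_small_instance_against_exhaustive_kmeans():
    # 7 distinct values in 4 clear groups; brute-force the optimal 4-way
    # contiguous partition by SSE and compare midpoint boundaries
    values = np.array([1.0, 1.1, 5.0, 5.1, 9.0, 9.1, 13.0])
    best, best_sse = None, np.inf
    sv = np.sort(values)
    nv = sv.size
    for i in range(1, nv - 2):
        for j in range(i + 1, nv - 1):
            for k in range(j + 1, nv):
                parts = [sv[:i], sv[i:j], sv[j:k], sv[k:]]
                sse = sum(((p - p.mean()) ** 2).sum() for p in parts)
                if sse < best_sse:
                    best_sse, best = sse, parts
    centers = sorted((p.mean() for p in best), reverse=True)
    expected = [(a + b) / 2 for a, b in zip(centers[:-1], centers[1:])]
    np.testing.assert_allclose(cal.fit_score_boundaries(values, seed=0), expected)


def test_too_few_distinct_values_rejected():
    with pytest.raises(CalibrationError):
        cal.fit_score_boundaries(np.repeat([1.0, 2.0, 3.0], 5), seed=0)


def test_assignment_and_tie_rule(model):
    c1, c2 = model.center_c1, model.center_c2
    assert cal.assign_cluster(*c1, model)[0] == "C1"
    assert cal.assign_cluster(*c2, model)[0] == "C2"
    mid = (c1 + c2) / 2.0
    assert cal.assign_cluster(mid[0], mid[1], model)[0] == "C1"  # tie -> C1


def test_boundaries_interleave_centers(model):
    rng = np.random.default_rng(4)
    values = np.concatenate([rng.normal(c, 2.0, 40) for c in (90.0, 60.0, 35.0, 10.0)])
    km_centers = np.sort(
        __import__("sklearn.cluster", fromlist=["KMeans"])
        .KMeans(n_clusters=4, n_init=10, random_state=0).fit(values.reshape(-1, 1))
        .cluster_centers_.ravel()
    )[::-1]
    b = cal.fit_score_boundaries(values, seed=0)
    pattern = np.empty(7)
    pattern[0::2] = km_centers
    pattern[1::2] = b
    assert np.all(np.diff(pattern) < 0)  # c1 > b1 > c2 > b2 > c3 > b3 > c4


def test_model_contract_validation():
    with pytest.raises(CalibrationError):
        ft.CalibrationModel(center_c1=(40.0, 2.0), center_c2=(80.0, 3.0),
                            b_alpha_c1=(3, 2, 1), b_alpha_c2=(3, 2, 1),
                            b_freq_c1=(3, 2, 1), b_freq_c2=(3, 2, 1))
    with pytest.raises(CalibrationError):
        ft.CalibrationModel(center_c1=(80.0, 2.0), center_c2=(40.0, 3.0),
                            b_alpha_c1=(1, 2, 3), b_alpha_c2=(3, 2, 1),
                            b_freq_c1=(3, 2, 1), b_freq_c2=(3, 2, 1))


def test_center_consistency_grows_with_n():
    # recovered centers converge to the true means as per-cluster n grows
    feats, styles, sevs = ft.reference_cohort(seed=3, n_per_cell=200)
    normal = feats[sevs == 0]
    c1, c2 = cal.fit_performance_clusters(normal, seed=0)
    assert np.linalg.norm(c1 - np.array([85.0, 2.2])) < 0.5
    assert np.linalg.norm(c2 - np.array([50.0, 3.2])) < 0.5
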
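"""PCA factorization, LDA, stepwise AIC selection and cross-validation."""

import numpy as np
import pytest

import breathdx as bx
from breathdx import ValidationError
from breathdx.enose import _fit_lda_matrix, cross_site_transfer, loocv
from breathdx.preprocess import RangeNormalizer

from conftest import sensor_values


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_data():
    t = np.linspace(0, 1, 10)
    X = np.column_stack([t, t])  # points on the line y = x
    pool = bx.pca_scores(X)
    ev = pool.basis.explained_variance
    assert ev[0] > 0
    # PC-1 carries all variance; no second component survives
    assert pool.scores.shape[1] == 1
    assert pool.tags == [f"raw-{i}" for i in (1, 2)] + ["PC-1"]


def test_pca_trace_conservation_and_round_trip():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 5))
    pool = bx.pca_scores(X)
    total_var = np.var(X - X.mean(axis=0), axis=0, ddof=1).sum()
    assert pool.basis.explained_variance.sum() == pytest.approx(total_var)
    # reconstruction from all scores reproduces the centered data
    recon = pool.scores @ pool.basis.components.T
    assert np.allclose(recon, X - X.mean(axis=0), atol=1e-10)


def test_pca_score_count_bounded_by_samples():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(4, 10))
    pool = bx.pca_scores(X)
    assert pool.scores.shape[1] <= 3
    with pytest.raises(ValidationError):
        bx.pca_scores(X[:1])


def test_pool_projection_matches_training_scores():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(10, 4))
    pool = bx.pca_scores(X)
    proj = pool.project(X)
    assert np.allclose(proj[:, :4], X)
    assert np.allclose(proj[:, 4:], pool.scores, atol=1e-10)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def _two_clouds(rng, n=20, sep=6.0, d=2):
    xa = rng.normal(0, 1, size=(n, d))
    xb = rng.normal(sep, 1, size=(n, d))
    return np.vstack([xa, xb]), np.array(["A"] * n + ["B"] * n)


def test_lda_separable_limit():
    X, y = _two_clouds(np.random.default_rng(3))
    model = _fit_lda_matrix(X, y)
    assert np.all(model.predict(X) == y)


def test_lda_boundary_is_perpendicular_bisector():
    """Equal priors + shared spherical covariance: midpoint scores tie."""
    rng = np.random.default_rng(4)
    base = rng.normal(0, 1, size=(30, 2))
    X = np.vstack([base, base + np.array([4.0, 0.0])])
    y = np.array(["A"] * 30 + ["B"] * 30)
    model = _fit_lda_matrix(X, y)
    mid = (model.class_means[0] + model.class_means[1]) / 2
    s = model._scores(mid[None, :])[0]
    assert s[0] == pytest.approx(s[1], abs=1e-9)
    # a point nudged toward A classifies as A
    toward_a = mid + 0.1 * (model.class_means[0] - model.class_means[1])
    assert model.predict(toward_a[None, :])[0] == "A"


def test_lda_matches_sklearn_predictions():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(5)
    X, y = _two_clouds(rng, n=25, sep=1.5, d=3)
    ours = _fit_lda_matrix(X, y)
    theirs = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
    assert np.mean(ours.predict(X) == theirs.predict(X)) == 1.0


def test_lda_affine_rescaling_invariance():
    """Consistent affine feature rescaling leaves predictions unchanged."""
    rng = np.random.default_rng(6)
    X, y = _two_clouds(rng, n=15, sep=2.0, d=3)
    base = _fit_lda_matrix(X, y).predict(X)
    scale = np.array([3.0, 0.5, 10.0])
    shift = np.array([1.0, -2.0, 7.0])
    moved = _fit_lda_matrix(X * scale + shift, y).predict(X * scale + shift)
    assert np.all(base == moved)


def test_lda_equal_spherical_equals_nearest_centroid():
    rng = np.random.default_rng(7)
    X, y = _two_clouds(rng, n=12, sep=1.0, d=2)
    model = _fit_lda_matrix(X, y)
    # force equal priors and spherical pooled covariance
    model.log_priors = np.zeros_like(model.log_priors)
    model.pooled_covariance_inverse = np.eye(2)
    pred = model.predict(X)
    d = np.linalg.norm(X[:, None, :] - model.class_means[None, :, :], axis=2)
    nearest = np.array(model.classes, dtype=object)[np.argmin(d, axis=1)]
    assert np.all(pred == nearest)


def test_lda_validates_inputs():
    with pytest.raises(ValidationError):
        _fit_lda_matrix(np.zeros((4, 2)), ["A", "A", "A", "A"])
    with pytest.raises(ValidationError):
        _fit_lda_matrix(np.zeros((4, 5)), ["A", "A", "B", "B"])


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------

def test_stepwise_finds_planted_sensor(planted_enose_records):
    obs = bx.observation_table(planted_enose_records, per="subject")
    X = sensor_values(obs)
    Xn = RangeNormalizer().fit(X).transform(X)
    pool = bx.pca_scores(Xn)
    selected = bx.stepwise_select(pool, obs["group"].tolist())
    assert "raw-1" in selected


def test_stepwise_null_selection_near_empty():
    """Pure-noise pools select at most 2 of >60 candidates in >=90% of runs."""
    near_empty = 0
    runs = 40
    for seed in range(runs):
        spec = bx.CohortSpec.single_site({"AD": 15, "HC": 15}, seed=2000 + seed)
        records = bx.generate_enose_cohort(spec, bx.EffectModel(sensor_noise_sd=1.0))
        obs = bx.observation_table(records, per="subject")
        X = sensor_values(obs)
        Xn = RangeNormalizer().fit(X).transform(X)
        selected = bx.stepwise_select(bx.pca_scores(Xn), obs["group"].tolist())
        near_empty += len(selected) <= 2
    assert near_empty / runs >= 0.9


def test_stepwise_both_direction_deterministic(planted_enose_records):
    obs = bx.observation_table(planted_enose_records, per="subject")
    Xn = RangeNormalizer().fit(sensor_values(obs)).transform(sensor_values(obs))
    pool = bx.pca_scores(Xn)
    a = bx.stepwise_select(pool, obs["group"].tolist(), direction="both")
    b = bx.stepwise_select(pool, obs["group"].tolist(), direction="both")
    assert a == b


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def test_loocv_separable_diagonal_and_bookkeeping(planted_enose_records):
    obs = bx.observation_table(planted_enose_records, per="subject")
    X = sensor_values(obs)
    y = obs["group"].tolist()
    report = loocv(X, y)
    cm = report.confusion
    # column sums equal per-class sample counts
    for j, lab in enumerate(cm.labels):
        assert cm.counts[:, j].sum() == y.count(lab)
    assert cm.total == len(y) - len(report.skipped_folds)
    # the 4-sd planted shift separates the groups
    assert cm.accuracy() == 1.0
    assert np.all(np.diag(cm.counts) == [15, 15])


def test_loocv_held_out_sample_cannot_leak():
    """Corrupting the held-out sample leaves its fold's fit unchanged."""
    spec = bx.CohortSpec.single_site({"AD": 6, "HC": 6}, seed=9, n_sensors=8)
    effect = bx.EffectModel.planted_sensor(8, "AD", sensor=2, shift=5.0)
    records = bx.generate_enose_cohort(spec, effect)
    obs = bx.observation_table(records, per="subject")
    X = sensor_values(obs)
    y = obs["group"].tolist()
    base = loocv(X, y)
    X_out = X.copy()
    X_out[0] = 1e6  # absurd outlier as the held-out sample of fold 0
    outl = loocv(X_out, y)
    assert base.per_fold_predictions[0]["selected"] == \
        outl.per_fold_predictions[0]["selected"]


def test_cross_site_self_transfer_equals_resubstitution(planted_enose_records):
    obs = bx.observation_table(planted_enose_records, per="subject")
    X = sensor_values(obs)
    y = obs["group"].tolist()
    rep = cross_site_transfer(X, y, X, y)
    norm = RangeNormalizer().fit(X)
    pool = bx.pca_scores(norm.transform(X))
    tags = bx.stepwise_select(pool, y)
    model = bx.fit_lda(pool, y, tags)
    resub = model.predict(pool.matrix(tags))
    assert [f["estimated"] for f in rep.per_fold_predictions] == list(resub)


def test_cross_site_transfer_degrades_with_batch_offset():
    """A large site batch effect drives transfer accuracy toward chance."""
    n_sensors = 16
    shift = np.zeros(n_sensors)
    shift[0] = 4.0
    offset = np.full(n_sensors, 25.0)
    sites = {"Marburg": {"AD": 12, "HC": 12}, "Bonn": {"AD": 12, "HC": 12}}

    def run(site_off):
        spec = bx.CohortSpec(site_groups=sites, n_sensors=n_sensors, seed=21)
        eff = bx.EffectModel(sensor_shift={"AD": shift}, sensor_noise_sd=1.0,
                             site_offset={"Bonn": site_off})
        records = bx.generate_enose_cohort(spec, eff)
        obs = bx.observation_table(records, per="subject")
        tr = obs[obs["site"] == "Marburg"]
        te = obs[obs["site"] == "Bonn"]
        rep = cross_site_transfer(sensor_values(tr), tr["group"].tolist(),
                                  sensor_values(te), te["group"].tolist())
        return rep.confusion.accuracy()

    assert run(np.zeros(n_sensors)) > 0.9
    assert run(offset) <= 0.75


def test_cross_site_rejects_sensor_mismatch():
    with pytest.raises(ValidationError):
        cross_site_transfer(np.zeros((4, 3)), ["A", "A", "B", "B"],
                            np.zeros((2, 4)), ["A", "B"])
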
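import numpy as np
import pytest

from tvae.gp import (FitnessDataset, GpHyperparams, GpModel, eval_metrics,
                     fit_gp, rbf_kernel, split_dataset, train_test_split_counts)


def test_rbf_kernel_values(rng):
    h = GpHyperparams(1.0, 1.0, 1e-8)
    z = rng.normal(size=3)
    assert rbf_kernel(z, z, h) == pytest.approx(1.0)
    z1, z2 = np.zeros(2), np.array([np.sqrt(2.0), 0.0])
    assert rbf_kernel(z1, z2, h) == pytest.approx(np.exp(-1.0), abs=1e-12)
    a, b = rng.normal(size=4), rng.normal(size=4)
    assert rbf_kernel(a, b, h) == rbf_kernel(b, a, h)
    with pytest.raises(ValueError):
        GpHyperparams(1.0, -1.0, 0.0)


def test_gp_predict_matches_dense_solve(rng):
    """Posterior mean/variance equal the direct k*^T (K + s I)^-1 y solve."""
    n, d = 50, 2
    z = rng.normal(size=(n, d))
    y = np.sin(z[:, 0]) + 0.5 * z[:, 1] + 0.1 * rng.normal(size=n)
    hyper = GpHyperparams(1.3, 0.8, 0.05)
    model = GpModel(FitnessDataset(z, y), hyper)
    zq = rng.normal(size=(7, d))
    mean, var = model.predict(zq)

    k_train = rbf_kernel(z, z, hyper) + hyper.noise_var * np.eye(n)
    k_inv = np.linalg.inv(k_train)
    ks = rbf_kernel(zq, z, hyper)
    mean_ref = y.mean() + ks @ k_inv @ (y - y.mean())
    var_ref = hyper.signal_var + hyper.noise_var - np.einsum(
        "mn,nk,mk->m", ks, k_inv, ks)
    assert np.allclose(mean, mean_ref, atol=1e-8)
    assert np.allclose(var, var_ref, atol=1e-8)


def test_gp_interpolates_training_points_at_tiny_noise(rng):
    z = rng.normal(size=(20, 2))
    y = rng.normal(size=20)
    model = GpModel(FitnessDataset(z, y), GpHyperparams(2.0, 1.0, 1e-10))
    mean, var = model.predict(z)
    assert np.allclose(mean, y, atol=1e-4)
    assert np.all(var < 1e-4)


def test_gp_reverts_to_prior_far_away(rng):
    z = rng.normal(size=(15, 2))
    y = 5.0 + rng.normal(size=15)
    hyper = GpHyperparams(2.0, 0.5, 0.1)
    model = GpModel(FitnessDataset(z, y), hyper)
    mean, var = model.predict(np.array([100.0, 100.0]))
    assert mean == pytest.approx(y.mean(), abs=1e-8)
    assert var == pytest.approx(hyper.signal_var + hyper.noise_var, abs=1e-8)


def test_gp_matches_sklearn_reference(rng):
    """Independent cross-check of the posterior against sklearn's GPR
    at fixed hyperparameters."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    n = 40
    z = rng.normal(size=(n, 3))
    y = z[:, 0] ** 2 - z[:, 1] + 0.2 * rng.normal(size=n)
    hyper = GpHyperparams(1.7, 1.2, 0.09)
    mine = GpModel(FitnessDataset(z, y), hyper)
    sk = GaussianProcessRegressor(
        kernel=ConstantKernel(hyper.signal_var, "fixed") * RBF(hyper.length_scale, "fixed")
        + WhiteKernel(hyper.noise_var, "fixed"),
        optimizer=None, normalize_y=False)
    sk.fit(z, y - y.mean())  # same constant-mean convention as GpModel
    zq = rng.normal(size=(9, 3))
    mean, var = mine.predict(zq)
    mean_sk, sd_sk = sk.predict(zq, return_std=True)
    assert np.allclose(mean, y.mean() + mean_sk, atol=1e-6)
    assert np.allclose(np.sqrt(var), sd_sk, atol=1e-6)


def test_fit_gp_constant_target(rng):
    z = rng.normal(size=(10, 2))
    model = fit_gp(FitnessDataset(z, np.full(10, 3.7)))
    mean, _ = model.predict(rng.normal(size=(5, 2)))
    assert np.allclose(mean, 3.7, atol=1e-6)


def test_fit_gp_improves_on_initialization(rng):
    z = rng.normal(size=(60, 2))
    y = np.cos(z[:, 0]) + 0.3 * rng.normal(size=60)
    data = FitnessDataset(z, y)
    model = fit_gp(data, seed=0)
    from tvae.gp import _neg_lml

    y_var = float(np.var(y))
    from scipy.spatial.distance import cdist

    scale = float(np.median(cdist(z, z)))
    init = -_neg_lml(np.log([y_var, scale, 0.1 * y_var]), data)
    assert model.log_marginal_likelihood() >= init - 1e-9


def test_fit_gp_recovers_length_scale():
    """Median fitted length scale within a factor 1.5 of truth
    (data generated from a GP with sg2=2, lambda=1.5, sn2=0.1, n=200)."""
    truth = GpHyperparams(2.0, 1.5, 0.1)
    ratios = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        z = rng.uniform(-3, 3, size=(200, 2))
        k = rbf_kernel(z, z, truth) + truth.noise_var * np.eye(200)
        y = rng.multivariate_normal(np.zeros(200), k, method="cholesky")
        model = fit_gp(FitnessDataset(z, y), seed=seed)
        ratios.append(model.hyper.length_scale / truth.length_scale)
    median = float(np.median(ratios))
    assert 1 / 1.5 <= median <= 1.5


def test_synthetic_landscape_heldout_pearson():
    """GP on 200 2-D latents with a smooth fitness + noise sd 0.5
    reaches held-out Pearson >= 0.9."""
    rng = np.random.default_rng(2024)
    z = rng.normal(size=(200, 2))
    f = 60.0 + 4.0 * np.sin(z[:, 0]) + 3.0 * z[:, 1]
    y = f + 0.5 * rng.normal(size=200)
    train, test = split_dataset(FitnessDataset(z, y), 0.2, seed=0)
    model = fit_gp(train, seed=0)
    pred, _ = model.predict(test.z)
    r, mad = eval_metrics(pred, test.y)
    assert r >= 0.9
    assert mad < 2.0


def test_eval_metrics_hand_values():
    r, mad = eval_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
    assert mad == pytest.approx(1 / 3)
    # hand Pearson for (1,2,3) vs (1,2,4)
    assert r == pytest.approx(np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1])
    pred = np.array([3.0, 1.0, 2.0])
    truth = pred.copy()
    assert eval_metrics(pred, truth) == (pytest.approx(1.0), pytest.approx(0.0))
    r2, _ = eval_metrics(-(truth - truth.mean()), truth)
    assert r2 == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        eval_metrics(pred, np.ones(3))


def test_split_counts_reproduce_protocol():
    assert train_test_split_counts(278, 0.2) == (222, 56)
    assert train_test_split_counts(10, 0.2) == (8, 2)


def test_split_dataset_is_seeded_partition(rng):
    data = FitnessDataset(rng.normal(size=(30, 2)), rng.normal(size=30))
    tr1, te1 = split_dataset(data, 0.2, seed=5)
    tr2, te2 = split_dataset(data, 0.2, seed=5)
    assert np.array_equal(tr1.z, tr2.z) and np.array_equal(te1.y, te2.y)
    assert tr1.n + te1.n == 30 and te1.n == 6
    assert len(set(tr1.ids) | set(te1.ids)) == 30
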
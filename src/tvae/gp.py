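"""Gaussian-process regression from latent codes to fitness values.

An RBF-kernel GP maps the encoder's latent means to a scalar fitness
(e.g. T50, the temperature at which half of a protein is irreversibly
inactivated).  Hyperparameters (signal variance, length scale, noise
variance) are fitted by maximizing the log marginal likelihood with
multi-start L-BFGS-B in log space; predictions use a cached Cholesky
factorization of K + sigma_n^2 I.  The target is centered by its
training mean, which is added back at prediction (constant mean
function), so far from the data the posterior reverts to the training
mean with variance sigma_g^2 + sigma_n^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

NOISE_FLOOR = 1e-8


@dataclass
class FitnessDataset:
    """Latent codes z (n x d) with fitness labels y (n,)."""

    z: np.ndarray
    y: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.z.shape[0] != self.y.size:
            raise ValueError("z and y must have matching first dimension")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("fitness labels must be finite (no missing values)")
        if self.ids is None:
            self.ids = [f"seq_{i}" for i in range(self.y.size)]

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def d(self) -> int:
        return self.z.shape[1]


@dataclass
class GpHyperparams:
    signal_var: float
    length_scale: float
    noise_var: float

    def __post_init__(self) -> None:
        if self.signal_var <= 0 or self.length_scale <= 0:
            raise ValueError("signal variance and length scale must be positive")
        self.noise_var = max(float(self.noise_var), NOISE_FLOOR)


def rbf_kernel(z1: np.ndarray, z2: np.ndarray, hyper: GpHyperparams) -> float | np.ndarray:
    """k(z1, z2) = sigma_g^2 exp(-||z1 - z2||^2 / (2 lambda^2)).

    Accepts single d-vectors (returns a scalar) or (n x d, m x d)
    matrices (returns the n x m Gram block).
    """
    a = np.atleast_2d(np.asarray(z1, dtype=float))
    b = np.atleast_2d(np.asarray(z2, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("inputs must share a dimension")
    sq = cdist(a, b, "sqeuclidean")
    k = hyper.signal_var * np.exp(-0.5 * sq / hyper.length_scale**2)
    return float(k[0, 0]) if (np.asarray(z1).ndim == 1 and np.asarray(z2).ndim == 1) else k


class GpModel:
    """Fitted GP: hyperparameters + cached Cholesky solve of the training set."""

    def __init__(self, data: FitnessDataset, hyper: GpHyperparams):
        self.data = data
        self.hyper = hyper
        self.y_mean = float(np.mean(data.y))
        k = rbf_kernel(data.z, data.z, hyper)
        k[np.diag_indices_from(k)] += hyper.noise_var
        try:
            self._chol = cho_factor(k, lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "kernel matrix is singular despite jitter; increase noise_var "
                "or remove duplicate latent points") from err
        self._alpha = cho_solve(self._chol, data.y - self.y_mean)

    def log_marginal_likelihood(self) -> float:
        yc = self.data.y - self.y_mean
        logdet = 2.0 * np.sum(np.log(np.diag(self._chol[0])))
        return float(-0.5 * yc @ self._alpha - 0.5 * logdet
                     - 0.5 * self.data.n * np.log(2.0 * np.pi))

    def predict(self, z_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance at query point(s).

        Returns scalars for a single d-vector, arrays for an m x d
        batch.  Variance includes the noise term, so at a training
        point with sigma_n^2 -> 0 the mean reproduces the label and the
        variance -> 0.
        """
        single = np.asarray(z_star).ndim == 1
        zq = np.atleast_2d(np.asarray(z_star, dtype=float))
        ks = rbf_kernel(zq, self.data.z, self.hyper)  # m x n
        mean = self.y_mean + ks @ self._alpha
        v = cho_solve(self._chol, ks.T)  # n x m
        var = self.hyper.signal_var + self.hyper.noise_var - np.einsum("mn,nm->m", ks, v)
        var = np.maximum(var, 0.0)
        if single:
            return float(mean[0]), float(var[0])
        return mean, var


def _neg_lml(log_params: np.ndarray, data: FitnessDataset) -> float:
    hyper = GpHyperparams(*np.exp(log_params))
    try:
        return -GpModel(data, hyper).log_marginal_likelihood()
    except np.linalg.LinAlgError:
        return 1e12


def fit_gp(data: FitnessDataset, n_restarts: int = 5, seed: int = 0) -> GpModel:
    """Maximize the log marginal likelihood over (sigma_g^2, lambda, sigma_n^2).

    Optimization runs in log space with L-BFGS-B from a data-driven
    initial point plus ``n_restarts`` seeded random restarts; the best
    optimum wins.  Degenerate (constant-y) data falls back to a tiny
    signal variance so predictions equal the constant.
    """
    if data.n < 2:
        raise ValueError("GP fitting requires n >= 2")
    y_var = float(np.var(data.y))
    scale = float(np.median(cdist(data.z, data.z))) or 1.0
    if y_var == 0.0:
        return GpModel(data, GpHyperparams(NOISE_FLOOR * 10, scale, NOISE_FLOOR))
    rng = np.random.default_rng(seed)
    x0 = np.log([y_var, scale, 0.1 * y_var])
    starts = [x0] + [x0 + rng.normal(0.0, 1.0, size=3) for _ in range(n_restarts)]
    best = None
    for start in starts:
        res = minimize(_neg_lml, start, args=(data,), method="L-BFGS-B",
                       bounds=[(-15, 15)] * 3)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    model = GpModel(data, GpHyperparams(*np.exp(best.x)))
    # optimization contract: never worse than the untuned initial point
    init_lml = -_neg_lml(x0, data)
    if model.log_marginal_likelihood() < init_lml:
        model = GpModel(data, GpHyperparams(*np.exp(x0)))
    return model


def eval_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(Pearson r, mean absolute deviation) between predictions and truth."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size != truth.size or pred.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    mad = float(np.mean(np.abs(pred - truth)))
    if np.ptp(truth) == 0.0:
        raise ValueError("Pearson correlation is undefined for constant truth")
    r = float(pearsonr(pred, truth).statistic)
    return r, mad


def train_test_split_counts(n: int, test_frac: float) -> tuple[int, int]:
    """Train/test sizes with the test count rounded to nearest.

    278 items at test_frac 0.2 give 222 train / 56 test.
    """
    n_test = int(round(n * test_frac))
    return n - n_test, n_test


def split_dataset(data: FitnessDataset, test_frac: float, seed: int
                  ) -> tuple[FitnessDataset, FitnessDataset]:
    """Seeded, stratification-free random split."""
    _, n_test = train_test_split_counts(data.n, test_frac)
    rng = np.random.default_rng(seed)
    order = rng.permutation(data.n)
    test_idx, train_idx = np.sort(order[:n_test]), np.sort(order[n_test:])
    ids = np.asarray(data.ids)
    return (
        FitnessDataset(data.z[train_idx], data.y[train_idx], list(ids[train_idx])),
        FitnessDataset(data.z[test_idx], data.y[test_idx], list(ids[test_idx])),
    )
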
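import numpy as np
import pytest

from tvae.msa_prep import encode_onehot, family_onehot
from tvae.vae import (TVAE, LatentGaussian, TrainConfig, kl_to_standard_normal,
                      mean_reconstruction_identity, reparameterize)
from tvae.tcn import TcnConfig


def mc_kl_estimate(g: LatentGaussian, n: int, seed: int) -> float:
    """Monte-Carlo E_q[log q(z) - log p(z)] with p = N(0, I)."""
    rng = np.random.default_rng(seed)
    z = g.mu + g.sigma * rng.standard_normal((n, g.d))
    log_q = -0.5 * np.sum((z - g.mu) ** 2 / g.sigma**2 + g.log_var + np.log(2 * np.pi), axis=1)
    log_p = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
    return float(np.mean(log_q - log_p))


def importance_sampled_loglik(model: TVAE, onehot: np.ndarray, n_samples: int,
                              seed: int) -> float:
    """log p_hat(x) = logmeanexp(log p(x|z) + log p(z) - log q(z|x)), z ~ q."""
    g = model.encode(onehot)[0]
    rng = np.random.default_rng(seed)
    z = g.mu + g.sigma * rng.standard_normal((n_samples, g.d))
    probs = model.decode(z)  # (S, L, 21)
    target = np.argmax(onehot, axis=0)
    log_px_z = np.sum(np.log(probs[:, np.arange(target.size), target] + 1e-300), axis=1)
    log_p = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
    log_q = -0.5 * np.sum((z - g.mu) ** 2 / g.sigma**2 + g.log_var + np.log(2 * np.pi), axis=1)
    w = log_px_z + log_p - log_q
    return float(np.log(np.mean(np.exp(w - w.max()))) + w.max())


def test_kl_closed_form_basics():
    assert kl_to_standard_normal(LatentGaussian(np.zeros(4), np.zeros(4))) == 0.0
    assert kl_to_standard_normal(LatentGaussian([1.0], [0.0])) == pytest.approx(0.5)


def test_kl_matches_monte_carlo(rng):
    """Closed form within 1% of a 10^6-sample MC estimate, 20 random Gaussians."""
    for i in range(20):
        g = LatentGaussian(rng.uniform(-2, 2, size=3), rng.uniform(-1, 1, size=3))
        exact = kl_to_standard_normal(g)
        mc = mc_kl_estimate(g, 10**6, seed=100 + i)
        assert mc == pytest.approx(exact, rel=0.01)


def test_reparameterize_is_seeded_and_limits():
    g = LatentGaussian([1.0, -2.0], [-60.0, -60.0])  # sigma ~ 0
    assert np.allclose(reparameterize(g, 0), g.mu, atol=1e-12)
    g2 = LatentGaussian([0.5, 0.5], [0.3, -0.3])
    assert np.array_equal(reparameterize(g2, 7), reparameterize(g2, 7))


def test_reparameterize_clt_mean():
    g = LatentGaussian([2.0, -1.0, 0.5], [0.4, -0.2, 0.0])
    rng = np.random.default_rng(5)
    draws = g.mu + g.sigma * rng.standard_normal((10**5, 3))
    tol = 3 * g.sigma / np.sqrt(10**5)
    assert np.all(np.abs(draws.mean(axis=0) - g.mu) < tol)


def test_decode_columns_are_distributions(toy_model, rng):
    z = rng.normal(size=(5, 2))
    p = toy_model.decode(z)
    assert p.shape == (5, 20, 21)
    assert np.allclose(p.sum(axis=2), 1.0, atol=1e-6)
    assert np.array_equal(p, toy_model.decode(z))


def test_decoder_with_zero_weights_is_uniform(toy_model):
    saved = toy_model.decoder.fc2.w.data.copy(), toy_model.decoder.fc2.b.data.copy()
    toy_model.decoder.fc2.w.data[:] = 0.0
    toy_model.decoder.fc2.b.data[:] = 0.0
    p = toy_model.decode(np.zeros(2))
    assert np.allclose(p, 1.0 / 21)
    toy_model.decoder.fc2.w.data, toy_model.decoder.fc2.b.data = saved


def test_elbo_components_uniform_decoder(toy_model, rng):
    saved = toy_model.decoder.fc2.w.data.copy(), toy_model.decoder.fc2.b.data.copy()
    toy_model.decoder.fc2.w.data[:] = 0.0
    toy_model.decoder.fc2.b.data[:] = 0.0
    onehot = encode_onehot(rng.integers(0, 21, size=20).astype(np.int8))
    parts = toy_model.elbo_components(onehot, seed=1)
    assert parts.reconstruction == pytest.approx(-20 * np.log(21))
    assert parts.kl >= 0.0
    assert parts.elbo <= parts.reconstruction
    toy_model.decoder.fc2.w.data, toy_model.decoder.fc2.b.data = saved


def test_elbo_bounded_by_importance_sampled_loglik(toy_model, rng):
    """ELBO (64-draw estimate of E_q) <= IS log-likelihood (1000 samples)
    on 100 random inputs."""
    violations = 0
    for i in range(100):
        onehot = encode_onehot(rng.integers(0, 21, size=20).astype(np.int8))
        parts = toy_model.elbo_components(onehot, seed=i, n_samples=64)
        log_px = importance_sampled_loglik(toy_model, onehot, 1000, seed=1000 + i)
        if parts.elbo > log_px:
            violations += 1
    assert violations == 0


def test_training_progress_and_determinism(tiny_family):
    fam = tiny_family.family
    def build():
        return TVAE(TcnConfig(n_blocks=1, hidden_channels=8, out_channels=8,
                              dropout=0.0),
                    TrainConfig(epochs=40, dim_z=2, hidden_layer=16, seed=11),
                    fam.length)
    m1, m2 = build(), build()
    t1, t2 = m1.train(fam), m2.train(fam)
    assert t1[-1]["elbo"] > t1[0]["elbo"]
    assert t1 == t2  # bitwise-identical traces for identical config/data
    for p1, p2 in zip(m1.params(), m2.params()):
        assert np.array_equal(p1.data, p2.data)


def test_training_aborts_on_divergence(tiny_family):
    fam = tiny_family.family
    model = TVAE(TcnConfig(n_blocks=1, hidden_channels=4, out_channels=4, dropout=0.0),
                 TrainConfig(epochs=5, dim_z=2, hidden_layer=8, seed=1,
                             learning_rate=1e-3),
                 fam.length)
    model.decoder.fc2.w.data[:] = np.inf
    with pytest.raises(RuntimeError, match="diverged"):
        model.train(fam)


def test_memorization_identity(tiny_trained, tiny_family):
    """After 2000 epochs on 30 sequences the argmax reconstructions
    recover >= 95% of residues on average."""
    model, trace = tiny_trained
    assert trace[-1]["elbo"] > trace[0]["elbo"]
    assert mean_reconstruction_identity(tiny_family.family, model) >= 95.0
    assert np.isfinite(trace[-1]["kl"]) and trace[-1]["kl"] > 0.0


def test_fine_tune_zero_epochs_is_noop(tiny_trained, tiny_family):
    model, _ = tiny_trained
    before = [p.data.copy() for p in model.params()]
    model.fine_tune(tiny_family.family, epochs=0)
    for old, p in zip(before, model.params()):
        assert np.array_equal(old, p.data)


def test_fine_tune_adapts_to_held_out_clade(tiny_family):
    """Fine-tuning on a held-out clade improves its reconstruction
    log-likelihood relative to the pretrained model."""
    from tvae.msa_prep import AlignedFamily, family_onehot

    fam = tiny_family.family
    labels = tiny_family.clade_labels
    held = labels == labels[np.argmin(np.bincount(labels))]
    if held.sum() < 2:  # need a nontrivial held-out group
        held = labels == labels[0]
    pre = AlignedFamily(ids=[i for i, h in zip(fam.ids, held) if not h],
                        matrix=fam.matrix[~held])
    post = AlignedFamily(ids=[i for i, h in zip(fam.ids, held) if h],
                         matrix=fam.matrix[held])
    model = TVAE(TcnConfig(n_blocks=1, hidden_channels=12, out_channels=12,
                           dropout=0.0),
                 TrainConfig(epochs=300, dim_z=2, hidden_layer=24, seed=21,
                             learning_rate=3e-3),
                 fam.length)
    model.train(pre)

    def heldout_loglik():
        x = family_onehot(post)
        total = 0.0
        for i in range(post.n):
            g = model.encode(x[i])[0]
            probs = model.decode(g.mu)
            total += float(np.sum(np.log(
                probs[np.arange(fam.length), post.matrix[i]] + 1e-300)))
        return total

    before = heldout_loglik()
    model.fine_tune(post, epochs=300)
    assert heldout_loglik() > before


def test_fine_tune_rejects_length_mismatch(tiny_trained, clade_sim):
    model, _ = tiny_trained
    with pytest.raises(ValueError, match="length"):
        model.fine_tune(clade_sim.family, epochs=1)


def test_embed_family_shape_and_duplicates(toy_model, rng):
    from tvae.msa_prep import AlignedFamily

    row = rng.integers(0, 21, size=20).astype(np.int8)
    fam = AlignedFamily(ids=["a", "b"], matrix=np.stack([row, row]))
    emb = toy_model.embed_family(fam)
    assert emb.shape == (2, 2)
    assert np.array_equal(emb[0], emb[1])


def test_checkpoint_roundtrip(tmp_path, toy_model, rng):
    path = tmp_path / "model.ckpt.npz"
    toy_model.save(str(path))
    loaded = TVAE.load(str(path))
    x = family_onehot_like(rng)
    g1, g2 = toy_model.encode(x)[0], loaded.encode(x)[0]
    assert np.array_equal(g1.mu, g2.mu) and np.array_equal(g1.log_var, g2.log_var)


def family_onehot_like(rng):
    return encode_onehot(rng.integers(0, 21, size=20).astype(np.int8))
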
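"""Forward contracts of the model graph and exactness of its backward pass."""

import numpy as np
import pytest

from scdisentangle.network import DisentangledVAE, DsbnState, ModelConfig, reparameterize
from scdisentangle.objective import total_loss


@pytest.fixture
def toy_config():
    return ModelConfig(m=30, b=2, C=3, d=10, d1=4, d2=3,
                       enc_hidden=(12,), dec_hidden=(8, 11), cls_hidden=(7, 6), seed=1)


@pytest.fixture
def toy_model(toy_config):
    return DisentangledVAE(toy_config)


@pytest.fixture
def toy_batch(toy_config):
    rng = np.random.default_rng(0)
    n = 20
    X = rng.normal(size=(n, toy_config.m))
    B = np.zeros((n, toy_config.b))
    B[np.arange(n), rng.integers(0, toy_config.b, n)] = 1.0
    codes = rng.integers(0, toy_config.C, n)
    return X, B, codes


class TestConfig:
    def test_default_architecture_constants(self):
        cfg = ModelConfig(m=3000, b=6, C=3)
        assert cfg.d2 == 8
        assert cfg.cls_hidden == (100, 100, 100, 100)
        assert cfg.epochs == 50
        assert cfg.lr == 1e-4
        assert cfg.lambda_kl == 0.001 and cfg.mu_cls == 0.001
        assert cfg.enc_hidden == (512,) and cfg.d == 256 and cfg.dec_hidden == (256, 512)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(m=10, b=2, C=2, d1=8, d2=8)
        with pytest.raises(ValueError):
            ModelConfig(m=100, b=2, C=2, eps_bn=0.0)


class TestSharedEncoder:
    def test_output_nonnegative_and_correct_dim(self, toy_model, toy_batch):
        X, B, _ = toy_batch
        L = toy_model.encode_shared(X, B)
        assert L.shape == (20, toy_model.config.d)
        assert np.all(L >= 0)

    def test_default_shared_dim_is_256(self):
        model = DisentangledVAE(ModelConfig(m=500, b=2, C=2))
        L = model.encode_shared(np.zeros((3, 500)), np.zeros((3, 2)))
        assert L.shape == (3, 256)

    def test_zero_weights_give_zero_output(self, toy_model, toy_batch):
        X, B, _ = toy_batch
        for layer in toy_model.enc:
            layer.W[...] = 0.0
            layer.b[...] = 0.0
        assert np.all(toy_model.encode_shared(X, B) == 0.0)

    def test_dimension_mismatch_raises(self, toy_model):
        with pytest.raises(ValueError, match="dim"):
            toy_model.encode_shared(np.zeros((3, 99)), np.zeros((3, 2)))


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        mu = np.arange(6.0).reshape(2, 3)
        var = np.full((2, 3), 2.0)
        assert np.array_equal(reparameterize(mu, var, np.zeros((2, 3))), mu)

    def test_variance_vs_stddev_scaling(self):
        mu = np.zeros((1, 2))
        var = np.full((1, 2), 4.0)
        noise = np.ones((1, 2))
        assert np.allclose(reparameterize(mu, var, noise, "variance"), 4.0)
        assert np.allclose(reparameterize(mu, var, noise, "stddev"), 2.0)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)))

    def test_seeded_replay_bit_identical(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        b1 = toy_model.forward(X, B, codes, rng=np.random.default_rng(7), train=True)
        toy_model.dsbn = DsbnState.init(toy_model.config.C, toy_model.config.d2)
        b2 = toy_model.forward(X, B, codes, rng=np.random.default_rng(7), train=True)
        assert np.array_equal(b1.Z_bio, b2.Z_bio)
        assert np.array_equal(b1.Z_cond, b2.Z_cond)


class TestVariationalHeads:
    def test_head_dims_under_defaults(self):
        model = DisentangledVAE(ModelConfig(m=500, b=2, C=2))
        L = model.encode_shared(np.zeros((3, 500)), np.zeros((3, 2)))
        assert model.head_mu_cond.forward(L).shape == (3, 8)
        assert model.head_mu_bio.forward(L).shape == (3, 16)

    def test_variance_strictly_positive(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        bundle = toy_model.forward(X, B, codes, train=False)
        assert np.all(bundle.var_bio > 0)
        assert np.all(bundle.var_cond > 0)

    def test_mean_head_unbounded(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        bundle = toy_model.forward(X, B, codes, train=False)
        assert np.any(bundle.mu_bio < 0)  # no activation on the mean head


class TestDsbn:
    def test_train_mode_hand_case(self, toy_model):
        # one domain, one feature with rows (1, 3): mean 2, var 1
        Z = np.array([[1.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        out = toy_model.dsbn_forward(Z, np.array([0, 0]), train=True)
        eps = toy_model.config.eps_bn
        assert np.allclose(out[:, 0], [-1 / np.sqrt(1 + eps), 1 / np.sqrt(1 + eps)])

    def test_train_mode_moments(self, toy_model):
        rng = np.random.default_rng(0)
        Z = rng.normal(2.0, 3.0, size=(40, 3))
        codes = np.repeat([0, 1], 20)
        out = toy_model.dsbn_forward(Z, codes, train=True)
        for dom in (0, 1):
            rows = out[codes == dom]
            assert np.all(np.abs(rows.mean(axis=0)) <= 1e-5)
            var = Z[codes == dom].var(axis=0)
            expected = var / (var + toy_model.config.eps_bn)
            assert np.all(np.abs(rows.var(axis=0) - expected) <= 1e-5)

    def test_single_cell_domain_outputs_zero(self, toy_model):
        Z = np.array([[5.0, -2.0, 1.0]])
        out = toy_model.dsbn_forward(Z, np.array([0]), train=True)
        assert np.allclose(out, 0.0)

    def test_eval_uses_running_stats(self, toy_model):
        toy_model.dsbn.running_mean[1] = 2.0
        toy_model.dsbn.running_var[1] = 4.0
        Z = np.array([[4.0, 4.0, 4.0]])
        out = toy_model.dsbn_forward(Z, np.array([1]), train=False)
        assert np.allclose(out, 2.0 / np.sqrt(4.0 + toy_model.config.eps_bn))

    def test_label_symmetry(self, toy_config):
        # swapping two domains' labels permutes branch assignment but leaves
        # the set of normalized outputs unchanged
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(30, toy_config.d2))
        codes = np.repeat([0, 1, 2], 10)
        swapped = codes.copy()
        swapped[codes == 0], swapped[codes == 1] = 1, 0
        m1 = DisentangledVAE(toy_config)
        m2 = DisentangledVAE(toy_config)
        out1 = m1.dsbn_forward(Z, codes, train=True)
        out2 = m2.dsbn_forward(Z, swapped, train=True)
        assert np.allclose(np.sort(out1, axis=0), np.sort(out2, axis=0))


class TestResidualAndClassifier:
    def test_residual_decomposition_exact(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        bundle = toy_model.forward(X, B, codes, rng=np.random.default_rng(0), train=True)
        assert np.array_equal(bundle.Z_cond_sp + bundle.Z_cond_shared, bundle.Z_cond)

    def test_residual_matches_elementwise_subtraction(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        bundle = toy_model.forward(X, B, codes, train=False)
        expected = np.asarray([[bundle.Z_cond[i, j] - bundle.Z_cond_shared[i, j]
                                for j in range(bundle.Z_cond.shape[1])]
                               for i in range(bundle.Z_cond.shape[0])])
        assert np.array_equal(bundle.Z_cond_sp, expected)

    def test_classifier_logprobs_normalized(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        bundle = toy_model.forward(X, B, codes, train=False)
        assert np.allclose(np.exp(bundle.cls_logprob).sum(axis=1), 1.0, atol=1e-6)

    def test_zero_final_layer_uniform(self, toy_model):
        toy_model.cls[-1].W[...] = 0.0
        toy_model.cls[-1].b[...] = 0.0
        logprob = toy_model.classify(np.random.default_rng(0).normal(size=(5, 3)))
        assert np.allclose(np.exp(logprob), 1.0 / 3.0)

    def test_classifier_hidden_sizes_default(self):
        cfg = ModelConfig(m=500, b=2, C=4)
        model = DisentangledVAE(cfg)
        assert [l.W.shape for l in model.cls] == [(8, 100), (100, 100), (100, 100), (100, 100), (100, 4)]


class TestDecoder:
    def test_output_shape_and_sign(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        bundle = toy_model.forward(X, B, codes, train=False)
        assert bundle.X_tilde.shape == X.shape
        assert np.any(bundle.X_tilde < 0)  # linear output can be negative

    def test_zero_weights_zero_reconstruction(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        for layer in toy_model.dec:
            layer.W[...] = 0.0
            layer.b[...] = 0.0
        assert np.all(toy_model.decode(np.ones((20, 4)), np.ones((20, 3)), B) == 0.0)


class TestEvalDeterminism:
    def test_eval_forward_deterministic(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        b1 = toy_model.forward(X, B, codes, train=False)
        b2 = toy_model.forward(X, B, codes, train=False)
        assert np.array_equal(b1.X_tilde, b2.X_tilde)
        assert np.array_equal(b1.Z_cond_sp, b2.Z_cond_sp)

    def test_eval_embeddings_are_means(self, toy_model, toy_batch):
        X, B, codes = toy_batch
        bundle = toy_model.forward(X, B, codes, train=False)
        assert np.array_equal(bundle.Z_bio, bundle.mu_bio)
        assert np.array_equal(bundle.Z_cond, bundle.mu_cond)


class TestGradients:
    """Backward pass vs central finite differences on the toy model.

    Each loss component is checked separately so the finite-difference
    quotient is not dominated by the other (much larger) terms.
    """

    @pytest.mark.parametrize("component", ["recon", "kl", "cls"])
    def test_backward_matches_finite_differences(self, toy_config, toy_batch, component):
        X, B, codes = toy_batch
        n = X.shape[0]
        model = DisentangledVAE(toy_config)
        model.dsbn.momentum = 0.0  # freeze running stats so replays are identical

        def component_loss():
            bundle = model.forward(X, B, codes, rng=np.random.default_rng(5), train=True)
            lb = total_loss(X, bundle.X_tilde, bundle.mu_bio, bundle.var_bio,
                            bundle.mu_cond, bundle.var_cond, bundle.cls_logprob, codes)
            return {"recon": lb.recon, "kl": lb.kl, "cls": lb.cls}[component], bundle

        _, bundle = component_loss()
        model.zero_grad()
        zeros = lambda a: np.zeros_like(a)
        prob = np.exp(bundle.cls_logprob)
        onehot = np.zeros((n, toy_config.C))
        onehot[np.arange(n), codes] = 1.0
        grads = dict(
            d_X_tilde=zeros(X), d_cls_logits=np.zeros((n, toy_config.C)),
            d_mu_bio=zeros(bundle.mu_bio), d_logvar_bio=zeros(bundle.mu_bio),
            d_mu_cond=zeros(bundle.mu_cond), d_logvar_cond=zeros(bundle.mu_cond),
        )
        if component == "recon":
            grads["d_X_tilde"] = 2.0 * (bundle.X_tilde - X)
        elif component == "kl":
            grads["d_mu_bio"] = bundle.mu_bio
            grads["d_logvar_bio"] = 0.5 * (bundle.var_bio - 1.0)
            grads["d_mu_cond"] = bundle.mu_cond
            grads["d_logvar_cond"] = 0.5 * (bundle.var_cond - 1.0)
        else:
            grads["d_cls_logits"] = (prob - onehot) / n
        model.backward(**grads)

        rng = np.random.default_rng(11)
        h = 1e-4
        for p, g in model.parameters():
            flat_p, flat_g = p.ravel(), g.ravel()
            for i in rng.integers(0, flat_p.size, size=2):
                old = flat_p[i]
                flat_p[i] = old + h
                lp, _ = component_loss()
                flat_p[i] = old - h
                lm, _ = component_loss()
                flat_p[i] = old
                fd = (lp - lm) / (2 * h)
                denom = max(abs(fd), abs(flat_g[i]), 1e-4)
                assert abs(fd - flat_g[i]) / denom <= 1e-3

    def test_checkpoint_roundtrip(self, toy_config, toy_batch, tmp_path):
        X, B, codes = toy_batch
        model = DisentangledVAE(toy_config)
        model.forward(X, B, codes, rng=np.random.default_rng(0), train=True)  # move running stats
        model.save(tmp_path / "ckpt.h5", extra={"note": "test"})
        loaded, extra = DisentangledVAE.load(tmp_path / "ckpt.h5")
        assert extra["note"] == "test"
        b1 = model.forward(X, B, codes, train=False)
        b2 = loaded.forward(X, B, codes, train=False)
        assert np.array_equal(b1.X_tilde, b2.X_tilde)
        assert np.array_equal(b1.Z_cond_sp, b2.Z_cond_sp)
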
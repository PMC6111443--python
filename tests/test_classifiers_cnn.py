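"""CNN forward/backward correctness: oracles, parameter counts, training."""

import numpy as np
import pytest

from emgdays.classifiers import (
    CNNConfig,
    cnn_forward,
    cnn_init,
    cnn_loss_grad,
    cnn_predict,
    cnn_train,
)
from emgdays.classifiers.cnn import _forward, _normalize
from emgdays.dataset import ValidationError


def conv_pool_fc_oracle(model, window):
    """Quadruple-loop valid convolution + ReLU + max pool + FC + softmax."""
    x = (window - model.channel_mean) / model.channel_std
    fh, fw, nf = model.conv_w.shape
    h, w = x.shape
    oh, ow = h - fh + 1, w - fw + 1
    conv = np.zeros((oh, ow, nf))
    for f in range(nf):
        for i in range(oh):
            for j in range(ow):
                s = 0.0
                for a in range(fh):
                    for b in range(fw):
                        s += x[i + a, j + b] * model.conv_w[a, b, f]
                conv[i, j, f] = max(s + model.conv_b[f], 0.0)
    ph, pw = model.config.pool_shape
    nh, nw = oh // ph, ow // pw
    pooled = np.zeros((nh, nw, nf))
    for f in range(nf):
        for i in range(nh):
            for j in range(nw):
                pooled[i, j, f] = conv[
                    i * ph : (i + 1) * ph, j * pw : (j + 1) * pw, f
                ].max()
    logits = pooled.reshape(-1) @ model.fc_w + model.fc_b
    e = np.exp(logits - logits.max())
    return e / e.sum()


@pytest.fixture(scope="module")
def default_model():
    return cnn_init((30, 8), 7, CNNConfig(seed=0), np.random.default_rng(0))


def test_forward_is_probability_vector(default_model):
    rng = np.random.default_rng(1)
    for _ in range(5):
        p = cnn_forward(default_model, rng.normal(size=(30, 8)))
        assert p.shape == (7,)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_parameter_counts_pin_architecture(default_model):
    """Valid 3x3 conv -> 28 x 6 x 32; 3x1 pool -> 9 x 6 x 32."""
    assert default_model.conv_w.size + default_model.conv_b.size == 320
    assert default_model.fc_w.size + default_model.fc_b.size == 12_103
    assert default_model.pooled_shape == (9, 6)


def test_forward_equals_loop_oracle(default_model):
    rng = np.random.default_rng(2)
    # exercise the stored normalization too
    default_model.channel_mean = rng.normal(size=8) * 0.1
    default_model.channel_std = rng.uniform(0.5, 2.0, size=8)
    for _ in range(3):
        w = rng.normal(size=(30, 8))
        np.testing.assert_allclose(
            cnn_forward(default_model, w),
            conv_pool_fc_oracle(default_model, w),
            atol=1e-6,
        )


def test_gradients_match_finite_differences():
    """Micro-network (4x4 input, 2 filters, 2 classes) parameter gradients
    vs central differences at 1e-5 relative tolerance."""
    cfg = CNNConfig(
        n_filters=2, filter_shape=(3, 3), pool_shape=(2, 1), seed=0
    )
    rng = np.random.default_rng(3)
    model = cnn_init((4, 4), 2, cfg, rng)
    X = rng.normal(size=(6, 4, 4))
    y1h = np.eye(2)[rng.integers(0, 2, size=6)]
    params = ["conv_w", "conv_b", "fc_w", "fc_b"]
    _, grads = cnn_loss_grad(model, X, y1h)
    eps = 1e-6
    for p, g in zip(params, grads):
        base = getattr(model, p)
        num = np.zeros_like(base)
        it = np.nditer(base, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            for sign in (+1, -1):
                perturbed = base.copy()
                perturbed[idx] += sign * eps
                setattr(model, p, perturbed)
                val, _ = cnn_loss_grad(model, X, y1h)
                num[idx] += sign * val / (2 * eps)
            setattr(model, p, base)
        np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-7)


def test_training_fits_easy_data_deterministically():
    """Amplitude-coded 3-class windows: training converges, and the same
    seed reproduces the exact weights."""
    rng = np.random.default_rng(4)
    n = 240
    y = rng.integers(0, 3, size=n)
    # class-specific channel activation patterns riding on noise
    pattern = np.array(
        [[2, 0, 0, 0, 2, 0, 0, 0],
         [0, 0, 2, 0, 0, 0, 2, 0],
         [0, 2, 0, 2, 0, 2, 0, 2]],
        dtype=float,
    )
    X = rng.normal(size=(n, 30, 8)) * (0.3 + pattern[y][:, None, :])
    cfg = CNNConfig(n_filters=8, max_epochs=15, lr=0.05, seed=5)
    m1 = cnn_train(X, y, cfg)
    assert np.mean(cnn_predict(m1, X) == y) > 0.9
    m2 = cnn_train(X, y, cfg)
    np.testing.assert_array_equal(m1.conv_w, m2.conv_w)
    np.testing.assert_array_equal(m1.fc_w, m2.fc_w)
    assert m1.loss_history == m2.loss_history


def test_wrong_input_shape_rejected(default_model):
    with pytest.raises(ValidationError, match="30"):
        cnn_forward(default_model, np.zeros((20, 8)))


def test_pool_must_fit():
    cfg = CNNConfig(filter_shape=(3, 3), pool_shape=(5, 1))
    with pytest.raises(ValidationError, match="pool"):
        cnn_init((6, 4), 2, cfg, np.random.default_rng(0))


def test_batch_forward_consistent_with_single(default_model):
    rng = np.random.default_rng(6)
    X = rng.normal(size=(4, 30, 8))
    batch = _forward(default_model, _normalize(default_model, X))
    for i in range(4):
        np.testing.assert_allclose(batch[i], cnn_forward(default_model, X[i]))
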
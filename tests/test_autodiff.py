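"""Reverse-mode engine: gradient checks against finite differences."""

import numpy as np
import pytest

from voxmotion import autodiff as ad
from voxmotion.fields import Grid3, VelocityField, integrate_velocity

from conftest import smooth_velocity


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def quadratic_loss(out: ad.Tensor, target: np.ndarray) -> ad.Tensor:
    return ad.Tensor(
        ((out.data - target) ** 2).sum(), (out,), lambda g: (2 * (out.data - target) * g,)
    )


@pytest.mark.parametrize(
    "nd,k,stride", [(2, 4, 2), (2, 3, 1), (3, 4, 2), (3, 3, 1)]
)
def test_conv_gradients_match_finite_differences(nd, k, stride):
    rng = np.random.default_rng(0)
    shape = (2, 2) + (6,) * nd
    x = ad.Tensor(rng.standard_normal(shape).astype(np.float32), requires_grad=True)
    w = ad.Parameter(rng.standard_normal((3, 2) + (k,) * nd).astype(np.float32) * 0.2)
    tgt_shape = ad.conv_nd(x, w, stride, 1).shape
    tgt = rng.standard_normal(tgt_shape).astype(np.float32)

    def f():
        out = ad.conv_nd(ad.Tensor(x.data), ad.Tensor(w.data), stride, 1)
        return float(((out.data.astype(np.float64) - tgt) ** 2).sum())

    out = ad.conv_nd(x, w, stride, 1)
    quadratic_loss(out, tgt).backward()
    for tensor in (x, w):
        num = numeric_grad(f, tensor.data)
        assert np.abs(num - tensor.grad).max() / np.abs(num).max() < 5e-3


@pytest.mark.parametrize("nd", [2, 3])
def test_transpose_conv_gradients(nd):
    rng = np.random.default_rng(1)
    x = ad.Tensor(rng.standard_normal((1, 2) + (3,) * nd).astype(np.float32), requires_grad=True)
    w = ad.Parameter(rng.standard_normal((2, 3) + (4,) * nd).astype(np.float32) * 0.1)
    out = ad.conv_transpose_nd(x, w, 2, 1)
    assert out.shape == (1, 3) + (6,) * nd  # doubles spatial size
    tgt = rng.standard_normal(out.shape).astype(np.float32)

    def f():
        o = ad.conv_transpose_nd(ad.Tensor(x.data), ad.Tensor(w.data), 2, 1)
        return float(((o.data.astype(np.float64) - tgt) ** 2).sum())

    quadratic_loss(out, tgt).backward()
    for tensor in (x, w):
        num = numeric_grad(f, tensor.data)
        assert np.abs(num - tensor.grad).max() / np.abs(num).max() < 5e-3


def test_batch_norm_gradients_and_running_stats():
    rng = np.random.default_rng(2)
    x = ad.Tensor(rng.standard_normal((4, 3, 5)).astype(np.float32), requires_grad=True)
    gamma = ad.Parameter(np.ones(3, dtype=np.float32))
    beta = ad.Parameter(np.zeros(3, dtype=np.float32))
    tgt = rng.standard_normal((4, 3, 5)).astype(np.float32)

    def f():
        rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
        o = ad.batch_norm(ad.Tensor(x.data), ad.Tensor(gamma.data), ad.Tensor(beta.data), rm, rv, True)
        return float(((o.data.astype(np.float64) - tgt) ** 2).sum())

    rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
    out = ad.batch_norm(x, gamma, beta, rm, rv, True)
    quadratic_loss(out, tgt).backward()
    for tensor in (x, gamma, beta):
        num = numeric_grad(f, tensor.data)
        assert np.abs(num - tensor.grad).max() / max(np.abs(num).max(), 1e-6) < 5e-3
    # running statistics moved toward the batch statistics
    assert rm.any() and not np.allclose(rv, 1.0)
    # evaluation mode uses the running statistics (different output)
    eval_out = ad.batch_norm(ad.Tensor(x.data), gamma, beta, rm, rv, False)
    assert not np.allclose(eval_out.data, out.data)


def test_squaring_step_gradient_inside_cells():
    rng = np.random.default_rng(3)
    sp = (2.0, 2.0, 2.0)
    # fractional sampling positions well inside cells avoid trilinear kinks
    d = ad.Tensor((0.6 + 0.3 * rng.random((1, 3, 5, 5, 5))).astype(np.float32), requires_grad=True)
    base = np.stack(np.meshgrid(*(np.arange(5, dtype=np.float32),) * 3, indexing="ij"))
    tgt = rng.standard_normal((1, 3, 5, 5, 5)).astype(np.float32)

    def f():
        o = ad.squaring_step(ad.Tensor(d.data), sp, base)
        return float(((o.data.astype(np.float64) - tgt) ** 2).sum())

    out = ad.squaring_step(d, sp, base)
    quadratic_loss(out, tgt).backward()
    num = numeric_grad(f, d.data)
    assert np.abs(num - d.grad).max() / np.abs(num).max() < 5e-3


def test_integrate_displacement_matches_reference_integrator():
    """The jitted training-time integrator agrees with the scipy-based one."""
    grid = Grid3((16, 16, 16), (2.0, 3.0, 2.0))
    u = smooth_velocity(grid, seed=4, max_voxels=2.0, sigma=3.0)
    ref = integrate_velocity(u, 8).components
    t = ad.integrate_displacement(ad.Tensor(u.components[None].astype(np.float32)), 8, grid.spacing)
    err_vox = np.abs(t.data[0] - ref) / np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    assert err_vox[:, 2:-2, 2:-2, 2:-2].max() < 1e-3


def test_masked_mse_loss_values_and_gradient():
    rng = np.random.default_rng(5)
    pred = ad.Tensor(rng.standard_normal((2, 3, 4, 4, 4)).astype(np.float32), requires_grad=True)
    label = pred.data.copy()
    mask = np.zeros((4, 4, 4), np.float32)
    mask[1:3, 1:3, 1:3] = 1
    assert float(ad.masked_mse_loss(pred, label, mask).data) == 0.0
    # offset of 2 on one component inside the mask -> 4/3
    label2 = label.copy()
    label2[:, 2][:, mask.astype(bool)] += 2.0
    loss = ad.masked_mse_loss(pred, label2, mask)
    assert float(loss.data) == pytest.approx(4.0 / 3.0, rel=1e-6)
    # differences outside the mask are invisible
    label3 = label.copy()
    label3[:, :, 0, 0, 0] += 100.0
    assert float(ad.masked_mse_loss(pred, label3, mask).data) == 0.0
    with pytest.raises(ValueError):
        ad.masked_mse_loss(pred, label, np.zeros((4, 4, 4), np.float32))
    loss.backward()
    num = numeric_grad(
        lambda: float(ad.masked_mse_loss(ad.Tensor(pred.data), label2, mask).data), pred.data, eps=1e-2
    )
    assert np.abs(num - pred.grad).max() < 5e-3


def test_gradient_penalty_measures_roughness():
    flat = ad.Tensor(np.ones((1, 3, 4, 4, 4), dtype=np.float32), requires_grad=True)
    assert float(ad.gradient_penalty(flat).data) == 0.0
    rng = np.random.default_rng(7)
    rough = ad.Tensor(rng.standard_normal((1, 3, 4, 4, 4)).astype(np.float32), requires_grad=True)
    out = ad.gradient_penalty(rough)
    assert float(out.data) > 0.0

    def f():
        return float(ad.gradient_penalty(ad.Tensor(rough.data)).data)

    out.backward()
    num = numeric_grad(f, rough.data, eps=1e-2)
    assert np.abs(num - rough.grad).max() / np.abs(num).max() < 5e-3


def test_adam_minimises_quadratic():
    p = ad.Parameter(np.array([5.0, -3.0], dtype=np.float32))
    opt = ad.Adam([p], lr=0.2)
    for _ in range(200):
        loss = ad.Tensor((p.data**2).sum(), (p,), lambda g: (2 * p.data * g,))
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_concat_reshape_activation_graph():
    rng = np.random.default_rng(6)
    a = ad.Tensor(rng.standard_normal((2, 2, 3)).astype(np.float32), requires_grad=True)
    b = ad.Tensor(rng.standard_normal((2, 1, 3)).astype(np.float32), requires_grad=True)
    tgt = rng.standard_normal((2, 9)).astype(np.float32)

    def graph(ax, bx):
        z = ad.concat([ad.relu(ax), ad.tanh(bx)], axis=1)
        return ad.reshape(z, (2, 9))

    def f():
        return float(((graph(ad.Tensor(a.data), ad.Tensor(b.data)).data.astype(np.float64) - tgt) ** 2).sum())

    out = graph(a, b)
    quadratic_loss(out, tgt).backward()
    for tensor in (a, b):
        num = numeric_grad(f, tensor.data)
        assert np.abs(num - tensor.grad).max() / max(np.abs(num).max(), 1e-6) < 5e-3
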
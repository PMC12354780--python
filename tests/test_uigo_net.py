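"""Network shape algebra, parameter bookkeeping, and training sanity."""

import numpy as np
import pytest

from uigo import losses
from uigo.autodiff import Adam
from uigo.uigo_net import NetConfig, _branch_widths, build

DESK = NetConfig(input_size=64, levels=2, base_filters=8, seed=0)


# -- closed-form parameter tally oracle ---------------------------------------

def unit_params(cin, cout, k):
    """conv (cout*cin*k*k + cout) + batchnorm (2*cout)."""
    return cout * cin * k * k + cout + 2 * cout


def branch_params(cin, bw, k):
    if k == 1:
        return unit_params(cin, bw, 1)
    return unit_params(cin, bw, 1) + unit_params(bw, bw, k)


def block_params(cin, width, kernels, use_residual):
    total = sum(branch_params(cin, bw, k)
                for k, bw in zip(kernels, _branch_widths(width, kernels)))
    if use_residual and cin != width:
        total += unit_params(cin, width, 1)
    return total


def expected_params(cfg: NetConfig) -> int:
    total = 0
    cin = 1
    for k in range(cfg.levels):
        w = cfg.level_width(k)
        for m in range(cfg.inception_modules):
            total += block_params(cin if m == 0 else w, w,
                                  cfg.inception_kernels, cfg.use_residual)
        comp = cfg.compressed_width(k)
        total += unit_params(w, comp, 1)
        cin = comp
    w_bottom = cfg.level_width(cfg.levels)
    for m in range(cfg.inception_modules):
        total += block_params(cin if m == 0 else w_bottom, w_bottom,
                              cfg.inception_kernels, cfg.use_residual)
    if cfg.use_pyramid_pool:
        proj_w = max(1, w_bottom // 3)
        total += 3 * unit_params(w_bottom, proj_w, 1)
        total += unit_params(w_bottom + 3 * proj_w, w_bottom, 1)
    cur = w_bottom
    for k in reversed(range(cfg.levels)):
        w = cfg.level_width(k)
        total += unit_params(cur, w, 3)                      # upsample conv
        dec_in = 2 * w
        if cfg.use_historic_stamp:
            total += unit_params(w, w, 1)                    # stamp projection
            dec_in = 3 * w
        for m in range(cfg.inception_modules):
            total += block_params(dec_in if m == 0 else w, w,
                                  cfg.inception_kernels, cfg.use_residual)
        cur = w
    total += cfg.out_channels * cfg.level_width(0) + cfg.out_channels  # 1x1 head
    return total


@pytest.mark.parametrize("cfg", [
    DESK,
    NetConfig(input_size=64, levels=2, base_filters=8, use_historic_stamp=False),
    NetConfig(input_size=64, levels=2, base_filters=8, use_residual=False),
    NetConfig(input_size=32, levels=2, base_filters=4, use_pyramid_pool=True),
    NetConfig(input_size=64, levels=3, base_filters=6, inception_modules=2),
])
def test_parameter_count_matches_closed_form_tally(cfg):
    _, summary = build(cfg)
    assert summary.total_params == expected_params(cfg)


# -- shape algebra -------------------------------------------------------------

@pytest.mark.parametrize("levels", [1, 2, 3, 4, 5])
def test_encoder_spatial_sizes_halve_per_level(levels):
    cfg = NetConfig(input_size=128, levels=levels, base_filters=4)
    _, summary = build(cfg)
    assert summary.spatial_sizes == [128 // 2 ** k for k in range(levels + 1)]


def test_full_scale_ladder_bottoms_out_at_32():
    cfg = NetConfig(input_size=512, levels=4, base_filters=4)
    _, summary = build(cfg)
    assert summary.bottleneck_size == 32
    assert summary.output_shape == (1, 512, 512)


def test_underflowing_config_names_offending_level():
    with pytest.raises(ValueError, match="level 4"):
        NetConfig(input_size=64, levels=5).validate()


def test_forward_output_shape_and_sigmoid_range(rng):
    net, _ = build(DESK)
    out = net.forward(rng.normal(size=(2, 64, 64)))
    assert out.data.shape == (2, 1, 64, 64)
    assert np.all(out.data > 0) and np.all(out.data < 1)


def test_forward_rejects_wrong_spatial_size(rng):
    net, _ = build(DESK)
    with pytest.raises(ValueError, match="64x64"):
        net.forward(rng.normal(size=(1, 32, 32)))


def test_eval_forward_is_pure_and_deterministic(rng):
    net, _ = build(DESK)
    batch = rng.normal(size=(2, 64, 64))
    before = [p.data.copy() for p in net.parameters()]
    out1 = net.forward(batch)
    out2 = net.forward(batch)
    assert np.array_equal(out1.data, out2.data)
    for p, b in zip(net.parameters(), before):
        assert np.array_equal(p.data, b)


# -- historic stamp channel algebra -------------------------------------------

def test_disabling_stamps_removes_exactly_the_projected_channels():
    with_stamps = build(DESK)[1]
    without = build(NetConfig(**{**DESK.__dict__, "use_historic_stamp": False}))[1]
    for dec_with, dec_without, k in zip(with_stamps.decoder_in_channels,
                                        without.decoder_in_channels,
                                        reversed(range(DESK.levels))):
        assert dec_with - dec_without == DESK.level_width(k)


def test_stamps_off_and_residual_off_give_plain_skip_concat():
    cfg = NetConfig(**{**DESK.__dict__, "use_historic_stamp": False,
                       "use_residual": False})
    _, summary = build(cfg)
    assert summary.decoder_in_channels == [2 * cfg.level_width(k)
                                           for k in reversed(range(cfg.levels))]


def test_branch_widths_concat_to_nominal_width():
    assert _branch_widths(16, (1, 3, 5)) == [5, 6, 5]
    assert sum(_branch_widths(17, (1, 3, 5))) == 17
    assert _branch_widths(8, (1, 3, 5))[1] == 4  # remainder to the 3x3 branch


# -- training sanity -----------------------------------------------------------

def test_gradients_finite_through_composite_loss(rng):
    cfg = NetConfig(input_size=32, levels=2, base_filters=4, seed=1)
    net, _ = build(cfg)
    batch = rng.normal(size=(2, 32, 32))
    target = (rng.random((2, 1, 32, 32)) < 0.2).astype(float)
    pred = net.forward(batch, training=True, rng=np.random.default_rng(0))
    loss, _ = losses.composite_loss(pred, target)
    loss.backward()
    grads = [p.grad for p in net.parameters()]
    assert all(g is not None and np.all(np.isfinite(g)) for g in grads)


def test_train_mode_loss_decreases_over_50_steps(rng):
    cfg = NetConfig(input_size=32, levels=2, base_filters=4, seed=2)
    net, _ = build(cfg)
    batch = rng.normal(size=(2, 32, 32))
    yy, xx = np.mgrid[0:32, 0:32]
    target = (((yy - 16) ** 2 + (xx - 16) ** 2) <= 36).astype(float)[None, None]
    target = np.repeat(target, 2, axis=0)
    opt = Adam(net.parameters(), lr=1e-3)
    history = []
    for _ in range(50):
        # fixed dropout masks (fresh identical rng) isolate the optimization signal
        pred = net.forward(batch, training=True, rng=np.random.default_rng(99))
        loss, _ = losses.composite_loss(pred, target)
        history.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    increases = sum(b >= a for a, b in zip(history, history[1:]))
    assert increases <= 5
    assert history[-1] < history[0]
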
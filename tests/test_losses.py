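"""Loss formulas: scalar hand evaluations, identities, surrogate behavior."""

import math

import numpy as np
import pytest
from scipy import stats

from uigo import losses
from uigo.autodiff import Tensor
from uigo.losses import (FocalParams, LossWeights, TverskyParams, composite_loss,
                         dice_loss, focal_loss, focal_tversky_loss,
                         hausdorff_surrogate, tversky_loss)
from uigo.metrics import hausdorff as exact_hausdorff


# -- focal ---------------------------------------------------------------------

def test_focal_perfect_prediction_is_numerically_zero():
    target = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert focal_loss(target.copy(), target) < 1e-5


def test_focal_reduces_to_half_bce_at_gamma_zero_alpha_half(rng):
    pred = rng.uniform(0.05, 0.95, size=(6, 6))
    target = (rng.random((6, 6)) < 0.4).astype(float)
    bce = -np.mean(target * np.log(pred) + (1 - target) * np.log(1 - pred))
    fl = focal_loss(pred, target, FocalParams(alpha=0.5, gamma=0.0))
    assert fl == pytest.approx(0.5 * bce, abs=1e-9)


def test_focal_single_pixel_hand_evaluation():
    val = focal_loss(np.array([[0.9]]), np.array([[1.0]]), FocalParams(alpha=0.25, gamma=2.0))
    assert val == pytest.approx(-0.25 * 0.1 ** 2 * math.log(0.9), abs=1e-9)


def test_focal_decreases_as_prediction_approaches_target():
    target = np.array([[1.0, 0.0]])
    vals = [focal_loss(np.array([[p, 1 - p]]), target) for p in (0.6, 0.7, 0.8, 0.9, 0.99)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# -- dice ----------------------------------------------------------------------

def test_dice_perfect_and_disjoint_limits():
    a = np.array([1.0, 1, 0, 0])
    assert dice_loss(a, a) < 1e-2            # smoothing keeps it near zero
    assert dice_loss(a, a, smooth=0.0) == pytest.approx(0.0)
    disjoint = np.array([0.0, 0, 1, 1])
    assert dice_loss(a, disjoint, smooth=0.0) == pytest.approx(1.0)


def test_dice_hard_mask_hand_count():
    # |A| = |B| = 2, overlap 1: loss = 1 - 2*1/4
    assert dice_loss(np.array([1.0, 1, 0, 0]), np.array([1, 0, 1, 0]),
                     smooth=0.0) == pytest.approx(0.5, abs=1e-9)


def test_dice_symmetry_for_binary_inputs(rng):
    a = (rng.random(20) < 0.5).astype(float)
    b = (rng.random(20) < 0.5).astype(float)
    assert dice_loss(a, b) == pytest.approx(dice_loss(b, a), abs=1e-12)


# -- tversky -------------------------------------------------------------------

def test_tversky_equals_dice_at_symmetric_weights(rng):
    pred = rng.uniform(0, 1, size=(5, 5))
    target = (rng.random((5, 5)) < 0.3).astype(float)
    tv = tversky_loss(pred, target, TverskyParams(alpha=0.5, beta=0.5))
    assert tv == pytest.approx(dice_loss(pred, target), abs=1e-9)


def test_tversky_hand_counts_and_perfect_prediction():
    pred = np.array([1.0, 1, 0, 0])
    target = np.array([1.0, 0, 1, 0])
    # TP=1, FP=1, FN=1: 1 - 1/(1 + 0.7 + 0.3)
    assert tversky_loss(pred, target, smooth=0.0) == pytest.approx(0.5, abs=1e-9)
    assert tversky_loss(target, target, smooth=0.0) == pytest.approx(0.0, abs=1e-9)


def test_focal_tversky_is_power_of_tversky(rng):
    pred = rng.uniform(0, 1, size=(4, 4))
    target = (rng.random((4, 4)) < 0.4).astype(float)
    base = tversky_loss(pred, target)
    assert focal_tversky_loss(pred, target) == pytest.approx(base ** 0.75, abs=1e-12)


# -- hausdorff surrogate -------------------------------------------------------

def _blob(h, w, cy, cx, r):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2).astype(float)


def test_surrogate_zero_on_perfect_binary_prediction():
    target = _blob(32, 32, 16, 16, 5)
    assert hausdorff_surrogate(target.copy(), target) == pytest.approx(0.0)


def test_surrogate_increases_as_predicted_blob_moves_away():
    target = _blob(48, 48, 24, 12, 4)
    vals = [hausdorff_surrogate(_blob(48, 48, 24, 12 + off, 4), target)
            for off in (0, 5, 10, 15, 20)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_surrogate_rank_correlates_with_exact_hausdorff(rng):
    surr, exact = [], []
    for _ in range(50):
        t = _blob(32, 32, rng.integers(8, 24), rng.integers(8, 24), rng.integers(3, 6))
        p = _blob(32, 32, rng.integers(8, 24), rng.integers(8, 24), rng.integers(3, 6))
        surr.append(hausdorff_surrogate(p, t))
        exact.append(exact_hausdorff(p.astype(bool), t.astype(bool))[0])
    rho = stats.spearmanr(surr, exact).statistic
    assert rho >= 0.8


def test_surrogate_empty_conventions():
    empty = np.zeros((16, 16))
    assert hausdorff_surrogate(empty.copy(), empty) == 0.0
    # prediction mass far from an empty target is penalized
    assert hausdorff_surrogate(_blob(16, 16, 8, 8, 3) * 0.9, empty) > 0.0


# -- composite -----------------------------------------------------------------

def test_composite_is_weighted_sum_of_stubbed_components(monkeypatch):
    monkeypatch.setattr(losses, "focal_loss", lambda *a, **k: Tensor(0.5))
    monkeypatch.setattr(losses, "dice_loss", lambda *a, **k: Tensor(0.2))
    monkeypatch.setattr(losses, "hausdorff_surrogate", lambda *a, **k: Tensor(0.1))
    total, comps = composite_loss(np.zeros((2, 2)) + 0.5, np.zeros((2, 2)))
    assert total == pytest.approx(0.27 * 0.5 + 0.69 * 0.2 + 0.04 * 0.1, abs=1e-12)
    assert total == pytest.approx(0.277, abs=1e-9)
    assert comps == {"focal": 0.5, "dice": 0.2, "hausdorff": 0.1}

    monkeypatch.setattr(losses, "focal_loss", lambda *a, **k: Tensor(1.0))
    monkeypatch.setattr(losses, "dice_loss", lambda *a, **k: Tensor(1.0))
    monkeypatch.setattr(losses, "hausdorff_surrogate", lambda *a, **k: Tensor(1.0))
    total, _ = composite_loss(np.zeros((2, 2)) + 0.5, np.zeros((2, 2)))
    assert total == pytest.approx(1.0, abs=1e-12)  # default weights sum to 1


def test_composite_zero_for_perfect_prediction():
    target = _blob(16, 16, 8, 8, 4)
    total, comps = composite_loss(target.copy(), target)
    assert comps["hausdorff"] == 0.0
    assert total < 0.05  # focal epsilon and dice smoothing keep it near zero


def test_composite_rejects_negative_weights():
    with pytest.raises(ValueError, match="non-negative"):
        LossWeights(w_focal=-0.1, w_dice=0.69, w_hausdorff=0.04)


# -- differentiability ---------------------------------------------------------

@pytest.mark.parametrize("loss_fn", [
    lambda p, t: focal_loss(p, t),
    lambda p, t: dice_loss(p, t),
    lambda p, t: hausdorff_surrogate(p, t),
    lambda p, t: tversky_loss(p, t),
    lambda p, t: composite_loss(p, t)[0],
])
@pytest.mark.parametrize("target_kind", ["mixed", "all_background"])
def test_losses_have_finite_gradients(loss_fn, target_kind, rng):
    pred = Tensor(rng.uniform(0.01, 0.99, size=(8, 8)), requires_grad=True)
    if target_kind == "mixed":
        target = (rng.random((8, 8)) < 0.3).astype(float)
    else:
        target = np.zeros((8, 8))
    loss = loss_fn(pred, target)
    loss.backward()
    assert np.all(np.isfinite(pred.grad))


def test_all_losses_are_nonnegative(rng):
    pred = rng.uniform(0, 1, size=(10, 10))
    target = (rng.random((10, 10)) < 0.4).astype(float)
    assert focal_loss(pred, target) >= 0
    assert dice_loss(pred, target) >= 0
    assert hausdorff_surrogate(pred, target) >= 0
    assert tversky_loss(pred, target) >= 0
    assert composite_loss(pred, target)[0] >= 0
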
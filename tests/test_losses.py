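import numpy as np
import pytest

from stemleaf import losses
from stemleaf.nn import Tensor


def brute_signed_distance(mask: np.ndarray) -> np.ndarray:
    """All-pairs nearest-opposite-pixel search (slow, exact)."""
    mask = mask.astype(bool)
    h, w = mask.shape
    coords = np.argwhere(np.ones_like(mask))
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    phi = np.zeros((h, w))
    for r, c in coords:
        opposite = bg if mask[r, c] else fg
        d = np.sqrt(((opposite - [r, c]) ** 2).sum(axis=1)).min()
        phi[r, c] = -d if mask[r, c] else d
    return phi


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        g = losses.one_hot(np.array([[0, 1], [2, 1]]), 3)
        assert losses.dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_is_one(self):
        labels = losses.one_hot(np.array([[0, 0]]), 2)
        probs = losses.one_hot(np.array([[1, 1]]), 2)
        assert losses.dice_loss(probs, labels) == pytest.approx(1.0, abs=1e-6)

    def test_hand_value_half(self):
        # N=2, C=2, g=[[1,0],[0,1]], s=[[.5,.5],[.5,.5]] -> 1 - 2*1/(2+2)
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = np.full((2, 2), 0.5)
        assert losses.dice_loss(s, g) == pytest.approx(0.5, abs=1e-6)

    def test_bounds_and_class_permutation_symmetry(self, rng):
        mask = rng.integers(0, 3, (6, 6))
        g = losses.one_hot(mask, 3)
        s = rng.dirichlet(np.ones(3), size=(6, 6))
        v = losses.dice_loss(s, g)
        assert 0.0 <= v <= 1.0
        perm = [2, 0, 1]
        assert losses.dice_loss(s[..., perm], g[..., perm]) == pytest.approx(v)

    def test_shape_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            losses.dice_loss(np.ones((2, 2)), np.ones((2, 3)))
        with pytest.raises(ValueError):
            losses.dice_loss(np.ones((0, 2)), np.ones((0, 2)))

    def test_tensor_variant_matches(self, rng):
        mask = rng.integers(0, 3, (5, 5))
        onehot = losses.one_hot(mask, 3)
        s = rng.dirichlet(np.ones(3), size=(5, 5))
        v_np = losses.dice_loss(s, onehot)
        s_t = Tensor(s.transpose(2, 0, 1)[None])
        v_t = losses.dice_loss_t(s_t, onehot.transpose(2, 0, 1)[None]).item()
        assert v_t == pytest.approx(v_np, abs=1e-6)


class TestSignedDistanceMap:
    def test_1x3_hand_case(self):
        phi, degenerate = losses.signed_distance_map(np.array([[0, 1, 0]]))
        assert not degenerate
        assert np.allclose(phi, [[1, -1, 1]])

    def test_all_background_degenerate(self):
        phi, degenerate = losses.signed_distance_map(np.zeros((4, 4)))
        assert degenerate and (phi > 0).all()

    def test_all_foreground_degenerate(self):
        phi, degenerate = losses.signed_distance_map(np.ones((4, 4)))
        assert degenerate and (phi < 0).all()

    def test_mirror_symmetry(self, rng):
        mask = rng.random((8, 8)) < 0.4
        mask[0, 0], mask[3, 3] = False, True  # non-degenerate
        phi, _ = losses.signed_distance_map(mask)
        phi_m, _ = losses.signed_distance_map(mask[:, ::-1])
        assert np.allclose(phi_m, phi[:, ::-1])

    @pytest.mark.parametrize("size", [3, 5, 8, 12])
    def test_matches_brute_force(self, size):
        rng = np.random.default_rng(size)
        for _ in range(8):
            mask = rng.random((size, size)) < rng.uniform(0.2, 0.8)
            if mask.all() or not mask.any():
                continue  # degenerate handled separately
            phi, degenerate = losses.signed_distance_map(mask)
            assert not degenerate
            assert np.allclose(phi, brute_signed_distance(mask))


class TestBoundaryLoss:
    def test_1x3_hand_case_mean_convention(self):
        # G=[0,1,0], s=[0,1,0]: sum phi*s = -1, spatial mean over 3 px
        labels = losses.one_hot(np.array([[0, 1, 0]]), 2)
        probs = labels.astype(float)
        assert losses.boundary_loss(probs, labels) == pytest.approx(-1.0 / 3.0)

    def test_zero_probability_gives_zero(self):
        labels = losses.one_hot(np.array([[0, 1, 0]]), 2)
        probs = np.zeros_like(labels, dtype=float)
        assert losses.boundary_loss(probs, labels) == 0.0

    def test_linearity_in_probs(self, rng):
        mask = rng.integers(0, 3, (6, 6))
        mask[0, 0], mask[1, 1], mask[2, 2] = 0, 1, 2
        labels = losses.one_hot(mask, 3)
        s1 = rng.dirichlet(np.ones(3), size=(6, 6))
        s2 = rng.dirichlet(np.ones(3), size=(6, 6))
        for alpha in (0.0, 0.3, 0.8, 1.0):
            blend = alpha * s1 + (1 - alpha) * s2
            expected = alpha * losses.boundary_loss(s1, labels) + (
                1 - alpha
            ) * losses.boundary_loss(s2, labels)
            assert losses.boundary_loss(blend, labels) == pytest.approx(expected)

    def test_moving_mass_inward_decreases_loss(self):
        # enumerate single-pixel mass moves on a 4x4 grid
        mask = np.zeros((4, 4), dtype=int)
        mask[1:3, 1:3] = 1
        labels = losses.one_hot(mask, 2)
        phi, _ = losses.signed_distance_map(mask == 1)
        base = np.full((4, 4), 0.5)
        inside = (1, 1)
        far_outside = (3, 3)
        assert phi[far_outside] > phi[inside]
        s_far = np.stack([1 - base, base], axis=-1).astype(float)
        s_far[far_outside][1] += 0.4
        s_in = np.stack([1 - base, base], axis=-1).astype(float)
        s_in[inside][1] += 0.4
        assert losses.boundary_loss(s_in, labels) < losses.boundary_loss(s_far, labels)


class TestComposite:
    def test_weight_zero_equals_dice(self, rng):
        mask = rng.integers(0, 2, (4, 4))
        mask[0, 0], mask[1, 1] = 0, 1
        labels = losses.one_hot(mask, 2)
        s = rng.dirichlet(np.ones(2), size=(4, 4))
        assert losses.dice_boundary_loss(s, labels, weight=0.0) == pytest.approx(
            losses.dice_loss(s, labels)
        )

    def test_additivity_exact(self):
        labels = losses.one_hot(np.array([[0, 1, 0]]), 2)
        probs = np.array([[[0.2, 0.8], [0.1, 0.9], [0.7, 0.3]]])
        total = losses.dice_boundary_loss(probs, labels, weight=1.0)
        assert total == pytest.approx(
            losses.dice_loss(probs, labels) + losses.boundary_loss(probs, labels)
        )

    def test_perfect_prediction_composite_is_boundary_term(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[1:4, 2] = 1
        labels = losses.one_hot(mask, 2)
        probs = labels.astype(float)
        composite = losses.dice_boundary_loss(probs, labels)
        assert composite == pytest.approx(losses.boundary_loss(probs, labels), abs=1e-6)
        assert composite < 0.0  # mean of phi over G is negative

    def test_negative_weight_rejected(self):
        labels = losses.one_hot(np.array([[0, 1]]), 2)
        with pytest.raises(ValueError):
            losses.dice_boundary_loss(labels.astype(float), labels, weight=-0.1)


class TestGradients:
    def test_finite_difference_gradient_on_4x4(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 3, (4, 4))
        mask[0, 0], mask[1, 1], mask[2, 2] = 0, 1, 2
        onehot = losses.one_hot(mask, 3).transpose(2, 0, 1)[None]
        phi = losses.distance_maps(mask, 3)[None]
        probs = rng.dirichlet(np.ones(3), size=(4, 4)).transpose(2, 0, 1)[None]

        t = Tensor(probs.astype(np.float64), requires_grad=True)
        loss = losses.dice_boundary_loss_t(t, onehot, phi)
        loss.backward()

        def f(arr):
            return losses.dice_boundary_loss_t(Tensor(arr), onehot, phi).item()

        eps = 1e-6
        num = np.zeros_like(probs)
        it = np.nditer(probs, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            p = probs.copy()
            p[idx] += eps
            up = f(p)
            p[idx] -= 2 * eps
            dn = f(p)
            num[idx] = (up - dn) / (2 * eps)
        scale = max(np.abs(num).max(), 1e-12)
        assert np.abs(num - t.grad).max() / scale < 1e-4
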
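"""Architecture: donut mask, receptive-field recurrence, J-invariance."""

import numpy as np
import pytest

from jdenoise import (NetSpec, JInvarianceError, donut_mask,
                      receptive_field, build_network, verify_j_invariance,
                      dependency_map_bruteforce)
from jdenoise.network import analytic_extent, path_receptive_field


def slice_1d(offsets):
    """Horizontal 1-D slice of a 2-D offset set (dy == 0)."""
    return sorted(dx for dy, dx in offsets if dy == 0)


class TestDonutMask:
    def test_k3(self):
        m = donut_mask(3)
        assert m.sum() == 8 and m[1, 1] == 0

    @pytest.mark.parametrize("K", [3, 5, 7])
    def test_sum_is_k2_minus_1(self, K):
        assert donut_mask(K).sum() == K * K - 1

    def test_k5_center_row(self):
        np.testing.assert_array_equal(donut_mask(5)[2], [1, 1, 0, 1, 1])

    @pytest.mark.parametrize("K", [2, 4, 1, -3, 0])
    def test_even_or_small_k_rejected(self, K):
        with pytest.raises(ValueError):
            donut_mask(K)


class TestReceptiveFieldRecurrence:
    def test_k3_d2_depth1_slice(self):
        """Donut ring {-1,+1} stepped by {-2,0,+2}: zero offset absent."""
        spec = NetSpec(donut_K=3, paths=((2, 1),), channels=4, skip=False)
        rf = receptive_field(spec)
        assert slice_1d(rf) == [-3, -1, 1, 3]
        assert (0, 0) not in rf

    def test_k3_d1_depth1_slice_violates(self):
        """d=1 lets the excluded center come back: the counterexample
        to relaxing the strict dilation condition.  The recurrence is
        enumerated by hand: donut ring stepped by {-1, 0, +1}."""
        ring = {(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)
                if (a, b) != (0, 0)}
        stepped = {(i + a, j + b) for (i, j) in ring
                   for a in (-1, 0, 1) for b in (-1, 0, 1)}
        assert sorted(dx for dy, dx in stepped if dy == 0) \
            == [-2, -1, 0, 1, 2]
        assert (0, 0) in stepped
        assert not NetSpec(donut_K=3, paths=((1, 1),), channels=4,
                           baseline_n2c=True).invariant

    @pytest.mark.parametrize("paths", [((2, 2), (3, 2)), ((2, 1), (3, 3)),
                                       ((2, 3), (3, 1))])
    def test_zero_absent_at_every_depth(self, paths):
        for d, m in paths:
            for depth in range(m + 1):
                spec = NetSpec(donut_K=3, paths=((d, depth),), channels=4)
                assert (0, 0) not in receptive_field(spec)

    def test_strict_boundary_k5_d2_contains_zero(self):
        spec = NetSpec(donut_K=5, paths=((2, 1),), channels=4,
                       baseline_n2c=True)
        # d == floor(K/2) is NOT sufficient: ring offset (0, 2) plus step
        # (0, -2) lands back on the center
        ring = {(a, b) for a in range(-2, 3) for b in range(-2, 3)
                if (a, b) != (0, 0)}
        stepped = {(i + a, j + b) for (i, j) in ring
                   for a in (-2, 0, 2) for b in (-2, 0, 2)}
        assert (0, 0) in stepped
        assert not NetSpec(donut_K=5, paths=((2, 1),), channels=4,
                           baseline_n2c=True).invariant

    def test_path_complementarity(self):
        """The union of the dilation-2 and dilation-3 path offsets
        strictly contains each path's own set."""
        spec = NetSpec(donut_K=3, paths=((2, 2), (3, 2)), channels=4)
        union = receptive_field(spec)
        p0 = path_receptive_field(spec, 0)
        p1 = path_receptive_field(spec, 1)
        assert p0 < union and p1 < union
        assert union == p0 | p1

    def test_baseline_includes_zero(self):
        spec = NetSpec(donut_K=3, paths=((2, 1),), channels=4,
                       baseline_n2c=True)
        assert (0, 0) in receptive_field(spec)


class TestBuildNetwork:
    def test_deterministic_initialization(self):
        spec = NetSpec(donut_K=3, paths=((2, 1), (3, 1)), channels=4)
        a = build_network(spec, seed=7)
        b = build_network(spec, seed=7)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_output_shape_preserved(self, small_net, rng):
        img = rng.random((64, 64))
        assert small_net.apply(img).shape == (64, 64)
        odd = rng.random((37, 51))
        assert small_net.apply(odd).shape == (37, 51)

    def test_noncompliant_spec_rejected_at_build(self):
        with pytest.raises(JInvarianceError):
            build_network(NetSpec(donut_K=3, paths=((1, 2),), channels=4))
        with pytest.raises(JInvarianceError):
            build_network(NetSpec(donut_K=5, paths=((2, 1), (3, 1)),
                                  channels=4))

    def test_baseline_flag_allows_any_dilation(self):
        build_network(NetSpec(donut_K=3, paths=((1, 2),), channels=4,
                              baseline_n2c=True), seed=0)

    def test_netspec_json_roundtrip(self):
        spec = NetSpec(donut_K=5, paths=((3, 2), (4, 1)), channels=12,
                       head_depth=3, skip=False)
        assert NetSpec.from_json(spec.to_json()) == spec


class TestJInvariance:
    def test_compliant_net_is_invariant(self, small_net, rng):
        img = rng.random((48, 48))
        assert verify_j_invariance(small_net, img, trials=16,
                                   seed=1) <= 1e-5

    def test_invariance_at_corners_and_edges(self, small_net, rng):
        """Zero padding keeps the guarantee on the boundary; the corner
        pixels are always probed."""
        img = rng.random((32, 32))
        assert verify_j_invariance(small_net, img, trials=1, seed=0,
                                   include_corners=True) <= 1e-5

    def test_baseline_net_violates(self, baseline_net, rng):
        img = rng.random((48, 48))
        assert verify_j_invariance(baseline_net, img, trials=8,
                                   seed=1) > 1e-3

    def test_unmasked_center_hook_violates(self, rng):
        """Ablation: removing the donut mask from a compliant net must
        break invariance."""
        spec = NetSpec(donut_K=3, paths=((2, 2), (3, 2)), channels=8)
        net = build_network(spec, seed=2)
        net.front.mask = None                      # test hook
        net.front.w[:, :, 1, 1] = 0.1              # give the center weight
        img = rng.random((48, 48))
        assert verify_j_invariance(net, img, trials=8, seed=1) > 1e-3


class TestDependencyOracle:
    def test_oracle_equivalence_small(self):
        spec = NetSpec(donut_K=3, paths=((2, 1), (3, 1)), channels=4)
        net = build_network(spec, seed=1)
        bf = dependency_map_bruteforce(net, analytic_extent(spec), seed=2)
        assert bf == receptive_field(spec)

    def test_noninvariant_net_contains_zero(self):
        spec = NetSpec(donut_K=3, paths=((1, 1),), channels=4,
                       baseline_n2c=True)
        net = build_network(spec, seed=1)
        bf = dependency_map_bruteforce(net, analytic_extent(spec), seed=2)
        assert (0, 0) in bf

    def test_zero_weights_net_has_empty_map(self):
        spec = NetSpec(donut_K=3, paths=((2, 1),), channels=4)
        net = build_network(spec, seed=1)
        for p in net.parameters():
            p[...] = 0.0
        assert dependency_map_bruteforce(net, analytic_extent(spec),
                                         seed=2) == frozenset()


class TestEngineGradients:
    def test_backward_matches_finite_differences(self, rng):
        """The hand-written backprop of the numpy engine against central
        finite differences on a tiny network."""
        spec = NetSpec(donut_K=3, paths=((2, 1), (3, 1)), channels=3,
                       head_depth=2)
        net = build_network(spec, seed=4)
        x = rng.random((1, 1, 12, 12)).astype(np.float32)
        noisy = rng.random((1, 1, 12, 12)).astype(np.float32)

        def loss_of(params_flat=None):
            pred = net.forward(x)
            return float(np.mean((pred - noisy) ** 2))

        net.zero_grad()
        pred = net.forward(x, cache=True)
        g = (2.0 / pred.size) * (pred - noisy)
        net.backward(g.astype(np.float32))
        pairs = list(net.param_grad_pairs())
        rng2 = np.random.default_rng(0)
        checked = 0
        for p, grad in pairs:
            flat_p = p.reshape(-1)
            flat_g = grad.reshape(-1)
            for idx in rng2.choice(flat_p.size,
                                   size=min(3, flat_p.size),
                                   replace=False):
                eps = 1e-3
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss_of()
                flat_p[idx] = orig - eps
                down = loss_of()
                flat_p[idx] = orig
                fd = (up - down) / (2 * eps)
                assert abs(fd - flat_g[idx]) < 5e-3 * max(
                    1.0, abs(fd)), (fd, flat_g[idx])
                checked += 1
        assert checked >= 20
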
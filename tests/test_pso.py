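import numpy as np
import pytest

from chromoswarm import (
    PSOConfig,
    Particle,
    ValidationError,
    generate_structure,
    if_to_distance,
    initialize_swarm,
    optimize,
    position_update,
    step,
    structure_to_if,
    velocity_update,
)
from chromoswarm.losses import LossSpec, loss
from chromoswarm.pso_core import swarm_losses
from tests.conftest import random_rotation


def make_wish(n=10, seed=0):
    s = generate_structure(n, seed=seed)
    return if_to_distance(structure_to_if(s, 1.0), 1.0)


class TestConfig:
    def test_defaults_match_tuned_operating_point(self):
        cfg = PSOConfig()
        assert cfg.swarm_size == 15
        assert cfg.c1 == 0.3
        assert cfg.c2 == 2.5
        assert cfg.threshold == 1e-6
        assert (cfg.init_low, cfg.init_high) == (-1.0, 1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"swarm_size": 1},
            {"threshold": -1.0},
            {"init_low": 1.0, "init_high": -1.0},
            {"c1": -0.1},
            {"loss_name": "nope"},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises((ValidationError, ValueError)):
            PSOConfig(**kwargs)


class TestInitializeSwarm:
    def test_shape_and_range(self):
        wish = make_wish(10)
        state = initialize_swarm(10, wish, PSOConfig(seed=0))
        assert state.positions.shape == (15, 30)
        assert np.all(state.positions >= -1) and np.all(state.positions <= 1)
        assert np.all(state.velocities == 0)
        assert state.iteration == 0

    def test_seeded_reproducibility(self):
        wish = make_wish(8)
        cfg = PSOConfig(seed=42)
        a, b = initialize_swarm(8, wish, cfg), initialize_swarm(8, wish, cfg)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.pbest_bin_costs, b.pbest_bin_costs)
        assert a.gbest_loss == b.gbest_loss

    def test_global_best_is_min_personal_best(self):
        wish = make_wish(8)
        state = initialize_swarm(8, wish, PSOConfig(seed=1))
        assert state.gbest_loss == min(p.personal_best_loss for p in state.particles)

    def test_too_few_bins(self):
        with pytest.raises(ValidationError):
            initialize_swarm(1, make_wish(8), PSOConfig())


class TestVelocityUpdate:
    def mk(self, x, v, p):
        x = np.asarray(x, float)
        return Particle(x, np.asarray(v, float), np.asarray(p, float), 0.0)

    def test_pure_inertia(self):
        cfg = PSOConfig(c1=0.0, c2=0.0, inertia_w=1.0)
        part = self.mk([0, 0, 0], [0.1, 0.2, 0.3], [0, 0, 0])
        out = velocity_update(part, np.zeros(3), cfg, (np.ones(3), np.ones(3)))
        np.testing.assert_allclose(out, [0.1, 0.2, 0.3])

    def test_converged_particle_keeps_scaled_inertia(self):
        cfg = PSOConfig(c1=0.3, c2=2.5, inertia_w=0.5)
        x = np.array([1.0, 2.0, 3.0])
        part = Particle(x, np.array([0.2, 0.0, -0.2]), x.copy(), 0.0)
        out = velocity_update(part, x.copy(), cfg, (np.ones(3), np.ones(3)))
        np.testing.assert_allclose(out, 0.5 * np.array([0.2, 0.0, -0.2]))

    def test_hand_traced_substitution(self):
        # w=0.5, V=0, c1=0.3, c2=2.5, R1=R2=1, P-X=1, G-X=2 -> 0.3 + 5.0 = 5.3
        cfg = PSOConfig(c1=0.3, c2=2.5, inertia_w=0.5)
        part = self.mk([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        out = velocity_update(part, np.full(3, 2.0), cfg, (np.ones(3), np.ones(3)))
        np.testing.assert_allclose(out, [5.3, 5.3, 5.3])

    def test_length_mismatch(self):
        part = self.mk([0, 0, 0], [0, 0, 0], [0, 0, 0])
        with pytest.raises(ValidationError):
            velocity_update(part, np.zeros(6), PSOConfig(), (np.ones(3), np.ones(3)))


class TestPositionUpdate:
    def test_examples(self):
        np.testing.assert_allclose(
            position_update([1.0, 1, 1], [0.0, 0, 0]), [1, 1, 1]
        )
        np.testing.assert_allclose(
            position_update([0.0, 0, 0], [1.0, -2, 3]), [1, -2, 3]
        )

    def test_additive_inverse(self):
        x = np.array([0.5, -1.0, 2.0])
        v = np.array([1.0, 2.0, -3.0])
        np.testing.assert_allclose(position_update(position_update(x, v), -v), x)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            position_update(np.zeros(3), np.zeros(4))


class TestStep:
    def test_global_best_never_worsens(self):
        wish = make_wish(10)
        cfg = PSOConfig(seed=2)
        state = initialize_swarm(10, wish, cfg)
        for _ in range(100):
            before = state.gbest_loss
            step(state, wish, cfg)
            assert state.gbest_loss <= before

    def test_zero_force_fixed_point(self):
        wish = make_wish(6)
        cfg = PSOConfig(seed=3, c1=0.0, c2=0.0, inertia_w=0.0)
        state = initialize_swarm(6, wish, cfg)
        pos = state.positions.copy()
        step(state, wish, cfg)
        np.testing.assert_array_equal(state.positions, pos)

    def test_matches_manual_recomputation_of_update_rule(self):
        """Replay the same RNG stream and recompute the cooperative update
        (velocity/position rules plus per-bin best bookkeeping) by hand."""
        n, S = 4, 2
        wish = make_wish(n, seed=5)
        wm = np.zeros((n, n))
        wm[wish.i, wish.j] = wm[wish.j, wish.i] = wish.d
        hw = wm > 0

        def full_sse(flat):
            c = flat.reshape(n, 3)
            i, j = wish.i, wish.j
            d = np.linalg.norm(c[i] - c[j], axis=1)
            return float(((d - wish.d) ** 2).sum())

        def bin_cost(bead, b, context):
            acc = 0.0
            for k in range(n):
                if k != b and hw[b, k]:
                    acc += (np.linalg.norm(bead - context[k]) - wm[b, k]) ** 2
            return acc

        cfg = PSOConfig(seed=11, swarm_size=S)
        state = initialize_swarm(n, wish, cfg)
        # shadow copies driven by an identical generator
        rng = np.random.default_rng(11)
        pos = rng.uniform(-1, 1, size=(S, 3 * n))
        vel = np.zeros((S, 3 * n))
        full = [full_sse(p) for p in pos]
        context = pos[int(np.argmin(full))].reshape(n, 3).copy()
        gbest_loss = min(full)
        pbest = pos.reshape(S, n, 3).copy()
        for _ in range(3):
            r1 = rng.uniform(size=(S, 3 * n))
            r2 = rng.uniform(size=(S, 3 * n))
            vel = (
                cfg.inertia_w * vel
                + cfg.c1 * r1 * (pbest.reshape(S, -1) - pos)
                + cfg.c2 * r2 * (context.reshape(-1) - pos)
            )
            pos = pos + vel
            coords = pos.reshape(S, n, 3)
            for s in range(S):
                for b in range(n):
                    if bin_cost(coords[s, b], b, context) < bin_cost(
                        pbest[s, b], b, context
                    ):
                        pbest[s, b] = coords[s, b]
            new_context = context.copy()
            for b in range(n):
                costs = [bin_cost(pbest[s, b], b, context) for s in range(S)]
                s_star = int(np.argmin(costs))
                if costs[s_star] < bin_cost(context[b], b, context):
                    new_context[b] = pbest[s_star, b]
            context = new_context
            gbest_loss = min(gbest_loss, full_sse(context.reshape(-1)))
            step(state, wish, cfg)
        np.testing.assert_allclose(state.positions, pos, atol=1e-12)
        np.testing.assert_allclose(state.context, context, atol=1e-12)
        assert state.gbest_loss == pytest.approx(gbest_loss, rel=1e-12)


class TestOptimize:
    def test_two_bead_distance_recovery(self):
        wish = if_to_distance(
            structure_to_if(
                generate_structure(4, seed=1), 1.0
            ),
            1.0,
        )
        # reduce to a genuine 2-bead problem
        from chromoswarm import WishDistances

        two = WishDistances(
            np.array([0]), np.array([1]), np.array([0.7]), 1.0, 1.0, 2
        )
        cfg = PSOConfig(seed=4, swarm_size=2, max_iterations=2000)
        structure, final_loss, trace, _ = optimize(two, 2, cfg)
        got = np.linalg.norm(structure.coords[0] - structure.coords[1])
        assert got == pytest.approx(0.7, rel=1e-3)

    def test_infinite_threshold_stops_at_patience(self):
        wish = make_wish(8)
        cfg = PSOConfig(seed=5, threshold=np.inf, patience=50)
        _, _, trace, converged = optimize(wish, 8, cfg)
        assert converged
        assert len(trace) - 1 <= 200

    @pytest.mark.parametrize("seed", range(3))
    def test_trace_monotone_non_increasing(self, seed):
        wish = make_wish(10, seed=seed)
        cfg = PSOConfig(seed=seed, max_iterations=400, patience=30)
        _, _, trace, _ = optimize(wish, 10, cfg)
        assert np.all(np.diff(trace) <= 0)

    def test_seeded_determinism_bit_identical(self):
        wish = make_wish(10)
        cfg = PSOConfig(seed=9, max_iterations=300, patience=30)
        s1, l1, t1, _ = optimize(wish, 10, cfg)
        s2, l2, t2, _ = optimize(wish, 10, cfg)
        np.testing.assert_array_equal(s1.coords, s2.coords)
        assert l1 == l2
        np.testing.assert_array_equal(t1, t2)

    def test_empty_wish_rejected(self):
        from chromoswarm import WishDistances

        empty = WishDistances(
            np.array([], int), np.array([], int), np.array([]), 1.0, 1.0, 5
        )
        with pytest.raises(ValidationError):
            optimize(empty, 5, PSOConfig(seed=0))

    def test_loss_invariant_under_rigid_motion(self):
        wish = make_wish(12)
        cfg = PSOConfig(seed=6, max_iterations=200, patience=20)
        structure, final_loss, _, _ = optimize(wish, 12, cfg)
        moved = structure.coords @ random_rotation(3).T + [5.0, -1.0, 2.0]
        model = swarm_losses(moved.reshape(1, -1), wish, cfg.loss_spec)[0]
        assert model == pytest.approx(final_loss, rel=1e-9)


def test_kernel_matches_numpy_distances():
    from chromoswarm.pso_core import _model_distances, _model_distances_numpy

    wish = make_wish(20, seed=2)
    rng = np.random.default_rng(0)
    positions = rng.normal(size=(5, 60))
    np.testing.assert_allclose(
        _model_distances(positions, wish),
        _model_distances_numpy(positions, wish),
        rtol=1e-12,
    )
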
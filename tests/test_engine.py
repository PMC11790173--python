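import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from turingrowth.engine import (
    DT,
    FIXED_POINT,
    MAX_A,
    MAX_B,
    MIN_A,
    MIN_B,
    PRESETS,
    GrowthSchedule,
    ReactionParams,
    SimulationConfig,
    growth_duration,
    laplacian9,
    make_initial_condition,
    preset_config,
    reaction_step,
    run_simulation,
)

LEOPARD = ReactionParams(s=6.0, r=30.0)


class TestLaplacian:
    def test_constant_field_gives_zero(self):
        assert np.allclose(laplacian9(np.full((8, 8), 4.0)), 0.0)

    def test_single_cell_stencil_weights(self):
        field = np.zeros((7, 9))
        field[3, 4] = 6.0
        out = laplacian9(field)
        assert out[3, 4] == pytest.approx(-20.0)
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            assert out[3 + di, 4 + dj] == pytest.approx(4.0)
        for di in (-1, 1):
            for dj in (-1, 1):
                assert out[3 + di, 4 + dj] == pytest.approx(1.0)
        out[2:5, 3:6] = 0.0
        assert np.allclose(out, 0.0)

    def test_corner_cell_wraps_periodically(self):
        # brute-force oracle: place the stencil with modular index arithmetic
        h, w = 5, 6
        field = np.zeros((h, w))
        field[0, 0] = 6.0
        expected = np.zeros((h, w))
        weights = {(-1, -1): 1, (-1, 0): 4, (-1, 1): 1, (0, -1): 4, (0, 0): -20,
                   (0, 1): 4, (1, -1): 1, (1, 0): 4, (1, 1): 1}
        for (di, dj), wgt in weights.items():
            expected[di % h, dj % w] += wgt
        assert np.allclose(laplacian9(field), expected)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            laplacian9(np.ones((2, 8)))
        with pytest.raises(ValueError):
            laplacian9(np.ones(8))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(np.float64, (9, 11), elements=st.floats(-50, 50)))
    def test_grid_sum_conserved(self, field):
        # the stencil weights sum to zero and periodic wrap loses nothing
        total = np.abs(field).sum() + 1.0
        assert abs(laplacian9(field).sum()) < 1e-9 * total


class TestReactionStep:
    def test_homogeneous_fixed_point_is_stationary(self):
        a = np.full((6, 6), FIXED_POINT[0])
        b = np.full((6, 6), FIXED_POINT[1])
        a2, b2, d2 = reaction_step(a, b, LEOPARD, g_now=0.0)
        assert np.array_equal(a2, a)
        assert np.array_equal(b2, b)
        assert d2 == LEOPARD.d

    def test_uniform_growth_step_matches_direct_arithmetic(self):
        g, dt = 0.05, DT
        dil = 1.0 + g * dt
        a = np.full((5, 5), 4.0)
        b = np.full((5, 5), 4.0)
        a2, b2, d2 = reaction_step(a, b, LEOPARD, g_now=g)
        exp_a = 4.0 / dil + (16.0 - 16.0 / dil**2) * dt
        exp_b = 4.0 / dil + (16.0 / dil**2 - 4.0 / dil - 12.0) * dt
        assert np.allclose(a2, exp_a)
        assert np.allclose(b2, exp_b)
        assert d2 == pytest.approx(LEOPARD.d / dil**2)

    def test_activator_ceiling_clamp(self):
        # raw update of a large uniform a exceeds the ceiling -> clamped to 4.4
        a = np.full((5, 5), MAX_A)
        b = np.full((5, 5), MIN_B)
        a2, _, _ = reaction_step(a, b, LEOPARD)  # 16 - a*b < 16 but positive here
        assert a2.max() == MAX_A

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reaction_step(np.ones((4, 4)), np.ones((4, 5)), LEOPARD)

    def test_non_finite_input_rejected(self):
        a = np.ones((4, 4))
        a[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            reaction_step(a, np.ones((4, 4)), LEOPARD)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.2))
    def test_clamp_invariant_on_random_fields(self, seed, g):
        rng = np.random.default_rng(seed)
        a = rng.uniform(MIN_A, MAX_A, (12, 12))
        b = rng.uniform(MIN_B, MAX_B, (12, 12))
        for _ in range(3):
            a, b, _ = reaction_step(a, b, LEOPARD, g_now=g)
        assert a.min() >= MIN_A and a.max() <= MAX_A
        assert b.min() >= MIN_B and b.max() <= MAX_B


class TestInitialConditions:
    def test_random_noise_is_seed_reproducible(self):
        a1, b1 = make_initial_condition("random_noise", (64, 64), seed=1)
        a2, b2 = make_initial_condition("random_noise", (64, 64), seed=1)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
        a3, _ = make_initial_condition("random_noise", (64, 64), seed=2)
        assert not np.array_equal(a1, a3)

    def test_middle_stripe_is_one_band_through_center(self):
        a, _ = make_initial_condition("middle_stripe", (64, 64), seed=5)
        elevated_cols = np.where((a > 4.2).all(axis=0))[0]
        assert 32 in elevated_cols or 31 in elevated_cols
        assert np.all(np.diff(elevated_cols) == 1)  # contiguous band

    def test_periodic_stripes_autocorrelation_peak(self):
        # brute-force circular autocorrelation of the cross-stripe profile
        a, _ = make_initial_condition("periodic_stripes", (64, 64), seed=5, n_stripes=5)
        profile = a.mean(axis=0) - a.mean()
        n = len(profile)
        ac = [float((profile * np.roll(profile, lag)).sum()) for lag in range(n)]
        peak_lag = 2 + int(np.argmax(ac[2 : n // 2]))
        assert peak_lag in (12, 13)  # 64 / 5 stripes

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_initial_condition("checkerboard", (16, 16), seed=0)


class TestRunSimulation:
    def test_deterministic_histories(self):
        cfg = preset_config("leopard", shape=(48, 48), n_iter=11_000, seed=9,
                            snapshot_interval=500)
        h1 = run_simulation(cfg)
        h2 = run_simulation(cfg)
        assert h1.iterations == h2.iterations
        assert h1.surface == h2.surface
        for s1, s2 in zip(h1.a_snapshots, h2.a_snapshots):
            assert np.array_equal(s1, s2)

    def test_numba_and_numpy_steppers_agree(self):
        cfg = SimulationConfig(
            reaction=LEOPARD,
            growth=GrowthSchedule(g=0.05, t_start=100, max_surface=1.01),
            shape=(24, 24), n_iter=300, snapshot_interval=100, seed=4,
        )
        fast = run_simulation(cfg, use_numba=True)
        ref = run_simulation(cfg, use_numba=False)
        assert fast.iterations == ref.iterations
        for sf, sr in zip(fast.a_snapshots, ref.a_snapshots):
            np.testing.assert_allclose(sf, sr, rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(fast.surface, ref.surface, rtol=1e-12)

    def test_no_growth_surface_stays_one(self):
        cfg = SimulationConfig(reaction=LEOPARD, growth=GrowthSchedule(g=0.0),
                               shape=(32, 32), n_iter=2_000,
                               snapshot_interval=500, seed=1)
        hist = run_simulation(cfg)
        assert all(s == 1.0 for s in hist.surface)
        assert hist.growth_end_iteration is None

    def test_growth_phase_bounds_and_surface_cap(self):
        g, smax = 0.05, 2.0
        cfg = SimulationConfig(
            reaction=LEOPARD, growth=GrowthSchedule(g=g, t_start=500, max_surface=smax),
            shape=(32, 32), n_iter=8_000, snapshot_interval=250, seed=1)
        hist = run_simulation(cfg)
        dur = growth_duration(g, smax)
        assert hist.growth_end_iteration == 500 + dur
        assert hist.surface[-1] == pytest.approx(smax, rel=2e-4)
        assert np.all(np.diff(hist.surface) >= 0)

    def test_snapshot_clamps_hold_everywhere(self, leopard_history):
        for a, b in zip(leopard_history.a_snapshots, leopard_history.b_snapshots):
            assert a.min() >= MIN_A and a.max() <= MAX_A + 1e-6
            assert b.min() >= MIN_B - 1e-6 and b.max() <= MAX_B + 1e-6
            assert np.isfinite(a).all() and np.isfinite(b).all()


class TestPresets:
    def test_published_parameter_table(self):
        expected = {
            "leopard": (6, 30, 0.05, "random_noise", 10_000),
            "emu": (10, 6, 0.05, "middle_stripe", 10_000),
            "pomacanthus": (10, 6, 0.05, "middle_stripe", 20_000),
            "ictidomys": (6, 30, 0.01, "periodic_stripes", 1_000),
            "tetraodon": (10, 8, 0.075, "random_noise", 10_000),
        }
        assert set(PRESETS) == set(expected)
        for name, (s, r, g, ic, t0) in expected.items():
            cfg = preset_config(name)
            assert cfg.reaction.s == s and cfg.reaction.r == r
            assert cfg.growth.g == g and cfg.growth.t_start == t0
            assert cfg.initial_condition == ic
            assert cfg.reaction.dt == 0.002

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_config("cheetah")


def test_anisotropic_growth_runs_and_grows_surface():
    cfg = SimulationConfig(
        reaction=LEOPARD,
        growth=GrowthSchedule(g=0.05, t_start=100, max_surface=1.2,
                              anisotropy=(0.08, 0.02)),
        shape=(32, 32), n_iter=1_500, snapshot_interval=500, seed=2)
    hist = run_simulation(cfg)
    assert hist.surface[-1] >= 1.2
    assert hist.growth_end_iteration is not None
    for a in hist.a_snapshots:
        assert a.min() >= MIN_A and a.max() <= MAX_A
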
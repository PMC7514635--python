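"""FlatPERM sampling against the exact-enumeration oracle."""

import numpy as np
import pytest

from trailzeros import (
    FlatPermConfig,
    HistogramState,
    ModelWeights,
    effective_coefficients,
    enumerate_trails,
    grow_tour,
    run_flatperm,
)
from trailzeros.flatperm import state_to_table


class TestGrowth:
    def test_noninteracting_short_walks_have_zero_variance(self):
        # at N_max = 2 the atmosphere is deterministic (4 then 3), so every
        # tour's weight at n = 2 is exactly 4 * 3 = 12
        w = ModelWeights.isat()
        cfg = FlatPermConfig(n_max=2, tours=50, seed=5)
        (est,) = run_flatperm(w, cfg)
        assert est.table.counts[(1, 0, 0, 0, 0)] == 4.0
        assert est.table.counts[(2, 0, 0, 0, 0)] == 12.0

    def test_single_tour_on_fresh_histogram(self):
        w = ModelWeights.isat()
        cfg = FlatPermConfig(n_max=6, tours=1, seed=9)
        state = HistogramState.fresh(w, cfg)
        grow_tour(state, w, cfg, np.random.default_rng(1))
        assert state.tours == 1
        # a first visit never prunes: the start cell and length-1 cell are hit
        assert state.S[0, 0] == 1
        assert state.S[1, 0] == 1
        assert state.C[1, 0] == 4.0

    def test_estimates_unbiased_at_small_n(self, exact_isat_n10):
        w = ModelWeights.isat()
        cfg = FlatPermConfig(n_max=8, tours=30000, seed=17, replicates=6)
        estimates = run_flatperm(w, cfg)
        for n in (4, 6, 8):
            exact = exact_isat_n10.marginal_interactions(n)
            for ni, truth in exact.items():
                vals = [e.table.counts.get((n, ni, 0, 0, 0), 0.0)
                        for e in estimates]
                mean = np.mean(vals)
                sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
                assert abs(mean - truth) < 4 * max(sem, 1e-9 * truth), \
                    f"N={n}, NI={ni}: {mean} vs exact {truth}"

    def test_variance_shrinks_with_tour_budget(self, exact_isat_n10):
        w = ModelWeights.isat()
        def spread(tours, seed):
            cfg = FlatPermConfig(n_max=8, tours=tours, seed=seed, replicates=5)
            vals = [e.table.counts[(8, 1, 0, 0, 0)]
                    for e in run_flatperm(w, cfg)]
            return np.std(vals, ddof=1)
        assert spread(50000, 23) < spread(5000, 23)


class TestReplicates:
    def test_same_seed_is_bit_reproducible(self):
        w = ModelWeights.isat()
        cfg = FlatPermConfig(n_max=8, tours=5000, seed=4, replicates=2)
        a = run_flatperm(w, cfg)
        b = run_flatperm(w, cfg)
        for ea, eb in zip(a, b):
            assert ea.table.counts == eb.table.counts
            assert ea.seed == eb.seed

    def test_replicate_seeds_distinct(self):
        cfg = FlatPermConfig(n_max=4, tours=1, seed=0, replicates=8)
        seeds = cfg.replicate_seeds()
        assert len(set(seeds)) == 8
        assert all(0 <= s < 2**31 for s in seeds)

    def test_visaw_never_estimates_crossings(self):
        w = ModelWeights.visaw()
        cfg = FlatPermConfig(n_max=10, tours=20000, seed=2,
                             flat_axes="coll_cross")
        (est,) = run_flatperm(w, cfg)
        assert all(k[2] == 0 for k in est.table.counts)

    def test_checkpoint_round_trip(self, tmp_path):
        w = ModelWeights.isat()
        cfg = FlatPermConfig(n_max=6, tours=100, seed=8)
        state = HistogramState.fresh(w, cfg)
        rng = np.random.default_rng(0)
        for _ in range(5):
            grow_tour(state, w, cfg, rng)
        path = tmp_path / "state.npz"
        state.save(path)
        other = HistogramState.fresh(w, cfg)
        other.restore(path)
        assert np.array_equal(other.C, state.C)
        assert other.tours == state.tours


class TestEffectiveCoefficients:
    def test_unit_weights_reduce_to_surface_marginal(self, exact_surface_n8):
        w = ModelWeights.isat(1.0, surface=True)
        cfg = FlatPermConfig(n_max=8, tours=20000, seed=6, replicates=12,
                             flat_axes="surface")
        tables = effective_coefficients(w, cfg)
        for n in (4, 8):
            exact = exact_surface_n8.marginal_surface(n)
            for ns, truth in exact.items():
                vals = [t.counts.get((n, 0, 0, 0, ns), 0.0) for t in tables]
                mean = np.mean(vals)
                sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
                assert abs(mean - truth) < 5 * max(sem, 1e-4 * truth)

    def test_carried_tau_matches_weighted_exact_sum(self, exact_surface_n8):
        tau = 3.0
        w = ModelWeights.isat(tau, surface=True)
        cfg = FlatPermConfig(n_max=8, tours=20000, seed=13, replicates=12,
                             flat_axes="surface")
        tables = effective_coefficients(w, cfg)
        # oracle: fold tau into the exact table by hand
        for n in (6, 8):
            truth: dict[int, float] = {}
            for (nn, nc, nx, nstr, ns), v in exact_surface_n8.slice(n).items():
                truth[ns] = truth.get(ns, 0.0) + v * tau ** (nc + nx)
            for ns, tval in truth.items():
                vals = [t.counts.get((n, 0, 0, 0, ns), 0.0) for t in tables]
                mean = np.mean(vals)
                sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
                assert abs(mean - tval) < 4 * max(sem, 2e-3 * tval)

    def test_rod_contributes_full_surface_power(self):
        # the straight rod along the wall reaches N_S = N under the
        # steps-in-surface convention, so the top polynomial coefficient is
        # populated
        w = ModelWeights.isat(1.0, surface=True)
        cfg = FlatPermConfig(n_max=6, tours=20000, seed=3,
                             flat_axes="surface")
        (table,) = effective_coefficients(w, cfg)
        assert table.counts.get((6, 0, 0, 0, 6), 0.0) > 0


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FlatPermConfig(n_max=0, tours=1)
        with pytest.raises(ValueError):
            FlatPermConfig(n_max=4, tours=0)
        with pytest.raises(ValueError):
            FlatPermConfig(n_max=4, tours=1, flat_axes="bogus")

    def test_model_config_consistency(self):
        with pytest.raises(ValueError):
            run_flatperm(ModelWeights.isat(),  # bulk model
                         FlatPermConfig(n_max=4, tours=1, flat_axes="surface"))
        with pytest.raises(ValueError):
            run_flatperm(
                ModelWeights(tau_c=2.0, tau_x=1.0, variant="generalized"),
                FlatPermConfig(n_max=4, tours=1, flat_axes="ni"),
            )
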
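"""Orchestration: paired training, batched evaluation, sweep bookkeeping.

These tests run on reduced problem sizes (small reservoirs, few test runs)
so the full pipeline is exercised end to end in seconds.
"""

import numpy as np
import pandas as pd
import pytest

from selcon.experiment import (
    SweepConfig,
    _train_batch,
    build_corpus,
    derive_seeds,
    evaluate_pair,
    peak_radius,
    run_ensemble,
    run_sweep,
    selectivity_curve,
    train_pair,
    train_pairs,
)
from selcon.readout import Readout
from selcon.reservoir import PlasticityConfig, init_reservoir, run_trial

SMALL = dict(n_neurons=60, density=0.2, n_test_runs=6, master_seed=3,
             noise_sigma=1e-3)


@pytest.fixture(scope="module")
def small_config():
    return SweepConfig(radii=(0.5, 1.0), eval_kinds=("RN", "RefRN"),
                       comparison_kinds=("RefRN",), n_surrogates=200, **SMALL)


@pytest.fixture(scope="module")
def corpus(small_config):
    session, test_set, seeds = build_corpus(small_config)
    return session, test_set, seeds


class TestSeeds:
    def test_deterministic(self):
        assert derive_seeds(5) == derive_seeds(5)

    def test_distinct_masters_differ(self):
        assert derive_seeds(5) != derive_seeds(6)

    def test_all_seeds_in_int32_range(self):
        seeds = derive_seeds(12345)

        def flatten(obj):
            if isinstance(obj, dict):
                for v in obj.values():
                    yield from flatten(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    yield from flatten(v)
            else:
                yield obj

        for s in flatten(seeds):
            assert 0 <= s < 2**31


class TestTrainPair:
    def test_zero_alpha_arms_identical(self, corpus):
        session, _, seeds = corpus
        cfg = SweepConfig(radii=(1.0,), alpha=0.0, **SMALL)
        pair = train_pair(1.0, session, cfg, seeds)
        np.testing.assert_array_equal(pair.hebb.net.W, pair.nonhebb.net.W)
        np.testing.assert_array_equal(pair.hebb.readout.W_out,
                                      pair.nonhebb.readout.W_out)

    def test_deterministic_from_master_seed(self, corpus):
        session, _, seeds = corpus
        cfg = SweepConfig(radii=(1.0,), **SMALL)
        p1 = train_pair(1.0, session, cfg, seeds)
        p2 = train_pair(1.0, session, cfg, seeds)
        np.testing.assert_array_equal(p1.hebb.net.W, p2.hebb.net.W)
        np.testing.assert_array_equal(p1.hebb.readout.W_out,
                                      p2.hebb.readout.W_out)

    def test_small_plasticity_drift(self, corpus):
        session, _, seeds = corpus
        cfg = SweepConfig(radii=(1.0,), **SMALL)
        pair = train_pair(1.0, session, cfg, seeds)
        assert pair.nonhebb.rho_after == pytest.approx(1.0, rel=1e-9)
        assert pair.hebb.rho_after != pair.nonhebb.rho_after
        assert abs(pair.hebb.rho_after - 1.0) / 1.0 < 0.05

    def test_batch_matches_trial_by_trial(self, corpus):
        session, _, seeds = corpus
        cfg = SweepConfig(radii=(0.8,), optimize_readout=False, **SMALL)
        pair = train_pair(0.8, session, cfg, seeds)
        net = init_reservoir(cfg.reservoir_config(0.8, seeds["init"]))
        plast = PlasticityConfig(enabled=True, alpha=cfg.alpha)
        for t, stim in enumerate(session.stimuli):
            _, net = run_trial(net, stim, seeds["trial_init"][t], plast,
                               seeds["trial_noise"][t])
        np.testing.assert_allclose(pair.hebb.net.W, net.W, rtol=1e-7,
                                   atol=1e-12)

    def test_per_network_input_weights_respected(self, corpus):
        session, _, seeds = corpus
        cfg = SweepConfig(radii=(0.8,), **SMALL)
        net_a = init_reservoir(cfg.reservoir_config(0.8, seeds["init"]))
        net_b = net_a.copy()
        net_b.W_in = -net_a.W_in  # flipped input projection
        _train_batch([net_a, net_b], [False, False], session, cfg, seeds)
        assert not np.array_equal(net_a.W, None)  # training ran
        # with alpha=0 both reservoirs keep identical W; states differed but
        # that is only observable through the readouts
        w_init = Readout.random(cfg.n_neurons, seeds["w_out"]).W_out
        # both started from the same readout yet learned different weights
        r_a, r_b = _train_batch(
            [net_a.copy(), net_b.copy()], [False, False], session, cfg,
            seeds)[0]
        assert not np.allclose(r_a.W_out, r_b.W_out)
        assert not np.allclose(r_a.W_out, w_init)


class TestEvaluate:
    def test_row_counts_and_metrics(self, small_config, corpus):
        session, test_set, seeds = corpus
        pair = train_pair(1.0, session, small_config, seeds)
        res = evaluate_pair(pair, test_set, small_config, seeds)
        assert set(res) == {"RN", "RefRN"}
        ev = res["RefRN"]["hebb"]
        assert ev.output_r.shape == (small_config.n_test_runs,)
        assert ev.node_r.shape == (small_config.node_sample_size,
                                   small_config.n_test_runs)
        assert ev.rmse.shape == (1999,)
        assert np.all(ev.rmse >= 0)

    def test_fresh_noise_consistency_near_zero(self, small_config, corpus):
        # inter-segment correlation cannot detect repetition in stimuli
        # whose halves are different time series
        session, test_set, seeds = corpus
        cfg = SweepConfig(radii=(0.5,), eval_kinds=("N", "RefN"),
                          n_test_runs=20, **{k: v for k, v in SMALL.items()
                                             if k != "n_test_runs"})
        pair = train_pair(0.5, session, cfg, seeds)
        res = evaluate_pair(pair, build_corpus(cfg)[1], cfg, seeds)
        for kind in ("N", "RefN"):
            for arm in res[kind].values():
                assert abs(np.nanmean(arm.output_r)) < 0.15


class TestSweep:
    @pytest.fixture(scope="class")
    def bundle(self, small_config):
        return run_sweep(small_config)

    def test_tables_complete(self, bundle, small_config):
        n_runs = small_config.n_test_runs
        counts = bundle.consistency.groupby(
            ["radius", "arm", "kind", "level"]).size()
        # every cell holds one row per run (output) or per run x node
        assert set(counts.unique()) <= {
            n_runs, n_runs * small_config.node_sample_size}
        assert len(bundle.drift) == 2 * len(small_config.radii)
        assert not bundle.tests.empty

    def test_nrmse_grand_mean_one(self, bundle):
        for radius, grp in bundle.error_series.groupby("radius"):
            assert grp["nrmse"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_provenance_reproduces_bitwise(self, small_config, bundle):
        again = run_sweep(small_config)
        pd.testing.assert_frame_equal(bundle.consistency, again.consistency)
        pd.testing.assert_frame_equal(bundle.tests, again.tests)
        pd.testing.assert_frame_equal(bundle.error_series, again.error_series)

    def test_saving(self, bundle, tmp_path):
        out = bundle.save(tmp_path / "results")
        assert (out / "consistency.csv").exists()
        assert (out / "provenance.json").exists()

    def test_selectivity_curve_shape(self, bundle, small_config):
        curve = selectivity_curve(bundle.consistency, level="node")
        assert list(curve.index) == list(small_config.radii)
        assert np.isfinite(peak_radius(curve))


class TestEnsemble:
    def test_smoke_and_pairing(self):
        cfg = SweepConfig(radii=(1.0,), comparison_kinds=("RefRN",),
                          n_surrogates=200, **SMALL)
        bundle = run_ensemble(cfg, n_instances=4, radii=(1.0,),
                              n_runs_per_instance=4)
        assert len(bundle.means) == 2 * 4  # levels x instances
        assert bundle.means[["hebb_r", "nonhebb_r"]].notna().all().all()
        assert len(bundle.tests) == 2
        assert (bundle.tests["n_instances"] == 4).all()

    def test_instances_differ(self):
        cfg = SweepConfig(radii=(1.0,), comparison_kinds=("RefRN",),
                          n_surrogates=200, **SMALL)
        bundle = run_ensemble(cfg, n_instances=3, radii=(1.0,),
                              n_runs_per_instance=3)
        vals = bundle.means.query("level == 'output'")["hebb_r"].values
        assert len(np.unique(vals)) == 3
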
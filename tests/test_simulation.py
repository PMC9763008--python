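"""Virtual subject, replication harness, and policy comparison."""

import numpy as np
import pytest
from pydantic import ValidationError

from eebae.errors import ConfigError
from eebae.inference import posterior_update, precompute_likelihoods, uniform_prior
from eebae.models import GAFModel, GAFParams, GAFStimulus, gaf_response_prob
from eebae.simulation import (
    ExperimentConfig,
    _replication_seeds,
    build_grids,
    build_model,
    compare_policies,
    exploitation_count,
    run_replications,
    simulate_response,
)
from tests.conftest import make_gaf_config


class TestConfigValidation:
    def test_unknown_key_rejected(self, small_gaf):
        data = small_gaf.model_dump()
        data["bogus"] = 1
        with pytest.raises(ValidationError):
            ExperimentConfig.model_validate(data)

    @pytest.mark.parametrize(
        "patch",
        [
            {"truth": {"t_cr": 4.0, "sigma": 2.0}},  # outside range
            {"replications": 0},
            {"param_ranges": {"t_cr": (10, 5), "sigma": (1, 4)}},
            {"policy": {"kind": "ee", "trials": 0, "epsilon": 1.0}},
            {"policy": {"kind": "ee", "trials": 10, "epsilon": None}},
            {"truth": {"t_cr": 7.0}},  # missing parameter
        ],
    )
    def test_invalid_fields_rejected(self, small_gaf, patch):
        data = small_gaf.model_dump()
        data.update(patch)
        with pytest.raises(ValidationError):
            ExperimentConfig.model_validate(data)

    def test_default_spacing_rules(self, small_gaf):
        assert small_gaf.spacing == {"t_cr": "linear", "sigma": "linear"}
        csf = ExperimentConfig.model_validate(
            {
                "model": "csf",
                "param_ranges": {
                    "gamma_max": (2, 2000),
                    "f_max": (0.2, 100),
                    "beta1": (2, 128),
                    "delta1": (0.2, 3),
                },
                "param_grid_sizes": {"gamma_max": 3, "f_max": 3, "beta1": 3, "delta1": 3},
                "stim_ranges": {"log_f": (-0.7, 1.55), "log_c": (-3, 0)},
                "stim_grid_sizes": {"log_f": 3, "log_c": 3},
                "truth": {"gamma_max": 100, "f_max": 2.5, "beta1": 2.5, "delta1": 0.25},
                "policy": {"kind": "ee", "epsilon": 1.5, "trials": 5},
            }
        )
        assert set(csf.spacing.values()) == {"log10"}


class TestVirtualSubject:
    def test_degenerate_probabilities(self):
        class Always(GAFModel):
            def __init__(self, p):
                self.p = p

            def response_prob(self, theta, stim):
                return np.broadcast_arrays(np.asarray(self.p), np.asarray(stim)[..., 0])[0]

        rng = np.random.default_rng(0)
        assert all(
            simulate_response(rng, Always(1.0), [7.0, 2.0], [8.0]) == 1 for _ in range(20)
        )
        assert all(
            simulate_response(rng, Always(0.0), [7.0, 2.0], [8.0]) == 0 for _ in range(20)
        )

    def test_acceptance_frequency_matches_probit_at_critical_gap(self):
        model = GAFModel()
        truth = [7.3, 2.2804]
        rng = np.random.default_rng(12)
        n = 20_000
        hits = sum(simulate_response(rng, model, truth, [7.3]) for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_continuous_truth_not_snapped_to_grid(self, small_gaf):
        # the simulated response probability comes from the exact truth,
        # which lies between grid nodes
        model = build_model(small_gaf)
        grid, _ = build_grids(small_gaf)
        p_truth = float(model.response_prob(small_gaf.truth_vector(), np.array([8.0])))
        p_nodes = model.response_prob(grid.nodes, np.array([8.0]))
        assert not np.any(np.isclose(p_nodes, p_truth, atol=1e-12))


class TestReplications:
    def test_single_replication_equals_aggregate(self, small_gaf):
        config = small_gaf.model_copy(update={"replications": 1})
        traj = run_replications(config, keep_logs=True)
        records = traj.logs[0]
        np.testing.assert_allclose(traj.entropy_bits, [r.entropy_bits for r in records])
        np.testing.assert_allclose(traj.mse, [r.sq_error for r in records])
        assert traj.exploit_counts[0] == exploitation_count(records)

    def test_same_base_seed_reproduces_aggregates(self, small_gaf):
        a = run_replications(small_gaf)
        b = run_replications(small_gaf)
        np.testing.assert_array_equal(a.entropy_bits, b.entropy_bits)
        np.testing.assert_array_equal(a.mse, b.mse)
        np.testing.assert_array_equal(a.exploit_counts, b.exploit_counts)

    def test_replication_seeds_distinct_and_reproducible(self, small_gaf):
        config = small_gaf.model_copy(update={"replications": 20})
        keys_a = [s.spawn_key for s in _replication_seeds(config)]
        keys_b = [s.spawn_key for s in _replication_seeds(config)]
        assert keys_a == keys_b
        assert len(set(keys_a)) == 20
        traj = run_replications(config, keep_logs=True)
        responses = {tuple(r.response for r in log) for log in traj.logs}
        assert len(responses) > 1  # replications are genuinely independent

    def test_mse_declines_with_trials_gaf(self):
        # truth deliberately away from the uniform-prior mean (7.5, 2.5),
        # so both parameters start with substantial error
        config = make_gaf_config(
            truth={"t_cr": 6.0, "sigma": 3.5}, replications=200, policy={"trials": 120}
        )
        traj = run_replications(config)
        assert np.all(traj.mse[-1] < traj.mse[0])

    def test_exploitation_count_extremes(self):
        classical = make_gaf_config(policy={"kind": "classical", "epsilon": None})
        assert run_replications(classical).exploit_counts.max() == 0
        random = make_gaf_config(policy={"kind": "random", "epsilon": None})
        assert np.all(run_replications(random).exploit_counts == 40)


class TestPolicyComparison:
    def test_classical_vs_classical_ratio_is_one(self):
        cl = make_gaf_config(policy={"kind": "classical", "epsilon": None})
        cmp_ = compare_policies(cl, cl.model_copy(deep=True))
        np.testing.assert_allclose(cmp_.final_mse_ratio, 1.0, atol=1e-15)
        np.testing.assert_array_equal(cmp_.first.entropy_bits, cmp_.second.entropy_bits)

    def test_high_threshold_ee_equals_pure_random(self):
        ee = make_gaf_config(policy={"epsilon": 50.0})
        random = make_gaf_config(policy={"kind": "random", "epsilon": None})
        cmp_ = compare_policies(ee, random)
        np.testing.assert_array_equal(cmp_.first.entropy_bits, cmp_.second.entropy_bits)
        np.testing.assert_array_equal(cmp_.first.mse, cmp_.second.mse)

    def test_config_mismatch_beyond_policy_rejected(self, small_gaf):
        other = small_gaf.model_copy(update={"seed": 123})
        with pytest.raises(ConfigError):
            compare_policies(small_gaf, other)

    def test_replayed_ee_arm_identical_to_standalone_run(self):
        # exact-sweep configs: the shared-prefix reconstruction must agree
        # byte for byte with simulating the EE arm from scratch
        ee = make_gaf_config(sweep_mass_cutoff=0.0, replications=8, policy={"trials": 60})
        cl = make_gaf_config(
            sweep_mass_cutoff=0.0,
            replications=8,
            policy={"kind": "classical", "epsilon": None, "trials": 60},
        )
        cmp_ = compare_policies(ee, cl, keep_logs=True)
        assert cmp_.first_arm_replayed
        direct = run_replications(ee, keep_logs=True)
        np.testing.assert_array_equal(cmp_.first.entropy_bits, direct.entropy_bits)
        np.testing.assert_array_equal(cmp_.first.mse, direct.mse)
        np.testing.assert_array_equal(cmp_.first.exploit_counts, direct.exploit_counts)
        for a, b in zip(cmp_.first.logs, direct.logs):
            assert a == b

    def test_bayes_core_is_policy_independent(self):
        # forcing the classical stimulus sequence through manual updates
        # reproduces the classical run's final posterior estimate exactly
        config = make_gaf_config(policy={"kind": "classical", "epsilon": None}, replications=1)
        model = build_model(config)
        grid, sg = build_grids(config)
        table = precompute_likelihoods(model, grid, sg)
        traj = run_replications(config, keep_logs=True, table=table)
        records = traj.logs[0]
        state = uniform_prior(grid)
        for rec in records:
            state = posterior_update(state, table.table[:, rec.stimulus_index], rec.response)
        from eebae.inference import estimate_mean

        np.testing.assert_allclose(
            estimate_mean(state, grid), records[-1].estimate, atol=1e-12
        )


class TestIdentifiability:
    def test_on_grid_truth_modal_node_recovered(self):
        # truth placed exactly on a grid node; with many trials the modal
        # posterior node should be the truth node in nearly all replications
        # sigma separates adjacent grid nodes only slowly, so the run is
        # long enough for the mode to settle on the true node
        config = make_gaf_config(
            truth={"t_cr": 5 + 5 * 4 / 9, "sigma": 1 + 3 * 4 / 9},
            policy={"trials": 5000},
            replications=30,
            seed=17,
        )
        model = build_model(config)
        grid, sg = build_grids(config)
        table = precompute_likelihoods(model, grid, sg)
        traj = run_replications(config, keep_logs=True, table=table)
        truth = config.truth_vector()
        truth_node = int(np.argmin(np.sum((grid.nodes - truth) ** 2, axis=1)))
        hits = 0
        for log in traj.logs:
            state = uniform_prior(grid)
            for rec in log:
                state = posterior_update(state, table.table[:, rec.stimulus_index], rec.response)
            hits += int(np.argmax(state.mass) == truth_node)
        assert hits >= 0.95 * len(traj.logs)
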
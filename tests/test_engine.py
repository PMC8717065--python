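"""Engine-level tests: initialization, stepping, runs, ensembles, invariants."""

import numpy as np
import pytest

from crewrisk import (
    ConfigError,
    ScenarioConfig,
    init_population,
    run_replicates,
    run_simulation,
    steady_state_rate,
)
from crewrisk.engine import Trajectory


def _pop_fields(pop):
    return (
        pop.safety_awareness, pop.safety_knowledge, pop.safety_attitude,
        pop.perception_coeff, pop.conformity, pop.rule_awareness,
        pop.management_norm, pop.risk_acceptance,
    )


class TestInitPopulation:
    def test_default_crew(self):
        cfg = ScenarioConfig()
        pop = init_population(cfg, np.random.default_rng(0))
        assert pop.n_workers == 200
        assert np.all(pop.safety_attitude == 0.5)
        assert np.all(pop.safety_awareness == 0.8)
        assert np.all((pop.perception_coeff >= 0.4) & (pop.perception_coeff <= 1.0))
        assert np.all((pop.management_norm >= 0.1) & (pop.management_norm <= 0.9))
        # acceptance seeded with the initial attitude for day-1 colleague effect
        assert np.array_equal(pop.risk_acceptance, pop.safety_attitude)

    def test_seeded_determinism(self, tiny_config):
        a = init_population(tiny_config, np.random.default_rng(5))
        b = init_population(tiny_config, np.random.default_rng(5))
        for fa, fb in zip(_pop_fields(a), _pop_fields(b)):
            assert np.array_equal(fa, fb)

    def test_inverted_norm_bounds_rejected(self):
        with pytest.raises(ConfigError, match="wn_low"):
            ScenarioConfig(env=ScenarioConfig().env.__class__(wn_low=0.9, wn_high=0.1)).validate()


class TestRunSimulation:
    def test_trajectory_length(self, tiny_config):
        traj = run_simulation(tiny_config.replace(n_days=10), seed=1)
        assert traj.n_days == 10
        assert traj.to_frame().shape[0] == 10

    def test_same_seed_identical(self, tiny_config):
        a = run_simulation(tiny_config, seed=3)
        b = run_simulation(tiny_config, seed=3)
        assert a.to_frame().equals(b.to_frame())

    def test_different_seeds_differ(self):
        cfg = ScenarioConfig(n_workers=50, n_cols=10, n_rows=5, n_days=30,
                             replicates=1, steady_window=10)
        a = run_simulation(cfg, seed=1)
        b = run_simulation(cfg, seed=2)
        assert not np.array_equal(a.unsafe_count, b.unsafe_count)

    def test_no_exposure_means_no_unsafe(self, tiny_config):
        traj = run_simulation(tiny_config.replace(site_risk=0.0), seed=4)
        assert np.all(traj.unsafe_count == 0)
        assert np.all(traj.exposure_count == 0)

    def test_full_norm_weight_with_zero_norm_means_no_unsafe(self, tiny_config):
        """With all weight on a zero-tolerance norm the acceptance threshold is
        0, and perceived risk (> 0 on any exposed, discovered day) always
        exceeds it."""
        cfg = tiny_config.replace(rule_awareness=1.0, wn_low=0.0, wn_high=0.0)
        traj = run_simulation(cfg, seed=5)
        assert np.all(traj.unsafe_count == 0)

    def test_overwhelming_perceived_risk_all_safe(self):
        """Constructed limit: guaranteed exposure and discovery, perception
        coefficient >= 1.5 and actual risk near 0.9 put perceived risk ~1.35,
        far above the acceptance of ~0.1 pinned by the norms."""
        cfg = ScenarioConfig(
            n_workers=12, n_cols=4, n_rows=3, n_days=20, replicates=1,
            steady_window=5, sa0=1.0, sk0=1.0, p0_low=1.5, p0_high=1.5,
            rule_awareness=1.0,
        ).replace(site_risk=1.0, wn_low=0.1, wn_high=0.1, ar_mu=0.9, ar_sigma=0.01)
        traj = run_simulation(cfg, seed=6)
        assert np.all(traj.exposure_count == 12)
        assert np.all(traj.unsafe_count == 0)

    def test_daily_count_ordering(self, tiny_config):
        traj = run_simulation(tiny_config.replace(n_days=50), seed=7)
        assert np.all(traj.accident_count <= traj.unsafe_count)
        assert np.all(traj.unsafe_count <= traj.exposure_count)
        assert np.all(traj.exposure_count <= tiny_config.n_workers)
        assert np.all((traj.unsafe_rate >= 0) & (traj.unsafe_rate <= 1))

    def test_state_bounds_hold_after_many_steps(self, tiny_config):
        cfg = tiny_config.replace(n_days=80, site_risk=0.9)
        rng = np.random.default_rng(8)
        pop = init_population(cfg, rng)
        from crewrisk import step_day

        for _ in range(cfg.n_days):
            step_day(pop, cfg.env, rng)
        for arr in (pop.safety_attitude, pop.risk_acceptance, pop.management_norm):
            assert np.all((arr >= 0.0) & (arr <= 1.0))
        assert np.all(pop.perception_coeff >= cfg.env.p_floor)
        assert pop.n_workers == cfg.n_workers

    def test_counting_undetected_hazards_raises_the_rate(self, tiny_config):
        """With the same draws, treating undetected hazards as unsafe acts can
        only add unsafe workers on the first day."""
        day1_default = run_simulation(tiny_config, seed=9).unsafe_count[0]
        day1_strict = run_simulation(
            tiny_config.replace(count_undetected_as_unsafe=True), seed=9
        ).unsafe_count[0]
        assert day1_strict >= day1_default


class TestEnsemble:
    def test_single_replicate_mean_equals_trajectory(self, tiny_config):
        ens = run_replicates(tiny_config.replace(replicates=1))
        assert np.array_equal(ens.day_mean, ens.trajectories[0].unsafe_rate)

    def test_day_mean_within_replicate_envelope(self, tiny_config):
        ens = run_replicates(tiny_config)
        assert ens.replicates == tiny_config.replicates
        rates = ens.rates
        assert np.all(ens.day_mean >= rates.min(axis=0) - 1e-12)
        assert np.all(ens.day_mean <= rates.max(axis=0) + 1e-12)

    def test_zero_site_risk_zero_steady_rate(self, tiny_config):
        ens = run_replicates(tiny_config.replace(site_risk=0.0))
        assert ens.steady_state_rate() == 0.0

    def test_master_seed_reproducibility(self, tiny_config):
        a = run_replicates(tiny_config).to_frame()
        b = run_replicates(tiny_config).to_frame()
        assert a.equals(b)

    def test_tidy_frame_columns(self, tiny_config):
        f = run_replicates(tiny_config).to_frame()
        assert list(f.columns) == [
            "replicate", "day", "unsafe_count", "unsafe_rate",
            "accident_count", "exposure_count", "mean_AT", "mean_RA",
        ]


class TestSteadyStateRate:
    def test_constant_trajectory(self):
        traj = Trajectory(
            n_workers=10,
            unsafe_count=np.full(100, 2),
            accident_count=np.zeros(100, dtype=int),
            exposure_count=np.full(100, 5),
            mean_attitude=np.full(100, 0.5),
            mean_acceptance=np.full(100, 0.5),
        )
        assert steady_state_rate(traj, 50) == pytest.approx(0.2)

    def test_hand_mean_over_trailing_window(self):
        counts = np.array([9, 9, 1, 2, 3])
        traj = Trajectory(
            n_workers=10,
            unsafe_count=counts,
            accident_count=np.zeros(5, dtype=int),
            exposure_count=np.full(5, 10),
            mean_attitude=np.zeros(5),
            mean_acceptance=np.zeros(5),
        )
        assert steady_state_rate(traj, 3) == pytest.approx(0.2)

    def test_window_longer_than_run_raises(self, tiny_config):
        traj = run_simulation(tiny_config.replace(n_days=5), seed=1)
        with pytest.raises(ValueError):
            steady_state_rate(traj, 6)


def test_config_validation_names_offending_field():
    with pytest.raises(ConfigError, match="conformity"):
        ScenarioConfig(conformity=1.2).validate()
    with pytest.raises(ConfigError, match="n_cols/n_rows"):
        ScenarioConfig(n_workers=7).validate()
    with pytest.raises(ConfigError, match="steady_window"):
        ScenarioConfig(n_days=10, steady_window=50).validate()
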
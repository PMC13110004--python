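"""Tests for subgroup sampling, schedules, covariates, LoD and assembly."""

import math

import numpy as np
import pytest

from mrdsim import (
    CovariateSpec,
    HazardSpec,
    ScheduleSpec,
    SimulationConfig,
    SubgroupSpec,
)
from mrdsim.cohort import (
    ConfigError,
    Observation,
    apply_lod,
    build_cohort,
    build_schedule,
    config_from_dict,
    config_to_dict,
    generate_covariates,
    sample_subject_truth,
)
from conftest import small_config


def _subgroup(**kw):
    base = dict(
        name="CR",
        n=5,
        beta0_meanlog=-2.0,
        beta0_sdlog=0.5,
        beta1_meanlog=-6.0,
        beta1_sdlog=0.5,
        te=6.0,
        relapse_prob=0.5,
        relapse_mean=20.0,
        relapse_sd=4.0,
        beta2=0.3,
        sigma=0.02,
    )
    base.update(kw)
    return SubgroupSpec(**base)


class TestSubjectTruth:
    def test_degenerate_distributions_are_deterministic(self, rng):
        sub = _subgroup(
            beta0_sdlog=0.0, beta1_sdlog=0.0, relapse_sd=0.0, relapse_prob=1.0
        )
        p = sample_subject_truth(sub, rng)
        assert p.beta0 == pytest.approx(math.exp(-2.0))
        assert p.beta1 == pytest.approx(math.exp(-6.0))
        assert p.tr == 20.0
        assert (p.te, p.beta2, p.sigma) == (6.0, 0.3, 0.02)

    def test_lognormal_moments(self, rng):
        sub = _subgroup(beta0_meanlog=-2.0, beta0_sdlog=0.5)
        draws = np.log([sample_subject_truth(sub, rng).beta0 for _ in range(10_000)])
        assert abs(draws.mean() - (-2.0)) < 3 * 0.5 / math.sqrt(10_000)

    def test_no_relapse_branch(self, rng):
        sub = _subgroup(relapse_prob=0.0)
        assert all(
            math.isinf(sample_subject_truth(sub, rng).tr) for _ in range(50)
        )

    def test_relapse_times_truncated_above_te(self, rng):
        sub = _subgroup(relapse_prob=1.0, relapse_mean=7.0, relapse_sd=3.0)
        trs = [sample_subject_truth(sub, rng).tr for _ in range(500)]
        assert all(tr > 6.0 for tr in trs)

    def test_impossible_truncation_raises(self, rng):
        with pytest.raises(ConfigError, match="relapse_mean"):
            _subgroup(relapse_prob=1.0, relapse_mean=5.0)  # below te=6


class TestSchedule:
    def test_regular_grid(self, rng):
        sched = ScheduleSpec(mode="regular", interval=3.0, horizon=12.0)
        times, missing = build_schedule(sched, rng)
        assert times == [0.0, 3.0, 6.0, 9.0, 12.0]
        assert missing == [False] * 5

    def test_all_visits_missing_at_prob_one(self, rng):
        sched = ScheduleSpec(
            mode="regular", interval=3.0, horizon=12.0, miss_prob=1.0
        )
        _, missing = build_schedule(sched, rng)
        assert all(missing)

    def test_missing_fraction_binomial(self, rng):
        sched = ScheduleSpec(
            mode="regular", interval=1.0, horizon=9.0, miss_prob=0.2
        )
        flags = []
        while len(flags) < 10_000:
            _, missing = build_schedule(sched, rng)
            flags.extend(missing)
        frac = np.mean(flags[:10_000])
        assert abs(frac - 0.2) < 3 * math.sqrt(0.2 * 0.8 / 10_000)

    def test_jitter_preserves_order(self, rng):
        sched = ScheduleSpec(
            mode="regular", interval=3.0, horizon=30.0, jitter_sd=0.3
        )
        for _ in range(100):
            times, _ = build_schedule(sched, rng)
            assert all(b > a for a, b in zip(times, times[1:]))

    def test_explicit_mode(self, rng):
        sched = ScheduleSpec(mode="explicit", visit_times=(0.0, 1.0, 6.0))
        times, _ = build_schedule(sched, rng)
        assert times == [0.0, 1.0, 6.0]

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigError):
            ScheduleSpec(mode="regular", interval=-1.0, horizon=10.0)
        with pytest.raises(ConfigError):
            ScheduleSpec(mode="explicit", visit_times=(3.0, 1.0))


class TestCovariates:
    def test_degenerate_draws(self, rng):
        specs = [
            CovariateSpec("always", "binary", {"p": 1.0}),
            CovariateSpec("zero", "continuous", {"mean": 0.0, "sd": 0.0}),
        ]
        baseline, tracks = generate_covariates(specs, rng)
        assert baseline == {"always": 1, "zero": 0.0}
        assert tracks == {}

    def test_categorical_frequencies(self, rng):
        spec = CovariateSpec(
            "arm", "categorical", {"levels": ["A", "B"], "probs": [0.5, 0.5]}
        )
        draws = [spec.draw(rng) for _ in range(10_000)]
        frac = draws.count("A") / 10_000
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_time_variant_track_structure(self, rng):
        spec = CovariateSpec(
            "response",
            "categorical",
            {"levels": ["CR", "PD"], "probs": [0.7, 0.3]},
            change_times=(6.0, 12.0),
        )
        _, tracks = generate_covariates([spec], rng)
        starts = [t for t, _ in tracks["response"]]
        assert starts == [0.0, 6.0, 12.0]
        assert all(v in ("CR", "PD") for _, v in tracks["response"])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError, match="kind"):
            CovariateSpec("x", "poisson", {})

    def test_categorical_encoding_for_hazard(self):
        spec = CovariateSpec(
            "arm", "categorical", {"levels": ["A", "B", "C"], "probs": [0.3, 0.3, 0.4]}
        )
        assert spec.numeric("B") == 1.0


class TestLod:
    def test_strict_threshold_convention(self):
        obs = [
            Observation("s1", 0.0, 5e-5, 5e-5, False, False),
            Observation("s1", 1.0, 1e-4, 1e-4, False, False),
        ]
        apply_lod(obs, 1e-4)
        assert obs[0].below_lod is True
        assert obs[1].below_lod is False  # boundary equality is detectable

    def test_flag_count_matches_recount(self, rng):
        values = rng.lognormal(-9, 2, size=1000)
        obs = [
            Observation("s", float(i), float(v), float(v), False, False)
            for i, v in enumerate(values)
        ]
        apply_lod(obs, 1e-4)
        assert sum(o.below_lod for o in obs) == int((values < 1e-4).sum())

    def test_censor_at_lod_replaces_value(self):
        obs = [Observation("s", 0.0, 5e-5, 5e-5, False, False)]
        apply_lod(obs, 1e-4, censor_at_lod=True)
        assert obs[0].value == 1e-4 and obs[0].raw_value == 5e-5

    def test_missing_observations_untouched(self):
        obs = [Observation("s", 0.0, None, None, False, True)]
        apply_lod(obs, 1e-4)
        assert obs[0].below_lod is False


class TestBuildCohort:
    def test_subject_counts_and_unique_ids(self):
        cfg = SimulationConfig(
            subgroups=(_subgroup(name="A", n=3), _subgroup(name="B", n=2)),
            hazard=HazardSpec(baseline_params={"rate": 0.05}, t_max=30.0),
            schedule=ScheduleSpec(mode="regular", interval=3.0, horizon=30.0),
        )
        ds = build_cohort(cfg, 1)
        assert len(ds.subjects) == 5
        assert len({s.id for s in ds.subjects}) == 5

    def test_determinism_under_fixed_seed(self):
        from mrdsim.io import _dataset_to_obj

        cfg = small_config(n=15, alpha1=0.4, link_scale="log10", miss_prob=0.1)
        a = _dataset_to_obj(build_cohort(cfg, 42))
        b = _dataset_to_obj(build_cohort(cfg, 42))
        assert a == b

    def test_different_seeds_differ(self):
        cfg = small_config(n=10)
        a = build_cohort(cfg, 1)
        b = build_cohort(cfg, 2)
        assert [s.event_time for s in a.subjects] != [
            s.event_time for s in b.subjects
        ]

    def test_no_observation_after_followup_end(self):
        cfg = small_config(n=40, alpha1=0.5, link_scale="log10", rate=0.05)
        ds = build_cohort(cfg, 3)
        end = {s.id: s.event_time for s in ds.subjects}
        assert ds.observations
        assert all(o.time <= end[o.subject_id] for o in ds.observations)
        assert all(s.event_time <= cfg.hazard.t_max for s in ds.subjects)

    def test_event_status_partitions(self):
        cfg = small_config(n=30, dropout_rate=0.02)
        ds = build_cohort(cfg, 5)
        for s in ds.subjects:
            if s.status == 1:
                assert s.censor_reason == "none"
            else:
                assert s.censor_reason in ("administrative", "dropout")

    def test_trajectory_shape_invariants(self, rng):
        from mrdsim.trajectory import mu

        # no relapse, beta0 >> beta1: every true curve is non-increasing
        cfg = small_config(n=20, relapse_prob=0.0)
        ds = build_cohort(cfg, 11)
        for s in ds.subjects:
            grid = np.linspace(0, 30, 40)
            vals = [mu(s.truth, float(t)) for t in grid]
            assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        # universal relapse with growth: every curve eventually exceeds beta1
        cfg2 = small_config(n=20, relapse_prob=1.0)
        ds2 = build_cohort(cfg2, 12)
        for s in ds2.subjects:
            assert math.isfinite(s.truth.tr)
            assert mu(s.truth, s.truth.tr + 20.0) > s.truth.beta1

    def test_gamma_length_validated(self):
        with pytest.raises(ConfigError, match="gamma"):
            small_config(n=5, gamma=(0.5,))  # no covariates declared


class TestConfigRoundTrip:
    def test_dict_round_trip(self):
        cfg = small_config(
            n=8,
            alpha1=0.3,
            covariates=(CovariateSpec("tp53", "binary", {"p": 0.4}),),
            gamma=(0.5,),
        )
        assert config_to_dict(config_from_dict(config_to_dict(cfg))) == (
            config_to_dict(cfg)
        )

    def test_aggregated_errors(self):
        bad = {
            "subgroups": [
                {"name": "X", "n": 0, "beta0_meanlog": 0, "beta1_meanlog": 0,
                 "te": -1},
            ],
            "hazard": {"baseline_params": {"rate": -0.1}},
        }
        with pytest.raises(ConfigError) as exc:
            config_from_dict(bad)
        msg = str(exc.value)
        assert "subgroups[0]" in msg and "hazard" in msg

    def test_unknown_top_level_key_warns(self):
        cfg = config_to_dict(small_config(n=3))
        cfg["frobnicate"] = 1
        with pytest.warns(UserWarning, match="frobnicate"):
            config_from_dict(cfg)
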
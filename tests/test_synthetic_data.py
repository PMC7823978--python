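"""Generator tests: cohort moments, design constraints, trace fidelity and
study round trips."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import leashwalk as lw
from leashwalk.synthetic_data import (
    EVENT_GUARD, CohortMoments, SimulationParams, _matched_truncnorm,
    build_design, cohort_frame, generate_cohort, simulate_outcome_table,
    simulate_study, simulate_walk_trace, read_study, write_study,
)
from leashwalk.tension_meter import SAMPLE_DT, TENSION_RESOLUTION


class TestCohort:
    def test_moments_recovered_at_n1000(self):
        m = CohortMoments()
        dogs = generate_cohort(1000, seed=42)
        df = cohort_frame(dogs)
        # sample means within 4 standard errors of the configured moments
        for col, mean, sd in [("age", m.age_mean, m.age_sd),
                              ("weight", m.weight_mean, m.weight_sd),
                              ("height", m.height_mean, m.height_sd),
                              ("length", m.length_mean, m.length_sd),
                              ("cephalic_index", m.ci_mean, m.ci_sd)]:
            se = sd / np.sqrt(len(df))
            assert abs(df[col].mean() - mean) < 4 * se, col
            assert abs(df[col].std() - sd) < 0.15 * sd, col
        p = df["sex"].eq("female").mean()
        assert abs(p - m.p_female) < 0.05
        source_props = df["source"].value_counts(normalize=True)
        for name, target in zip(("stray", "surrendered", "returned", "other"),
                                m.source_probs):
            assert abs(source_props.get(name, 0.0) - target) < 0.06

    def test_truncated_normal_moment_matching(self):
        # age truncates only 1.46 sd below its mean: the naive parameters
        # would bias the mean upward; the matched ones must not
        loc, scale = _matched_truncnorm(44.82, 29.37, 2.0, np.inf)
        a = (2.0 - loc) / scale
        mu, var = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale,
                                        moments="mv")
        assert float(mu) == pytest.approx(44.82, abs=1e-6)
        assert float(np.sqrt(var)) == pytest.approx(29.37, abs=1e-6)

    def test_determinism(self):
        a = cohort_frame(generate_cohort(50, seed=3))
        b = cohort_frame(generate_cohort(50, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = cohort_frame(generate_cohort(50, seed=3))
        b = cohort_frame(generate_cohort(50, seed=4))
        assert not a.equals(b)

    def test_profile_invariants(self, small_cohort):
        for d in small_cohort:
            assert d.weight > 0
            assert 1 <= d.bcs <= 9
            assert d.cephalic_index == pytest.approx(
                d.skull_width / d.skull_length)
            assert d.age >= 2.0

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=1)


class TestDesign:
    def test_study_scale_design(self, full_design):
        assert full_design.n_walks == 370
        df = full_design.to_frame()
        assert df["walker_id"].nunique() == 74
        assert df["walker_id"].value_counts().eq(5).all()
        # a walker never repeats a dog; all pairs unique
        pairs = list(zip(df["walker_id"], df["dog_id"]))
        assert len(set(pairs)) == 370
        assert df["dog_id"].nunique() <= 111

    def test_dog_usage_balanced(self, full_design):
        counts = full_design.to_frame()["dog_id"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_single_walker(self):
        design = build_design(5, 1, 5, seed=0)
        df = design.to_frame()
        assert sorted(df["dog_id"]) == [f"D{i:03d}" for i in range(1, 6)]

    def test_infeasible_design_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            build_design(3, 2, 5, seed=0)
        with pytest.raises(ValueError):
            build_design(0, 2, 1, seed=0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(1, 12), st.integers(1, 8), st.integers(1, 6),
           st.integers(0, 1000))
    def test_feasible_designs_always_validate(self, n_dogs, n_walkers,
                                              walks, seed):
        if n_dogs < walks:
            with pytest.raises(ValueError):
                build_design(n_dogs, n_walkers, walks, seed=seed)
        else:
            design = build_design(n_dogs, n_walkers, walks, seed=seed)
            design.validate()
            assert design.n_walks == n_walkers * walks


class TestWalkTrace:
    def test_zero_process_gives_flat_zero_trace(self, small_cohort):
        params = SimulationParams(dog_pull_rate=0.0, handler_pull_rate=0.0,
                                  noise_sd=0.0, accel_noise_sd=0.0)
        trace, events = simulate_walk_trace(small_cohort[0], params, seed=1)
        assert events == []
        assert np.all(trace.tension == 0.0)
        assert len(trace.tension) == int(round(params.walk_duration / SAMPLE_DT))

    def test_tension_quantized_to_meter_resolution(self, small_cohort):
        params = SimulationParams()
        trace, _ = simulate_walk_trace(small_cohort[1], params, seed=2)
        steps = trace.tension / TENSION_RESOLUTION
        assert np.allclose(steps, np.round(steps), atol=1e-9)
        assert trace.tension.min() >= 0.0
        assert trace.tension.max() <= 100.0

    def test_event_count_is_poisson_with_the_configured_rate(self,
                                                             small_cohort):
        params = SimulationParams()  # dog rate 0.02/s over 600 s -> mean 12
        counts = []
        for seed in range(200):
            _, events = simulate_walk_trace(small_cohort[0], params, seed=seed)
            counts.append(sum(e.initiator == "dog" for e in events))
        mean = np.mean(counts)
        target = params.dog_pull_rate * params.walk_duration
        tol = 4 * np.sqrt(target / 200)  # 4 standard errors of a Poisson mean
        assert abs(mean - target) < tol

    def test_events_have_guard_clearance(self, small_cohort):
        params = SimulationParams()
        for seed in range(10):
            _, events = simulate_walk_trace(small_cohort[0], params, seed=seed)
            ordered = sorted(events, key=lambda e: e.onset_s)
            for a, b in zip(ordered, ordered[1:]):
                assert b.onset_s - (a.onset_s + a.duration_s) >= EVENT_GUARD - 1e-9

    def test_trace_determinism(self, small_cohort):
        params = SimulationParams()
        t1, e1 = simulate_walk_trace(small_cohort[0], params, seed=5)
        t2, e2 = simulate_walk_trace(small_cohort[0], params, seed=5)
        assert np.array_equal(t1.tension, t2.tension)
        assert np.array_equal(t1.accel, t2.accel)
        assert e1 == e2


class TestParams:
    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimulationParams(walk_duration=-1.0).validate()
        with pytest.raises(ValueError):
            SimulationParams(dog_pull_rate=-0.1).validate()
        with pytest.raises(ValueError):
            SimulationParams(head_visible_fraction=0.0).validate()

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = {"walk_duration": 300.0, "dog_pull_rate": 0.03,
               "covariate_effects": {"nt_max": {"weight": 0.01}}}
        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump(cfg))
        p = SimulationParams.from_yaml(path)
        assert p.walk_duration == 300.0
        assert p.covariate_effects["nt_max"]["weight"] == 0.01

    def test_residual_sd_overrides(self):
        p = SimulationParams()
        assert p.outcome_residual_sd("track_pct") == 4.0
        assert p.outcome_residual_sd("nt_max") == p.residual_sd


class TestOutcomeTable:
    def test_shape_and_determinism(self, small_design, small_cohort):
        params = SimulationParams()
        tab1, truth1 = simulate_outcome_table(small_design, small_cohort,
                                              params, seed=9)
        tab2, _ = simulate_outcome_table(small_design, small_cohort,
                                         params, seed=9)
        assert len(tab1) == small_design.n_walks
        assert np.isfinite(tab1["y"]).all()
        pd.testing.assert_frame_equal(tab1, tab2)
        assert truth1["outcome"] == "nt_max"
        assert set(truth1["dog_intercepts"]) == set(tab1["dog_id"].unique())

    def test_planted_effect_shifts_the_outcome(self, small_design,
                                               small_cohort):
        base = SimulationParams(residual_sd=0.01, random_sd_dog=0.0,
                                random_sd_walker=0.0)
        planted = SimulationParams(
            residual_sd=0.01, random_sd_dog=0.0, random_sd_walker=0.0,
            covariate_effects={"nt_max": {"weight": 0.05}})
        t0, _ = simulate_outcome_table(small_design, small_cohort, base, seed=3)
        t1, _ = simulate_outcome_table(small_design, small_cohort, planted,
                                       seed=3)
        shift = (t1["y"] - t0["y"]).to_numpy()
        assert np.allclose(shift, 0.05 * t1["weight"].to_numpy(), atol=1e-9)


class TestStudyBundle:
    def test_tables_are_consistent(self, small_bundle, small_design):
        b = small_bundle
        assert len(b.design) == small_design.n_walks
        assert set(b.traces) == set(b.design["walk_id"])
        assert set(b.ethograms) == set(b.design["walk_id"])
        assert set(b.questionnaires["walk_id"]) == set(b.design["walk_id"])
        assert set(b.assessments["dog_id"]) == set(b.design["dog_id"].unique())
        qcols = [f"q{i}" for i in range(1, 14)]
        assert b.questionnaires[qcols].isin([1, 2, 3, 4, 5]).all().all()

    def test_ethograms_validate(self, small_bundle):
        from leashwalk.ethogram_metrics import validate_log
        for log in small_bundle.ethograms.values():
            assert validate_log(log) == []

    def test_ground_truth_bookkeeping(self, small_bundle):
        gt = small_bundle.ground_truth
        assert set(gt["events"]) == set(small_bundle.traces)
        for walk_id, events in gt["events"].items():
            for e in events:
                assert e["initiator"] in ("dog", "handler")
                assert e["winner"] in ("dog", "handler")
                assert 0 <= e["onset_s"] <= 120.0

    def test_write_read_round_trip(self, small_bundle, tmp_path):
        write_study(small_bundle, tmp_path / "study")
        loaded = read_study(tmp_path / "study")
        assert set(loaded.traces) == set(small_bundle.traces)
        wid = sorted(small_bundle.traces)[0]
        np.testing.assert_allclose(loaded.traces[wid].tension,
                                   small_bundle.traces[wid].tension,
                                   atol=1e-6)
        assert len(loaded.questionnaires) == len(small_bundle.questionnaires)
        assert loaded.ground_truth["seed"] == small_bundle.ground_truth["seed"]

    def test_same_seed_writes_identical_bytes(self, small_design,
                                              small_cohort, tmp_path):
        params = SimulationParams(walk_duration=120.0)
        for name in ("a", "b"):
            bundle = simulate_study(small_design, small_cohort, params, seed=7)
            write_study(bundle, tmp_path / name)
        walks = sorted((tmp_path / "a" / "walks").iterdir())
        assert walks, "no walk files written"
        for f in walks:
            assert filecmp.cmp(f, tmp_path / "b" / "walks" / f.name,
                               shallow=False)
        for rel in ("dogs.csv", "design.csv", "assessments.csv",
                    "questionnaires.csv", "ground_truth.json"):
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel,
                               shallow=False)

    def test_unknown_dog_in_design_rejected(self, small_cohort):
        design = lw.StudyDesign(2, 1, 2, [("W001", "D998"), ("W001", "D999")])
        with pytest.raises(ValueError, match="unknown dogs"):
            simulate_study(design, small_cohort, SimulationParams(), seed=0)
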
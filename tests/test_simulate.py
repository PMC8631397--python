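"""Cohort simulator: design balance, moment recovery, trace round-trips."""

import numpy as np
import pandas as pd
import pytest

from oculonet.datasets import target_correlation_matrix
from oculonet.events import DetectionParams, detect_events
from oculonet.measures import ALL_MEASURES
from oculonet.simulate import (
    GROUP_DEFAULTS,
    LatencyParams,
    LogitNormalMargin,
    SimulationConfig,
    TrialOutcome,
    TrialSpec,
    default_margins,
    expected_classification,
    generate_cognitive_scores,
    generate_gaze_trace,
    generate_task_design,
    generate_trial_outcomes,
    matched_latent_correlation,
    nearest_correlation,
    simulate_cohort,
    simulate_measures,
)


class TestTaskDesign:
    def test_antisaccade_design_is_balanced(self):
        design = generate_task_design("AS", seed=1)
        assert len(design) == 80
        sides = [np.sign(tr.ps_x_deg) for tr in design]
        assert sides.count(-1.0) == 40 and sides.count(1.0) == 40
        assert all(abs(tr.ps_x_deg) == 15.0 for tr in design)

    def test_gonogo_design_is_balanced(self):
        design = generate_task_design("GnG", seed=1)
        assert len(design) == 80
        conds = [tr.condition for tr in design]
        assert conds.count("Go") == 40 and conds.count("NoGo") == 40
        locs = [tr.location_index for tr in design]
        assert all(locs.count(k) == 10 for k in range(8))

    def test_timing_intervals_respect_bounds(self):
        for tr in generate_task_design("GnG", seed=3):
            assert 2000.0 <= tr.fp_duration_ms <= 4000.0
            assert 2000.0 <= tr.intertrial_ms <= 3000.0

    def test_same_seed_reproduces_ordering(self):
        d1 = generate_task_design("AS", seed=1)
        d2 = generate_task_design("AS", seed=1)
        assert d1 == d2

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            generate_task_design("smooth_pursuit", seed=0)


class TestTrialSpecInvariants:
    def test_as_eccentricity_enforced(self):
        with pytest.raises(ValueError):
            TrialSpec("AS", "none", 10.0, 0.0, 2500.0, 2500.0)

    def test_gng_needs_location(self):
        with pytest.raises(ValueError):
            TrialSpec("GnG", "Go", 15.0, 0.0, 2500.0, 2500.0, location_index=9)

    def test_fixation_interval_bounds(self):
        with pytest.raises(ValueError):
            TrialSpec("AS", "none", 15.0, 0.0, 1500.0, 2500.0)


class TestCognitiveScores:
    MEANS = GROUP_DEFAULTS["patient"]["cognitive_means"]
    SDS = GROUP_DEFAULTS["patient"]["cognitive_sds"]

    def test_recovers_target_correlation_at_large_n(self):
        corr = (
            target_correlation_matrix().loc[list(ALL_MEASURES[:6]),
                                            list(ALL_MEASURES[:6])].to_numpy()
        )
        scores = generate_cognitive_scores(5000, self.MEANS, self.SDS, corr, seed=7)
        got = np.corrcoef(scores.T)
        # DS (col 1) vs SC (col 4): published 0.63
        assert got[1, 4] == pytest.approx(0.63, abs=0.05)
        assert np.max(np.abs(got - corr)) < 0.05

    def test_identity_correlation_gives_independence(self):
        scores = generate_cognitive_scores(
            5000, self.MEANS, self.SDS, np.eye(6), seed=3
        )
        got = np.corrcoef(scores.T)
        off = got[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_zero_sds_collapse_to_mean(self):
        scores = generate_cognitive_scores(
            20, self.MEANS, np.zeros(6), np.eye(6), seed=0
        )
        assert np.allclose(scores, np.asarray(self.MEANS))

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            generate_cognitive_scores(0, self.MEANS, self.SDS, np.eye(6), seed=0)
        bad = np.eye(6)
        bad[0, 1] = 0.5  # not symmetric
        with pytest.raises(ValueError):
            generate_cognitive_scores(10, self.MEANS, self.SDS, bad, seed=0)


class TestNearestCorrelation:
    def test_valid_matrix_unchanged(self):
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(nearest_correlation(c), c)

    def test_indefinite_matrix_repaired(self):
        c = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_correlation(c)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.allclose(fixed, fixed.T)


class TestTrialOutcomes:
    LAT = LatencyParams(361.0, 98.0)

    def test_full_accuracy_gives_only_correct_and_miss(self):
        design = generate_task_design("AS", seed=2)
        outs = generate_trial_outcomes(design, 1.0, self.LAT, seed=0)
        assert all(o.label in ("correct", "miss") for o in outs)

    def test_zero_accuracy_gives_no_correct(self):
        design = generate_task_design("AS", seed=2)
        outs = generate_trial_outcomes(design, 0.0, self.LAT, seed=0)
        assert not any(o.label == "correct" for o in outs)

    def test_correct_fraction_tracks_accuracy(self):
        design = generate_task_design("AS", seed=2) * 125  # 10,000 trials
        outs = generate_trial_outcomes(design, 0.75, self.LAT, seed=3, miss_prob=0.0)
        frac = np.mean([o.label == "correct" for o in outs])
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_error_latencies_run_faster_than_correct(self):
        design = generate_task_design("AS", seed=2) * 30
        outs = generate_trial_outcomes(design, 0.5, self.LAT, seed=4, miss_prob=0.0)
        correct = [o.latency_ms for o in outs if o.label == "correct"]
        error = [o.latency_ms for o in outs if o.label == "error"]
        assert np.mean(error) < np.mean(correct)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            generate_trial_outcomes([], 1.5, self.LAT, seed=0)


class TestLatencyParams:
    def test_sample_moments_match_request(self):
        lp = LatencyParams(361.0, 139.0)
        draws = lp.sample(np.random.default_rng(0), 200_000)
        assert np.mean(draws) == pytest.approx(361.0, rel=0.01)
        assert np.std(draws) == pytest.approx(139.0, rel=0.02)
        assert draws.min() > lp.shift_ms

    def test_mean_must_exceed_shift(self):
        with pytest.raises(ValueError):
            LatencyParams(50.0, 10.0)


class TestGazeTrace:
    AS_TRIAL = TrialSpec("AS", "none", 15.0, 0.0, 2500.0, 2500.0)
    NOGO_TRIAL = TrialSpec("GnG", "NoGo", 15.0, 0.0, 2500.0, 2500.0, location_index=0)
    GO_TRIAL = TrialSpec("GnG", "Go", 15.0, 0.0, 2500.0, 2500.0, location_index=0)

    def test_correct_antisaccade_lands_at_mirror_position(self):
        out = TrialOutcome("correct", 300.0)
        rec = generate_gaze_trace(self.AS_TRIAL, out, seed=0, noise_sd=0.1)
        assert np.mean(rec.x_deg[-50:]) == pytest.approx(-15.0, abs=0.2)

    def test_correct_nogo_holds_fixation(self):
        out = TrialOutcome("correct", None)
        rec = generate_gaze_trace(self.NOGO_TRIAL, out, seed=0, noise_sd=0.1)
        assert np.max(np.abs(rec.x_deg)) < 2.0

    def test_detector_recovers_embedded_onset(self):
        out = TrialOutcome("correct", 300.0)
        rec = generate_gaze_trace(self.GO_TRIAL, out, seed=1, noise_sd=0.1)
        saccades = [e for e in detect_events(rec, DetectionParams())
                    if e.kind == "saccade" and e.amplitude_deg > 2.0]
        assert len(saccades) == 1
        onset_rel = saccades[0].onset_ms - self.GO_TRIAL.ps_onset_ms
        assert onset_rel == pytest.approx(300.0, abs=8.0)  # two sample periods

    def test_sample_spacing_follows_rate(self):
        out = TrialOutcome("miss", None)
        rec = generate_gaze_trace(self.AS_TRIAL, out, seed=0, sampling_rate=500.0)
        assert np.allclose(np.diff(rec.t_ms), 2.0)

    def test_bad_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_gaze_trace(
                self.AS_TRIAL, TrialOutcome("miss", None), seed=0, sampling_rate=0.0
            )


class TestMeasureSimulation:
    def test_copula_matching_preserves_target_pearson(self):
        cfg = SimulationConfig()
        margins = default_margins(cfg, "patient")
        target = cfg.target_correlation.to_numpy()
        latent = matched_latent_correlation(margins, target)
        assert np.linalg.eigvalsh(latent).min() > 0
        # latent correlations exceed targets in magnitude for nonlinear margins
        i, j = 8, 4  # ASEs (logit-normal) vs SC (normal), target -0.35
        assert abs(latent[i, j]) >= abs(target[i, j])

    def test_sample_correlations_near_target_at_n93(self):
        # Per-pair tolerance is 3 standard errors, SE = (1 - r^2) / sqrt(n).
        # Across 66 simultaneous pairs a calibrated generator still exceeds
        # 3 SE somewhere ~16% of the time, so allow at most two chance
        # exceedances, each within a 4 SE hard cap.
        cfg = SimulationConfig()
        df = simulate_measures(93, cfg, "patient", seed=5)
        got = np.corrcoef(df.to_numpy().T)
        target = cfg.target_correlation.to_numpy()
        se = (1 - target**2) / np.sqrt(93)
        iu = np.triu_indices(12, 1)
        z = np.abs(got - target)[iu] / se[iu]
        assert np.sum(z > 3.0) <= 2
        assert np.max(z) < 4.0

    def test_margin_medians_match_calibration(self):
        cfg = SimulationConfig()
        df = simulate_measures(4000, cfg, "patient", seed=2)
        assert df["ASEs"].median() == pytest.approx(0.100, abs=0.02)
        assert df["GnGEs"].median() == pytest.approx(0.400, abs=0.03)
        assert df["ASLs"].mean() == pytest.approx(361.0, abs=6.0)
        assert df["VM"].mean() == pytest.approx(43.5, abs=1.0)

    def test_logit_margin_validates_quartiles(self):
        with pytest.raises(ValueError):
            LogitNormalMargin(0.5, 0.6, 0.7)


class TestCohort:
    def test_cohort_is_reproducible(self):
        cfg = SimulationConfig(n_patients=4, n_controls=2)
        c1 = simulate_cohort(cfg, seed=11)
        c2 = simulate_cohort(cfg, seed=11)
        pd.testing.assert_frame_equal(c1.measures, c2.measures)
        sid = c1.subject_ids[0]
        assert c1.designs[sid] == c2.designs[sid]
        assert c1.outcomes[sid] == c2.outcomes[sid]

    def test_group_sizes_and_columns(self):
        cfg = SimulationConfig(n_patients=5, n_controls=3)
        cohort = simulate_cohort(cfg, seed=0, include_trials=False)
        assert (cohort.measures["group"] == "patient").sum() == 5
        assert (cohort.measures["group"] == "control").sum() == 3
        assert list(cohort.measures.columns[2:]) == list(ALL_MEASURES)

    def test_trial_outcomes_consistent_with_design(self):
        cfg = SimulationConfig(n_patients=2, n_controls=1)
        cohort = simulate_cohort(cfg, seed=4)
        for sid in cohort.subject_ids:
            for task in ("AS", "GnG"):
                assert len(cohort.designs[sid][task]) == 80
                assert len(cohort.outcomes[sid][task]) == 80
                for tr, out in zip(cohort.designs[sid][task], cohort.outcomes[sid][task]):
                    label = expected_classification(tr, out)
                    assert label in ("correct", "error", "miss", "discarded")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_patients=0)
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1)
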
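"""Synthetic-claims generator: determinism, ground-truth consistency, noise."""

import numpy as np
import pandas as pd
import pytest

from gpp_journey.catalog import load_catalog
from gpp_journey.cohort import build_cohort
from gpp_journey.config import StudyConfig
from gpp_journey.pipeline import run_pipeline
from gpp_journey.survival import km_fit, km_median_ci, ttnt_samples
from gpp_journey.synth import (
    DurationDist,
    GroundTruth,
    NoiseConfig,
    PathwayState,
    ScenarioConfig,
    generate_cohort,
    inject_noise,
    lot_recovery,
    preset_scenarios,
    simulate_to_dir,
)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        simulate_to_dir("simple_switching", seed=5, out_dir=a, n_patients=40)
        simulate_to_dir("simple_switching", seed=5, out_dir=b, n_patients=40)
        for name in ("patients.csv", "diagnoses.csv", "prescriptions.csv",
                     "groundtruth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_to_dir("simple_switching", seed=5, out_dir=a, n_patients=40)
        simulate_to_dir("simple_switching", seed=6, out_dir=b, n_patients=40)
        assert (a / "prescriptions.csv").read_bytes() != (b / "prescriptions.csv").read_bytes()


class TestPresets:
    def test_unknown_preset_lists_names(self):
        with pytest.raises(ValueError, match="simple_switching"):
            preset_scenarios("banana")

    def test_edge_cases_includes_documented_specials(self):
        config = preset_scenarios("edge_cases", n_patients=20, seed=0)
        bundle, truth = generate_cohort(config)
        assert "edge_single_dx" in truth.patients
        assert not truth.patients["edge_single_dx"].included
        assert truth.patients["edge_early_death"].included

    def test_ground_truth_round_trips_through_json(self, tmp_path):
        _, truth = generate_cohort(preset_scenarios("combinations", 15, seed=2))
        truth.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.scenario == truth.scenario
        assert set(back.patients) == set(truth.patients)
        pid = sorted(truth.patients)[0]
        assert back.patients[pid] == truth.patients[pid]


class TestRecovery:
    @pytest.mark.parametrize("preset", ["simple_switching", "combinations", "bio_switch"])
    def test_derived_lots_equal_ground_truth(self, preset):
        bundle, truth = generate_cohort(preset_scenarios(preset, n_patients=80, seed=11))
        results = run_pipeline(bundle)
        report = lot_recovery(results.lots, truth)
        assert report["fraction_matched"] == 1.0, report["mismatches"][:3]

    def test_derived_episodes_equal_ground_truth(self):
        bundle, truth = generate_cohort(preset_scenarios("combinations", 60, seed=4))
        results = run_pipeline(bundle)
        eps = results.episodes
        for pid, pt in truth.patients.items():
            if not pt.included:
                continue
            for drug, want in pt.episodes.items():
                got = eps[(eps["patient_id"] == pid) & (eps["drug_code"] == drug)]
                pairs = [(s.date().isoformat(), e.date().isoformat())
                         for s, e in zip(got["start"], got["end"])]
                assert pairs == [tuple(iv) for iv in want], (pid, drug)

    def test_eligibility_decisions_match_truth(self):
        bundle, truth = generate_cohort(preset_scenarios("edge_cases", 30, seed=9))
        cohort = build_cohort(bundle).set_index("patient_id")
        for pid, pt in truth.patients.items():
            assert bool(cohort.loc[pid, "included"]) == pt.included, pid
            assert cohort.loc[pid, "reason"] == pt.reason, pid

    def test_ttnt_median_recovers_configured_exponential(self):
        """A two-state pathway whose first line lasts Exp(median 6 months):
        the KM median of derived first-line TTNT lands within 5%."""
        states = {
            "first": PathwayState(
                drugs=["etretinate"],
                duration=DurationDist(dist="exponential", median_months=6.0),
                next={"second": 1.0}),
            "second": PathwayState(
                drugs=["cyclosporin"],
                duration=DurationDist(dist="fixed", median_months=3.0)),
        }
        config = ScenarioConfig(
            name="exp_check", n_patients=2000, seed=17,
            states=states, initial={"first": 1.0},
            min_line_days=1, max_line_days=100_000,
            annual_death_rate=0.0, index_margin_days=1400,
        )
        bundle, truth = generate_cohort(config)
        results = run_pipeline(bundle)
        samples = ttnt_samples(results.lots)
        first = samples[(samples["lot_number"] == 1) & samples["event"]]
        median, _ = km_median_ci(km_fit(first["duration_days"], np.ones(len(first), bool)))
        true_median = truth.state_median_days["first"]
        assert abs(median - true_median) / true_median < 0.05


class TestGrammarValidation:
    def test_identical_adjacent_category_sets_rejected(self):
        states = {
            "a": PathwayState(drugs=["guselkumab"],
                              duration=DurationDist(median_months=6.0),
                              next={"b": 1.0}),
            "b": PathwayState(drugs=["risankizumab"],  # same IL-23 category
                              duration=DurationDist(median_months=6.0)),
        }
        config = ScenarioConfig(states=states, initial={"a": 1.0}, n_patients=5)
        with pytest.raises(ValueError, match="undetectable"):
            generate_cohort(config)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            PathwayState(drugs=["etretinate"],
                         duration=DurationDist(median_months=6.0),
                         next={"x": 0.7, "y": 0.6})

    def test_bad_distribution_rejected(self):
        with pytest.raises(ValueError):
            DurationDist(dist="exponential", median_months=-1)
        with pytest.raises(ValueError):
            DurationDist(dist="weibull", shape=0.0, scale_months=5.0)


class TestNoise:
    def setup_bundle(self):
        return generate_cohort(preset_scenarios("simple_switching", 40, seed=21))

    def test_empty_noise_is_identity(self):
        bundle, truth = self.setup_bundle()
        noisy, truth2 = inject_noise(bundle, truth, NoiseConfig(), seed=1)
        pd.testing.assert_frame_equal(noisy.prescriptions, bundle.prescriptions)
        assert truth2.lot_truth_valid

    def test_subthreshold_jitter_preserves_episode_counts(self):
        bundle, truth = self.setup_bundle()
        noisy, truth2 = inject_noise(bundle, truth, NoiseConfig(jitter_days=10), seed=1)
        cat = load_catalog()
        cfg = StudyConfig(study_window=bundle.study_window)
        from gpp_journey.episodes import build_episodes
        before = build_episodes(bundle.prescriptions, cat, cfg)
        after = build_episodes(noisy.prescriptions, cat, cfg)
        count = lambda df: df.groupby(["patient_id", "drug_code"])["episode_index"].max()
        pd.testing.assert_series_equal(count(before), count(after))

    def test_suprathreshold_gap_splits_episode(self):
        bundle, truth = self.setup_bundle()
        noisy, truth2 = inject_noise(bundle, truth, NoiseConfig(n_gaps=1, gap_days=75),
                                     seed=3)
        results = run_pipeline(noisy)
        # updated ground truth still matches the derived episodes …
        eps = results.episodes
        n_extra = 0
        for pid, pt in truth2.patients.items():
            if not pt.included:
                continue
            for drug, want in pt.episodes.items():
                got = eps[(eps["patient_id"] == pid) & (eps["drug_code"] == drug)]
                pairs = [(s.date().isoformat(), e.date().isoformat())
                         for s, e in zip(got["start"], got["end"])]
                assert pairs == [tuple(iv) for iv in want], (pid, drug)
                n_extra += len(want) - len(truth.patients[pid].episodes[drug])
        # … and exactly one patient-drug gained an episode
        assert n_extra == 1
        assert not truth2.lot_truth_valid

    def test_threshold_crossing_jitter_rejected(self):
        bundle, truth = self.setup_bundle()
        with pytest.raises(ValueError, match="crosses"):
            inject_noise(bundle, truth, NoiseConfig(jitter_days=61), seed=1)

    def test_subthreshold_gap_request_rejected(self):
        bundle, truth = self.setup_bundle()
        with pytest.raises(ValueError, match="sub-threshold"):
            inject_noise(bundle, truth, NoiseConfig(n_gaps=1, gap_days=30), seed=1)
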
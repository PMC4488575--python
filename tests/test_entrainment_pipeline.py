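"""The inference chain: omnibus pooling, re-pairing null, per-trial
detection, vector-length comparison, tempo mismatch, and the full run."""

import numpy as np
import pytest

from tapentrain import (BonferroniPlan, StudyConfig, TapTrial,
                        condition_omnibus, generate_stimulus_track,
                        planted_entrainment_study, repaired_null, run_study,
                        simulate_study, tempo_mismatch,
                        trialwise_entrainment, vector_length_comparison)
from tapentrain.entrainment_pipeline import PRINTED_CRITERIA, PipelineError
from tapentrain.synthetic_data import TapperParams, simulate_trial


class TestBonferroniPlan:
    def test_criterion_from_count(self):
        assert BonferroniPlan("f", n_comparisons=20).criterion == \
            pytest.approx(0.0025)

    def test_explicit_criterion_override(self):
        plan = BonferroniPlan("f", criterion_override=0.000794)
        assert plan.criterion == 0.000794

    def test_published_criteria_are_below_alpha(self):
        assert all(c < 0.05 for c in PRINTED_CRITERIA.values())


class TestConditionOmnibus:
    def test_identical_phases_maximally_significant(self):
        track = generate_stimulus_track("ISI400", 40)
        trials = [TapTrial(trial_id=f"t{i}", role="test",
                           onsets_ms=tuple(70.0 + 400.0 * k
                                           for k in range(30)))
                  for i in range(18)]
        from tapentrain import StudyDataset
        dataset = StudyDataset(participant_id="p")
        dataset.sessions["ISI400"] = [(t, track) for t in trials]
        plan = BonferroniPlan("omnibus", criterion_override=0.000794)
        rep = condition_omnibus(dataset, "ISI400", plan)
        assert rep.n_pooled == 540
        assert rep.pooled.statistic == 0
        assert rep.pooled.significant
        assert rep.pooled.summary.resultant_length == pytest.approx(1.0)
        assert rep.pooled.summary.mean_direction_deg == pytest.approx(63.0)

    def test_no_stim_without_reference_track_rejected(self):
        dataset = simulate_study("human_like", seed=61,
                                 conditions=["NO_STIM"])
        with pytest.raises(PipelineError):
            condition_omnibus(dataset, "NO_STIM",
                              BonferroniPlan("omnibus"))

    def test_min_taps_threshold_skips_short_trials(self, tiny_dataset):
        plan = BonferroniPlan("omnibus", n_comparisons=1)
        with pytest.raises(PipelineError):
            condition_omnibus(tiny_dataset, "ISI400", plan, min_taps=30)
        rep = condition_omnibus(tiny_dataset, "ISI400", plan, min_taps=3)
        assert rep.n_trials == 3 and rep.n_pooled == 9


class TestRepairedNull:
    def _pool(self, n=30, seed=71):
        rng = np.random.default_rng(seed)
        params = TapperParams(base_period_ms=430.0, period_noise_sd_ms=140.0,
                              drift_sd_ms=27.0)
        return [simulate_trial(params, rng=rng, role="training",
                               trial_id=f"tr{i}") for i in range(n)]

    def test_observed_p_of_one_gives_proportion_one(self):
        track = generate_stimulus_track("ISI400", 80)
        res = repaired_null(self._pool(), track, observed_p=1.0,
                            n_iter=50, seed=1)
        assert res.proportion_extreme == 1.0

    def test_tiny_observed_p_gives_proportion_near_zero(self):
        track = generate_stimulus_track("ISI400", 80)
        res = repaired_null(self._pool(), track, observed_p=1e-12,
                            n_iter=50, seed=2)
        assert res.proportion_extreme <= 0.05

    def test_pool_too_small_rejected(self):
        track = generate_stimulus_track("ISI400", 80)
        with pytest.raises(ValueError, match="training pool"):
            repaired_null(self._pool(n=10), track, observed_p=0.5,
                          n_iter=10, n_select=18)

    def test_reproducible_under_seed(self):
        track = generate_stimulus_track("ISI400", 80)
        pool = self._pool()
        a = repaired_null(pool, track, 0.3, n_iter=100, seed=5)
        b = repaired_null(pool, track, 0.3, n_iter=100, seed=5)
        assert a.proportion_extreme == b.proportion_extreme


class TestTrialwiseEntrainment:
    def test_planted_trials_recovered(self):
        ps = planted_entrainment_study(6, coupling_gain=0.7, seed=81)
        track = ps.dataset.track_for("ISI400")
        plan = BonferroniPlan("trialwise",
                              criterion_override=PRINTED_CRITERIA[
                                  "exp1_trialwise"])
        res = trialwise_entrainment(ps.dataset.test_trials("ISI400"),
                                    track, plan)
        assert abs(res.n_significant - 6) <= 2

    def test_single_locked_trial_detected(self):
        track = generate_stimulus_track("ISI400", 40)
        locked = TapTrial(trial_id="t", role="test",
                          onsets_ms=tuple(50.0 + 400.0 * k
                                          for k in range(30)))
        plan = BonferroniPlan("trialwise", criterion_override=0.000278)
        res = trialwise_entrainment([locked], track, plan)
        assert res.n_significant == 1


class TestVectorLengthComparison:
    def test_identical_pairs_give_zero_t(self):
        res = vector_length_comparison([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert res.t == 0.0

    def test_df_is_pairs_minus_one(self):
        res = vector_length_comparison([0.5, 0.6, 0.4, 0.7],
                                       [0.2, 0.3, 0.25, 0.4])
        assert res.df == 3 and res.t > 0


class TestTempoMismatch:
    @pytest.mark.parametrize("median, isi, expected", [
        (449.5, 400.0, 11.0), (400.0, 400.0, 0.0), (355.5, 600.0, 68.8),
    ])
    def test_worked_examples(self, median, isi, expected):
        assert tempo_mismatch(median, isi) == pytest.approx(expected,
                                                            abs=0.05)

    def test_classification_against_20_percent_rule(self):
        assert tempo_mismatch(355.5, 600.0) >= 20.0
        assert tempo_mismatch(449.5, 400.0) < 20.0


class TestRunStudy:
    def test_empty_dataset_yields_empty_report(self):
        from tapentrain import StudyDataset
        report = run_study(StudyDataset(participant_id="p"))
        assert report.conditions == {} and report.tempo is None

    def test_deterministic_under_config_seed(self):
        dataset = simulate_study("chimp_like", seed=91,
                                 conditions=["NO_STIM", "ISI400"])
        cfg = StudyConfig(seed=7, n_iter=50, monte_carlo="all")
        a = run_study(dataset, cfg).to_dict()
        b = run_study(dataset, cfg).to_dict()
        assert a == b

    def test_familywise_control_under_no_coupling(self):
        flagged = 0
        for seed in range(40):
            dataset = simulate_study("chimp_like", seed=1000 + seed,
                                     conditions=["ISI400"])
            cfg = StudyConfig(seed=seed, monte_carlo="none")
            rep = run_study(dataset, cfg)
            flagged += bool(rep.conditions["ISI400"].pooled.significant)
        assert flagged / 40 <= 0.05

    def test_coupled_study_detected_and_confirmed(self):
        ps = planted_entrainment_study(18, coupling_gain=0.5, seed=93)
        cfg = StudyConfig(seed=8, n_iter=200, monte_carlo="significant")
        rep = run_study(ps.dataset, cfg)
        cond = rep.conditions["ISI400"]
        assert cond.pooled.significant
        assert cond.monte_carlo is not None
        assert cond.monte_carlo.proportion_extreme < 0.05
        assert cond.tempo_mismatch_percent is not None

    def test_report_serialises_to_json(self, tmp_path):
        dataset = simulate_study("human_like", seed=95,
                                 conditions=["NO_STIM", "ISI500"])
        rep = run_study(dataset, StudyConfig(seed=9, monte_carlo="none"))
        text = rep.to_json(tmp_path / "report.json")
        import json
        payload = json.loads(text)
        assert "ISI500" in payload["conditions"]
        assert payload["conditions"]["ISI500"]["pooled"]["n"] == 540
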
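import numpy as np
import pingouin as pg
import pytest

from gazeplan.behavior import (
    DegenerateDataError,
    FilterReport,
    SchemaError,
    TrialRecord,
    cluster_strategies,
    filter_trials,
    hotelling_t2,
    load_fixation_table,
    summarize_subjects,
    write_fixation_table,
)

import oracles


def make_trial(subject="sub01", block=1, trial=1, shape="S1", condition="short",
               mirrored=0, present=0, found=0, entered=1, fixations=((0.0, 0.0),)):
    fix = np.array([[x, y, 130.0 + 250 * k, 200.0]
                    for k, (x, y) in enumerate(fixations)])
    return TrialRecord(subject_id=subject, block=block, trial=trial,
                       shape_id=shape, condition=condition, mirrored=mirrored,
                       target_present=present, target_found=found,
                       entered_shape=entered, fixations=fix)


class TestLoadTable:
    def test_round_trip(self, tmp_path):
        trials = [
            make_trial(trial=1, condition="short", fixations=((1.25, -0.5),)),
            make_trial(trial=2, condition="long",
                       fixations=((2.0, 0.125), (-3.75, 4.0))),
        ]
        path = tmp_path / "fix.csv"
        write_fixation_table(trials, path)
        back = load_fixation_table(path)
        assert len(back) == 2
        for a, b in zip(trials, back):
            assert a.subject_id == b.subject_id and a.condition == b.condition
            assert np.array_equal(a.fixations, b.fixations)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,block\ns1,1\n")
        with pytest.raises(SchemaError, match="missing"):
            load_fixation_table(path)

    def test_unknown_condition_names_row(self, tmp_path):
        trials = [make_trial()]
        path = tmp_path / "fix.csv"
        write_fixation_table(trials, path)
        text = path.read_text().replace("short", "medium")
        path.write_text(text)
        with pytest.raises(SchemaError, match="row 0"):
            load_fixation_table(path)


class TestFilterTrials:
    def test_planted_violations_counted_exactly(self):
        trials = []
        k = 0
        for _ in range(70):
            k += 1
            trials.append(make_trial(trial=k, condition="short"))
        for _ in range(10):  # never entered the shape
            k += 1
            trials.append(make_trial(trial=k, entered=0))
        for _ in range(10):  # wrong fixation count for a short trial
            k += 1
            trials.append(make_trial(trial=k, condition="short",
                                     fixations=((0, 0), (1, 1))))
        for _ in range(10):  # target present
            k += 1
            trials.append(make_trial(trial=k, present=1))
        kept, rep = filter_trials(trials)
        assert rep.n_input == 100
        assert rep.n_no_shape_gaze == 10
        assert rep.n_wrong_fixation_count == 10
        assert rep.n_target_present == 10
        assert rep.n_final == len(kept) == 70
        assert rep.telescopes()

    def test_empty_input(self):
        kept, rep = filter_trials([])
        assert kept == [] and rep.n_input == 0 and rep.telescopes()

    def test_clean_input_untouched(self):
        trials = [make_trial(trial=i) for i in range(20)]
        kept, rep = filter_trials(trials)
        assert rep.n_final == rep.n_input == 20

    def test_stage_percentages_follow_reported_denominators(self):
        rep = FilterReport(n_input=6400, n_no_shape_gaze=15,
                           n_wrong_fixation_count=1097, n_target_present=2699,
                           n_strategy_discarded=276, n_final=2313)
        assert rep.pct_no_shape_gaze == pytest.approx(100 * 15 / 6400)
        assert rep.pct_wrong_fixation_count == pytest.approx(100 * 1097 / 6385)
        assert rep.telescopes()


class TestClusterStrategies:
    def test_two_separated_clusters_keep_majority(self):
        rng = np.random.default_rng(0)
        a = rng.normal((0, 0), 0.5, size=(350, 2))
        b = rng.normal((10, 0), 0.5, size=(150, 2))
        pts = np.vstack([a, b])
        res = cluster_strategies(pts, seed=0)
        assert res.kept_fraction == pytest.approx(0.7, abs=0.05)
        assert res.n_components == 2

    def test_single_cluster_keeps_everything(self):
        rng = np.random.default_rng(1)
        pts = rng.normal((3, -2), 0.4, size=(200, 2))
        res = cluster_strategies(pts, seed=0)
        assert res.n_components == 1
        assert res.kept_fraction == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal((0, 0), 1, (60, 2)),
                         rng.normal((8, 8), 1, (40, 2))])
        r1 = cluster_strategies(pts, seed=5)
        r2 = cluster_strategies(pts, seed=5)
        assert np.array_equal(r1.assignments, r2.assignments)


class TestSummaries:
    def test_simple_mean(self):
        trials = [
            make_trial(trial=1, fixations=((1.0, 1.0),)),
            make_trial(trial=2, fixations=((3.0, 3.0),)),
        ]
        s = summarize_subjects(trials)
        slot = ("S1", "short", 1)
        assert np.allclose(s.observations(slot), [[2.0, 2.0]])

    def test_mirrored_trials_reflected_to_canonical(self):
        trials = [
            make_trial(trial=1, mirrored=0, fixations=((4.0, 1.0),)),
            make_trial(trial=2, mirrored=1, fixations=((-4.0, 1.0),)),
        ]
        s = summarize_subjects(trials)
        assert np.allclose(s.observations(("S1", "short", 1)), [[4.0, 1.0]])

    def test_mirroring_whole_dataset_leaves_canonical_means(self):
        rng = np.random.default_rng(0)
        trials = []
        for i in range(40):
            x, y = rng.normal((5, -2), 1.0)
            trials.append(make_trial(subject=f"s{i%4}", trial=i,
                                     mirrored=i % 2,
                                     fixations=(((-x if i % 2 else x), y),)))
        s = summarize_subjects(trials)
        flipped = [TrialRecord(t.subject_id, t.block, t.trial, t.shape_id,
                               t.condition, 1 - t.mirrored, t.target_present,
                               t.target_found, t.entered_shape,
                               t.fixations * np.array([-1.0, 1.0, 1.0, 1.0]))
                   for t in trials]
        s2 = summarize_subjects(flipped)
        slot = ("S1", "short", 1)
        assert np.allclose(s.observations(slot), s2.observations(slot))

    def test_recovers_known_means_within_3se(self):
        rng = np.random.default_rng(7)
        mu = np.array([3.0, -1.0])
        sd = 1.0
        n_per = 25
        trials = []
        k = 0
        for subj in range(8):
            for _ in range(n_per):
                k += 1
                x, y = rng.normal(mu, sd)
                trials.append(make_trial(subject=f"s{subj}", trial=k,
                                         fixations=((x, y),)))
        s = summarize_subjects(trials)
        grand = s.observations(("S1", "short", 1)).mean(axis=0)
        se = sd / np.sqrt(8 * n_per)
        assert np.all(np.abs(grand - mu) < 3 * se * np.sqrt(8))


class TestHotelling:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((10, 2))
        r = hotelling_t2(a, a.copy())
        assert r.t2 == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_matrix_formula_oracle(self):
        a = np.array([[1.0, 2.0], [2.0, 4.5], [0.5, 1.0], [1.5, 2.5]])
        b = np.array([[3.0, 1.0], [4.0, 2.0], [2.5, 0.5], [3.5, 1.5]])
        r = hotelling_t2(a, b)
        assert r.t2 == pytest.approx(oracles.hotelling_two_sample(a, b), abs=1e-10)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((12, 2))
        b = rng.standard_normal((9, 2)) + 0.8
        r = hotelling_t2(a, b)
        ref = pg.multivariate_ttest(a, b)
        assert r.t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
        assert r.f_stat == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert r.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)
        assert r.df == (int(ref["df1"].iloc[0]), int(ref["df2"].iloc[0]))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((14, 2))
        b = rng.standard_normal((11, 2)) + (1.0, -0.5)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        r1 = hotelling_t2(a, b)
        r2 = hotelling_t2(a @ rot.T, b @ rot.T)
        assert r1.t2 == pytest.approx(r2.t2, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            hotelling_t2([[0, 0], [1, 1]], [[0, 0], [1, 1], [2, 2]])
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(DegenerateDataError):
            hotelling_t2(line, line + 1)
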
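"""SVM classification, video-exclusive folds, majority-vote consensus."""

import numpy as np
import pandas as pd
import pytest

from trajstyle.classify import (
    ConsensusReport,
    MotilityStyleClassifier,
    balanced_accuracy,
    evaluate_pipeline,
    majority_vote,
    make_video_folds,
    train_and_predict,
)

POS, NEG = "treated", "untreated"


def toy_manifest(n_videos_per_class=2, n_groups=2, n_tracks=8):
    rows = []
    for lab in (POS, NEG):
        for v in range(n_videos_per_class):
            vid = f"{lab}-{v}"
            for g in range(n_groups):
                for t in range(n_tracks):
                    rows.append((vid, g, len(rows), lab))
    return pd.DataFrame(rows, columns=["video_id", "group_id", "track_id", "label"])


def separable_features(manifest, rng, spread=0.1):
    mu = {POS: 1.0, NEG: -1.0}
    base = np.array([mu[l] for l in manifest.label])[:, None]
    return base + rng.normal(0, spread, (len(manifest), 10))


class TestFolds:
    def test_four_videos_two_per_class(self):
        m = toy_manifest(2)
        folds = make_video_folds(m)
        for f in (0, 1):
            vids = folds.videos(f)
            assert len(vids) == 2
            labs = {m[m.video_id == v].label.iloc[0] for v in vids}
            assert labs == {POS, NEG}

    def test_no_video_in_both_folds(self):
        folds = make_video_folds(toy_manifest(3))
        assert not set(folds.videos(0)) & set(folds.videos(1))

    def test_experiment_wise_split(self):
        m = toy_manifest(6)
        exp = {v: (1 if int(v[-1]) < 3 else 2) for v in m.video_id.unique()}
        folds = make_video_folds(m, experiment_ids=exp)
        assert set(folds.videos(0)) == {v for v, e in exp.items() if e == 1}
        assert set(folds.videos(1)) == {v for v, e in exp.items() if e == 2}

    def test_impossible_stratification_raises(self):
        m = toy_manifest(1)  # one video per class: each fold would be one-class
        with pytest.raises(ValueError):
            make_video_folds(m)


class TestTrainAndPredict:
    def test_separable_features_perfect_both_turns(self, rng):
        m = toy_manifest()
        F = separable_features(m, rng)
        preds = train_and_predict(F, m.label.to_numpy(), m.video_id.to_numpy(),
                                  make_video_folds(m))
        assert (preds.pred.to_numpy() == m.label.to_numpy()).all()
        assert set(preds.turn) == {0, 1}

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(99)
        m = toy_manifest(4, 2, 10)
        F = rng.normal(0, 1, (len(m), 20))  # features carry no label signal
        preds = train_and_predict(F, m.label.to_numpy(), m.video_id.to_numpy(),
                                  make_video_folds(m))
        acc = balanced_accuracy(m.label, preds.pred)
        # binomial-ish bounds around 50% for n=320 rows
        assert 35.0 < acc < 65.0

    def test_single_class_training_fold_raises(self, rng):
        X = rng.normal(0, 1, (10, 4))
        with pytest.raises(ValueError, match="single class"):
            MotilityStyleClassifier().fit(X, np.array([POS] * 10))

    def test_margin_sign_positive_for_treated_side(self, rng):
        m = toy_manifest()
        F = separable_features(m, rng)
        preds = train_and_predict(F, m.label.to_numpy(), m.video_id.to_numpy(),
                                  make_video_folds(m))
        pos_margins = preds.margin[(m.label == POS).to_numpy()]
        assert (pos_margins > 0).all()


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote([POS, POS, NEG]) == POS
        assert majority_vote([NEG, NEG, NEG, POS]) == NEG

    def test_tie_broken_by_summed_margin(self):
        assert majority_vote([POS, NEG], [0.2, -0.9]) == NEG
        assert majority_vote([POS, NEG], [0.9, -0.2]) == POS

    def test_zero_sum_tie_defaults_negative_with_warning(self):
        with pytest.warns(UserWarning):
            assert majority_vote([POS, NEG], [0.5, -0.5]) == NEG

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_unanimous_group_keeps_label(self):
        assert majority_vote([POS] * 7) == POS

    def test_vote_improves_over_members_when_above_chance(self):
        # independent per-member errors at p=0.7 correct: the group majority is
        # more often right than a single member (tested over 20 seeds)
        improvements = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            member_acc = []
            group_acc = []
            for _ in range(50):
                truth = POS
                correct = rng.random(11) < 0.7
                labels = [POS if c else NEG for c in correct]
                member_acc.append(correct.mean())
                group_acc.append(majority_vote(labels) == truth)
            improvements.append(np.mean(group_acc) - np.mean(member_acc))
        assert np.mean(improvements) > 0
        assert np.mean([i > 0 for i in improvements]) >= 0.8


class TestBalancedAccuracy:
    def test_perfect(self):
        assert balanced_accuracy([POS, NEG], [POS, NEG]) == 100.0

    def test_all_positive_on_imbalanced_mix(self):
        t = [POS] * 7 + [NEG] * 3
        assert balanced_accuracy(t, [POS] * 10) == 50.0

    def test_hand_counted_confusion(self):
        t = [POS] * 10 + [NEG] * 10
        p = [POS] * 8 + [NEG] * 2 + [POS] * 7 + [NEG] * 3
        assert balanced_accuracy(t, p) == pytest.approx(55.0)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import balanced_accuracy_score

        t = rng.choice([POS, NEG], 50)
        p = rng.choice([POS, NEG], 50)
        if len(set(t)) == 2:
            assert balanced_accuracy(t, p) == pytest.approx(
                100 * balanced_accuracy_score(t, p)
            )

    def test_one_class_truth_raises(self):
        with pytest.raises(ValueError):
            balanced_accuracy([POS, POS], [POS, NEG])

    def test_invariant_to_row_permutation(self, rng):
        t = np.array([POS] * 12 + [NEG] * 8)
        p = rng.choice([POS, NEG], 20)
        perm = rng.permutation(20)
        assert balanced_accuracy(t, p) == balanced_accuracy(t[perm], p[perm])


class TestEvaluatePipeline:
    def test_separable_design_perfect_at_all_levels(self, rng):
        m = toy_manifest()
        F = separable_features(m, rng)
        rep = evaluate_pipeline(m, F)
        assert rep.averages == {
            "track_acc": 100.0, "group_acc": 100.0, "video_acc": 100.0
        }

    def test_report_roundtrip(self, rng, tmp_path):
        m = toy_manifest()
        rep = evaluate_pipeline(m, separable_features(m, rng))
        rep.to_json(tmp_path / "r.json")
        back = ConsensusReport.from_json(tmp_path / "r.json")
        assert back.averages == rep.averages and back.folds == rep.folds

    def test_consensus_ordering_on_noisy_design(self):
        # calibrated overlap: per-track accuracy above chance but far from 1;
        # majority voting should not hurt at group level, and video level should
        # dominate, in >= 80% of 20 seeds
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            m = toy_manifest(2, 4, 15)
            F = separable_features(m, rng, spread=2.5)
            rep = evaluate_pipeline(m, F)
            a = rep.averages
            if a["group_acc"] >= a["track_acc"] and a["video_acc"] >= a["group_acc"]:
                ok += 1
        assert ok >= 16


class TestLeakageGuard:
    def test_selection_mask_depends_only_on_training_rows(self, rng):
        m = toy_manifest()
        F = separable_features(m, rng).astype(np.float64)
        folds = make_video_folds(m)
        _, models = train_and_predict(
            F, m.label.to_numpy(), m.video_id.to_numpy(), folds, return_models=True
        )
        F_noised = F.copy()
        row_fold = folds.row_folds(m.video_id.to_numpy())
        for turn in (0, 1):
            F_noised[row_fold == turn] = rng.normal(0, 100, F[row_fold == turn].shape)
        # noise test rows of turn 0 while keeping its training rows: masks identical
        for turn, model in enumerate(models):
            F_mod = F.copy()
            F_mod[row_fold == turn] = F_noised[row_fold == turn]
            _, models2 = train_and_predict(
                F_mod, m.label.to_numpy(), m.video_id.to_numpy(), folds,
                return_models=True,
            )
            np.testing.assert_array_equal(
                model.selector_.retained_mask_, models2[turn].selector_.retained_mask_
            )
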
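"""Splitting, SVM training, replicate merging and threshold calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from organsort.classify import (
    PRPoint, SvmConfig, UNCLASSIFIED, aggregate_neighborhood, apply_thresholds,
    calibrate_class_threshold, calibrate_thresholds, merge_replicates,
    reconcile_levels, split_markers, train_predict, unique_argmax,
)
from organsort.quantio import ProfileMatrix


def brute_force_calibration(scores, is_argmax, is_true, floor):
    """Independent quadratic-time search over every candidate threshold."""
    candidates = sorted(set(list(scores) + [0.0, 1.0]))
    best_floor, best_f1 = None, None
    for t in candidates:
        tp = fp = fn = 0
        for s, am, tr in zip(scores, is_argmax, is_true):
            pred = am and s >= t
            if pred and tr:
                tp += 1
            elif pred and not tr:
                fp += 1
            elif not pred and tr:
                fn += 1
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if tp + fp > 0 and prec >= floor:
            key = (rec, prec, -t)
            if best_floor is None or key > best_floor[0]:
                best_floor = (key, t, prec, rec)
        key = (f1, prec, -t)
        if best_f1 is None or key > best_f1[0]:
            best_f1 = (key, t, prec, rec)
    if best_floor is not None:
        return best_floor[1], "precision-floor", best_floor[2], best_floor[3]
    if best_f1[0][0] == 0.0:  # no threshold yields a true positive
        return float("nan"), "closed", best_f1[2], best_f1[3]
    return best_f1[1], "F1-max", best_f1[2], best_f1[3]


class TestSplit:
    def test_two_thirds_split_counts(self):
        labels = pd.Series(
            np.repeat([1, 2, 3], 30), index=[f"P{i}" for i in range(90)]
        )
        train, test = split_markers(labels, SvmConfig(seed=0))
        assert len(train) == 60 and len(test) == 30
        for c in (1, 2, 3):
            assert (labels.loc[train] == c).sum() == 20
            assert (labels.loc[test] == c).sum() == 10

    def test_seeded_and_partition(self):
        labels = pd.Series(
            np.repeat([1, 2, 3], 30), index=[f"P{i}" for i in range(90)]
        )
        t1 = split_markers(labels, SvmConfig(seed=3))
        t2 = split_markers(labels, SvmConfig(seed=3))
        assert list(t1[0]) == list(t2[0]) and list(t1[1]) == list(t2[1])
        assert set(t1[0]).isdisjoint(t1[1])
        assert set(t1[0]) | set(t1[1]) == set(labels.index)

    def test_tiny_cluster_rejected(self):
        labels = pd.Series([1, 1, 1, 2, 2], index=list("abcde"))
        with pytest.raises(ValueError, match="fewer than 3"):
            split_markers(labels, SvmConfig())


def _separable_profiles(n_per=20, seed=0):
    """Two well-separated clusters, 3 replicates, 12 features."""
    rng = np.random.default_rng(seed)
    ids = [f"P{i}" for i in range(2 * n_per)]
    labels = pd.Series(np.repeat([1, 2], n_per), index=ids)
    centers = {1: np.r_[np.full(6, 0.15), np.full(6, 0.0167)],
               2: np.r_[np.full(6, 0.0167), np.full(6, 0.15)]}
    rows, idx = [], []
    for pid in ids:
        for rep in (1, 2, 3):
            v = np.abs(centers[labels[pid]] + rng.normal(0, 0.005, 12))
            rows.append(v / v.sum())
            idx.append((pid, rep))
    cols = pd.MultiIndex.from_tuples(
        [(o, c) for o in "ABCDEF" for c in ("x", "y")],
        names=["organelle", "condition"],
    )
    values = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(idx, names=["protein_id", "replicate"]),
        columns=cols,
    )
    flagged = pd.Series(False, index=values.index)
    return ProfileMatrix(values=values, flagged=flagged), labels


class TestTrainPredict:
    def test_separable_toy_is_perfectly_classified(self):
        profiles, labels = _separable_profiles()
        cfg = SvmConfig.preset("coarse", cv_folds=5, seed=0)
        train, test = split_markers(labels, cfg)
        per_rep = train_predict(profiles, labels.loc[train], cfg)
        assert set(per_rep) == {1, 2, 3}
        for rep, frame in per_rep.items():
            np.testing.assert_allclose(frame.sum(axis=1).to_numpy(), 1.0,
                                       atol=1e-6)
            assert frame.attrs["best_params"]["C"] in cfg.cost_grid
            assert frame.attrs["best_params"]["gamma"] in cfg.gamma_grid
            held_out = frame.loc[test].idxmax(axis=1)
            assert (held_out == labels.loc[test]).all()

    def test_single_class_rejected(self):
        profiles, labels = _separable_profiles()
        cfg = SvmConfig.preset("coarse", cv_folds=3, seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            train_predict(profiles, labels[labels == 1], cfg)


def _prob_frame(d, classes=("c1", "c2", "c3")):
    return pd.DataFrame(d, columns=list(classes))


class TestMerge:
    def test_two_of_three_agreement(self):
        reps = {}
        for i, top in enumerate(["c1", "c1", "c2"]):
            probs = {c: 0.1 for c in ("c1", "c2", "c3")}
            probs[top] = 0.8
            reps[i + 1] = pd.DataFrame([probs], index=["P1"])
        merged = merge_replicates(reps)
        assert merged.calls.loc["P1"] == "c1"
        assert merged.consistency.loc["P1"] == 2

    def test_all_disagree_is_unclassified(self):
        reps = {}
        for i, top in enumerate(["c1", "c2", "c3"]):
            probs = {c: 0.1 for c in ("c1", "c2", "c3")}
            probs[top] = 0.8
            reps[i + 1] = pd.DataFrame([probs], index=["P1"])
        merged = merge_replicates(reps)
        assert pd.isna(merged.calls.loc["P1"])

    def test_probability_averaging(self):
        reps = {
            1: pd.DataFrame([[0.6, 0.4]], index=["P1"], columns=["c1", "c2"]),
            2: pd.DataFrame([[0.8, 0.2]], index=["P1"], columns=["c1", "c2"]),
        }
        merged = merge_replicates(reps)
        np.testing.assert_allclose(
            merged.probabilities.loc["P1"].to_numpy(), [0.7, 0.3]
        )

    def test_fewer_than_two_replicates_unclassified(self):
        reps = {
            1: pd.DataFrame([[0.9, 0.1]], index=["P1"], columns=["c1", "c2"]),
            2: pd.DataFrame([[0.8, 0.2], [0.3, 0.7]], index=["P1", "P2"],
                            columns=["c1", "c2"]),
        }
        merged = merge_replicates(reps)
        assert pd.isna(merged.calls.loc["P2"])  # scored in one replicate only
        assert merged.calls.loc["P1"] == "c1"


class TestCalibration:
    def test_fixed_example_floor_attainable(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        is_true = np.array([True, True, False, True])
        is_argmax = np.ones(4, bool)
        t, mode, pt = calibrate_class_threshold(scores, is_argmax, is_true, 0.9)
        assert t == pytest.approx(0.8)
        assert mode == "precision-floor"
        assert pt.precision == pytest.approx(1.0)
        assert pt.recall == pytest.approx(2 / 3)

    def test_perfectly_separated_class(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        is_true = np.array([True, True, False, False])
        is_argmax = np.array([True, True, False, False])
        t, mode, pt = calibrate_class_threshold(scores, is_argmax, is_true, 0.9)
        assert mode == "precision-floor"
        assert pt.precision == 1.0 and pt.recall == 1.0
        assert t == pytest.approx(0.0)  # minimal candidate threshold

    def test_unattainable_floor_falls_back_to_f1(self):
        # top-scored predictions are false: no prefix reaches precision 0.9
        # (max attainable is 0.5), so calibration must switch to F1
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        is_true = np.array([False, True, False, True, False])
        is_argmax = np.ones(5, bool)
        t, mode, pt = calibrate_class_threshold(scores, is_argmax, is_true, 0.9)
        bt, bmode, bprec, brec = brute_force_calibration(
            scores, is_argmax, is_true, 0.9
        )
        assert mode == "F1-max" == bmode
        assert t == pytest.approx(bt)
        assert pt.precision == pytest.approx(bprec)

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for floor in (0.7, 0.9, 0.95):
            for _ in range(40):
                m = int(rng.integers(3, 25))
                scores = np.round(rng.random(m), 2)
                is_true = rng.random(m) < 0.4
                is_argmax = rng.random(m) < 0.8
                t, mode, pt = calibrate_class_threshold(
                    scores, is_argmax, is_true, floor
                )
                bt, bmode, bprec, brec = brute_force_calibration(
                    scores, is_argmax, is_true, floor
                )
                assert mode == bmode
                if np.isnan(bt):
                    assert np.isnan(t)
                else:
                    assert t == pytest.approx(bt)
                assert pt.precision == pytest.approx(bprec)
                assert pt.recall == pytest.approx(brec)

    def test_raising_floor_never_raises_recall(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            m = int(rng.integers(5, 30))
            scores = rng.random(m)
            is_true = rng.random(m) < 0.5
            is_argmax = np.ones(m, bool)
            recalls = []
            for floor in (0.5, 0.7, 0.9):
                _, mode, pt = calibrate_class_threshold(
                    scores, is_argmax, is_true, floor
                )
                if mode == "precision-floor":
                    recalls.append(pt.recall)
            assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_absent_class_gets_no_threshold(self):
        probs = pd.DataFrame(
            [[0.9, 0.1], [0.7, 0.3]], index=["P1", "P2"], columns=["c1", "c2"]
        )
        truth = pd.Series(["c1", "c1"], index=["P1", "P2"])
        table = calibrate_thresholds(probs, truth, "cluster", 0.9)
        c2 = table.set_index("class").loc["c2"]
        assert c2["mode"] == "absent" and np.isnan(c2["threshold"])
        calls = apply_thresholds(probs, table)
        assert (calls.dropna() != "c2").all()


class TestAggregateReconcile:
    def test_neighborhood_sum(self):
        probs = pd.DataFrame(
            [[0.3, 0.4, 0.3]], index=["P1"], columns=["c1", "c2", "c9"]
        )
        nb = aggregate_neighborhood(
            probs, {"c1": "secretory", "c2": "secretory", "c9": "nuclear"}
        )
        assert nb.loc["P1", "secretory"] == pytest.approx(0.7)
        assert nb.loc["P1", "nuclear"] == pytest.approx(0.3)

    def test_mass_conserved(self):
        rng = np.random.default_rng(4)
        raw = rng.random((20, 6))
        probs = pd.DataFrame(
            raw / raw.sum(axis=1, keepdims=True),
            index=[f"P{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(1, 7)],
        )
        nb_map = {f"c{i}": ("A" if i < 4 else "B") for i in range(1, 7)}
        nb = aggregate_neighborhood(probs, nb_map)
        np.testing.assert_allclose(nb.sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_single_cluster_neighborhood(self):
        probs = pd.DataFrame([[1.0]], index=["P1"], columns=["c18"])
        nb = aggregate_neighborhood(probs, {"c18": "ribosome"})
        assert nb.loc["P1", "ribosome"] == pytest.approx(1.0)

    def test_reconcile_rules(self):
        nb_map = {"c10": "nuclear", "c1": "secretory"}
        cluster_calls = pd.Series(
            {"keep": "c10", "drop": "c10", "mismatch": "c10", "rescue": pd.NA}
        )
        nb_calls = pd.Series(
            {"keep": "nuclear", "drop": pd.NA, "mismatch": "secretory",
             "rescue": "secretory"}
        )
        out = reconcile_levels(cluster_calls, nb_calls, nb_map)
        assert out.loc["keep", "cluster"] == "c10"
        assert out.loc["keep", "neighborhood"] == "nuclear"
        assert out.loc["drop", "cluster"] == UNCLASSIFIED
        assert out.loc["drop", "neighborhood"] == UNCLASSIFIED
        assert out.loc["mismatch", "cluster"] == UNCLASSIFIED
        assert out.loc["rescue", "neighborhood"] == "secretory"
        assert out.attrs["n_reconciled"] == 2
        # assignment invariant: any protein with both calls is consistent
        both = out[(out.cluster != UNCLASSIFIED) & (out.neighborhood != UNCLASSIFIED)]
        assert all(nb_map[c] == n for c, n in zip(both.cluster, both.neighborhood))

    def test_unique_argmax_tie_is_na(self):
        probs = pd.DataFrame([[0.5, 0.5], [0.6, 0.4]], index=["tie", "ok"],
                             columns=["c1", "c2"])
        am = unique_argmax(probs)
        assert pd.isna(am.loc["tie"]) and am.loc["ok"] == "c1"
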
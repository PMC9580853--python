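"""Sanitation, feature assembly, CV protocol, metrics and the ensemble."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rinsev import ml_framework as ml
from rinsev.ml_framework import (FeatureAssembler, MedianEnsemble,
                                 TunedClassifier, classify_scores,
                                 ensemble_search, evaluate,
                                 exclusion_tradeoff, normalize_features,
                                 run_protocol, sanitize_mutations, saturate,
                                 stratified_folds, validate_grid)


# ---------------------------------------------------------------------------
# Sanitation
# ---------------------------------------------------------------------------

def _raw_table():
    rows = [
        (30, "A", "V", "severe"),              # signal/propeptide region
        (200, "G", "R", "mild"),               # activation peptide 192-226
        (480, "L", "P", "severe"),             # beyond the mature protein
        (100, "C", "C", "mild"),               # synonymous
        (100, "X", "R", "mild"),               # non-standard residue
        (100, "C", "R", "mild/moderate"),      # ambiguous class string
        (110, "D", "N", "moderate/severe"),    # ambiguous class string
        (120, "E", "K", "presymptomatic"),     # unparseable severity
        (60, "F", "L", "mild"),                # keep -> mild_moderate
        (130, "G", "D", "Moderate"),           # keep -> mild_moderate
        (300, "H", "Y", "SEVERE"),             # keep -> severe
        (424, "F", "S", "severe"),             # keep -> severe
    ]
    return pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "severity"])


class TestSanitation:
    def test_twelve_row_table_survivors(self):
        clean, log = sanitize_mutations(_raw_table())
        assert list(clean["position"]) == [60, 130, 300, 424]
        assert list(clean["severity"]) == ["mild_moderate", "mild_moderate",
                                           "severe", "severe"]
        assert len(log) == 8

    def test_drop_reasons(self):
        _, log = sanitize_mutations(_raw_table())
        reasons = dict(zip(log["position"], log["reason"]))
        assert reasons[30] == "outside_activated_protein"
        assert reasons[200] == "activation_peptide"
        assert reasons[480] == "outside_activated_protein"
        assert reasons[110] == "ambiguous_severity"
        assert reasons[120] == "unparseable_severity"
        assert "synonymous" in set(log["reason"])
        assert "nonstandard_aa" in set(log["reason"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            sanitize_mutations(pd.DataFrame({"position": [1]}))


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_minmax_two_values(self):
        X = pd.DataFrame({"f": [2.0, 6.0]})
        Xn, mins, ranges = normalize_features(X)
        assert list(Xn["f"]) == [0.0, 1.0]

    def test_constant_column_zero(self):
        X = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
        Xn, _, _ = normalize_features(X)
        assert (Xn["f"] == 0.0).all()

    def test_applied_to_new_rows_clips(self):
        X = pd.DataFrame({"f": [0.0, 10.0]})
        _, mins, ranges = normalize_features(X)
        out = ml.apply_normalization(pd.DataFrame({"f": [-5.0, 5.0, 15.0]}),
                                     mins, ranges)
        assert list(out["f"]) == [0.0, 0.5, 1.0]


class TestAssembler:
    def test_missing_conservation_drops_row(self, globule_bundle, synthetic_aa_dist):
        pft = globule_bundle["position_features"].copy()
        pos0 = pft.index[2]
        pft.loc[pos0, "conservation"] = np.nan
        asm = FeatureAssembler(pft, synthetic_aa_dist)
        muts = pd.DataFrame({"position": [pos0, pft.index[3]],
                             "wt_aa": [pft.loc[pos0, "aa"], pft.loc[pft.index[3], "aa"]],
                             "mut_aa": ["W", "W"],
                             "severity": ["severe", "mild_moderate"]})
        X, y, log = asm.assemble(muts)
        assert len(X) == 1
        assert list(log["reason"]) == ["missing_feature_value"]

    def test_unknown_position_dropped(self, globule_bundle, synthetic_aa_dist):
        asm = FeatureAssembler(globule_bundle["position_features"], synthetic_aa_dist)
        muts = pd.DataFrame({"position": ["9999"], "wt_aa": ["A"],
                             "mut_aa": ["V"], "severity": ["severe"]})
        X, _, log = asm.assemble(muts)
        assert len(X) == 0 and list(log["reason"]) == ["position_not_in_structure"]

    def test_features_in_unit_interval(self, planted_dataset):
        X = planted_dataset["X"]
        assert float(X.min().min()) >= 0.0
        assert float(X.max().max()) <= 1.0
        assert not X.isna().any().any()


class TestStratifiedFolds:
    def test_balanced_folds_for_stated_class_sizes(self):
        y = np.array([0] * 213 + [1] * 180)
        folds = stratified_folds(y, k=10, seed=0)
        for f in range(10):
            n0 = int(((folds == f) & (y == 0)).sum())
            n1 = int(((folds == f) & (y == 1)).sum())
            assert n0 in (21, 22) and n1 == 18

    def test_tiny_exact_split(self):
        y = np.array([0, 1] * 10)
        folds = stratified_folds(y, k=10, seed=1)
        for f in range(10):
            assert ((folds == f) & (y == 0)).sum() == 1
            assert ((folds == f) & (y == 1)).sum() == 1

    def test_deterministic(self):
        y = np.array([0] * 30 + [1] * 30)
        assert (stratified_folds(y, 5, seed=9) == stratified_folds(y, 5, seed=9)).all()

    def test_class_smaller_than_k(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([0] * 30 + [1] * 5), k=10)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def kappa_oracle(tp, fn, fp, tn):
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n ** 2
    return (po - pe) / (1 - pe)


def mcc_oracle(tp, fn, fp, tn):
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def auc_oracle(probs, labels):
    """Rank statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _probs_from_confusion(tp, fn, fp, tn):
    labels = np.array([1] * (tp + fn) + [0] * (fp + tn))
    probs = np.array([0.9] * tp + [0.1] * fn + [0.9] * fp + [0.1] * tn)
    return probs, labels


class TestEvaluate:
    def test_worked_confusion_case(self):
        probs, labels = _probs_from_confusion(40, 10, 5, 45)
        m = evaluate(probs, labels)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["kappa"] == pytest.approx(0.70)
        assert m["mcc"] == pytest.approx(0.7035, abs=5e-4)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_oracles(self, seed):
        rng = np.random.default_rng(seed)
        tp, fn, fp, tn = rng.integers(1, 50, size=4)
        probs, labels = _probs_from_confusion(tp, fn, fp, tn)
        m = evaluate(probs, labels)
        assert m["kappa"] == pytest.approx(kappa_oracle(tp, fn, fp, tn), abs=1e-12)
        assert m["mcc"] == pytest.approx(mcc_oracle(tp, fn, fp, tn), abs=1e-12)
        assert m["auc"] == pytest.approx(auc_oracle(probs, labels), abs=1e-12)

    def test_perfect_and_uninformative_auc(self):
        labels = np.array([0, 0, 1, 1])
        assert evaluate(np.array([0.1, 0.2, 0.8, 0.9]), labels)["auc"] == 1.0
        assert evaluate(np.array([0.5] * 4, dtype=float), labels)["auc"] == 0.5

    def test_single_class_auc_missing(self):
        m = evaluate(np.array([0.2, 0.7]), np.array([1, 1]))
        assert np.isnan(m["auc"])


# ---------------------------------------------------------------------------
# Classifiers and protocol
# ---------------------------------------------------------------------------

def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 2))
    y = (X[:, 0] > 0.5).astype(int)
    X[:, 0] = np.where(y, X[:, 0] + 0.3, X[:, 0] - 0.3)  # widen the gap
    return pd.DataFrame(X, columns=["f1", "f2"]), pd.Series(y)


class TestTunedClassifier:
    @pytest.mark.parametrize("alg", ["DT", "SVM_radial"])
    def test_separable_data_perfect_training_accuracy(self, alg):
        X, y = _separable()
        clf = TunedClassifier(alg, inner_k=3, seed=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_grid_bounds_enforced(self):
        X, y = _separable()
        clf = TunedClassifier("RF", grid={"n_estimators": [2, 200]},
                              inner_k=2, seed=0)
        with pytest.raises(ValueError, match="n_estimators"):
            clf.fit(X, y)
        with pytest.raises(ValueError, match="max_depth"):
            validate_grid("XGB", {"max_depth": [30]})

    def test_single_class_rejected(self):
        X, _ = _separable()
        with pytest.raises(ValueError):
            TunedClassifier("DT").fit(X, np.zeros(len(X)))


class TestProtocol:
    def test_report_shape_and_oof_coverage(self):
        X, y = _separable(n=40, seed=3)
        rep = run_protocol(X, y, algorithms=("DT", "NB"), repetitions=2, k=2,
                           inner_k=2, base_seed=0)
        assert len(rep.metrics) == 2 * 2 * 2  # reps x folds x algorithms
        for r in (0, 1):
            oof = rep.oof[r]
            assert not oof.isna().any().any()
            assert list(oof.columns) == ["DT", "NB"]
            assert len(oof) == len(X)

    def test_deterministic_given_base_seed(self):
        X, y = _separable(n=50, seed=4)
        a = run_protocol(X, y, algorithms=("DT", "RF"), repetitions=1, k=2,
                         inner_k=2, base_seed=5)
        b = run_protocol(X, y, algorithms=("DT", "RF"), repetitions=1, k=2,
                         inner_k=2, base_seed=5)
        assert a.oof[0].equals(b.oof[0])
        assert a.metrics.drop(columns="best_params").equals(
            b.metrics.drop(columns="best_params"))


# ---------------------------------------------------------------------------
# Ensemble, severity score, exclusion zone
# ---------------------------------------------------------------------------

def ensemble_oracle(oof, y, threshold=0.5):
    """Independent exhaustive search (accuracy of the median)."""
    best, best_acc = None, -1.0
    cols = list(oof.columns)
    for size in range(1, len(cols) + 1):
        for subset in itertools.combinations(cols, size):
            med = np.median(oof[list(subset)].values, axis=1)
            acc = ((med >= threshold).astype(int) == y).mean()
            if acc > best_acc:
                best, best_acc = subset, acc
    return best, best_acc


class TestEnsembleSearch:
    def test_single_column_identity(self):
        oof = pd.DataFrame({"A": [0.9, 0.1, 0.8, 0.2]})
        y = np.array([1, 0, 1, 0])
        best, table = ensemble_search(oof, y)
        assert best == ("A",)
        assert table.loc[0, "accuracy"] == 1.0

    def test_duplicate_columns_tie_prefers_smaller_subset(self):
        oof = pd.DataFrame({"A": [0.9, 0.1], "B": [0.9, 0.1]})
        y = np.array([1, 0])
        best, _ = ensemble_search(oof, y)
        assert best == ("A",)

    def test_hand_made_pair_beats_rest(self):
        # A and C agree and are right; B is anti-correlated
        y = np.array([1, 1, 0, 0, 1, 0])
        oof = pd.DataFrame({
            "A": [0.8, 0.7, 0.2, 0.3, 0.9, 0.1],
            "B": [0.1, 0.2, 0.9, 0.8, 0.2, 0.9],
            "C": [0.9, 0.6, 0.1, 0.4, 0.8, 0.2],
        })
        best, table = ensemble_search(oof, y)
        oracle_best, oracle_acc = ensemble_oracle(oof, y)
        assert best == oracle_best
        got = table.set_index(table["subset"]).loc[[best]]["accuracy"].iloc[0]
        assert got == pytest.approx(oracle_acc)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_m3(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 30)
        oof = pd.DataFrame(rng.random((30, 3)), columns=["A", "B", "C"])
        best, _ = ensemble_search(oof, y)
        oracle_best, _ = ensemble_oracle(oof, y)
        assert best == oracle_best


class TestSeverityScore:
    def test_median_of_members(self):
        scores = np.median(np.array([[0.9, 0.8, 0.95]]), axis=1)
        assert scores[0] == pytest.approx(0.9)
        assert classify_scores(scores)[0] == "severe"

    def test_exclusion_zone_abstains(self):
        assert classify_scores([0.50], margin=0.1)[0] == "abstain"
        assert classify_scores([0.61], margin=0.1)[0] == "severe"
        assert classify_scores([0.39], margin=0.1)[0] == "mild_moderate"

    def test_zero_margin_never_abstains(self):
        rng = np.random.default_rng(0)
        calls = classify_scores(rng.random(100), margin=0.0)
        assert "abstain" not in set(calls)

    def test_ensemble_estimator_roundtrip(self):
        X, y = _separable(n=50, seed=6)
        ens = MedianEnsemble(("DT", "NB"), inner_k=2, seed=0).fit(X, y)
        s = ens.severity_score(X)
        assert s.shape == (len(X),)
        assert ((s >= 0) & (s <= 1)).all()
        assert (ens.predict(X) == (s >= 0.5).astype(int)).all()
        proba = ens.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        # sklearn get_params/set_params contract
        assert MedianEnsemble(**ens.get_params()).algorithms == ("DT", "NB")


class TestExclusionTradeoff:
    def test_zero_margin_retains_all(self):
        curve = exclusion_tradeoff([0.1, 0.6, 0.9], [0, 1, 1])
        assert curve.loc[curve["margin"] == 0.0, "retained_fraction"].iloc[0] == 1.0

    def test_retention_non_increasing(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = (scores > 0.5).astype(int)
        curve = exclusion_tradeoff(scores, labels)
        assert (np.diff(curve["retained_fraction"]) <= 1e-12).all()

    def test_full_abstention_missing_accuracy(self):
        curve = exclusion_tradeoff([0.5, 0.5], [0, 1], margins=[0.4])
        assert curve["retained_fraction"].iloc[0] == 0.0
        assert np.isnan(curve["accuracy"].iloc[0])


class TestSaturate:
    def test_nineteen_predictions_per_position(self, globule_bundle,
                                               synthetic_aa_dist,
                                               planted_dataset):
        asm = planted_dataset["assembler"]
        X, y = planted_dataset["X"], planted_dataset["y"]
        ens = MedianEnsemble(("DT", "NB"), inner_k=2, seed=0).fit(X, y)
        positions = [p for p in asm.position_features.index
                     if not asm.position_features.loc[p, ["phi", "psi"]].isna().any()][:10]
        preds = saturate(ens, asm, positions=positions)
        assert len(preds) == 19 * 10
        per_pos = preds.groupby("position").size()
        assert (per_pos == 19).all()
        assert set(preds["call"]) <= {"severe", "mild_moderate"}
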
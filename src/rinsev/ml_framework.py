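"""Severity classification of factor IX point mutations.

The pipeline: sanitize the raw clinical mutation table, assemble one
feature row per mutation (wild-type position's structural measures,
centrality panel, conservation, amino-acid substitution distance and any
external predictor scores), min-max normalize to [0, 1], run a repeated
stratified k-fold protocol with per-fold hyperparameter tuning over six
classifier families, search all classifier subsets for the best
median-probability ensemble, and expose the ensemble's P(severe) as a
Severity Score with an optional abstention margin ("exclusion zone")
around the 0.5 decision boundary.

Estimators follow scikit-learn conventions (``fit``/``predict_proba``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn model selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, cohen_kappa_score,
                             matthews_corrcoef, roc_auc_score)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .aa_index import AADistanceIndex
from .residue_analysis import group_contrast

logger = logging.getLogger(__name__)

__all__ = [
    "LIGHT_CHAIN", "HEAVY_CHAIN", "ACTIVATION_PEPTIDE", "ALGORITHMS",
    "sanitize_mutations", "FeatureAssembler", "normalize_features",
    "stratified_folds", "TunedClassifier", "MedianEnsemble", "evaluate",
    "validate_grid", "default_grids", "GRID_BOUNDS", "position_feature_table",
    "run_protocol", "CVReport", "ensemble_search", "classify_scores",
    "exclusion_tradeoff", "saturate", "buried_contrast",
]

# Mature-protein residue ranges of activated factor IX (HGVS numbering).
LIGHT_CHAIN = (47, 191)
HEAVY_CHAIN = (227, 461)
ACTIVATION_PEPTIDE = (192, 226)

ALGORITHMS = ("DT", "RF", "NB", "SVM_radial", "SVM_poly", "XGB")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Mapping of reported severity strings to the two-class label; strings
#: spanning two classes are ambiguous and dropped during sanitation.
_SEVERITY_MAP = {
    "mild": "mild_moderate",
    "moderate": "mild_moderate",
    "mild_moderate": "mild_moderate",
    "severe": "severe",
}
_AMBIGUOUS = {"mild/moderate", "moderate/severe", "mild/severe"}


# ---------------------------------------------------------------------------
# Sanitation
# ---------------------------------------------------------------------------

def sanitize_mutations(raw: pd.DataFrame,
                       ranges: tuple = (LIGHT_CHAIN, HEAVY_CHAIN)):
    """Apply the clinical-database sanitation rules to a raw mutation table.

    Keeps missense records whose position lies inside the activated
    protein (light chain 47-191 or heavy chain 227-461 by default); maps
    mild and moderate onto one ``mild_moderate`` class; drops rows with
    ambiguous severity strings ("mild/moderate", "moderate/severe"),
    positions in the signal/propeptide or activation peptide, identical
    wild-type/mutant residues, or non-standard amino acids.  Every drop
    is returned with a reason code.

    Parameters
    ----------
    raw : DataFrame with columns ``position``, ``wt_aa``, ``mut_aa``,
        ``severity`` (strings); extra columns are carried through.

    Returns
    -------
    (clean, log) : clean DataFrame plus a per-drop log DataFrame with
        columns ``row``, ``position``, ``reason``.
    """
    required = {"position", "wt_aa", "mut_aa", "severity"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"mutation table lacks columns: {sorted(missing)}")

    drops = []
    keep_rows = []
    for idx, row in raw.iterrows():
        try:
            pos = int(row["position"])
        except (TypeError, ValueError):
            drops.append((idx, row["position"], "unparseable_position"))
            continue
        wt, mut = str(row["wt_aa"]).strip().upper(), str(row["mut_aa"]).strip().upper()
        if wt not in _STANDARD_AA or mut not in _STANDARD_AA:
            drops.append((idx, pos, "nonstandard_aa"))
            continue
        if wt == mut:
            drops.append((idx, pos, "synonymous"))
            continue
        if ACTIVATION_PEPTIDE[0] <= pos <= ACTIVATION_PEPTIDE[1]:
            drops.append((idx, pos, "activation_peptide"))
            continue
        if not any(lo <= pos <= hi for lo, hi in ranges):
            drops.append((idx, pos, "outside_activated_protein"))
            continue
        sev_raw = str(row["severity"]).strip().lower()
        if sev_raw in _AMBIGUOUS:
            drops.append((idx, pos, "ambiguous_severity"))
            continue
        sev = _SEVERITY_MAP.get(sev_raw)
        if sev is None:
            drops.append((idx, pos, "unparseable_severity"))
            continue
        new = row.copy()
        new["position"] = pos
        new["wt_aa"], new["mut_aa"] = wt, mut
        new["severity"] = sev
        keep_rows.append(new)

    log = pd.DataFrame(drops, columns=["row", "position", "reason"])
    for _, pos, reason in drops:
        logger.info("dropped mutation at position %s: %s", pos, reason)
    clean = pd.DataFrame(keep_rows).reset_index(drop=True)
    return clean, log


# ---------------------------------------------------------------------------
# Feature assembly and normalization
# ---------------------------------------------------------------------------

#: numeric per-position columns consumed from the structure property /
#: centrality tables when present
STRUCTURE_FEATURES = [
    "areaSAS", "areaSES", "rel_exposure", "relSESA_norm", "buried",
    "kd_hydrophobicity", "phi", "psi", "conservation",
    "degree", "betweenness", "closeness", "burts_constraint",
    "authority", "pagerank",
]


def position_feature_table(model, props: pd.DataFrame,
                           cent: pd.DataFrame) -> pd.DataFrame:
    """Join per-residue properties and centralities into one table keyed
    by author residue number (string).

    Residues absent from the RIN (isolated nodes) get missing centrality
    values; conservation comes from the structure annotations.
    """
    key_to_num = {r.key: f"{r.number}{r.icode}" for r in model}
    df = props.copy()
    for col in cent.columns:
        df[col] = cent[col].reindex(df.index)
    df["conservation"] = [r.conservation if r.conservation is not None else np.nan
                          for r in model]
    df["buried"] = df["buried"].astype(float)
    df.index = [key_to_num[k] for k in df.index]
    df.index.name = "position"
    return df


def normalize_features(X: pd.DataFrame):
    """Min-max normalize every column to [0, 1] over the given rows.

    Constant columns map to 0 (warning logged).  Returns the normalized
    frame plus the (mins, ranges) Series needed to transform new rows.
    """
    mins = X.min(axis=0)
    ranges = X.max(axis=0) - mins
    const = ranges == 0
    if const.any():
        logger.warning("constant feature column(s) normalized to 0: %s",
                       list(X.columns[const]))
    safe = ranges.replace(0, 1.0)
    return (X - mins) / safe, mins, ranges


def apply_normalization(X: pd.DataFrame, mins: pd.Series, ranges: pd.Series,
                        clip: bool = True) -> pd.DataFrame:
    """Apply stored min-max constants to new rows (clipped to [0, 1])."""
    safe = ranges.replace(0, 1.0)
    out = (X - mins) / safe
    return out.clip(0.0, 1.0) if clip else out


class FeatureAssembler:
    """Build normalized feature matrices for mutations at known positions.

    Holds the per-position structure/centrality table, the 20x20
    amino-acid distance index and the list of external predictor columns
    to carry from the mutation table.  After :meth:`fit` (which freezes
    the min-max constants on the training rows, the normalization
    convention being global over the retained instances), the same
    transform is applied to any new mutation set, including full
    saturation mutagenesis.
    """

    def __init__(self, position_features: pd.DataFrame,
                 aa_dist: AADistanceIndex,
                 extra_cols: tuple[str, ...] = ()):
        self.position_features = position_features
        self.aa_dist = aa_dist
        self.extra_cols = tuple(extra_cols)
        self.wt_aa_ = (dict(zip(position_features.index, position_features["aa"]))
                       if "aa" in position_features.columns else {})
        self.mins_: pd.Series | None = None
        self.ranges_: pd.Series | None = None

    # -- raw assembly -----------------------------------------------------
    def assemble(self, muts: pd.DataFrame):
        """One raw (unnormalized) feature row per mutation.

        Rows at positions absent from the structure table or with any
        missing feature value are removed and logged.  Returns
        (X, y, dropped_log); ``y`` is None when no severity column.
        """
        feat_cols = [c for c in STRUCTURE_FEATURES
                     if c in self.position_features.columns]
        rows, labels, kept_idx, drops = [], [], [], []
        for idx, m in muts.iterrows():
            pos = str(m["position"])
            if pos not in self.position_features.index:
                drops.append((idx, pos, "position_not_in_structure"))
                continue
            base = self.position_features.loc[pos, feat_cols].astype(float)
            row = base.to_dict()
            row["aa_distance"] = self.aa_dist[(m["wt_aa"], m["mut_aa"])]
            for c in self.extra_cols:
                row[c] = float(m[c]) if c in m and pd.notna(m[c]) else np.nan
            if any(pd.isna(v) for v in row.values()):
                drops.append((idx, pos, "missing_feature_value"))
                continue
            rows.append(row)
            kept_idx.append(idx)
            labels.append(m.get("severity"))
        X = pd.DataFrame(rows, index=kept_idx)
        y = None
        if "severity" in muts.columns:
            y = pd.Series([1 if s == "severe" else 0 for s in labels],
                          index=kept_idx, name="severe")
        log = pd.DataFrame(drops, columns=["row", "position", "reason"])
        if len(log):
            logger.info("feature assembly dropped %d mutation(s)", len(log))
        return X, y, log

    # -- normalized training / prediction matrices ------------------------
    def fit(self, muts: pd.DataFrame):
        """Assemble the training matrix and freeze normalization constants."""
        X, y, log = self.assemble(muts)
        Xn, self.mins_, self.ranges_ = normalize_features(X)
        return Xn, y, log

    def transform(self, muts: pd.DataFrame):
        """Assemble + normalize new mutations with the frozen constants."""
        if self.mins_ is None:
            raise RuntimeError("assembler not fitted; call fit() first")
        X, y, log = self.assemble(muts)
        return apply_normalization(X, self.mins_, self.ranges_), y, log

    def saturation_table(self, positions=None) -> pd.DataFrame:
        """All 19 substitutions per position as a mutation table."""
        if not self.wt_aa_:
            raise RuntimeError("position table lacks an 'aa' column")
        positions = list(self.position_features.index) if positions is None else \
            [str(p) for p in positions]
        recs = []
        for pos in positions:
            wt = self.wt_aa_.get(pos)
            if wt is None:
                logger.warning("position %s lacks a wild-type residue; skipped", pos)
                continue
            for mut in "ACDEFGHIKLMNPQRSTVWY":
                if mut != wt:
                    recs.append((pos, wt, mut))
        return pd.DataFrame(recs, columns=["position", "wt_aa", "mut_aa"])


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per instance).

    Each fold's class counts differ from the ideal ratio by at most one
    instance.  Raises if any class has fewer than ``k`` members.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} < k={k} instances")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test] = f
    return folds


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def default_grids(n_features: int = 16, seed: int = 0) -> dict:
    """Hyperparameter search lattices per algorithm.

    Continuous search intervals are sampled on fixed coarse lattices;
    interval bounds: DT min-split [2, 50], min-leaf [1, 35], complexity
    [0.0001, 1]; RF trees [4, 100], mtry [2, 7] (capped at the feature
    count), leaf size [1, 5]; SVM radial gamma in [0.01, 1.5]; SVM poly
    coef c in [0, 2], degree {2..5}; XGBoost depth [1, 25], learning
    rate (0, 0.5].  Gaussian NB is smoothed via ``var_smoothing`` (the
    analogue of Laplace smoothing for continuous features).
    """
    mtry = sorted({min(v, n_features) for v in (2, 4, 7)})
    return {
        "DT": {"min_samples_split": [2, 10, 25, 50],
               "min_samples_leaf": [1, 5, 15, 35],
               "ccp_alpha": [0.0001, 0.001, 0.01, 0.1, 1.0]},
        "RF": {"n_estimators": [4, 50, 100],
               "max_features": mtry,
               "min_samples_leaf": [1, 3, 5]},
        "NB": {"var_smoothing": [1e-9, 1e-6, 1e-3, 1e-1]},
        "SVM_radial": {"estimator__gamma": [0.01, 0.1, 0.3, 0.5, 1.0, 1.5]},
        "SVM_poly": {"estimator__coef0": [0.0, 1.0, 2.0],
                     "estimator__degree": [2, 3, 4, 5]},
        "XGB": {"max_depth": [1, 3, 10, 25],
                "learning_rate": [0.01, 0.1, 0.3, 0.5]},
    }


#: search interval per tunable hyperparameter, per algorithm
GRID_BOUNDS = {
    "DT": {"min_samples_split": (2, 50), "min_samples_leaf": (1, 35),
           "ccp_alpha": (0.0001, 1.0)},
    "RF": {"n_estimators": (4, 100), "max_features": (2, 7),
           "min_samples_leaf": (1, 5)},
    "NB": {"var_smoothing": (0.0, 1.0)},
    "SVM_radial": {"estimator__gamma": (0.01, 1.5)},
    "SVM_poly": {"estimator__coef0": (0.0, 2.0), "estimator__degree": (2, 5)},
    "XGB": {"max_depth": (1, 25), "learning_rate": (0.0, 0.5)},
}


def validate_grid(algorithm: str, grid: dict) -> dict:
    """Reject grid points outside the documented search intervals."""
    bounds = GRID_BOUNDS.get(algorithm, {})
    for param, values in grid.items():
        if param not in bounds:
            continue
        lo, hi = bounds[param]
        bad = [v for v in values if not lo <= v <= hi]
        if bad:
            raise ValueError(f"{algorithm} grid: {param} value(s) {bad} outside "
                             f"the search interval [{lo}, {hi}]")
    return grid


def _base_estimator(algorithm: str, seed: int):
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "NB":
        return GaussianNB()
    if algorithm == "SVM_radial":
        return CalibratedClassifierCV(SVC(kernel="rbf", C=1.0, random_state=seed),
                                      method="sigmoid", cv=3, ensemble=False)
    if algorithm == "SVM_poly":
        return CalibratedClassifierCV(SVC(kernel="poly", gamma="scale", C=1.0,
                                          random_state=seed),
                                      method="sigmoid", cv=3, ensemble=False)
    if algorithm == "XGB":
        return XGBClassifier(n_estimators=50, n_jobs=1, random_state=seed,
                             eval_metric="logloss", verbosity=0,
                             tree_method="hist")
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class TunedClassifier(BaseEstimator, ClassifierMixin):
    """One classifier family with inner-CV hyperparameter tuning.

    ``fit`` runs a stratified ``inner_k``-fold grid search (criterion:
    accuracy) over the algorithm's lattice and refits the best point on
    the full training data; grid-order ties resolve to the first best
    point.  Probabilities come from the refit model.

    Parameters
    ----------
    algorithm : one of ``ALGORITHMS``.
    grid : optional explicit parameter grid (validated against the
        documented intervals is the caller's business).
    inner_k : inner cross-validation folds used for tuning.
    seed : controls fold shuffling and any stochastic learner.
    """

    def __init__(self, algorithm: str = "RF", grid: dict | None = None,
                 inner_k: int = 10, seed: int = 0):
        self.algorithm = algorithm
        self.grid = grid
        self.inner_k = inner_k
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        grid = self.grid if self.grid is not None else \
            default_grids(n_features=X.shape[1], seed=self.seed)[self.algorithm]
        if not grid:
            raise ValueError("empty hyperparameter grid")
        validate_grid(self.algorithm, grid)
        cv = StratifiedKFold(n_splits=self.inner_k, shuffle=True,
                             random_state=self.seed)
        search = GridSearchCV(_base_estimator(self.algorithm, self.seed), grid,
                              scoring="accuracy", cv=cv, n_jobs=1, refit=True)
        search.fit(X, y)
        self.search_ = search
        self.best_params_ = search.best_params_
        self.best_estimator_ = search.best_estimator_
        self.classes_ = search.best_estimator_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(np.asarray(X, dtype=float))


class MedianEnsemble(BaseEstimator, ClassifierMixin):
    """Median-probability ensemble of tuned classifiers with abstention.

    The Severity Score of an instance is the per-instance median of the
    member classifiers' P(severe).  ``predict`` calls severe at score >=
    0.5; :meth:`predict_with_abstention` additionally abstains inside the
    exclusion zone |score - 0.5| < ``margin``.
    """

    def __init__(self, algorithms: tuple[str, ...] = ("RF", "XGB"),
                 inner_k: int = 10, seed: int = 0, margin: float = 0.0,
                 grids: dict | None = None):
        self.algorithms = algorithms
        self.inner_k = inner_k
        self.seed = seed
        self.margin = margin
        self.grids = grids

    def fit(self, X, y):
        y = np.asarray(y)
        self.members_ = {}
        for alg in self.algorithms:
            grid = None if self.grids is None else self.grids.get(alg)
            self.members_[alg] = TunedClassifier(alg, grid=grid,
                                                 inner_k=self.inner_k,
                                                 seed=self.seed).fit(X, y)
        self.classes_ = next(iter(self.members_.values())).classes_
        return self

    def _member_probs(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        cols = []
        for m in self.members_.values():
            proba = m.predict_proba(X)
            pos = int(np.where(m.classes_ == 1)[0][0])
            cols.append(proba[:, pos])
        return np.column_stack(cols)

    def severity_score(self, X) -> np.ndarray:
        """Per-instance median of member P(severe)."""
        return np.median(self._member_probs(X), axis=1)

    def predict_proba(self, X):
        s = self.severity_score(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X):
        return (self.severity_score(X) >= 0.5).astype(int)

    def predict_with_abstention(self, X, margin: float | None = None) -> np.ndarray:
        m = self.margin if margin is None else margin
        return classify_scores(self.severity_score(X), m)


def classify_scores(scores, margin: float = 0.0) -> np.ndarray:
    """Turn Severity Scores into calls; abstain iff |score - 0.5| < margin."""
    scores = np.asarray(scores, dtype=float)
    calls = np.where(scores >= 0.5, "severe", "mild_moderate").astype(object)
    calls[np.abs(scores - 0.5) < margin] = "abstain"
    return calls


# ---------------------------------------------------------------------------
# Evaluation and protocol
# ---------------------------------------------------------------------------

def evaluate(probs, labels, threshold: float = 0.5) -> dict:
    """Accuracy, Cohen's kappa, MCC and AUC from P(severe) and 0/1 labels.

    Severe (1) is the positive class; AUC is the rank statistic over the
    probabilities and is missing (logged) for single-class label sets.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (probs >= threshold).astype(int)
    out = {
        "accuracy": accuracy_score(labels, pred),
        "kappa": cohen_kappa_score(labels, pred),
        "mcc": matthews_corrcoef(labels, pred),
    }
    if len(np.unique(labels)) < 2:
        logger.warning("AUC undefined: single-class labels")
        out["auc"] = np.nan
    else:
        out["auc"] = roc_auc_score(labels, probs)
    return out


@dataclass
class CVReport:
    """Output of the repeated stratified CV protocol.

    ``metrics``: one row per repetition x fold x algorithm;
    ``oof``: per repetition, a DataFrame of out-of-fold P(severe) with
    one column per algorithm (every instance predicted exactly once per
    repetition per algorithm); ``y``: the 0/1 labels.
    """

    metrics: pd.DataFrame
    oof: dict = field(default_factory=dict)
    y: pd.Series = None

    def mean_metrics(self) -> pd.DataFrame:
        return (self.metrics.groupby("algorithm")
                [["accuracy", "kappa", "mcc", "auc"]].mean())

    def stacked_oof(self):
        """All repetitions stacked: (probabilities DataFrame, labels)."""
        frames, labels = [], []
        for rep in sorted(self.oof):
            frames.append(self.oof[rep])
            labels.append(self.y)
        return pd.concat(frames, ignore_index=True), pd.concat(labels, ignore_index=True)


def run_protocol(X: pd.DataFrame, y, algorithms=ALGORITHMS,
                 repetitions: int = 10, k: int = 10, inner_k: int = 10,
                 base_seed: int = 0) -> CVReport:
    """Repeated stratified k-fold evaluation with per-fold tuning.

    For each repetition (seed = ``base_seed`` + repetition index) the
    data are split into ``k`` stratified folds; per fold, every
    algorithm is tuned on the training part (inner ``inner_k``-fold grid
    search) and predicts the held-out part.  Out-of-fold probabilities
    are collected per instance, per algorithm, per repetition.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = pd.Series(np.asarray(y, dtype=int)).reset_index(drop=True)
    records = []
    oof: dict[int, pd.DataFrame] = {}
    for rep in range(repetitions):
        seed = base_seed + rep
        folds = stratified_folds(y, k=k, seed=seed)
        probs = pd.DataFrame(np.nan, index=X.index, columns=list(algorithms))
        for fold in range(k):
            test = folds == fold
            train = ~test
            for alg in algorithms:
                clf = TunedClassifier(alg, inner_k=inner_k, seed=seed)
                clf.fit(X[train], y[train])
                pos = int(np.where(clf.classes_ == 1)[0][0])
                p = clf.predict_proba(X[test])[:, pos]
                probs.loc[test, alg] = p
                m = evaluate(p, y[test])
                records.append({"repetition": rep, "fold": fold,
                                "algorithm": alg, **m,
                                "best_params": clf.best_params_})
        assert not probs.isna().any().any()
        oof[rep] = probs
    report = CVReport(metrics=pd.DataFrame(records), oof=oof, y=y)
    return report


def ensemble_search(oof: pd.DataFrame, y, criterion: str = "accuracy",
                    threshold: float = 0.5):
    """Exhaustive median-ensemble search over classifier subsets.

    Evaluates every non-empty subset of the probability columns by the
    per-instance median, scored with ``criterion`` at ``threshold``.
    Ties prefer smaller subsets, then lexicographic order.  Returns
    (best subset tuple, DataFrame of all subsets with their metrics).
    """
    y = np.asarray(y, dtype=int)
    cols = list(oof.columns)
    if not cols:
        raise ValueError("no probability columns to search over")
    rows = []
    best_subset, best_score = None, -np.inf
    for size in range(1, len(cols) + 1):
        for subset in itertools.combinations(cols, size):
            med = np.median(oof[list(subset)].to_numpy(dtype=float), axis=1)
            m = evaluate(med, y, threshold=threshold)
            rows.append({"subset": subset, "size": size, **m})
            if m[criterion] > best_score:
                best_subset, best_score = subset, m[criterion]
    table = pd.DataFrame(rows)
    return best_subset, table


def exclusion_tradeoff(scores, labels, margins=None) -> pd.DataFrame:
    """Coverage/accuracy trade-off of the exclusion zone.

    Per margin, instances with |score - 0.5| < margin abstain; accuracy
    is computed over the retained instances only.  A margin retaining
    nothing yields missing accuracy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if margins is None:
        margins = np.round(np.arange(0.0, 0.50, 0.05), 2)
    rows = []
    for m in margins:
        keep = np.abs(scores - 0.5) >= m
        retained = keep.mean()
        if keep.any():
            acc = accuracy_score(labels[keep], (scores[keep] >= 0.5).astype(int))
        else:
            acc = np.nan
        rows.append({"margin": float(m), "retained_fraction": float(retained),
                     "accuracy": acc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Saturation mutagenesis
# ---------------------------------------------------------------------------

def saturate(ensemble: MedianEnsemble, assembler: FeatureAssembler,
             positions=None, margin: float = 0.0) -> pd.DataFrame:
    """Severity Score for every position x 19 substitutions.

    Positions whose features cannot be assembled are skipped (logged by
    the assembler).  Returns one row per (position, wt, mut) with the
    score and the call at ``margin``.
    """
    muts = assembler.saturation_table(positions)
    Xn, _, log = assembler.transform(muts)
    kept = muts.loc[Xn.index]
    scores = ensemble.severity_score(Xn)
    out = pd.DataFrame({
        "position": kept["position"].values,
        "wt_aa": kept["wt_aa"].values,
        "mut_aa": kept["mut_aa"].values,
        "severity_score": scores,
        "call": classify_scores(scores, margin),
    })
    out.attrs["n_skipped"] = len(log)
    return out


def buried_contrast(saturation: pd.DataFrame, buried_by_position: dict):
    """Compare mean per-residue Severity Scores of buried vs exposed sites.

    Returns (mean buried, mean exposed, rank-sum p-value).
    """
    per_res = saturation.groupby("position")["severity_score"].mean()
    buried = [v for p, v in per_res.items() if buried_by_position.get(str(p))]
    exposed = [v for p, v in per_res.items()
               if buried_by_position.get(str(p)) is False]
    _, p = group_contrast(buried, exposed)
    return float(np.mean(buried)), float(np.mean(exposed)), p
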
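"""Multivariate NTCP model building: workflow, tuning, and nested CV.

A model is assembled in five steps, in this order: feature-group selection,
z-score scaling, sampling (class balancing / data cleaning), feature
selection, and classification.  The component vocabularies are

* 7 classifiers — LR-L1, LR-L2, LR-EN, kNN, SVM, ET, GTB;
* 7 selector options — UFS-F, UFS-MI, RFE-LR, RFE-ET, MB-LR, MB-ET, none;
* 10 sampler options — ROS, SMOTE, ADASYN, OSS, TL, ENN, NCL, SMOTE+ENN,
  SMOTE+TL, none;

giving 490 configurations per end point (1,960 over the four end points).
Hyperparameters are tuned by random search (default 300 draws) under
stratified Monte Carlo cross-validation (time-specific end points) or a
modified leave-pair-out CV that removes all same-patient observations from
the training fold (longitudinal end point).  Generalization performance is
estimated with nested cross-validation: the random search runs inside each
outer training fold and only the outer test folds contribute to the
generalization AUC.

The model-fitting surface is statsmodels-style: :class:`NTCPModel` wraps the
data and a :class:`ModelConfig`; ``fit()`` runs the tuning loop and returns
an :class:`NTCPResults` with the chosen hyperparameters, the tuning AUC and
its BCa interval, and a refit scorer; ``fit_nested()`` returns a
:class:`GeneralizationResult`.

Every scaler, sampler and selector is fitted strictly inside the training
portion of each split — no statistic of a test fold ever reaches the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .features import ALL_GROUPS, FeatureTable
from .sampling import SAMPLERS, apply_sampler
from .univariate import bca_interval, mwu_auc

__all__ = [
    "CLASSIFIERS",
    "SELECTORS",
    "ModelConfig",
    "ModelData",
    "SplitScheme",
    "TuningResult",
    "GeneralizationResult",
    "NTCPModel",
    "NTCPResults",
    "bernoulli_group_selection",
    "apply_selector",
    "train_classifier",
    "sample_hyperparameters",
    "mccv_splits",
    "lpocv_splits",
    "lpocv_auc",
    "random_search",
    "nested_cv",
    "enumerate_model_space",
    "reference_model_configs",
]

CLASSIFIERS: tuple[str, ...] = ("LR-L1", "LR-L2", "LR-EN", "kNN", "SVM", "ET", "GTB")
SELECTORS: tuple[str, ...] = ("UFS-F", "UFS-MI", "RFE-LR", "RFE-ET", "MB-LR", "MB-ET", "none")
ENDPOINTS: tuple[str, ...] = ("early", "late", "long-term", "longitudinal")
TIME_SPECIFIC: tuple[str, ...] = ("early", "late", "long-term")


@dataclass(frozen=True)
class ModelConfig:
    """One point of the model space.

    ``feature_groups`` restricts the table to whole feature groups;
    ``features`` (optional) pins an explicit column list instead, which is
    how the fixed mean-dose/morphological reference models are expressed.
    """

    classifier: str
    selector: str = "none"
    sampler: str = "none"
    endpoint: str = "long-term"
    feature_groups: tuple[str, ...] = ALL_GROUPS
    features: tuple[str, ...] | None = None
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.sampler not in SAMPLERS:
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.features is None and not self.feature_groups:
            raise ValueError("feature_groups must be nonempty")


@dataclass
class ModelData:
    """Numeric design matrix with observation bookkeeping."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    patient_ids: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y).astype(int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")

    def subset(self, idx) -> "ModelData":
        pid = None if self.patient_ids is None else self.patient_ids[idx]
        return ModelData(self.X[idx], self.y[idx], self.feature_names, pid)


@dataclass(frozen=True)
class SplitScheme:
    """Cross-validation scheme: stratified MCCV or modified LPOCV."""

    kind: str = "MCCV"  # 'MCCV' | 'LPOCV'
    n_splits: int = 300
    test_fraction: float = 0.1

    def __post_init__(self):
        if self.kind not in ("MCCV", "LPOCV"):
            raise ValueError(f"unknown split scheme {self.kind!r}")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if self.kind == "MCCV" and not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# step 1: feature-group selection


def bernoulli_group_selection(
    groups: Sequence[str] = ALL_GROUPS, p: float = 0.5, rng=None
) -> tuple[str, ...]:
    """Keep each feature group with probability ``p``; never return nothing.

    Each group passes an independent Bernoulli trial; if no group survives,
    the whole round of trials is repeated.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if not groups:
        raise ValueError("no groups available")
    rng = np.random.default_rng(rng)
    while True:
        keep = tuple(g for g in groups if rng.uniform() < p)
        if keep:
            return keep


# ---------------------------------------------------------------------------
# step 4: feature selection


def apply_selector(name: str, X, y, n_features: int | None = None, rng=None) -> np.ndarray:
    """Select feature columns; returns sorted column indices.

    UFS ranks columns by F-score or mutual information and keeps the top
    ``n_features``; RFE recursively drops the weakest feature of the named
    model down to ``n_features``; MB keeps columns whose importance in the
    named model exceeds the mean importance; 'none' keeps everything.  A
    requested size larger than the column count keeps all columns with a
    warning.
    """
    from sklearn.ensemble import ExtraTreesClassifier
    from sklearn.feature_selection import (
        RFE,
        SelectFromModel,
        SelectKBest,
        f_classif,
        mutual_info_classif,
    )
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    d = X.shape[1]
    if d < 1:
        raise ValueError("no features to select from")
    if name == "none":
        return np.arange(d)
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    if name in ("UFS-F", "UFS-MI", "RFE-LR", "RFE-ET"):
        if n_features is None:
            n_features = min(15, d)
        if n_features > d:
            warnings.warn(f"{name}: requested {n_features} of {d} features; keeping all")
            n_features = d
    with warnings.catch_warnings():
        # folds routinely contain constant columns (e.g. sex in a small
        # stratum); the score functions handle them, so keep the noise down
        warnings.simplefilter("ignore")
        if name == "UFS-F":
            sel = SelectKBest(f_classif, k=n_features).fit(X, y)
        elif name == "UFS-MI":
            score = lambda X_, y_: mutual_info_classif(X_, y_, random_state=seed)
            sel = SelectKBest(score, k=n_features).fit(X, y)
        elif name == "RFE-LR":
            est = LogisticRegression(max_iter=1000)
            sel = RFE(est, n_features_to_select=n_features).fit(X, y)
        elif name == "RFE-ET":
            est = ExtraTreesClassifier(n_estimators=50, random_state=seed)
            sel = RFE(est, n_features_to_select=n_features).fit(X, y)
        elif name == "MB-LR":
            est = LogisticRegression(penalty="l1", solver="liblinear", C=1.0, max_iter=1000)
            sel = SelectFromModel(est, threshold="mean").fit(X, y)
        elif name == "MB-ET":
            est = ExtraTreesClassifier(n_estimators=50, random_state=seed)
            sel = SelectFromModel(est, threshold="mean").fit(X, y)
        else:
            raise ValueError(f"unknown selector {name!r}")
    idx = np.flatnonzero(sel.get_support())
    if idx.size == 0:
        idx = np.arange(d)  # model-based threshold kept nothing: keep all
    return idx


# ---------------------------------------------------------------------------
# step 5: classification


def train_classifier(name: str, hyperparameters: dict, X, y, rng=None):
    """Fit a classifier and return it; use :func:`decision_scores` to score.

    All classifiers expose a continuous risk score (decision function or
    positive-class probability, higher = more likely positive) and are
    deterministic given the supplied generator.
    """
    from sklearn.ensemble import ExtraTreesClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    h = dict(hyperparameters)
    if name == "LR-L1":
        clf = LogisticRegression(
            penalty="l1", solver="liblinear", C=h.get("C", 1.0), max_iter=2000,
            random_state=seed,
        )
    elif name == "LR-L2":
        clf = LogisticRegression(C=h.get("C", 1.0), max_iter=2000)
    elif name == "LR-EN":
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", C=h.get("C", 1.0),
            l1_ratio=h.get("l1_ratio", 0.5), max_iter=5000, random_state=seed,
        )
    elif name == "kNN":
        clf = KNeighborsClassifier(n_neighbors=min(int(h.get("n_neighbors", 5)), len(y)))
    elif name == "SVM":
        clf = SVC(kernel="rbf", C=h.get("C", 1.0), gamma=h.get("gamma", "scale"))
    elif name == "ET":
        clf = ExtraTreesClassifier(
            n_estimators=int(h.get("n_estimators", 100)),
            max_depth=h.get("max_depth"),
            random_state=seed,
        )
    elif name == "GTB":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=int(h.get("n_estimators", 100)),
            max_depth=int(h.get("max_depth", 3)),
            learning_rate=h.get("learning_rate", 0.1),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    else:
        raise ValueError(f"unknown classifier {name!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            clf.fit(X, y)
        except Exception as exc:  # noqa: BLE001 — annotate with the config
            raise RuntimeError(f"classifier {name} failed to train: {exc}") from exc
    return clf


def decision_scores(clf, X) -> np.ndarray:
    """Continuous risk scores, higher = more likely positive."""
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)


# ---------------------------------------------------------------------------
# hyperparameter spaces

#: Default random-search spaces.  Each entry maps a hyperparameter to a
#: sampler ``f(rng) -> value``.  Overridable via ``space`` arguments.
def _log_uniform(lo, hi):
    return lambda rng: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


DEFAULT_SPACES: dict[str, dict[str, Callable]] = {
    "LR-L1": {"C": _log_uniform(1e-3, 1e3)},
    "LR-L2": {"C": _log_uniform(1e-3, 1e3)},
    "LR-EN": {"C": _log_uniform(1e-3, 1e3), "l1_ratio": lambda rng: float(rng.uniform())},
    "kNN": {"n_neighbors": lambda rng: int(rng.integers(1, 31))},
    "SVM": {"C": _log_uniform(1e-3, 1e3), "gamma": _log_uniform(1e-4, 10.0)},
    "ET": {
        "n_estimators": lambda rng: int(rng.integers(50, 501)),
        "max_depth": lambda rng: int(rng.integers(2, 9)),
    },
    "GTB": {
        "n_estimators": lambda rng: int(rng.integers(50, 501)),
        "max_depth": lambda rng: int(rng.integers(2, 9)),
        "learning_rate": _log_uniform(0.01, 0.3),
    },
}

_SIZED_SELECTORS = ("UFS-F", "UFS-MI", "RFE-LR", "RFE-ET")


def sample_hyperparameters(
    config: ModelConfig, n_features: int, rng, space: dict | None = None
) -> dict:
    """Draw one hyperparameter configuration for a model config."""
    rng = np.random.default_rng(rng)
    space = {**DEFAULT_SPACES[config.classifier], **(space or {})}
    h = {k: f(rng) for k, f in space.items()}
    if config.selector in _SIZED_SELECTORS:
        h["n_selected"] = int(rng.integers(1, min(15, n_features) + 1))
    return h


# ---------------------------------------------------------------------------
# cross-validation splits


def mccv_splits(
    labels, n_splits: int = 300, test_fraction: float = 0.1, rng=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified Monte Carlo CV: repeated random stratified holdouts.

    Each split holds out ``test_fraction`` of the observations with the test
    class ratio within one observation of the cohort ratio; train and test
    are disjoint and cover the index set.
    """
    labels = np.asarray(labels).astype(int)
    n = labels.size
    n_test = max(int(round(n * test_fraction)), 2)
    n_pos_test = int(round(labels.mean() * n_test))
    n_pos_test = min(max(n_pos_test, 1), n_test - 1)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each class needs >= 2 observations for stratified MCCV")
    if n_pos_test >= pos.size or (n_test - n_pos_test) >= neg.size:
        raise ValueError("class too small to stratify at this test fraction")
    rng = np.random.default_rng(rng)
    splits = []
    for _ in range(n_splits):
        test = np.concatenate(
            [
                rng.choice(pos, size=n_pos_test, replace=False),
                rng.choice(neg, size=n_test - n_pos_test, replace=False),
            ]
        )
        test = np.sort(test)
        train = np.setdiff1d(np.arange(n), test)
        splits.append((train, test))
    return splits


def lpocv_splits(
    patient_ids, labels, n_pairs: int = 300, rng=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Modified leave-pair-out CV splits for grouped longitudinal data.

    Each split's test fold is one positive and one negative observation from
    different patients; the training fold excludes every observation sharing
    a patient id with either test observation.  ``n_pairs`` random pairs are
    drawn with replacement from the cross-patient positive x negative pairs.
    """
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels).astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative observation")
    rng = np.random.default_rng(rng)
    all_idx = np.arange(labels.size)
    splits = []
    attempts = 0
    while len(splits) < n_pairs:
        i = rng.choice(pos)
        j = rng.choice(neg)
        attempts += 1
        if patient_ids[i] == patient_ids[j]:
            if attempts > 100 * n_pairs:
                raise ValueError("no cross-patient positive-negative pair exists")
            continue
        test = np.array([i, j])
        exclude = np.isin(patient_ids, [patient_ids[i], patient_ids[j]])
        train = all_idx[~exclude]
        splits.append((train, test))
    return splits


def lpocv_auc(pair_scores: Iterable[tuple[float, float]]) -> float:
    """AUC over LPOCV pairs: fraction with positive scored above negative,
    ties counting one half."""
    vals = [1.0 if sp > sn else (0.5 if sp == sn else 0.0) for sp, sn in pair_scores]
    if not vals:
        raise ValueError("no pair scores supplied")
    return float(np.mean(vals))


def make_splits(scheme: SplitScheme, data: ModelData, rng):
    if scheme.kind == "MCCV":
        return mccv_splits(data.y, scheme.n_splits, scheme.test_fraction, rng)
    if data.patient_ids is None:
        raise ValueError("LPOCV requires patient ids on the observations")
    return lpocv_splits(data.patient_ids, data.y, scheme.n_splits, rng)


# ---------------------------------------------------------------------------
# workflow fitting and evaluation


class FittedWorkflow:
    """Scaler + selected columns + classifier, fitted on one training set."""

    def __init__(self, config: ModelConfig, hyper: dict, X, y, rng):
        from sklearn.preprocessing import StandardScaler

        self.config = config
        self.hyper = dict(hyper)
        self.scaler = StandardScaler().fit(X)
        Xs = self.scaler.transform(X)
        Xr, yr = apply_sampler(config.sampler, Xs, y, rng)
        self.columns = apply_selector(
            config.selector, Xr, yr, self.hyper.get("n_selected"), rng
        )
        clf_hyper = {k: v for k, v in self.hyper.items() if k != "n_selected"}
        self.classifier = train_classifier(
            config.classifier, clf_hyper, Xr[:, self.columns], yr, rng
        )

    def decision(self, X) -> np.ndarray:
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        return decision_scores(self.classifier, Xs[:, self.columns])

    def predict(self, X) -> np.ndarray:
        """Binary predictions at the classifier's native threshold."""
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        return np.asarray(self.classifier.predict(Xs[:, self.columns]), dtype=int)


def _evaluate(config, hyper, data: ModelData, splits, scheme_kind: str, rng):
    """Cross-validated AUC of one hyperparameter configuration.

    Returns (auc, per-split scores): per-split AUCs for MCCV, per-pair
    correctness indicators (1 / 0.5 / 0) for LPOCV.
    """
    per_split = []
    if scheme_kind == "MCCV":
        for train, test in splits:
            wf = FittedWorkflow(config, hyper, data.X[train], data.y[train], rng)
            scores = wf.decision(data.X[test])
            _, auc = mwu_auc(scores, data.y[test])
            per_split.append(auc)
        return float(np.mean(per_split)), np.asarray(per_split)
    for train, test in splits:  # LPOCV: test = [positive, negative]
        wf = FittedWorkflow(config, hyper, data.X[train], data.y[train], rng)
        sp, sn = wf.decision(data.X[test])
        if data.y[test][0] == 0:
            sp, sn = sn, sp
        per_split.append(1.0 if sp > sn else (0.5 if sp == sn else 0.0))
    return float(np.mean(per_split)), np.asarray(per_split)


@dataclass
class TuningResult:
    """Outcome of the random hyperparameter search."""

    config: ModelConfig
    best_hyperparameters: dict
    tuning_auc: float
    ci: tuple[float, float]
    per_split_scores: np.ndarray
    n_iter: int

    def __post_init__(self):
        if not 0 <= self.tuning_auc <= 1:
            raise ValueError("tuning AUC out of [0, 1]")


def random_search(
    config: ModelConfig,
    data: ModelData,
    n_iter: int = 300,
    scheme: SplitScheme | None = None,
    rng=None,
    space: dict | None = None,
    compute_ci: bool = True,
    n_boot: int = 2000,
) -> tuple[TuningResult, FittedWorkflow]:
    """Tune a model config by random search and refit the best on all data.

    ``n_iter`` hyperparameter draws are each scored by cross-validated AUC
    on a shared set of splits; the best configuration (ties: first drawn)
    is retrained on the full data.  The tuning AUC's BCa interval is
    bootstrapped over the per-split scores.
    """
    if scheme is None:
        scheme = SplitScheme("LPOCV" if config.endpoint == "longitudinal" else "MCCV")
    rng = np.random.default_rng(rng)
    splits = make_splits(scheme, data, rng)
    best = None
    failures = []
    for it in range(n_iter):
        hyper = sample_hyperparameters(config, data.X.shape[1], rng, space)
        eval_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        try:
            auc, per_split = _evaluate(config, hyper, data, splits, scheme.kind, eval_rng)
        except (RuntimeError, ValueError) as exc:
            failures.append((hyper, str(exc)))
            continue
        if best is None or auc > best[0]:
            best = (auc, hyper, per_split)
    if best is None:
        raise RuntimeError(
            f"all {n_iter} candidates failed for {config}: "
            + "; ".join(msg for _, msg in failures[:3])
        )
    auc, hyper, per_split = best
    if compute_ci and np.ptp(per_split) > 0:
        ci = bca_interval(
            per_split, lambda s: float(np.mean(s)), n_boot=n_boot,
            rng=np.random.default_rng(rng.integers(0, 2**31 - 1)),
        )
    else:
        ci = (auc, auc)
    final = FittedWorkflow(
        config, hyper, data.X, data.y, np.random.default_rng(rng.integers(0, 2**31 - 1))
    )
    result = TuningResult(
        config=config,
        best_hyperparameters=hyper,
        tuning_auc=auc,
        ci=ci,
        per_split_scores=per_split,
        n_iter=n_iter,
    )
    return result, final


@dataclass
class GeneralizationResult:
    """Nested-CV estimate of out-of-sample performance."""

    config: ModelConfig
    auc: float
    ci: tuple[float, float]
    tuning_auc: float  # mean inner-loop best AUC (optimistic counterpart)
    outer_scores: np.ndarray

    @property
    def optimism(self) -> float:
        """Tuning AUC minus generalization AUC."""
        return self.tuning_auc - self.auc


def nested_cv(
    config: ModelConfig,
    data: ModelData,
    outer_scheme: SplitScheme | None = None,
    inner_scheme: SplitScheme | None = None,
    n_iter: int = 300,
    rng=None,
    space: dict | None = None,
    n_boot: int = 2000,
) -> GeneralizationResult:
    """Estimate generalization AUC with nested cross-validation.

    For each outer split the full random search (inner CV included) runs on
    the outer-training portion only; the tuned model is then scored on the
    outer test fold.  Outer-fold scores aggregate to the generalization AUC
    with a BCa bootstrap interval.
    """
    if outer_scheme is None:
        outer_scheme = (
            SplitScheme("LPOCV", n_splits=100)
            if config.endpoint == "longitudinal"
            else SplitScheme("MCCV", n_splits=100)
        )
    if inner_scheme is None:
        inner_scheme = SplitScheme(
            "LPOCV" if config.endpoint == "longitudinal" else "MCCV"
        )
    rng = np.random.default_rng(rng)
    outer_splits = make_splits(outer_scheme, data, rng)
    outer_scores = []
    inner_aucs = []
    for train, test in outer_splits:
        sub = data.subset(train)
        tuning, workflow = random_search(
            config, sub, n_iter=n_iter, scheme=inner_scheme,
            rng=np.random.default_rng(rng.integers(0, 2**31 - 1)),
            space=space, compute_ci=False,
        )
        inner_aucs.append(tuning.tuning_auc)
        scores = workflow.decision(data.X[test])
        if outer_scheme.kind == "MCCV":
            _, auc = mwu_auc(scores, data.y[test])
            outer_scores.append(auc)
        else:
            sp, sn = scores
            if data.y[test][0] == 0:
                sp, sn = sn, sp
            outer_scores.append(1.0 if sp > sn else (0.5 if sp == sn else 0.0))
    outer_scores = np.asarray(outer_scores)
    auc = float(np.mean(outer_scores))
    if np.ptp(outer_scores) > 0:
        ci = bca_interval(
            outer_scores, lambda s: float(np.mean(s)), n_boot=n_boot,
            rng=np.random.default_rng(rng.integers(0, 2**31 - 1)),
        )
    else:
        ci = (auc, auc)
    return GeneralizationResult(
        config=config,
        auc=auc,
        ci=ci,
        tuning_auc=float(np.mean(inner_aucs)),
        outer_scores=outer_scores,
    )


# ---------------------------------------------------------------------------
# model space


def enumerate_model_space(endpoints: Sequence[str] = ENDPOINTS) -> dict:
    """Enumerate every (classifier, selector, sampler) combination.

    Returns the per-endpoint and total counts plus per-algorithm involvement
    tallies split into time-specific and longitudinal end points.
    """
    configs = [
        ModelConfig(classifier=c, selector=s, sampler=m, endpoint=e)
        for e in endpoints
        for c in CLASSIFIERS
        for s in SELECTORS
        for m in SAMPLERS
    ]
    def tally(key):
        out: dict[str, dict[str, int]] = {}
        for cfg in configs:
            bucket = "longitudinal" if cfg.endpoint == "longitudinal" else "time-specific"
            name = getattr(cfg, key)
            out.setdefault(name, {"time-specific": 0, "longitudinal": 0})
            out[name][bucket] += 1
        return out

    per_endpoint = {
        e: sum(1 for c in configs if c.endpoint == e) for e in endpoints
    }
    return {
        "configs": configs,
        "per_endpoint": per_endpoint,
        "total": len(configs),
        "per_classifier": tally("classifier"),
        "per_selector": tally("selector"),
        "per_sampler": tally("sampler"),
    }


def reference_model_configs(endpoint: str = "long-term") -> dict[str, ModelConfig]:
    """Fixed logistic reference models: mean-dose and morphological.

    The four mean-dose models use the ipsilateral mean, the contralateral
    mean, the volume-weighted mean over both glands, and the bivariate
    (ipsi, contra) pair; the morphological model uses the four dose-moment
    covariates.  All are plain L2 logistic regressions with no sampling or
    selection.
    """
    def cfg(features):
        return ModelConfig(
            classifier="LR-L2", selector="none", sampler="none",
            endpoint=endpoint, features=tuple(features),
        )

    return {
        "mean_ipsi": cfg(["mean_ipsi"]),
        "mean_contra": cfg(["mean_contra"]),
        "mean_both": cfg(["mean_both"]),
        "mean_ipsi+contra": cfg(["mean_ipsi", "mean_contra"]),
        "morphological": cfg(
            ["eta111_ipsi", "eta002_contra", "eta300_contra", "eta110_product"]
        ),
    }


# ---------------------------------------------------------------------------
# statsmodels-style surface


class NTCPModel:
    """A configurable NTCP model bound to a feature table and an end point.

    Parameters
    ----------
    table
        Wide feature table (or DataFrame) whose rows are observations of the
        chosen end point.  For the longitudinal end point the visit time
        must already be a column (``time_months``).
    labels
        Binary outcome per row.
    config
        The workflow configuration (classifier / selector / sampler /
        feature groups).
    patient_ids
        Required for the longitudinal end point (grouped LPOCV).
    """

    def __init__(self, table, labels, config: ModelConfig, patient_ids=None):
        df = table.data if isinstance(table, FeatureTable) else pd.DataFrame(table)
        if config.features is not None:
            missing = [f for f in config.features if f not in df.columns]
            if missing:
                raise ValueError(f"config pins unknown feature columns {missing}")
            cols = list(config.features)
        else:
            ft = FeatureTable(df)
            cols = ft.columns_in_groups(config.feature_groups)
            if "time_months" in df.columns and "time_months" not in cols:
                cols = cols + ["time_months"]  # longitudinal time covariate
            if not cols:
                raise ValueError(
                    f"no columns found for feature groups {config.feature_groups}"
                )
        self.config = config
        self.data = ModelData(
            df[cols].to_numpy(dtype=float),
            np.asarray(labels).astype(int),
            cols,
            None if patient_ids is None else np.asarray(patient_ids),
        )

    @classmethod
    def from_endpoint(cls, table: FeatureTable, endpoint_dataset, config: ModelConfig):
        """Align a per-patient feature table with an end-point dataset.

        Time-specific end points take one row per labelled patient; the
        longitudinal end point repeats a patient's features once per visit
        and appends the visit time as a covariate.
        """
        rows = endpoint_dataset.rows
        df = table.data.loc[rows["patient_id"]].reset_index(drop=True)
        if "time_months" in rows.columns:
            df = df.assign(time_months=rows["time_months"].to_numpy())
        return cls(
            df, rows["label"].to_numpy(), config,
            patient_ids=rows["patient_id"].to_numpy(),
        )

    def fit(
        self,
        n_iter: int = 300,
        scheme: SplitScheme | None = None,
        rng=None,
        space: dict | None = None,
        n_boot: int = 2000,
    ) -> "NTCPResults":
        """Tune by random search and refit the best model on all data."""
        tuning, workflow = random_search(
            self.config, self.data, n_iter=n_iter, scheme=scheme, rng=rng,
            space=space, n_boot=n_boot,
        )
        return NTCPResults(model=self, tuning=tuning, workflow=workflow)

    def fit_nested(
        self,
        outer_scheme: SplitScheme | None = None,
        inner_scheme: SplitScheme | None = None,
        n_iter: int = 300,
        rng=None,
        space: dict | None = None,
        n_boot: int = 2000,
    ) -> GeneralizationResult:
        """Nested-CV generalization estimate for this model."""
        return nested_cv(
            self.config, self.data, outer_scheme=outer_scheme,
            inner_scheme=inner_scheme, n_iter=n_iter, rng=rng, space=space,
            n_boot=n_boot,
        )


class NTCPResults:
    """Fitted NTCP model: tuned hyperparameters, scores, and a scorer."""

    def __init__(self, model: NTCPModel, tuning: TuningResult, workflow: FittedWorkflow):
        self.model = model
        self.tuning = tuning
        self.workflow = workflow

    @property
    def params(self) -> dict:
        return self.tuning.best_hyperparameters

    @property
    def tuning_auc(self) -> float:
        return self.tuning.tuning_auc

    @property
    def ci(self) -> tuple[float, float]:
        return self.tuning.ci

    @property
    def selected_features(self) -> list[str]:
        return [self.model.data.feature_names[i] for i in self.workflow.columns]

    def predict_scores(self, X=None) -> np.ndarray:
        """Risk scores on new data (default: the training table)."""
        return self.workflow.decision(self.model.data.X if X is None else X)

    def summary(self) -> str:
        c = self.model.config
        lines = [
            f"NTCP model — endpoint: {c.endpoint}",
            f"  classifier: {c.classifier}, selector: {c.selector}, sampler: {c.sampler}",
            f"  observations: {len(self.model.data.y)} "
            f"({int(self.model.data.y.sum())} events)",
            f"  tuning AUC: {self.tuning_auc:.3f} "
            f"(95% BCa CI {self.ci[0]:.3f}-{self.ci[1]:.3f}, "
            f"{self.tuning.n_iter} search draws)",
            f"  best hyperparameters: "
            + ", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                        for k, v in self.params.items()),
            f"  selected features ({len(self.selected_features)}): "
            + ", ".join(self.selected_features),
        ]
        return "\n".join(lines)
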
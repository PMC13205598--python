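"""Train-Synthetic / Test-Real (TSTR) evaluation harness.

The clinical task: predict chronic-kidney-disease onset after the diabetes
diagnosis from the pre-diagnosis history only (sex, age at diabetes, and
per-comorbidity presence/first-age restricted to onsets at or before the
anchor age).  Three training scenarios — real, synthetic, hybrid
(concatenation) — are each fitted over repeated stratified K-fold training
subsets and always evaluated on one fixed, fully real test set.

The default classifier is an additive model of boosted depth-1 stumps
(each tree splits on a single feature, so the ensemble is a sum of
per-feature shape functions) exposing per-feature global importances; any
classifier with ``fit`` / ``predict_proba`` / ``feature_importances()`` can
be plugged in instead, including sequence models.

Stability diagnostics: the hyperbolic weighted Kendall tau (HWT) between
feature-importance rankings, and the prediction-distribution stability (PDS)
quantiles of per-patient probability differences between CV-subset models
and the full-pool model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .records import FEMALE, Cohort

__all__ = [
    "PredictionTask",
    "build_task",
    "AdditiveBoostingClassifier",
    "run_tstr",
    "auroc_by_group",
    "hyperbolic_weighted_tau",
    "prediction_distribution_stability",
    "TSTRScenarioResult",
]

AGE_SENTINEL = -1.0  # missing first-diagnosis ages (companion flag column exists)


@dataclass
class PredictionTask:
    X: np.ndarray  # [n, p]
    y: np.ndarray  # [n] bool
    feature_names: list
    sex: np.ndarray  # per-patient sex labels
    diagnosis_year: np.ndarray  # per-patient year (or -1)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def label_balance(self) -> float:
        return float(self.y.mean())


def build_task(cohort: Cohort, require_label_variation: bool = False) -> PredictionTask:
    """Build the endpoint-prediction task from a (prediction-refined) cohort.

    Leakage guard: a comorbidity first diagnosed after the anchor age
    contributes neither its flag nor its age; the endpoint code is the label
    and never a feature.
    """
    codes = [c for c in cohort.comorbidity_codes if c != cohort.endpoint_code]
    names = ["sex_female", "age_at_diabetes"]
    for c in codes:
        names += [c, f"age_{c}"]
    rows = np.zeros((len(cohort.records), len(names)))
    y = np.zeros(len(cohort.records), dtype=bool)
    sex = np.empty(len(cohort.records), dtype=object)
    years = np.full(len(cohort.records), -1)
    for i, r in enumerate(cohort.records):
        anchor_age = r.first_age_of(cohort.anchor_code)
        rows[i, 0] = 1.0 if r.sex == FEMALE else 0.0
        rows[i, 1] = anchor_age if anchor_age is not None else AGE_SENTINEL
        for j, c in enumerate(codes):
            age = r.first_age_of(c)
            pre = age is not None and anchor_age is not None and age <= anchor_age
            rows[i, 2 + 2 * j] = 1.0 if pre else 0.0
            rows[i, 3 + 2 * j] = age if pre else AGE_SENTINEL
        y[i] = r.has_code(cohort.endpoint_code)
        sex[i] = r.sex
        if r.diagnosis_year is not None:
            years[i] = r.diagnosis_year
    if require_label_variation and len(np.unique(y)) < 2:
        raise ValueError("cohort has no endpoint variation; unusable for training")
    return PredictionTask(X=rows, y=y, feature_names=names, sex=sex, diagnosis_year=years)


class AdditiveBoostingClassifier:
    """Boosted depth-1 stumps: an additive model with per-feature importances.

    Each boosting round grows a single-split tree, so the fitted function is a
    sum of univariate piecewise-constant shape functions; global importance is
    the total split gain attributed to each feature.
    """

    def __init__(self, n_estimators: int = 300, learning_rate: float = 0.1, seed: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.seed = seed
        self._model = None

    def fit(self, X, y):
        from lightgbm import LGBMClassifier

        self._model = LGBMClassifier(
            max_depth=1,
            num_leaves=2,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            min_child_samples=5,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        self._model.fit(np.asarray(X), np.asarray(y, dtype=int))
        return self

    def predict_proba(self, X):
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            return self._model.predict_proba(np.asarray(X))

    def feature_importances(self) -> np.ndarray:
        return self._model.booster_.feature_importance(importance_type="gain")

    def clone(self, seed: Optional[int] = None) -> "AdditiveBoostingClassifier":
        return AdditiveBoostingClassifier(
            self.n_estimators, self.learning_rate, self.seed if seed is None else seed
        )


def importance_ranking(importances: np.ndarray, names: Sequence[str]) -> list:
    """Features by descending importance, name-lexicographic tie-break."""
    order = sorted(range(len(names)), key=lambda i: (-importances[i], names[i]))
    return [names[i] for i in order]


@dataclass
class TSTRScenarioResult:
    scenario: str
    auroc_per_fit: list
    auroc_full: float
    mean_auroc: float = field(init=False)
    sd_auroc: float = field(init=False)
    cv_probabilities: list = field(default_factory=list)  # per fit, on real test
    full_probabilities: Optional[np.ndarray] = None
    rankings: list = field(default_factory=list)  # per-fit importance rankings
    full_ranking: Optional[list] = None
    n_skipped_folds: int = 0

    def __post_init__(self):
        self.mean_auroc = float(np.mean(self.auroc_per_fit)) if self.auroc_per_fit else float("nan")
        self.sd_auroc = float(np.std(self.auroc_per_fit)) if self.auroc_per_fit else float("nan")

    def summary(self) -> str:
        return (
            f"{self.scenario}: AUROC {self.mean_auroc:.3f} +/- {self.sd_auroc:.3f} "
            f"({len(self.auroc_per_fit)} CV fits, full-pool {self.auroc_full:.3f})"
        )


def run_tstr(
    real_train: PredictionTask,
    synth_train: Optional[PredictionTask],
    real_test: PredictionTask,
    scenario: str = "real",
    cv: tuple = (10, 10),
    model: Optional[AdditiveBoostingClassifier] = None,
    seed: int = 0,
) -> TSTRScenarioResult:
    """Fit the scenario's training pool over repeats x folds CV training
    subsets plus once on the full pool; every fit is scored on the fixed real
    test set.  Hybrid pools concatenate real and synthetic rows (no
    reweighting, no deduplication)."""
    if scenario == "real":
        pool_X, pool_y = real_train.X, real_train.y
    elif scenario == "synthetic":
        if synth_train is None:
            raise ValueError("synthetic scenario needs a synthetic training task")
        pool_X, pool_y = synth_train.X, synth_train.y
    elif scenario == "hybrid":
        if synth_train is None:
            raise ValueError("hybrid scenario needs a synthetic training task")
        pool_X = np.vstack([real_train.X, synth_train.X])
        pool_y = np.concatenate([real_train.y, synth_train.y])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if len(np.unique(pool_y)) < 2:
        raise ValueError("training pool has a single class")
    proto = model if model is not None else AdditiveBoostingClassifier(seed=seed)
    repeats, folds = cv
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    aurocs, probs, rankings = [], [], []
    skipped = 0
    names = real_train.feature_names
    for k, (train_idx, _) in enumerate(splitter.split(pool_X, pool_y)):
        yk = pool_y[train_idx]
        if len(np.unique(yk)) < 2:
            skipped += 1
            continue
        clf = proto.clone(seed=seed + 1 + k) if hasattr(proto, "clone") else proto
        clf.fit(pool_X[train_idx], yk)
        p = clf.predict_proba(real_test.X)[:, 1]
        aurocs.append(float(roc_auc_score(real_test.y, p)))
        probs.append(p)
        if hasattr(clf, "feature_importances"):
            rankings.append(importance_ranking(clf.feature_importances(), names))
    full = proto.clone(seed=seed) if hasattr(proto, "clone") else proto
    full.fit(pool_X, pool_y)
    p_full = full.predict_proba(real_test.X)[:, 1]
    return TSTRScenarioResult(
        scenario=scenario,
        auroc_per_fit=aurocs,
        auroc_full=float(roc_auc_score(real_test.y, p_full)),
        cv_probabilities=probs,
        full_probabilities=p_full,
        rankings=rankings,
        full_ranking=(
            importance_ranking(full.feature_importances(), names)
            if hasattr(full, "feature_importances")
            else None
        ),
        n_skipped_folds=skipped,
    )


def auroc_by_group(
    probabilities: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> pd.DataFrame:
    """AUROC within each stratum of the real test set; strata with a single
    class are flagged (NaN AUROC)."""
    rows = []
    for g in sorted(pd.unique(groups), key=str):
        sel = groups == g
        yk = y[sel]
        if len(np.unique(yk)) < 2:
            rows.append({"group": g, "n": int(sel.sum()), "auroc": float("nan")})
        else:
            rows.append(
                {
                    "group": g,
                    "n": int(sel.sum()),
                    "auroc": float(roc_auc_score(yk, probabilities[sel])),
                }
            )
    return pd.DataFrame(rows)


def hyperbolic_weighted_tau(
    rank_a: Sequence[str], rank_b: Sequence[str], weighted: bool = True
) -> float:
    """Weighted Kendall tau between two rankings of the same item set.

    Additive hyperbolic weights w(r) = 1/(1+r) over zero-based ranks: an
    exchanged (discordant) pair at reference ranks (i, j) contributes
    w(i) + w(j); the statistic is (concordant - discordant weight) over the
    total pair weight, averaged over the two choices of reference ranking.
    With ``weighted=False`` all pair weights are equal and the statistic
    reduces to the unweighted Kendall tau.
    """
    if set(rank_a) != set(rank_b) or len(set(rank_a)) != len(rank_a):
        raise ValueError("rankings must be permutations of one item set")
    n = len(rank_a)
    if n < 2:
        return 1.0
    pos_a = {item: i for i, item in enumerate(rank_a)}
    pos_b = {item: i for i, item in enumerate(rank_b)}

    def one_sided(ref_pos, other_pos):
        items = list(ref_pos)
        num = den = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                u, v = items[i], items[j]
                if weighted:
                    w = 1.0 / (1.0 + ref_pos[u]) + 1.0 / (1.0 + ref_pos[v])
                else:
                    w = 1.0
                concordant = (ref_pos[u] - ref_pos[v]) * (other_pos[u] - other_pos[v]) > 0
                num += w if concordant else -w
                den += w
        return num / den

    return 0.5 * (one_sided(pos_a, pos_b) + one_sided(pos_b, pos_a))


def prediction_distribution_stability(
    cv_probabilities: Sequence[np.ndarray],
    full_probabilities: np.ndarray,
    quantiles: Sequence[float] = (0.01, 0.25, 0.50, 0.75, 0.99),
) -> dict:
    """Quantiles of per-patient probability differences between each CV-subset
    model and the full-pool model."""
    diffs = np.concatenate([p - full_probabilities for p in cv_probabilities])
    qs = np.quantile(diffs, quantiles)
    return {f"q{int(q * 100):02d}": float(v) for q, v in zip(quantiles, qs)}
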
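"""False-registration filters: short-duration rule and tree classifier.

The SD method removes every stay shorter than a threshold (one minute by
default).  The ML method trains a gradient-boosted tree ensemble on the
13 registration features to classify CR vs FR and removes predicted FRs;
winter-garden registrations — for which no labelled training data exist —
are handled by the SD rule instead.  In both methods a removed stay is
absorbed by extending the preceding registration (the tag is presumed to
remain in its last registered zone until re-registered), consecutive
same-zone registrations are merged, and durations are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from statsmodels.stats.contingency_tables import mcnemar

from .features import FEATURE_COLUMNS, build_features, encode_features
from .zones import Zone

DEFAULT_SD_THRESHOLD_S = 60.0

#: modest default grid over tree depth / shrinkage / ensemble size
DEFAULT_GRID = {
    "max_depth": [3, 6],
    "learning_rate": [0.1, 0.3],
    "max_iter": [100, 200],
}


@dataclass
class FilterResult:
    """Outcome of a filtering pass over a registration table."""

    kept: pd.DataFrame
    removed_count: int
    method: str


@dataclass
class ClassifierReport:
    """Held-out performance of the CR/FR classifier."""

    accuracy: float
    precision_fr: float
    recall_fr: float
    precision_cr: float
    recall_cr: float
    chosen_hyperparameters: dict
    feature_importances: dict = field(default_factory=dict)


@dataclass
class FRClassifier:
    """A fitted CR/FR tree-ensemble classifier over the feature schema."""

    estimator: HistGradientBoostingClassifier
    categories: dict

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predict 'CR'/'FR' per feature row."""
        if list(features.columns) != FEATURE_COLUMNS:
            raise ValueError("feature schema mismatch")
        X, _, _ = encode_features(features, self.categories)
        return self.estimator.predict(X)

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FRClassifier":
        import joblib

        return joblib.load(path)


def sd_filter(
    regs: pd.DataFrame, threshold: float = DEFAULT_SD_THRESHOLD_S
) -> FilterResult:
    """Remove registrations lasting less than ``threshold`` seconds.

    A tag's first registration is never removed (it has no predecessor to
    absorb it).  Idempotent: filtering a filtered table is a no-op.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if regs.empty:
        return FilterResult(regs.copy(), 0, "SD")
    remove = regs["duration"].to_numpy(float) < threshold
    remove &= ~_is_first_of_tag(regs)
    kept, n_removed = _absorb_and_merge(regs, remove)
    return FilterResult(kept, n_removed, "SD")


def ml_filter(
    regs: pd.DataFrame,
    model: FRClassifier,
    sd_threshold: float = DEFAULT_SD_THRESHOLD_S,
) -> FilterResult:
    """Remove indoor registrations the classifier predicts FR; apply the
    SD rule to winter-garden registrations (no training data there)."""
    if regs.empty:
        return FilterResult(regs.copy(), 0, "ML")
    features = build_features(regs)
    pred = model.predict(features)
    is_wg = (regs["zone"] == Zone.WINTER_GARDEN.value).to_numpy()
    short = regs["duration"].to_numpy(float) < sd_threshold
    remove = np.where(is_wg, short, pred == "FR")
    remove &= ~_is_first_of_tag(regs)
    kept, n_removed = _absorb_and_merge(regs, remove)
    return FilterResult(kept, n_removed, "ML")


def _is_first_of_tag(regs: pd.DataFrame) -> np.ndarray:
    return (regs.groupby("tag_id", sort=False).cumcount() == 0).to_numpy()


def _absorb_and_merge(regs: pd.DataFrame, remove: np.ndarray):
    """Drop flagged rows, extend the preceding stay over each gap, merge
    consecutive same-zone stays and recompute durations."""
    n_removed = int(remove.sum())
    out_parts = []
    for _, grp in regs.groupby("tag_id", sort=False):
        mask = ~remove[regs.index.get_indexer(grp.index)]
        sub = grp.loc[mask].copy()
        if sub.empty:
            continue
        starts = sub["t_start"].to_numpy(float)
        end = float(grp["t_start"].iloc[-1] + grp["duration"].iloc[-1])
        # absorb: each kept stay runs to the next kept start (or stream end)
        sub["duration"] = np.append(starts[1:], end) - starts
        # merge runs of equal zones
        zones = sub["zone"].to_numpy(object)
        new_run = np.ones(len(sub), dtype=bool)
        new_run[1:] = zones[1:] != zones[:-1]
        run_id = np.cumsum(new_run) - 1
        if (~new_run).any():
            dur = np.bincount(run_id, weights=sub["duration"].to_numpy(float))
            sub = sub.loc[new_run]
            sub["duration"] = dur
        out_parts.append(sub)
    kept = (
        pd.concat(out_parts, ignore_index=True)
        if out_parts
        else regs.iloc[0:0].copy()
    )
    return kept, n_removed


def train_fr_classifier(
    features: pd.DataFrame,
    labels,
    n_folds: int = 3,
    grid: dict | None = None,
    seed: int = 0,
    holdout_fraction: float = 0.25,
) -> tuple[FRClassifier, ClassifierReport]:
    """Grid-search a gradient-boosted tree CR/FR classifier with k-fold CV.

    Winter-garden rows are excluded from training.  Metrics are computed
    on a stratified held-out split; normalized permutation importances
    (summing to 1) are exposed in the report.
    """
    labels = np.asarray(labels, dtype=object)
    mask = (features["zone"] != Zone.WINTER_GARDEN.value).to_numpy()
    features, labels = features.loc[mask], labels[mask]
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate training set: a single label class")

    X, cat_mask, categories = encode_features(features)
    counts = pd.Series(labels).value_counts()
    stratify = labels if counts.min() >= 2 else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, test_size=holdout_fraction, stratify=stratify, random_state=seed
    )
    if len(np.unique(y_tr)) < 2:  # the rare class fell entirely in the holdout
        X_tr, y_tr = X, labels
    base = HistGradientBoostingClassifier(
        categorical_features=cat_mask, random_state=seed
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid or DEFAULT_GRID, cv=cv, n_jobs=1)
    search.fit(X_tr, y_tr)
    est = search.best_estimator_

    y_hat = est.predict(X_te)
    report = ClassifierReport(
        accuracy=float((y_hat == y_te).mean()),
        precision_fr=float(precision_score(y_te, y_hat, pos_label="FR",
                                           zero_division=0)),
        recall_fr=float(recall_score(y_te, y_hat, pos_label="FR",
                                     zero_division=0)),
        precision_cr=float(precision_score(y_te, y_hat, pos_label="CR",
                                           zero_division=0)),
        recall_cr=float(recall_score(y_te, y_hat, pos_label="CR",
                                     zero_division=0)),
        chosen_hyperparameters=dict(search.best_params_),
        feature_importances=_normalized_importances(est, X_te, y_te, seed),
    )
    return FRClassifier(est, categories), report


def _normalized_importances(est, X, y, seed) -> dict:
    imp = permutation_importance(est, X, y, n_repeats=5, random_state=seed)
    raw = np.clip(imp.importances_mean, 0.0, None)
    total = raw.sum()
    if total == 0:
        raw = np.ones_like(raw)
        total = raw.sum()
    return dict(zip(FEATURE_COLUMNS, (raw / total).tolist()))


@dataclass
class McNemarResult:
    statistic: float
    pvalue: float
    n_discordant: int
    exact: bool
    no_discordance: bool = False


def mcnemar_compare(pred_a, pred_b, truth) -> McNemarResult:
    """McNemar's paired test of two classifiers' error proportions.

    Uses the exact binomial form when fewer than 25 predictions are
    discordant, the continuity-corrected chi-square form otherwise.
    """
    pred_a, pred_b, truth = (np.asarray(v, dtype=object) for v in (pred_a, pred_b, truth))
    if not (len(pred_a) == len(pred_b) == len(truth)):
        raise ValueError("prediction vectors must have equal length")
    err_a = pred_a != truth
    err_b = pred_b != truth
    b = int((~err_a & err_b).sum())  # a right, b wrong
    c = int((err_a & ~err_b).sum())
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(0.0, 1.0, 0, True, no_discordance=True)
    table = [[int((~err_a & ~err_b).sum()), b], [c, int((err_a & err_b).sum())]]
    exact = n_disc < 25
    res = mcnemar(table, exact=exact, correction=True)
    return McNemarResult(float(res.statistic), float(res.pvalue), n_disc, exact)
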
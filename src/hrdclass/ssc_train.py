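"""Semi-supervised self-training classifier and LOOCV threshold calibration.

The classifier follows Yarowsky-style self-training: fit a random forest on
the labelled samples, score the unlabelled pool, admit every sample whose
class-max probability reaches ``confidence_floor`` as a pseudo-label, refit,
and repeat — refreshing all pseudo-labels each round — until the
pseudo-labelling stabilises or ``max_iter`` is reached.  The final model is
refit on the augmented set.  Original labels are never removed or flipped.
A never-revise variant that grows the pseudo-labelled set by
confidence-ranked batches is available as ``strategy='incremental'``; it is
not the default because confidence-ordered admission trains intermediate
forests on spatially extreme subsets and degrades them (see the methods
note).

The decision threshold is calibrated by leave-one-out cross-validation over
the labelled samples: each is held out in turn (the unlabelled pool stays
available to every fold), the held-out probabilities are amalgamated, and the
threshold maximising F1 for the positive class is chosen.  Class imbalance is
handled by this threshold, not by resampling.  Calls at exactly the threshold
are positive.
"""

from __future__ import annotations

import dataclasses
import logging
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier

from .core_io import ConfigurationError, FeatureMatrix, ValidationError
from .selection import NormalisationParams

log = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "positive", "negative"


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelConfig:
    """One model configuration: feature list + learner and loop controls.

    ``strategy`` selects the self-training loop: 'relabel' (default) admits
    every unlabelled sample whose class-max probability reaches
    ``confidence_floor`` and refreshes all pseudo-labels each round until they
    stabilise; 'incremental' grows the pseudo-labelled set by confidence-
    ranked batches of ``batch_fraction`` of the pool per iteration and never
    revises a pseudo-label.  ``stop_fraction`` is the portion of the pool
    that must be pseudo-labelled before stopping ('relabel') or that is
    consumed in total ('incremental').
    """

    model_id: str
    features: tuple[str, ...]
    n_trees: int = 500
    min_leaf: int = 1
    strategy: str = "relabel"
    confidence_floor: float = 0.5
    batch_fraction: float = 0.1
    stop_fraction: float = 0.7
    max_iter: int = 40
    seed: int = 0
    reference_threshold: float | None = None

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


def load_registry(path=None) -> dict[str, ModelConfig]:
    """The shipped seven-model registry (five primary + two auxiliary)."""
    if path is None:
        text = resources.files("hrdclass.data").joinpath("models.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    blocks = {k: list(v) for k, v in raw["blocks"].items()}
    registry = {}
    for model_id, entry in raw["models"].items():
        if "features" in entry:
            feats = list(entry["features"])
        else:
            feats = [f for b in entry["blocks"] for f in blocks[b]]
            feats = [f for f in feats if f not in set(entry.get("exclude", ()))]
        registry[model_id] = ModelConfig(
            model_id=model_id, features=tuple(feats),
            reference_threshold=entry.get("reference_threshold"))
    return registry


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainedClassifier:
    config: ModelConfig
    forest: RandomForestClassifier
    threshold: float
    importances: pd.Series
    training_log: list[dict]
    normalisation: NormalisationParams | None = None

    def predict_proba(self, features: FeatureMatrix | pd.DataFrame) -> pd.Series:
        values = features.values if isinstance(features, FeatureMatrix) else features
        missing = [f for f in self.config.features if f not in values.columns]
        if missing:
            raise ConfigurationError(f"missing feature column(s) {missing}")
        X = values[list(self.config.features)].to_numpy(dtype=float)
        pos_idx = list(self.forest.classes_).index(POSITIVE)
        p = self.forest.predict_proba(X)[:, pos_idx]
        return pd.Series(p, index=values.index, name="p_hrd")

    def predict(self, features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
        p = self.predict_proba(features)
        return pd.DataFrame({"p_hrd": p, "call": np.where(
            p >= self.threshold, POSITIVE, NEGATIVE)}, index=p.index)


def _design(features: FeatureMatrix, config: ModelConfig) -> pd.DataFrame:
    missing = [f for f in config.features if f not in features.feature_names]
    if missing:
        raise ConfigurationError(f"missing feature column(s) {missing}")
    return features.values[list(config.features)]


def _new_forest(config: ModelConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees, max_features="sqrt",
        min_samples_leaf=config.min_leaf, random_state=seed, n_jobs=1)


def self_train(features: FeatureMatrix, labels: pd.Series,
               config: ModelConfig, threshold: float | None = None
               ) -> TrainedClassifier:
    """Fit the self-training ensemble.

    ``labels``: 'positive'/'negative'/'unknown' per sample; unknowns form the
    unlabelled pool.  Original labels are immutable; only pseudo-labels can
    be assigned or (in the default relabelling loop) revised.  ``threshold``
    may be supplied (e.g. from a prior LOOCV calibration); defaults to 0.5
    until calibrated.
    """
    X = _design(features, config)
    if X.to_numpy().std(axis=0).max() == 0 and len(X) > 1:
        raise ValidationError("all features constant")
    labels = labels.reindex(X.index)
    labelled = labels.isin([POSITIVE, NEGATIVE])
    y = labels[labelled].copy()
    if (y == POSITIVE).sum() == 0 or (y == NEGATIVE).sum() == 0:
        raise ValidationError("need both classes among labelled samples")

    pool = list(X.index[~labelled])
    if config.strategy == "relabel":
        train_idx, train_y, history = _loop_relabel(X, y, pool, config)
    elif config.strategy == "incremental":
        train_idx, train_y, history = _loop_incremental(X, y, pool, config)
    else:
        raise ConfigurationError(f"unknown strategy {config.strategy!r}")

    final = _new_forest(config, config.seed)
    final.fit(X.loc[train_idx].to_numpy(dtype=float),
              [train_y[i] for i in train_idx])
    importances = pd.Series(final.feature_importances_,
                            index=list(config.features)).sort_values(ascending=False)
    return TrainedClassifier(config=config, forest=final,
                             threshold=0.5 if threshold is None else threshold,
                             importances=importances, training_log=history)


def _loop_relabel(X: pd.DataFrame, y: pd.Series, pool: list,
                  config: ModelConfig):
    """Yarowsky-style loop: admit every pool sample whose class-max
    probability reaches the confidence floor, refreshing all pseudo-labels
    each round, until the pseudo-labelling stabilises with at least
    ``stop_fraction`` of the pool covered (or ``max_iter``)."""
    history: list[dict] = []
    pseudo: dict = {}  # sample -> pseudo label
    n_pool0 = len(pool)
    for it in range(config.max_iter if pool else 0):
        train_idx = list(y.index) + list(pseudo)
        train_y = {**y.to_dict(), **pseudo}
        forest = _new_forest(config, config.seed + it + 1)
        forest.fit(X.loc[train_idx].to_numpy(dtype=float),
                   [train_y[i] for i in train_idx])
        proba = forest.predict_proba(X.loc[pool].to_numpy(dtype=float))
        conf = proba.max(axis=1)
        pred = forest.classes_[np.argmax(proba, axis=1)]
        new_pseudo = {s: p for s, p, c in zip(pool, pred, conf)
                      if c >= config.confidence_floor}
        if new_pseudo == pseudo:
            break  # pseudo-labelling has stabilised
        history.append({
            "iteration": it,
            "added": [(s, p, float(c)) for s, p, c in zip(pool, pred, conf)
                      if c >= config.confidence_floor and s not in pseudo],
            "revised": sum(1 for s in new_pseudo
                           if s in pseudo and new_pseudo[s] != pseudo[s]),
            "pool_remaining": n_pool0 - len(new_pseudo)})
        pseudo = new_pseudo
    train_idx = list(y.index) + list(pseudo)
    return train_idx, {**y.to_dict(), **pseudo}, history


def _loop_incremental(X: pd.DataFrame, y: pd.Series, pool: list,
                      config: ModelConfig):
    """Never-revise variant: grow the pseudo-labelled set by confidence-
    ranked batches until ``stop_fraction`` of the pool is consumed."""
    history: list[dict] = []
    pool = list(pool)
    n_pool0 = len(pool)
    batch_size = max(1, int(np.ceil(config.batch_fraction * n_pool0))) \
        if n_pool0 else 0
    n_stop = int(np.floor(config.stop_fraction * n_pool0))
    consumed = 0
    train_idx = list(y.index)
    train_y = y.to_dict()
    it = 0
    while pool and consumed < n_stop and it < config.max_iter:
        forest = _new_forest(config, config.seed + it + 1)
        forest.fit(X.loc[train_idx].to_numpy(dtype=float),
                   [train_y[i] for i in train_idx])
        proba = forest.predict_proba(X.loc[pool].to_numpy(dtype=float))
        conf = proba.max(axis=1)
        pred = forest.classes_[np.argmax(proba, axis=1)]
        take = min(batch_size, n_stop - consumed)
        order = np.argsort(-conf, kind="stable")
        picked = [k for k in order if conf[k] >= config.confidence_floor][:take]
        if not picked:
            break
        added = []
        for k in picked:
            sample = pool[k]
            train_idx.append(sample)
            train_y[sample] = pred[k]
            added.append((sample, pred[k], float(conf[k])))
        pool = [s for j, s in enumerate(pool) if j not in set(picked)]
        consumed += len(added)
        history.append({"iteration": it, "added": added,
                        "pool_remaining": len(pool)})
        it += 1
    return train_idx, train_y, history


def supervised_fit(features: FeatureMatrix, labels: pd.Series,
                   config: ModelConfig) -> TrainedClassifier:
    """Plain forest on the labelled samples only (self-training baseline)."""
    masked = labels.where(labels.isin([POSITIVE, NEGATIVE]), other=None).dropna()
    sub = FeatureMatrix(features.values.loc[masked.index],
                        dict(features.blocks), features.state)
    return self_train(sub, masked, config)


def loocv_probabilities(features: FeatureMatrix, labels: pd.Series,
                        config: ModelConfig) -> pd.Series:
    """Held-out probability for every labelled sample, via LOOCV.

    Each fold retrains the self-training classifier without the held-out
    sample; the unknown-status pool is available to every fold.
    """
    labels = labels.reindex(features.values.index)
    labelled_idx = list(labels.index[labels.isin([POSITIVE, NEGATIVE])])
    out = {}
    for i in labelled_idx:
        fold_labels = labels.drop(index=i)
        fold_fm = FeatureMatrix(features.values.drop(index=i),
                                dict(features.blocks), features.state)
        clf = self_train(fold_fm, fold_labels, config)
        out[i] = float(clf.predict_proba(features.values.loc[[i]]).iloc[0])
    return pd.Series(out, name="p_hrd").reindex(labelled_idx)


def f1_score_at(probabilities: np.ndarray, y_true: np.ndarray,
                threshold: float) -> float:
    calls = probabilities >= threshold
    tp = int((calls & y_true).sum())
    fp = int((calls & ~y_true).sum())
    fn = int((~calls & y_true).sum())
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def optimal_threshold(probabilities: pd.Series | np.ndarray,
                      labels: pd.Series | np.ndarray) -> tuple[float, float]:
    """(threshold, F1): midpoint-scan threshold maximising F1; ties -> smallest.

    Candidates are the midpoints between consecutive sorted unique
    probabilities plus the 0 and 1 boundaries.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    y_true = (y == POSITIVE) if y.dtype.kind in "OU" else y.astype(bool)
    if y_true.all() or (~y_true).all():
        raise ValidationError("both classes required for threshold calibration")
    uniq = np.unique(p)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_t, best_f1 = 0.0, -1.0
    for t in candidates:
        f1 = f1_score_at(p, y_true, t)
        if f1 > best_f1:  # strict: ties keep the smallest threshold
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


def train_calibrated(features: FeatureMatrix, labels: pd.Series,
                     config: ModelConfig) -> tuple[TrainedClassifier, pd.Series]:
    """LOOCV-calibrated final model: returns (classifier, loocv probabilities)."""
    loocv = loocv_probabilities(features, labels, config)
    thr, _ = optimal_threshold(loocv, labels.reindex(loocv.index))
    clf = self_train(features, labels, config, threshold=thr)
    return clf, loocv


def feature_importance(classifier: TrainedClassifier,
                       method: str = "impurity",
                       features: FeatureMatrix | None = None,
                       labels: pd.Series | None = None,
                       n_repeats: int = 10) -> pd.Series:
    """Per-feature importance, sorted descending.

    'impurity' reads the forest's mean decrease in impurity; 'permutation'
    recomputes importances on supplied labelled data.
    """
    if method == "impurity":
        return classifier.importances
    if method == "permutation":
        from sklearn.inspection import permutation_importance
        if features is None or labels is None:
            raise ConfigurationError("permutation importance needs data + labels")
        mask = labels.isin([POSITIVE, NEGATIVE])
        X = features.values.loc[mask, list(classifier.config.features)]
        res = permutation_importance(
            classifier.forest, X.to_numpy(dtype=float),
            labels[mask].to_numpy(), n_repeats=n_repeats,
            random_state=classifier.config.seed)
        return pd.Series(res.importances_mean,
                         index=list(classifier.config.features)
                         ).sort_values(ascending=False)
    raise ConfigurationError(f"unknown importance method {method!r}")
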
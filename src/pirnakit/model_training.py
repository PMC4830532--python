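"""Feature-combination classifiers: direct concatenation and weighted ensemble.

Two ways of combining the per-feature encodings into one predictor:

* **direct** -- concatenate the selected feature blocks into one vector
  and fit a single random forest on it;
* **ensemble** -- fit one random forest per selected feature, score each
  by internal cross-validation AUC (score_i), and predict the convex
  combination F(x) = sum_i w_i f_i(x) with w_i = score_i / sum(score).

Either way, the feature subset itself is chosen by exhaustively scoring
every non-empty subset of the candidate features by internal CV AUC on
the training data only, and the winner is refitted on the full training
set. With the five default sequence features that is 2^5 - 1 = 31
candidate subsets.

The base classifier is a random forest (500 trees, square-root feature
sampling by default); probabilities are the forest's class-vote
fractions. All randomness flows from the single seed in
:class:`ClassifierSpec`, so identical spec + identical data yields
identical fitted models and predictions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from pirnakit.feature_encoders import (
    FeatureMatrix,
    FeatureParams,
    PSSMModel,
    extract_features,
    train_pssm,
)
from pirnakit.sequence_io import POSITIVE, SequenceSet

DIRECT = "direct"
ENSEMBLE = "ensemble"


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of the decision-forest base classifier."""

    n_trees: int = 500
    max_features: str = "sqrt"
    seed: int = 0
    inner_folds: int = 5

    def make(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )


def _labels_to_y(labels: Sequence[Optional[str]]) -> np.ndarray:
    if any(l is None for l in labels):
        raise ValueError("all records must carry a class label")
    return np.array([1 if l == POSITIVE else 0 for l in labels], dtype=int)


def fit_feature_model(
    features: np.ndarray, labels: Sequence, spec: ClassifierSpec
) -> RandomForestClassifier:
    """Fit one random forest on a single feature block.

    ``labels`` may be 'positive'/'negative' strings or 0/1 integers.
    The fitted model's ``predict_proba`` column 1 is the positive-class
    probability f_i(x) in [0, 1].
    """
    y = _as_y(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = spec.make()
    model.fit(features, y)
    return model


def _as_y(labels: Sequence) -> np.ndarray:
    labels = list(labels)
    if labels and isinstance(labels[0], str):
        return _labels_to_y(labels)
    return np.asarray(labels, dtype=int)


def _positive_proba(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    idx = int(np.where(model.classes_ == 1)[0][0])
    return model.predict_proba(X)[:, idx]


def internal_cv_score(
    features: np.ndarray,
    labels: Sequence,
    spec: ClassifierSpec,
    folds: Optional[int] = None,
) -> float:
    """Mean held-out AUC of a feature block under stratified k-fold CV.

    Folds are assigned from the spec seed, so the same inputs always
    yield the same score.
    """
    y = _as_y(labels)
    folds = folds or spec.inner_folds
    if folds < 2:
        raise ValueError("internal CV needs at least 2 folds")
    if len(y) < folds:
        raise ValueError(f"{len(y)} records cannot be split into {folds} folds")
    aucs = []
    for _, (tr, te) in enumerate(_fold_iter(y, folds, spec.seed)):
        model = spec.make()
        model.fit(features[tr], y[tr])
        aucs.append(roc_auc_score(y[te], _positive_proba(model, features[te])))
    return float(np.mean(aucs))


def _fold_iter(y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return skf.split(np.zeros(len(y)), y)


def ensemble_weights(scores: Sequence[float]) -> list[float]:
    """Normalize internal CV scores into convex weights w_i = score_i / sum."""
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to weight")
    if any(s <= 0 for s in scores):
        raise ValueError(f"all scores must be > 0, got {scores}")
    total = float(sum(scores))
    return [s / total for s in scores]


@dataclass
class CombinationModel:
    """A fitted feature-combination predictor (direct or ensemble mode).

    Carries everything needed to re-encode and score new sequences: the
    selected feature subset, the per-feature or concatenated classifier,
    ensemble weights, the encoder parameters and the PSSM snapshot from
    training time.
    """

    mode: str
    selected_features: list[str]
    spec: ClassifierSpec
    params: FeatureParams
    pssm: Optional[PSSMModel] = None
    classifier: Optional[RandomForestClassifier] = None  # direct mode
    feature_models: dict[str, RandomForestClassifier] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    internal_scores: dict[str, float] = field(default_factory=dict)
    subset_search: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in (DIRECT, ENSEMBLE):
            raise ValueError(f"mode must be 'direct' or 'ensemble', got {self.mode!r}")
        if not self.selected_features:
            raise ValueError("selected feature subset is empty")
        if self.mode == ENSEMBLE and self.weights:
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"ensemble weights sum to {total}, expected 1")

    # -- prediction ---------------------------------------------------------

    def predict_scores(
        self, seqs: SequenceSet, annotations: Optional[Mapping] = None
    ) -> np.ndarray:
        """Positive-class score in [0, 1] per record, in set order."""
        matrix = extract_features(
            seqs,
            self.selected_features,
            params=self.params,
            pssm=self.pssm,
            annotations=annotations,
            extra_encoders=getattr(self, "_extra_encoders", None),
        )
        return self.predict_from_matrix(matrix)

    def predict_from_matrix(self, matrix: FeatureMatrix) -> np.ndarray:
        if self.mode == DIRECT:
            assert self.classifier is not None
            X = matrix.select(self.selected_features).values
            return _positive_proba(self.classifier, X)
        out = np.zeros(len(matrix.row_ids))
        for name in self.selected_features:
            out += self.weights[name] * _positive_proba(
                self.feature_models[name], matrix.block_values(name)
            )
        return out

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write metadata (JSON), the PSSM table (TSV) and classifier state."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "mode": self.mode,
            "selected_features": self.selected_features,
            "weights": self.weights,
            "internal_scores": self.internal_scores,
            "subset_search": [[list(s), a] for s, a in self.subset_search],
            "spec": {
                "n_trees": self.spec.n_trees,
                "max_features": self.spec.max_features,
                "seed": self.spec.seed,
                "inner_folds": self.spec.inner_folds,
            },
            "params": {
                "ks": list(self.params.ks),
                "m_of_k": {str(k): v for k, v in self.params.m_of_k.items()},
                "delta_of_k": {str(k): v for k, v in self.params.delta_of_k.items()},
                "d": self.params.d,
                "lambda": self.params.lam,
                "w": self.params.w,
            },
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        if self.pssm is not None:
            self.pssm.to_tsv(directory / "pssm.tsv")
        state = {"classifier": self.classifier, "feature_models": self.feature_models}
        joblib.dump(state, directory / "classifiers.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "CombinationModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec = ClassifierSpec(**meta["spec"])
        p = meta["params"]
        params = FeatureParams(
            ks=tuple(p["ks"]),
            m_of_k={int(k): v for k, v in p["m_of_k"].items()},
            delta_of_k={int(k): v for k, v in p["delta_of_k"].items()},
            d=p["d"],
            lam=p["lambda"],
            w=p["w"],
        )
        pssm = None
        if (directory / "pssm.tsv").exists():
            pssm = PSSMModel.from_tsv(directory / "pssm.tsv")
        state = joblib.load(directory / "classifiers.joblib")
        return cls(
            mode=meta["mode"],
            selected_features=meta["selected_features"],
            spec=spec,
            params=params,
            pssm=pssm,
            classifier=state["classifier"],
            feature_models=state["feature_models"],
            weights=meta["weights"],
            internal_scores=meta["internal_scores"],
            subset_search=[(tuple(s), a) for s, a in meta["subset_search"]],
        )


def predict(
    model: CombinationModel, seqs: SequenceSet, annotations: Optional[Mapping] = None
) -> np.ndarray:
    """Functional alias for :meth:`CombinationModel.predict_scores`."""
    return model.predict_scores(seqs, annotations)


# ---------------------------------------------------------------------------
# subset search


def _oof_probabilities(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold positive-class probabilities plus the fold id per row."""
    proba = np.zeros(len(y))
    fold_id = np.zeros(len(y), dtype=int)
    for f, (tr, te) in enumerate(_fold_iter(y, spec.inner_folds, spec.seed)):
        model = spec.make()
        model.fit(X[tr], y[tr])
        proba[te] = _positive_proba(model, X[te])
        fold_id[te] = f
    return proba, fold_id


def _mean_fold_auc(scores: np.ndarray, y: np.ndarray, fold_id: np.ndarray) -> float:
    aucs = []
    for f in np.unique(fold_id):
        mask = fold_id == f
        aucs.append(roc_auc_score(y[mask], scores[mask]))
    return float(np.mean(aucs))


def select_optimal_subset(
    training: SequenceSet,
    mode: str,
    candidate_features: Sequence[str],
    spec: ClassifierSpec,
    params: Optional[FeatureParams] = None,
    annotations: Optional[Mapping] = None,
    extra_encoders: Optional[Mapping] = None,
) -> CombinationModel:
    """Exhaustive feature-subset search by internal CV AUC, then refit.

    All 2^N - 1 non-empty subsets of ``candidate_features`` are scored
    by the internal cross-validation AUC of the mode's combined model on
    the training set only; the best subset (ties broken toward fewer
    features, then lexicographic order) is refitted on the full training
    set. Per-feature encodings are computed once and reused across
    subsets.
    """
    candidate_features = list(candidate_features)
    n = len(candidate_features)
    if n == 0:
        raise ValueError("no candidate features given")
    if n > 10:
        raise ValueError(f"exhaustive search over {2**n - 1} subsets refused for N={n} > 10")
    if params is None:
        params = FeatureParams()
    y = _labels_to_y(training.labels())
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    pssm = train_pssm(training, params.d) if "pssm" in candidate_features else None
    matrix = extract_features(
        training,
        candidate_features,
        params=params,
        pssm=pssm,
        annotations=annotations,
        extra_encoders=extra_encoders,
    )

    # per-feature out-of-fold probabilities and internal CV scores,
    # computed once and shared by every subset
    oof: dict[str, np.ndarray] = {}
    fold_id: Optional[np.ndarray] = None
    internal_scores: dict[str, float] = {}
    for name in candidate_features:
        proba, fold_id = _oof_probabilities(matrix.block_values(name), y, spec)
        oof[name] = proba
        internal_scores[name] = _mean_fold_auc(proba, y, fold_id)
    assert fold_id is not None

    results: list[tuple[tuple[str, ...], float]] = []
    for size in range(1, n + 1):
        for subset in itertools.combinations(candidate_features, size):
            if mode == ENSEMBLE:
                w = ensemble_weights([max(internal_scores[f], 1e-12) for f in subset])
                combined = sum(
                    wi * oof[f] for wi, f in zip(w, subset)
                )
                auc_score = _mean_fold_auc(np.asarray(combined), y, fold_id)
            elif mode == DIRECT:
                X = matrix.select(list(subset)).values
                proba, fid = _oof_probabilities(X, y, spec)
                auc_score = _mean_fold_auc(proba, y, fid)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            results.append((subset, auc_score))

    # best AUC; ties -> fewer features -> lexicographic name order
    best_subset, _ = max(
        results, key=lambda item: (item[1], -len(item[0]), tuple(reversed_order(item[0])))
    )
    return _refit(
        mode, list(best_subset), matrix, y, spec, params, pssm,
        internal_scores, results, extra_encoders,
    )


def reversed_order(names: Sequence[str]) -> tuple:
    """Sort key making lexicographically smaller tuples win under max()."""
    return tuple(tuple(-ord(c) for c in name) for name in names)


def _refit(
    mode: str,
    subset: list[str],
    matrix: FeatureMatrix,
    y: np.ndarray,
    spec: ClassifierSpec,
    params: FeatureParams,
    pssm: Optional[PSSMModel],
    internal_scores: dict[str, float],
    results: list,
    extra_encoders: Optional[Mapping],
) -> CombinationModel:
    model = CombinationModel(
        mode=mode,
        selected_features=subset,
        spec=spec,
        params=params,
        pssm=pssm,
        internal_scores=internal_scores,
        subset_search=results,
    )
    if extra_encoders:
        model._extra_encoders = dict(extra_encoders)  # type: ignore[attr-defined]
    if mode == DIRECT:
        model.classifier = fit_feature_model(matrix.select(subset).values, y, spec)
    else:
        w = ensemble_weights([max(internal_scores[f], 1e-12) for f in subset])
        model.weights = dict(zip(subset, w))
        for name in subset:
            model.feature_models[name] = fit_feature_model(
                matrix.block_values(name), y, spec
            )
    return model


def fit_combination_model(
    training: SequenceSet,
    mode: str,
    features: Sequence[str],
    spec: ClassifierSpec,
    params: Optional[FeatureParams] = None,
    annotations: Optional[Mapping] = None,
    select_subset: bool = True,
    extra_encoders: Optional[Mapping] = None,
) -> CombinationModel:
    """Fit a combination model, optionally skipping the subset search.

    With ``select_subset=False`` the given feature list is used as-is
    (internal CV scores are still computed in ensemble mode, since the
    weights derive from them).
    """
    if select_subset:
        return select_optimal_subset(
            training, mode, features, spec, params, annotations, extra_encoders
        )
    features = list(features)
    if params is None:
        params = FeatureParams()
    y = _labels_to_y(training.labels())
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    pssm = train_pssm(training, params.d) if "pssm" in features else None
    matrix = extract_features(
        training, features, params=params, pssm=pssm,
        annotations=annotations, extra_encoders=extra_encoders,
    )
    internal_scores: dict[str, float] = {}
    if mode == ENSEMBLE:
        for name in features:
            proba, fid = _oof_probabilities(matrix.block_values(name), y, spec)
            internal_scores[name] = _mean_fold_auc(proba, y, fid)
    return _refit(
        mode, features, matrix, y, spec, params, pssm, internal_scores, [], extra_encoders
    )
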
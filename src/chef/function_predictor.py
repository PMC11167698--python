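"""Multi-label models predicting functional labels from fingerprints.

:class:`FunctionPredictor` is a scikit-learn style estimator (``fit`` /
``predict_proba`` / ``get_params``) over three model kinds: one-vs-rest
logistic regression (C=0.001, max_iter=1000) and random forest
(100 trees, depth 10) ensembles, and a single shared-trunk multi-output
MLP ((512, 256) hidden units, 5 epochs, batch 32, lr 0.001, binary
cross-entropy).  Module-level functions (featurize, split, evaluate,
ranking, profile prediction) stay thin wrappers around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_array, check_is_fitted

from chef.corpus_io import ChefDataset, canonicalize_smiles
from chef.structure_coherence import fingerprint_molecules

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "ModelEval",
    "FunctionPredictor",
    "featurize",
    "split_train_test",
    "train_model",
    "evaluate",
    "rank_molecules_for_label",
    "predict_profile",
]


@dataclass
class ModelConfig:
    """Model hyperparameters; defaults are the winning settings per kind."""

    model_kind: str = "logistic"
    logistic_C: float = 0.001
    logistic_max_iter: int = 1000
    rf_n_estimators: int = 100
    rf_max_depth: int = 10
    mlp_hidden: tuple[int, int] = (512, 256)
    mlp_epochs: int = 5
    mlp_dropout: float = 0.2  # accepted for config parity; inert (see docs)
    mlp_batch_size: int = 32
    mlp_learning_rate: float = 0.001
    test_fraction: float = 0.1
    seed: int = 0
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.model_kind not in {"logistic", "random_forest", "mlp"}:
            raise ValueError(f"unknown model_kind: {self.model_kind!r}")


@dataclass
class ModelEval:
    """Per-label and macro test metrics.

    Macro averages are unweighted means over labels evaluated (those with
    at least one positive and one negative in the test set); untrainable
    or non-evaluable labels are counted, not averaged.
    """

    per_label: dict[str, tuple[float, float, int]]  # label -> (roc, pr, n_pos)
    macro_roc_auc: float
    macro_pr_auc: float
    n_labels_evaluated: int
    n_labels_skipped: int = 0


def featurize(dataset: ChefDataset, n_bits: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """(X, Y): molecule×bit fingerprints and molecule×label incidence.

    Row order matches the dataset's molecule order and Y's columns match
    the vocabulary order.  Molecules are already canonical, so fingerprint
    failure should not occur; if it does the offender is reported.
    """
    X = fingerprint_molecules([m.smiles for m in dataset.molecules], n_bits)
    Y = np.asarray(dataset.incidence.todense(), dtype=bool)
    return X, Y


def split_train_test(
    n_molecules: int | ChefDataset, cfg: ModelConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random disjoint, exhaustive train/test split (seeded)."""
    cfg = cfg or ModelConfig()
    n = n_molecules if isinstance(n_molecules, int) else n_molecules.n_molecules
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_test = int(round(n * cfg.test_fraction))
    n_test = min(max(n_test, 1), n - 1) if n > 1 else n_test
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


class FunctionPredictor(BaseEstimator):
    """Multi-label classifier from binary fingerprints to function labels.

    Parameters mirror :class:`ModelConfig`.  ``fit(X, Y)`` expects a binary
    indicator matrix Y; labels with no positive (or no negative) training
    example are marked untrainable and predicted at their training
    prevalence.  Deterministic given ``seed``.

    Attributes (after fit): ``labels_`` (label names), ``trainable_mask_``,
    ``estimators_`` (per-label models, or the single MLP as ``net_``),
    ``n_features_in_``.
    """

    def __init__(
        self,
        model_kind: str = "logistic",
        logistic_C: float = 0.001,
        logistic_max_iter: int = 1000,
        rf_n_estimators: int = 100,
        rf_max_depth: int = 10,
        mlp_hidden: tuple[int, int] = (512, 256),
        mlp_epochs: int = 5,
        mlp_dropout: float = 0.2,
        mlp_batch_size: int = 32,
        mlp_learning_rate: float = 0.001,
        seed: int = 0,
    ) -> None:
        self.model_kind = model_kind
        self.logistic_C = logistic_C
        self.logistic_max_iter = logistic_max_iter
        self.rf_n_estimators = rf_n_estimators
        self.rf_max_depth = rf_max_depth
        self.mlp_hidden = mlp_hidden
        self.mlp_epochs = mlp_epochs
        self.mlp_dropout = mlp_dropout
        self.mlp_batch_size = mlp_batch_size
        self.mlp_learning_rate = mlp_learning_rate
        self.seed = seed

    @classmethod
    def from_config(cls, cfg: ModelConfig) -> "FunctionPredictor":
        return cls(
            model_kind=cfg.model_kind,
            logistic_C=cfg.logistic_C,
            logistic_max_iter=cfg.logistic_max_iter,
            rf_n_estimators=cfg.rf_n_estimators,
            rf_max_depth=cfg.rf_max_depth,
            mlp_hidden=cfg.mlp_hidden,
            mlp_epochs=cfg.mlp_epochs,
            mlp_dropout=cfg.mlp_dropout,
            mlp_batch_size=cfg.mlp_batch_size,
            mlp_learning_rate=cfg.mlp_learning_rate,
            seed=cfg.seed,
        )

    def _base_estimator(self):
        if self.model_kind == "logistic":
            return LogisticRegression(
                C=self.logistic_C, max_iter=self.logistic_max_iter
            )
        if self.model_kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.rf_n_estimators,
                max_depth=self.rf_max_depth,
                random_state=self.seed,
            )
        raise ValueError(f"unknown model_kind: {self.model_kind!r}")

    def fit(self, X, Y, label_names: Sequence[str] | None = None) -> "FunctionPredictor":
        X = check_array(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=bool)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y row counts differ")
        self.n_features_in_ = X.shape[1]
        n_labels = Y.shape[1]
        self.labels_ = (
            list(label_names) if label_names is not None else [str(j) for j in range(n_labels)]
        )
        if len(self.labels_) != n_labels:
            raise ValueError("label_names length must match Y columns")
        pos = Y.sum(axis=0)
        self.trainable_mask_ = (pos >= 1) & (pos <= Y.shape[0] - 1)
        self.prevalence_ = Y.mean(axis=0)
        if np.all(X == X[0]):
            logger.warning("degenerate features: all rows identical")
        if self.model_kind == "mlp":
            cols = np.where(self.trainable_mask_)[0]
            self._mlp_cols_ = cols
            self.net_ = MLPClassifier(
                hidden_layer_sizes=tuple(self.mlp_hidden),
                batch_size=self.mlp_batch_size,
                learning_rate_init=self.mlp_learning_rate,
                max_iter=self.mlp_epochs,
                solver="adam",
                random_state=self.seed,
            )
            if len(cols):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # few-epoch non-convergence
                    self.net_.fit(X, Y[:, cols].astype(int))
            self.estimators_ = None
        else:
            base = self._base_estimator()
            self.estimators_ = []
            for j in range(n_labels):
                if not self.trainable_mask_[j]:
                    self.estimators_.append(None)
                    continue
                est = clone(base)
                if hasattr(est, "random_state"):
                    est.random_state = self.seed + j
                est.fit(X, Y[:, j].astype(int))
                self.estimators_.append(est)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n, n_labels) label probabilities; untrainable labels get their
        training prevalence as a constant score."""
        check_is_fitted(self, "labels_")
        X = check_array(X, dtype=np.float64)
        n = X.shape[0]
        out = np.tile(self.prevalence_, (n, 1))
        if self.model_kind == "mlp":
            if len(self._mlp_cols_):
                proba = self.net_.predict_proba(X)
                proba = np.asarray(proba)
                if proba.ndim == 1:
                    proba = proba[:, None]
                # single-output MLPClassifier returns (n, 2)
                if len(self._mlp_cols_) == 1 and proba.shape[1] == 2:
                    proba = proba[:, 1:]
                out[:, self._mlp_cols_] = proba
        else:
            for j, est in enumerate(self.estimators_):
                if est is not None:
                    out[:, j] = est.predict_proba(X)[:, 1]
        return out

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(X) >= threshold

    def label_index(self, label: str) -> int:
        check_is_fitted(self, "labels_")
        try:
            return self.labels_.index(label)
        except ValueError as exc:
            raise KeyError(f"unknown label: {label!r}") from exc


def train_model(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    cfg: ModelConfig | None = None,
    label_names: Sequence[str] | None = None,
) -> FunctionPredictor:
    """Fit a :class:`FunctionPredictor` per the config."""
    cfg = cfg or ModelConfig()
    return FunctionPredictor.from_config(cfg).fit(X_train, Y_train, label_names)


def evaluate(
    model: FunctionPredictor, X_test: np.ndarray, Y_test: np.ndarray
) -> ModelEval:
    """Per-label ROC-AUC / PR-AUC on the test set plus macro averages.

    Only labels with at least one positive and one negative test example
    are evaluated; the macro averages are unweighted means over those.
    """
    if len(X_test) == 0:
        raise ValueError("empty test set")
    Y_test = np.asarray(Y_test, dtype=bool)
    scores = model.predict_proba(X_test)
    per_label: dict[str, tuple[float, float, int]] = {}
    skipped = 0
    for j, label in enumerate(model.labels_):
        y = Y_test[:, j]
        n_pos = int(y.sum())
        if n_pos == 0 or n_pos == len(y):
            skipped += 1
            continue
        roc = float(roc_auc_score(y, scores[:, j]))
        pr = float(average_precision_score(y, scores[:, j]))
        per_label[label] = (roc, pr, n_pos)
    if per_label:
        rocs, prs, _ = zip(*per_label.values())
        macro_roc, macro_pr = float(np.mean(rocs)), float(np.mean(prs))
    else:
        macro_roc = macro_pr = float("nan")
    return ModelEval(
        per_label=per_label,
        macro_roc_auc=macro_roc,
        macro_pr_auc=macro_pr,
        n_labels_evaluated=len(per_label),
        n_labels_skipped=skipped,
    )


def rank_molecules_for_label(
    model: FunctionPredictor,
    X: np.ndarray,
    label: str,
    k: int = 10,
) -> list[tuple[int, float]]:
    """Top-k molecule indices by predicted probability for ``label``.

    Descending score; ties broken by dataset order (stable sort).  ``k``
    larger than the pool returns everything; ``k=0`` returns [].
    """
    j = model.label_index(label)
    scores = model.predict_proba(X)[:, j]
    order = np.argsort(-scores, kind="stable")
    return [(int(i), float(scores[i])) for i in order[: max(k, 0)]]


def predict_profile(
    model: FunctionPredictor, smiles: str, n_bits: int = 2048
) -> dict[str, float]:
    """Full functional profile (label → probability) for one structure."""
    canonical = canonicalize_smiles(smiles)
    if canonical is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    X = fingerprint_molecules([canonical], n_bits).astype(float)
    probs = model.predict_proba(X)[0]
    return dict(zip(model.labels_, map(float, probs)))
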
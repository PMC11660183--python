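"""Multi-label store-name classification.

The production-scale system this package mirrors fine-tunes an uncased
transformer encoder on labeled store names; that requires GPUs, licensed
training data, and weights that cannot be redistributed. The package
therefore ships a desk-scale **reference backend** — one-vs-rest regularized
logistic scorers over word and character n-grams of the normalized name —
behind the same contract (train on name/label-set examples, emit a raw score
in [0, 1] per class, threshold at 0.5). The surrounding pipeline is
backend-agnostic: a transformer backend plugs in by honoring the same
``train``/``predict_scores`` signatures on uncased text.

Training mirrors the published protocol shape: candidate models along a
regularization path are checkpointed and the state with the best validation
macro-F1 is retained, stopping after ``patience`` non-improving evaluations
(the analogue of early stopping on validation macro-F1). Optimizer fields
(learning rate 1e-6, beta1 0.9, beta2 0.999) are carried in the config for
the transformer contract; the reference backend does not use them.

Model/Results surface: :class:`StoreNameClassifier` is the model object built
from data; its :meth:`~StoreNameClassifier.fit` returns
:class:`StoreNameClassifierResults` holding the fitted state, validation
metrics and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression

from .classes import FoodClass, LabelSet, N_CLASSES, labelset_to_vector
from .datasets import LabeledExample, normalize_name
from .metrics import MetricsReport, confusion_counts, summarize

__all__ = [
    "TrainingConfig",
    "NameModel",
    "StoreNameClassifier",
    "StoreNameClassifierResults",
    "train",
    "predict_scores",
    "threshold_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyperparameters for training a name classifier.

    ``backend='reference'`` selects the n-gram logistic backend.
    ``backend='transformer'`` is a contract for GPU users and is not
    implemented here; its optimizer fields (learning_rate, beta1, beta2) are
    recorded for that contract. ``max_epochs`` bounds the number of
    regularization-path checkpoints evaluated and ``patience`` the number of
    consecutive non-improving checkpoints tolerated before stopping.
    """

    backend: str = "reference"
    learning_rate: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    early_stopping_metric: str = "validation_macro_f1"
    patience: int = 2
    max_epochs: int = 8
    threshold: float = 0.5
    regularization_strength: float = 1.0
    word_ngram_range: Tuple[int, int] = (1, 2)
    char_ngram_range: Tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# Regularization path evaluated as "epochs": weak -> strong fits, mirroring a
# model that improves checkpoint by checkpoint until validation F1 plateaus.
_C_LADDER = (0.01, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)


@dataclass
class NameModel:
    """A fitted multi-label name classifier (reference backend state)."""

    word_vectorizer: TfidfVectorizer
    char_vectorizer: TfidfVectorizer
    scorers: Dict[FoodClass, Optional[LogisticRegression]]
    threshold: float
    manifest: dict = field(default_factory=dict)

    def _features(self, normalized_names: Sequence[str]) -> sp.spmatrix:
        return sp.hstack(
            [
                self.word_vectorizer.transform(normalized_names),
                self.char_vectorizer.transform(normalized_names),
            ],
            format="csr",
        )

    def score_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Raw scores, shape (n_names, 10), in the fixed class order."""
        normalized = []
        for i, name in enumerate(names):
            try:
                normalized.append(normalize_name(name))
            except ValueError as exc:
                raise ValueError(f"name at index {i} is invalid: {exc}") from exc
        X = self._features(normalized)
        scores = np.zeros((len(normalized), N_CLASSES))
        for c, clf in self.scorers.items():
            if clf is None:
                continue  # degenerate class: constant score 0
            if isinstance(clf, float):  # constant scorer (single-class train)
                scores[:, c.index] = clf
            else:
                scores[:, c.index] = clf.predict_proba(X)[:, 1]
        return scores

    def save(self, path: str | Path) -> None:
        # sklearn vectorizers cache id(stop_words) — a memory address — which
        # would break the byte-identical serialization contract; drop it.
        for vec in (self.word_vectorizer, self.char_vectorizer):
            vec.__dict__.pop("_stop_words_id", None)
        with open(path, "wb") as fh:
            pickle.dump(self, fh, protocol=4)

    @staticmethod
    def load(path: str | Path) -> "NameModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, NameModel):
            raise ValueError(f"{path} does not contain a NameModel")
        return model


def _fit_checkpoint(
    X: sp.spmatrix, Y: np.ndarray, C: float, seed: int
) -> Dict[FoodClass, Optional[LogisticRegression]]:
    scorers: Dict[FoodClass, Optional[LogisticRegression]] = {}
    for c in FoodClass:
        y = Y[:, c.index]
        if y.sum() == 0:
            logger.warning(
                "class %s has no positive training examples; scorer is constant 0",
                c.value,
            )
            scorers[c] = None
        elif y.sum() == len(y):
            scorers[c] = 1.0  # type: ignore[assignment]
        else:
            clf = LogisticRegression(
                C=C,
                solver="lbfgs",
                max_iter=2000,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
            scorers[c] = clf
    return scorers


def _data_hash(examples: Sequence[LabeledExample]) -> str:
    h = hashlib.sha256()
    for e in examples:
        h.update(e.normalized_name.encode())
        h.update(bytes(labelset_to_vector(e.labels)))
    return h.hexdigest()[:16]


def train(
    train_set: Sequence[LabeledExample],
    validation_set: Sequence[LabeledExample],
    cfg: TrainingConfig | None = None,
) -> NameModel:
    """Fit the reference backend with early stopping on validation macro-F1.

    Checkpoints along a regularization path are evaluated on the validation
    set; the best-scoring state is retained and the search stops after
    ``cfg.patience`` consecutive non-improving checkpoints (or
    ``cfg.max_epochs`` checkpoints). Deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainingConfig()
    if cfg.backend != "reference":
        raise NotImplementedError(
            f"backend {cfg.backend!r} is a contract only; this package "
            "implements the 'reference' backend"
        )
    if not train_set or not validation_set:
        raise ValueError("train and validation sets must be non-empty")
    train_names = {e.normalized_name for e in train_set}
    val_names = {e.normalized_name for e in validation_set}
    if train_names & val_names:
        raise ValueError("train and validation sets share normalized names")

    X_names = [e.normalized_name for e in train_set]
    word_vec = TfidfVectorizer(
        ngram_range=cfg.word_ngram_range, analyzer="word", sublinear_tf=True
    )
    char_vec = TfidfVectorizer(
        ngram_range=cfg.char_ngram_range, analyzer="char_wb", sublinear_tf=True
    )
    X = sp.hstack(
        [word_vec.fit_transform(X_names), char_vec.fit_transform(X_names)],
        format="csr",
    )
    Y = np.vstack([labelset_to_vector(e.labels) for e in train_set])

    val_raw = [e.normalized_name for e in validation_set]
    val_actual = [e.labels for e in validation_set]

    ladder = [cfg.regularization_strength * C for C in _C_LADDER[: cfg.max_epochs]]
    best_f1, best_scorers, best_epoch = -1.0, None, -1
    stale = 0
    for epoch, C in enumerate(ladder):
        scorers = _fit_checkpoint(X, Y, C, cfg.seed)
        probe = NameModel(
            word_vectorizer=word_vec,
            char_vectorizer=char_vec,
            scorers=scorers,
            threshold=cfg.threshold,
        )
        preds = [
            threshold_scores(s, cfg.threshold)
            for s in probe.score_matrix(val_raw)
        ]
        macro = summarize(confusion_counts(preds, val_actual)).macro_f1
        if macro > best_f1:
            best_f1, best_scorers, best_epoch = macro, scorers, epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    manifest = {
        "config": asdict(cfg),
        "train_data_hash": _data_hash(list(train_set)),
        "n_train": len(train_set),
        "n_validation": len(validation_set),
        "stopped_epoch": best_epoch,
        "best_validation_macro_f1": best_f1,
    }
    return NameModel(
        word_vectorizer=word_vec,
        char_vectorizer=char_vec,
        scorers=best_scorers,
        threshold=cfg.threshold,
        manifest=manifest,
    )


def predict_scores(model: NameModel, names: Sequence[str]) -> np.ndarray:
    """Score raw names; rows follow input order, columns the fixed class order."""
    return model.score_matrix(names)


def threshold_scores(scores: Sequence[float], threshold: float = 0.5) -> LabelSet:
    """Convert one raw score vector into a label set (class held iff score >= t)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    arr = np.asarray(scores, dtype=float)
    if arr.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} scores, got shape {arr.shape}")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return frozenset(c for c in FoodClass if arr[c.index] >= threshold)


def predictions_frame(
    model: NameModel, names: Sequence[str], threshold: float | None = None
) -> pd.DataFrame:
    """Raw-score + Boolean prediction table, one row per input name."""
    t = model.threshold if threshold is None else threshold
    scores = predict_scores(model, names)
    data = {"name": list(names)}
    for c in FoodClass:
        data[f"score_{c.value}"] = scores[:, c.index]
    for c in FoodClass:
        data[f"label_{c.value}"] = scores[:, c.index] >= t
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class StoreNameClassifier:
    """Multi-label store-name classification model built from labeled examples.

    Parameters
    ----------
    train_set, validation_set
        Name-disjoint lists of :class:`~foodenv.datasets.LabeledExample`.
    config
        Optional :class:`TrainingConfig`; defaults to the reference backend.
    """

    def __init__(
        self,
        train_set: Sequence[LabeledExample],
        validation_set: Sequence[LabeledExample],
        config: TrainingConfig | None = None,
    ):
        self.train_set = list(train_set)
        self.validation_set = list(validation_set)
        self.config = config or TrainingConfig()

    @classmethod
    def from_split(cls, split, config: TrainingConfig | None = None):
        """Build from a :class:`~foodenv.datasets.DatasetSplit`."""
        return cls(split.train, split.validation, config)

    def fit(self) -> "StoreNameClassifierResults":
        model = train(self.train_set, self.validation_set, self.config)
        return StoreNameClassifierResults(self, model)


class StoreNameClassifierResults:
    """Fitted classifier state with validation diagnostics."""

    def __init__(self, model_spec: StoreNameClassifier, model: NameModel):
        self.model_spec = model_spec
        self.model = model
        self._val_report: MetricsReport | None = None

    @property
    def manifest(self) -> dict:
        return self.model.manifest

    def predict_scores(self, names: Sequence[str]) -> np.ndarray:
        return predict_scores(self.model, names)

    def predict(self, names: Sequence[str]) -> List[LabelSet]:
        scores = self.predict_scores(names)
        return [threshold_scores(s, self.model.threshold) for s in scores]

    def predictions_frame(self, names: Sequence[str]) -> pd.DataFrame:
        return predictions_frame(self.model, names)

    def evaluate(self, examples: Sequence[LabeledExample]) -> MetricsReport:
        preds = self.predict([e.normalized_name for e in examples])
        return summarize(confusion_counts(preds, [e.labels for e in examples]))

    @property
    def validation_report(self) -> MetricsReport:
        if self._val_report is None:
            self._val_report = self.evaluate(self.model_spec.validation_set)
        return self._val_report

    def summary(self) -> str:
        """Human-readable training + validation summary table."""
        rep = self.validation_report
        lines = [
            "Store-name multi-label classifier (reference backend)",
            f"  train examples:      {self.manifest['n_train']}",
            f"  validation examples: {self.manifest['n_validation']}",
            f"  stopped at checkpoint {self.manifest['stopped_epoch']} "
            f"(best validation macro-F1 {self.manifest['best_validation_macro_f1']:.3f})",
            "",
            rep.to_frame().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            f"  validation micro-F1: {rep.micro_f1:.3f}",
            f"  validation macro-F1: {rep.macro_f1:.3f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.model.save(path)
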
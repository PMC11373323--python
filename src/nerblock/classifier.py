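"""Masked-context entity-type classification.

Classifies masked context windows into the five classes
(ggp, che, dis, org, neg) with normalized class probabilities.

Two backends share one interface:

* ``reference`` — a hashed bag-of-words representation fed to a
  multinomial softmax (logistic) regression.  Fully deterministic given a
  seed, trains in seconds, and needs no pretrained weights.  All tests and
  desk-scale runs use it.
* ``transformer`` — a fine-tuning harness around a pretrained biomedical
  BERT model.  Training one requires GPU-scale resources and pretrained
  weights, so this backend only validates its configuration and raises a
  clear error when the ``transformers``/``torch`` stack is unavailable.

Both emit per-example probability distributions over the five labels in the
fixed order ggp, che, dis, org, neg.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.feature_extraction.text import HashingVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score

from .consensus import LABELS, ContextExample

__all__ = [
    "LABELS",
    "ClassProbabilities",
    "TrainConfig",
    "DegenerateTrainingError",
    "UntrainedModelError",
    "MissingBackendError",
    "ContextClassifier",
    "train",
    "predict_proba",
    "evaluate_micro_f1",
    "hyperparameter_grid",
]

ClassProbabilities = Mapping[str, float]


class DegenerateTrainingError(ValueError):
    """Training set has fewer than two classes."""


class UntrainedModelError(RuntimeError):
    """predict_proba called before training."""


class MissingBackendError(RuntimeError):
    """The transformer backend's dependencies are not installed."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are the selected values: learning rate 2e-5 and batch size 32
    (best grid combination), one epoch for the final large-scale training,
    maximum sequence length 256 sub-word tokens, and a 200-word context
    (100 words on each side of the mask).  The reference backend only
    consumes ``seed``; the remaining fields parameterize the transformer
    harness.
    """

    learning_rate: float = 2e-5
    batch_size: int = 32
    epochs: int = 1
    max_seq_length: int = 256
    context_words: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "epochs", "max_seq_length", "context_words"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def hyperparameter_grid() -> list[TrainConfig]:
    """The full selection grid: 5 learning rates x 2 batch sizes x 3 epoch
    counts, at fixed max sequence length 256 and 200-word contexts."""
    rates = (5e-5, 3e-5, 2e-5, 1e-5, 5e-6)
    batches = (32, 64)
    epochs = (2, 3, 4)
    return [
        TrainConfig(learning_rate=lr, batch_size=b, epochs=e)
        for lr, b, e in itertools.product(rates, batches, epochs)
    ]


def _truncate(text: str, max_tokens: int, mask: str = "[MASK]") -> str:
    """Truncate symmetrically around the mask token when too long."""
    words = text.split()
    if len(words) <= max_tokens:
        return text
    try:
        center = next(i for i, w in enumerate(words) if mask in w)
    except StopIteration:
        center = len(words) // 2
    half = max_tokens // 2
    lo = max(0, center - half)
    hi = min(len(words), lo + max_tokens)
    lo = max(0, hi - max_tokens)
    return " ".join(words[lo:hi])


class ContextClassifier:
    """Hashed bag-of-words softmax-regression scorer (reference backend)."""

    backend = "reference"

    def __init__(self, config: TrainConfig | None = None) -> None:
        self.config = config or TrainConfig()
        self._vectorizer = HashingVectorizer(
            n_features=2**18, alternate_sign=False, norm="l2"
        )
        self._clf: LogisticRegression | None = None
        self.labels: tuple[str, ...] = LABELS

    @property
    def is_trained(self) -> bool:
        return self._clf is not None

    def _features(self, examples: Sequence[ContextExample]):
        texts = [
            _truncate(ex.text, self.config.max_seq_length) for ex in examples
        ]
        return self._vectorizer.transform(texts)

    def fit(self, dataset: Sequence[ContextExample]) -> "ContextClassifier":
        if not dataset:
            raise DegenerateTrainingError("empty training set")
        labels = sorted({ex.label for ex in dataset})
        if len(labels) < 2:
            raise DegenerateTrainingError(
                f"training needs >= 2 classes, got only {labels}"
            )
        rng = np.random.default_rng(self.config.seed)
        order = rng.permutation(len(dataset))
        shuffled = [dataset[i] for i in order]
        X = self._features(shuffled)
        y = np.array([ex.label for ex in shuffled])
        self._clf = LogisticRegression(
            max_iter=1000,
            C=10.0,
            random_state=self.config.seed,
        )
        self._clf.fit(X, y)
        return self

    def predict_proba(
        self, examples: Sequence[ContextExample]
    ) -> list[dict[str, float]]:
        if self._clf is None:
            raise UntrainedModelError("model has not been trained")
        if not examples:
            return []
        P = self._clf.predict_proba(self._features(examples))
        seen = {lbl: i for i, lbl in enumerate(self._clf.classes_)}
        out = []
        for row in P:
            probs = {lbl: float(row[seen[lbl]]) if lbl in seen else 0.0 for lbl in self.labels}
            total = sum(probs.values())
            out.append({k: v / total for k, v in probs.items()})
        return out

    def predict(self, examples: Sequence[ContextExample]) -> list[str]:
        return [
            max(p, key=p.__getitem__) for p in self.predict_proba(examples)
        ]

    # --- persistence: metadata JSON + weights file ---------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "backend": self.backend,
            "config": asdict(self.config),
            "labels": list(self.labels),
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self._clf, path / "weights.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "ContextClassifier":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        if meta["backend"] != "reference":
            raise MissingBackendError(
                f"cannot load backend {meta['backend']!r} as a reference model"
            )
        model = cls(TrainConfig(**meta["config"]))
        model.labels = tuple(meta["labels"])
        model._clf = joblib.load(path / "weights.joblib")
        return model


class TransformerHarness:
    """Interface to fine-tune a pretrained masked-language model.

    Validates data and configuration, then delegates to the
    ``transformers`` stack.  Kept as a thin harness: the full fine-tune is
    a GPU-scale job outside desk scope.
    """

    backend = "transformer"

    def __init__(
        self, config: TrainConfig | None = None, model_name: str = "dmis-lab/biobert-base-cased-v1.1"
    ) -> None:
        self.config = config or TrainConfig()
        self.model_name = model_name

    def fit(self, dataset: Sequence[ContextExample]) -> "TransformerHarness":
        if len({ex.label for ex in dataset}) < 2:
            raise DegenerateTrainingError("training needs >= 2 classes")
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:
            raise MissingBackendError(
                "the transformer backend requires the 'transformers' and "
                "'torch' packages and pretrained weights; install them or "
                "use backend='reference'"
            ) from exc
        raise NotImplementedError(
            "full-scale fine-tuning is intentionally not bundled; see the "
            "methods note"
        )


def train(
    dataset: Sequence[ContextExample],
    config: TrainConfig | None = None,
    backend: str = "reference",
) -> ContextClassifier:
    """Train a masked-context entity-type classifier."""
    if backend == "reference":
        return ContextClassifier(config).fit(dataset)
    if backend == "transformer":
        return TransformerHarness(config).fit(dataset)  # type: ignore[return-value]
    raise ValueError(f"unknown backend {backend!r}")


def predict_proba(
    model: ContextClassifier, examples: Sequence[ContextExample]
) -> list[dict[str, float]]:
    """One probability distribution per example, order-aligned."""
    return model.predict_proba(examples)


def evaluate_micro_f1(
    model: ContextClassifier, examples: Sequence[ContextExample]
) -> float:
    """Micro-averaged F1 over all five labels (equals accuracy here,
    since every example carries exactly one label)."""
    if not examples:
        raise ValueError("cannot evaluate on an empty example set")
    y_true = [ex.label for ex in examples]
    y_pred = model.predict(examples)
    return float(f1_score(y_true, y_pred, average="micro"))
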
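"""The phenotype confirmation classifier.

A logistic regression on mention vectors decides whether a candidate
mention-UMLS link asserts a real phenotype of the patient. Trained either on
weakly labelled data (rule-partitioned, no annotation) or on manually
labelled pairs; only the recorded provenance differs. The "default
configuration" fit is pinned explicitly — L2 penalty, inverse regularisation
strength 1.0, tolerance 1e-4, up to 100 iterations — and recorded in
``train_meta`` so results reproduce across library versions.

Inference is the closed-form sigmoid on the stored weights, so a serialised
model is a plain JSON document independent of the fitting library. The
decision rule is ``probability >= threshold`` (tie to positive,
recall-biased); the default threshold is 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .encoder import MentionVector
from .links import CandidateLink
from .weak import WeakDataset


@dataclass
class TrainMeta:
    n_used: int
    seed: int
    reg_strength: float
    converged: bool


@dataclass
class ConfirmationModel:
    weights: np.ndarray
    bias: float
    threshold: float = 0.5
    provenance: str = "weak"  # "weak" or "strong"
    train_meta: TrainMeta | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("model weights must be finite")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie strictly between 0 and 1")

    @property
    def dim(self) -> int:
        return int(self.weights.shape[0])


def fit_confirmation_model(
    vectors: list[MentionVector],
    labels: list[int],
    reg_strength: float = 1.0,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    provenance: str = "weak",
    threshold: float = 0.5,
) -> ConfirmationModel:
    """L2-regularised binomial maximum-likelihood fit, deterministic per seed."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels differ in length")
    if len(vectors) < 2:
        raise ValueError("need at least two training examples")
    classes = set(labels)
    if classes != {0, 1}:
        raise ValueError(f"both classes required for training, got labels {sorted(classes)}")
    dims = {vector.v.shape[0] for vector in vectors}
    if len(dims) != 1:
        raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")

    X = np.stack([vector.v for vector in vectors])
    y = np.asarray(labels, dtype=int)
    # default penalty is L2; the strength is the inverse-regularisation C
    clf = LogisticRegression(
        C=reg_strength,
        tol=tol,
        max_iter=max_iter,
        solver="lbfgs",
        random_state=seed,
    )
    clf.fit(X, y)
    converged = bool(np.all(clf.n_iter_ < max_iter))
    return ConfirmationModel(
        weights=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        threshold=threshold,
        provenance=provenance,
        train_meta=TrainMeta(
            n_used=len(vectors), seed=seed, reg_strength=reg_strength, converged=converged
        ),
    )


def subsample_training(
    dataset: WeakDataset, n: int = 9000, seed: int = 0
) -> tuple[list[CandidateLink], list[int]]:
    """Uniform sample without replacement of min(n, |labelled|) labelled pairs."""
    pool = dataset.labelled
    rng = np.random.default_rng(seed)
    take = min(n, len(pool))
    indices = rng.choice(len(pool), size=take, replace=False) if take else []
    links = [pool[i][0] for i in indices]
    labels = [pool[i][1] for i in indices]
    return links, labels


def predict_confirmation(
    model: ConfirmationModel, vector: MentionVector
) -> tuple[float, int]:
    """(probability, decision); decision = 1 iff probability >= threshold."""
    if vector.v.shape[0] != model.dim:
        raise ValueError(
            f"vector dimension {vector.v.shape[0]} does not match model dimension {model.dim}"
        )
    probability = float(expit(model.weights @ vector.v + model.bias))
    return probability, int(probability >= model.threshold)


def confirm_links(
    links: list[CandidateLink],
    vectors: list[MentionVector],
    model: ConfirmationModel,
) -> list[tuple[CandidateLink, float]]:
    """Links the model confirms, order preserved, each with its probability."""
    if len(links) != len(vectors):
        raise ValueError("links and vectors differ in length")
    confirmed = []
    for link, vector in zip(links, vectors):
        probability, decision = predict_confirmation(model, vector)
        if decision:
            confirmed.append((link, probability))
    return confirmed


def save_model(model: ConfirmationModel, path: str | Path) -> None:
    document = {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "threshold": model.threshold,
        "provenance": model.provenance,
        "train_meta": asdict(model.train_meta) if model.train_meta else None,
    }
    Path(path).write_text(json.dumps(document), encoding="utf-8")


def load_model(path: str | Path) -> ConfirmationModel:
    document = json.loads(Path(path).read_text(encoding="utf-8"))
    meta = document.get("train_meta")
    return ConfirmationModel(
        weights=np.asarray(document["weights"], dtype=float),
        bias=float(document["bias"]),
        threshold=float(document["threshold"]),
        provenance=document.get("provenance", "weak"),
        train_meta=TrainMeta(**meta) if meta else None,
    )
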
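"""AdaBoost fusion of the three multi-scale CNNs.

The three networks are boosted sequentially on one shared training set:
CNN-1 is trained on the 32-cubes under the uniform sample distribution, its
weighted training error e_1 gives the coefficient
``alpha_1 = 1/2 ln((1 - e_1)/e_1)`` and a reweighting that raises the weight
of its mistakes; CNN-2 then trains on the 64-cubes under the new
distribution, and CNN-3 on the 96-cubes likewise.  The fused classifier is
``f(x) = sign(sum_k alpha_k G_k(x))`` over the three hard votes; a
normalized soft margin over the member probabilities provides the
continuous score needed for FROC analysis.

Each candidate is one boosting sample with one weight — its three scale
cubes travel together through every round.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np

from .networks import ARCH_NAMES, TrainConfig, build_model, train_cnn

__all__ = [
    "WeightedTrainingSet",
    "WeakClassifier",
    "EnsembleModel",
    "init_weights",
    "weighted_error",
    "classifier_coefficient",
    "update_weights",
    "hard_votes",
    "boost",
    "fit_acnn",
    "predict_label",
    "decision_score",
    "score_batch",
]

EPS_ERROR = 1e-10
_SCALE_BY_MEMBER = {0: 32, 1: 64, 2: 96}


@dataclass
class WeightedTrainingSet:
    """Samples (multi-scale cubes, labels in {-1,+1}) plus the boosting weights."""

    cubes: dict[int, np.ndarray]  # edge -> (m, edge, edge, edge)
    labels: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        m = len(self.labels)
        if self.weights is None:
            self.weights = init_weights(m)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != m:
            raise ValueError("weights and samples must have equal length")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        for edge, arr in self.cubes.items():
            if arr.shape[0] != m:
                raise ValueError(f"cube array for edge {edge} has wrong length")

    @property
    def m(self) -> int:
        return len(self.labels)


@dataclass
class WeakClassifier:
    """A trained member with its weighted error and log-odds coefficient."""

    model: Any
    alpha: float
    error: float
    input_edge: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.error < 1):
            raise ValueError(f"error must lie in (0, 1), got {self.error}")
        expected = classifier_coefficient(self.error)
        if abs(self.alpha - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(
                f"alpha {self.alpha} inconsistent with error {self.error}"
            )


@dataclass
class EnsembleModel:
    """Ordered weak classifiers; the fused model uses exactly three (CNN-1..3)."""

    members: list[WeakClassifier]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    @property
    def alphas(self) -> np.ndarray:
        return np.array([m.alpha for m in self.members])


# ---------------------------------------------------------------------------
# Boosting primitives
# ---------------------------------------------------------------------------

def init_weights(m: int) -> np.ndarray:
    """Uniform initial distribution: every weight exactly 1/m."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return np.full(m, 1.0 / m)


def weighted_error(
    predictions: Sequence[int], labels: Sequence[int], weights: Sequence[float]
) -> float:
    """e_k = sum of weights over misclassified samples, clipped to (0, 1)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=np.float64)
    if not (len(predictions) == len(labels) == len(weights)):
        raise ValueError("predictions, labels and weights must have equal length")
    err = float(np.sum(weights[predictions != labels]))
    return float(np.clip(err, EPS_ERROR, 1.0 - EPS_ERROR))


def classifier_coefficient(error: float) -> float:
    """alpha_k = 1/2 ln((1 - e_k)/e_k); natural log, decreasing in e_k."""
    if not (0 < error < 1):
        raise ValueError(f"error must lie strictly in (0, 1), got {error}")
    return 0.5 * np.log((1.0 - error) / error)


def update_weights(
    weights: Sequence[float],
    alpha: float,
    predictions: Sequence[int],
    labels: Sequence[int],
) -> np.ndarray:
    """Next-round distribution: w'_i ∝ w_i exp(-alpha y_i G(x_i)), renormalized.

    With alpha > 0, misclassified samples (y_i G_i = -1) gain weight and
    correctly classified ones lose it.
    """
    weights = np.asarray(weights, dtype=np.float64)
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    unnorm = weights * np.exp(-alpha * labels * predictions)
    z = unnorm.sum()
    return unnorm / z


def hard_votes(probabilities: np.ndarray) -> np.ndarray:
    """Map member probabilities to {-1, +1} votes; the p = 0.5 tie votes +1."""
    return np.where(np.asarray(probabilities) >= 0.5, 1, -1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def boost(
    trainers: Sequence[Callable[[np.ndarray], tuple[Any, np.ndarray]]],
    labels: Sequence[int],
    input_edges: Sequence[int] | None = None,
) -> tuple[EnsembleModel, dict]:
    """Run sequential boosting over arbitrary member trainers.

    Each trainer maps the current weight distribution to a fitted member and
    its {-1,+1} predictions on the training set.  Returns the ensemble plus
    a history dict with the per-round weight vectors, errors and alphas.
    """
    labels = np.asarray(labels)
    weights = init_weights(len(labels))
    members: list[WeakClassifier] = []
    history: dict = {"weights": [weights.copy()], "errors": [], "alphas": []}
    for k, trainer in enumerate(trainers):
        model, predictions = trainer(weights)
        err = weighted_error(predictions, labels, weights)
        alpha = classifier_coefficient(err)
        if err >= 0.5:
            warnings.warn(
                f"boosting round {k + 1}: weighted error {err:.3f} >= 0.5; "
                "member kept with non-positive alpha",
                stacklevel=2,
            )
        edge = input_edges[k] if input_edges is not None else None
        members.append(WeakClassifier(model, alpha, err, edge))
        weights = update_weights(weights, alpha, predictions, labels)
        history["weights"].append(weights.copy())
        history["errors"].append(err)
        history["alphas"].append(alpha)
    return EnsembleModel(members), history


def fit_acnn(
    dataset: WeightedTrainingSet,
    configs: Sequence[TrainConfig] | TrainConfig,
    seed: int = 0,
    profile: str = "tiny",
) -> tuple[EnsembleModel, dict]:
    """Boost CNN-1 (32-cubes) -> CNN-2 (64) -> CNN-3 (96) on one training set.

    Member errors are computed from test-mode (zero-offset) predictions on
    the training set after each member finishes training.
    """
    if isinstance(configs, TrainConfig):
        configs = [configs] * 3
    if len(configs) != 3:
        raise ValueError("need one TrainConfig per member (3)")
    for edge in (32, 64, 96):
        if edge not in dataset.cubes:
            raise ValueError(f"dataset lacks the {edge}-cube scale")
    labels = dataset.labels
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be in {-1, +1}")

    seed_rng = np.random.default_rng(seed)
    member_seeds = seed_rng.integers(0, 2**31 - 1, size=3)

    def make_trainer(k: int):
        name = ARCH_NAMES[k]
        edge = _SCALE_BY_MEMBER[k]
        cfg = configs[k]

        def trainer(weights: np.ndarray):
            member_cfg = TrainConfig(
                learning_rate=cfg.learning_rate,
                weight_decay=cfg.weight_decay,
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                seed=int(member_seeds[k]),
                rt_relu_sigma=cfg.rt_relu_sigma,
            )
            model = build_model(
                name, profile=profile, seed=int(member_seeds[k]),
                sigma=cfg.rt_relu_sigma,
            )
            model, probs = train_cnn(
                model, dataset.cubes[edge], labels, weights, member_cfg
            )
            return model, hard_votes(probs)

        return trainer

    trainers = [make_trainer(k) for k in range(3)]
    return boost(trainers, labels, input_edges=[32, 64, 96])


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _member_probability(member: WeakClassifier, patch) -> float:
    if hasattr(member.model, "predict_proba"):
        edge = member.input_edge or member.model.spec.input_edge
        return float(member.model.predict_proba(patch.cube(edge))[0])
    # stub members used in tests expose a plain callable
    return float(member.model(patch))


def predict_label(ensemble: EnsembleModel, patch) -> int:
    """Fused hard decision: sign(sum_k alpha_k G_k(x)); the exact tie maps to +1."""
    total = 0.0
    for member in ensemble.members:
        p = _member_probability(member, patch)
        vote = 1 if p >= 0.5 else -1
        total += member.alpha * vote
    return 1 if total >= 0 else -1


def decision_score(ensemble: EnsembleModel, patch) -> float:
    """Continuous fused score in [-1, 1]: sum_k alpha_k (2 p_k - 1) / sum_k |alpha_k|."""
    denom = float(np.sum(np.abs(ensemble.alphas)))
    if denom == 0:
        raise ValueError("all member coefficients are zero; score undefined")
    total = sum(
        member.alpha * (2.0 * _member_probability(member, patch) - 1.0)
        for member in ensemble.members
    )
    return float(total / denom)


def score_batch(
    ensemble: EnsembleModel, cubes: dict[int, np.ndarray], batch_size: int = 16
) -> np.ndarray:
    """Vectorized decision scores for many candidates (edge -> cube stack)."""
    denom = float(np.sum(np.abs(ensemble.alphas)))
    if denom == 0:
        raise ValueError("all member coefficients are zero; score undefined")
    n = next(iter(cubes.values())).shape[0]
    total = np.zeros(n)
    for member in ensemble.members:
        edge = member.input_edge or member.model.spec.input_edge
        probs = member.model.predict_proba(cubes[edge], batch_size=batch_size)
        total += member.alpha * (2.0 * probs - 1.0)
    return total / denom


def save_manifest(
    ensemble: EnsembleModel,
    path: str | Path,
    checkpoints: Sequence[str] | None = None,
    seed: int | None = None,
) -> Path:
    """Write the ensemble manifest: member order, alphas, errors, checkpoints."""
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "order": [ARCH_NAMES[k] for k in range(len(ensemble.members))],
                "alphas": [m.alpha for m in ensemble.members],
                "errors": [m.error for m in ensemble.members],
                "input_edges": [m.input_edge for m in ensemble.members],
                "checkpoints": list(checkpoints) if checkpoints else None,
                "seed": seed,
            },
            indent=2,
        )
    )
    return path
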
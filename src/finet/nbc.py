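"""Naïve Bayes classifier over nine-feature protein-pair evidence.

The classifier scores the probability that a protein pair reflects a
functional pathway event.  Training positives are FIs extracted from
curated pathways (filtered to pairs with at least one true feature);
negatives are random pairs over the same protein universe.  The scoring
prior is the pair-density prior — positives over all possible pairs of
the positive-set proteins — and is deliberately independent of the
negative:positive training ratio, which only controls how the
class-conditional feature probabilities are estimated.

Class-conditional probabilities use Laplace add-one smoothing so that no
likelihood is ever exactly 0 or 1; scores are accumulated in log space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from ._sampling import sample_pairs
from .features import FEATURES
from .pathway import FunctionalInteraction

__all__ = [
    "TrainingSet",
    "NBCModel",
    "ROCResult",
    "compute_prior",
    "sample_negative_pairs",
    "train_nbc",
    "score_pair",
    "score_matrix",
    "evaluate_roc",
    "predict_fis",
]

Pair = Tuple[str, str]


def compute_prior(n_positive_pairs: int, n_proteins: int) -> float:
    """Pair-density prior: positives over C(n_proteins, 2)."""
    if n_proteins < 2:
        raise ValueError("need at least two proteins")
    total = n_proteins * (n_proteins - 1) // 2
    if not 0 < n_positive_pairs <= total:
        raise ValueError(
            f"n_positive_pairs must be in (0, {total}], got {n_positive_pairs}"
        )
    return n_positive_pairs / total


def sample_negative_pairs(
    universe: Sequence[str],
    positives: Set[Pair],
    n: int,
    seed: Optional[int] = None,
) -> Set[Pair]:
    """n random pairs over the universe, excluding known positives.

    Uniform without replacement; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    return sample_pairs(universe, n, rng, exclude_pairs=positives)


@dataclass
class TrainingSet:
    """Positive/negative feature matrices and their size ratio."""

    positives: pd.DataFrame
    negatives: pd.DataFrame
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.positives.empty or self.negatives.empty:
            raise ValueError("both training classes must be non-empty")
        overlap = self.positives.index.intersection(self.negatives.index)
        if len(overlap):
            raise ValueError(f"{len(overlap)} pairs appear in both classes")
        if not self.positives.any(axis=1).all():
            raise ValueError("every positive must have at least one feature")
        self.ratio = len(self.negatives) / len(self.positives)


@dataclass
class NBCModel:
    """Trained model: prior, per-feature conditionals, score threshold."""

    prior: float
    theta_pos: Dict[str, float]
    theta_neg: Dict[str, float]
    threshold: float = 0.50
    feature_names: Tuple[str, ...] = FEATURES
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.prior < 1:
            raise ValueError("prior must be in (0, 1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        for th in (self.theta_pos, self.theta_neg):
            for name, v in th.items():
                if not 0 < v < 1:
                    raise ValueError(f"theta[{name}] must be in (0, 1)")

    def to_json(self, path) -> None:
        obj = {
            "prior": self.prior,
            "theta_pos": self.theta_pos,
            "theta_neg": self.theta_neg,
            "threshold": self.threshold,
            "feature_names": list(self.feature_names),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NBCModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            prior=obj["prior"],
            theta_pos=obj["theta_pos"],
            theta_neg=obj["theta_neg"],
            threshold=obj["threshold"],
            feature_names=tuple(obj["feature_names"]),
            meta=obj.get("meta", {}),
        )


def train_nbc(
    ts: TrainingSet, prior: float, threshold: float = 0.50
) -> NBCModel:
    """Estimate Laplace-smoothed conditionals from a training set.

    theta[f|class] = (count of f true in class + 1) / (class size + 2).
    """
    names = tuple(ts.positives.columns)
    if tuple(ts.negatives.columns) != names:
        raise ValueError("positive and negative feature columns differ")
    n_pos = len(ts.positives)
    n_neg = len(ts.negatives)
    theta_pos = {
        f: (int(ts.positives[f].sum()) + 1) / (n_pos + 2) for f in names
    }
    theta_neg = {
        f: (int(ts.negatives[f].sum()) + 1) / (n_neg + 2) for f in names
    }
    return NBCModel(
        prior=prior,
        theta_pos=theta_pos,
        theta_neg=theta_neg,
        threshold=threshold,
        feature_names=names,
        meta={"n_positives": n_pos, "n_negatives": n_neg, "ratio": ts.ratio},
    )


def _log_likelihoods(model: NBCModel, df: pd.DataFrame) -> np.ndarray:
    x = df[list(model.feature_names)].to_numpy(dtype=bool)
    tp = np.array([model.theta_pos[f] for f in model.feature_names])
    tn = np.array([model.theta_neg[f] for f in model.feature_names])
    lp = np.where(x, np.log(tp), np.log1p(-tp)).sum(axis=1)
    ln = np.where(x, np.log(tn), np.log1p(-tn)).sum(axis=1)
    return lp, ln


def score_matrix(model: NBCModel, df: pd.DataFrame) -> pd.Series:
    """Posterior P(FI | features) for every row; log-space accumulation."""
    lp, ln = _log_likelihoods(model, df)
    log_odds = (math.log(model.prior) + lp) - (
        math.log1p(-model.prior) + ln
    )
    post = 1.0 / (1.0 + np.exp(-log_odds))
    return pd.Series(post, index=df.index, name="score")


def score_pair(model: NBCModel, vector) -> float:
    """Posterior for a single feature vector (mapping or sequence)."""
    if isinstance(vector, dict):
        row = [bool(vector.get(f, False)) for f in model.feature_names]
    else:
        row = [bool(v) for v in vector]
        if len(row) != len(model.feature_names):
            raise ValueError("vector length does not match model features")
    df = pd.DataFrame([row], columns=list(model.feature_names))
    return float(score_matrix(model, df).iloc[0])


@dataclass
class ROCResult:
    """ROC points, trapezoid AUC, and operating point at the threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    sensitivity: float
    specificity: float

    @property
    def points(self):
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def evaluate_roc(
    model: NBCModel, test_pos: pd.DataFrame, test_neg: pd.DataFrame
) -> ROCResult:
    """ROC over every distinct score on an independent test set."""
    if test_pos.empty or test_neg.empty:
        raise ValueError("both test classes must be non-empty")
    s_pos = score_matrix(model, test_pos).to_numpy()
    s_neg = score_matrix(model, test_neg).to_numpy()
    scores = np.concatenate([s_pos, s_neg])
    labels = np.concatenate(
        [np.ones_like(s_pos), np.zeros_like(s_neg)]
    )
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    sens = float((s_pos >= model.threshold).mean())
    spec = float((s_neg < model.threshold).mean())
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr,
        auc=auc, sensitivity=sens, specificity=spec,
    )


def predict_fis(
    model: NBCModel, candidates: pd.DataFrame
) -> Set[FunctionalInteraction]:
    """Pairs with >=1 true feature scoring at or above the threshold.

    The one-feature rule mirrors the training-set filter: a pair with no
    evidence at all is never called, whatever the prior implies.
    """
    has_feature = candidates.any(axis=1)
    scores = score_matrix(model, candidates)
    keep = has_feature & (scores >= model.threshold)
    return {
        FunctionalInteraction(pair=(a, b), provenance="predicted")
        for a, b in candidates.index[keep]
    }
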
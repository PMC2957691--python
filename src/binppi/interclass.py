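"""Integration of per-channel evidence into a single reliability score.

Two combiners are provided. The noisy-OR rule treats each channel's
value as an independent probability that the pair truly interacts and
returns ``1 - prod(1 - p_i)`` — any single strong evidence suffices for
a high score. The linear max-margin classifier fits a hyperplane over
the feature vectors and ranks pairs by signed distance to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .net_io import ProteinPair

MODEL_KINDS = ("noisy_or", "linear_svm")
FEATURE_MODES = ("raw", "bin_confidence")


def noisy_or_combine(probabilities: Iterable[float]) -> float:
    """``1 - prod(1 - p_i)`` over per-channel probabilities in [0, 1].

    Monotone nondecreasing in every input, permutation invariant, and
    exactly 1 as soon as any input is 1. No clipping is applied.
    """
    p = np.asarray(list(probabilities), dtype=float)
    if p.size == 0:
        raise ValueError("noisy-OR needs at least one probability")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError(f"probabilities must lie in [0, 1], got {p}")
    return float(1.0 - np.prod(1.0 - p))


@dataclass
class ReliabilityModel:
    """A trained pair-reliability scorer.

    For ``noisy_or`` only the channel list (and optionally a per-channel
    raw->probability min/max map) is stored; the decision value is the
    noisy-OR of the per-channel probabilities. For ``linear_svm`` the
    learned weights and bias define the decision function. In ``raw``
    feature mode, features are min-max scaled per channel with the
    training-time ranges; ``bin_confidence`` features are used as-is
    (already in [0, 1]).
    """

    kind: str
    channels: list[str]
    feature_mode: str = "bin_confidence"
    weights: list[float] | None = None
    bias: float | None = None
    scale_min: list[float] | None = None
    scale_max: list[float] | None = None

    def _validate_features(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.channels if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks model channels: {missing}")
        return features[self.channels]

    def _scaled(self, x: np.ndarray) -> np.ndarray:
        if self.scale_min is None:
            return x
        lo = np.asarray(self.scale_min)
        span = np.asarray(self.scale_max) - lo
        span[span == 0] = 1.0
        return np.clip((x - lo) / span, 0.0, 1.0)

    def decision_values(self, features: pd.DataFrame) -> np.ndarray:
        x = self._validate_features(features).to_numpy(dtype=float)
        x = self._scaled(x)
        if self.kind == "noisy_or":
            if np.isnan(x).any() or (x < 0).any() or (x > 1).any():
                raise ValueError(
                    "noisy-OR inputs must be probabilities in [0, 1]; "
                    "supply bin-confidence features or a raw->probability scaling"
                )
            return 1.0 - np.prod(1.0 - x, axis=1)
        return x @ np.asarray(self.weights) + self.bias


def train_classifier(
    features: pd.DataFrame,
    labels: Sequence[int],
    kind: str,
    feature_mode: str = "bin_confidence",
    C: float = 1.0,
) -> ReliabilityModel:
    """Fit a reliability model on labeled feature vectors.

    ``features`` is a pair-indexed table with one column per channel and
    no missing values (the fill policy is applied upstream); ``labels``
    are 1 for positive, 0 for negative pairs, and both classes must be
    present. ``noisy_or`` needs no fitting beyond recording the channel
    list (plus the min-max probability map in raw mode); ``linear_svm``
    solves the max-margin problem with a linear kernel.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; options: {MODEL_KINDS}")
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {feature_mode!r}")
    y = np.asarray(list(labels), dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both a positive and a negative class")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values; apply the fill policy first")
    channels = list(features.columns)
    x = features.to_numpy(dtype=float)

    scale_min = scale_max = None
    if feature_mode == "raw":
        scale_min = x.min(axis=0).tolist()
        scale_max = x.max(axis=0).tolist()

    model = ReliabilityModel(
        kind=kind,
        channels=channels,
        feature_mode=feature_mode,
        scale_min=scale_min,
        scale_max=scale_max,
    )
    if kind == "noisy_or":
        if feature_mode == "bin_confidence" and ((x < 0).any() or (x > 1).any()):
            raise ValueError("bin-confidence features must lie in [0, 1]")
        return model
    svc = SVC(kernel="linear", C=C, random_state=0)
    svc.fit(model._scaled(x), y)
    model.weights = svc.coef_.ravel().tolist()
    model.bias = float(svc.intercept_[0])
    return model


def score_pairs(model: ReliabilityModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score every pair and rank by decision value.

    Returns a pair-indexed frame with a ``decision`` column, sorted
    descending; ties fall back to canonical pair order.
    """
    if len(features) == 0:
        return pd.DataFrame({"decision": []}, index=features.index)
    decisions = model.decision_values(features)
    ranked = pd.DataFrame({"decision": decisions}, index=features.index)
    order = sorted(range(len(ranked)), key=lambda i: (-decisions[i], features.index[i]))
    return ranked.iloc[order]


# ---------------------------------------------------------------------
# model persistence (self-describing JSON)
# ---------------------------------------------------------------------

def save_model(model: ReliabilityModel, path: str | Path) -> None:
    doc = {
        "kind": model.kind,
        "channels": model.channels,
        "feature_mode": model.feature_mode,
        "weights": model.weights,
        "bias": model.bias,
        "scale_min": model.scale_min,
        "scale_max": model.scale_max,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> ReliabilityModel:
    doc = json.loads(Path(path).read_text())
    return ReliabilityModel(**doc)
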
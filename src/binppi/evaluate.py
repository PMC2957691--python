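"""Evaluation protocol: cross-validated AUC per method, mu sweeps,
false-negative candidate generation and top-k GO-similarity curves.

Every "method" is a classifier over the labeled pairs: each single
evidence channel acts as its own classifier (decision value = the raw
score, or the Bin-Confidence of the score), and the integrated models
(noisy-OR, linear SVM) combine all channels. Bin partitions are rebuilt
inside each training fold so no test-fold information leaks into the
calibration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .evidence import EvidenceTable
from .interbin import BinPartition, transform_table
from .interclass import train_classifier
from .labels import LabeledPairSet
from .net_io import InteractionNetwork, ProteinPair

logger = logging.getLogger(__name__)

#: integrated methods; anything else names a single evidence channel
INTEGRATED_METHODS = ("noisy_or", "linear_svm")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, rank-statistic tie handling (ties count
    half). Requires both classes."""
    y = np.asarray(list(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both a positive and a negative class")
    return float(roc_auc_score(y, np.asarray(list(scores), dtype=float)))


@dataclass
class CVReport:
    """Per-method cross-validation result."""

    method: str
    feature_mode: str  # "raw" | "bin_confidence"
    mu_rel: float
    fold_aucs: list[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def default_methods(channels: Iterable[str]) -> list[tuple[str, str]]:
    """Every channel and both integrated models, in both feature modes."""
    out = []
    for ch in channels:
        out += [(ch, "raw"), (ch, "bin_confidence")]
    for m in INTEGRATED_METHODS:
        out += [(m, "raw"), (m, "bin_confidence")]
    return out


def fit_fold(
    table: EvidenceTable,
    labels: LabeledPairSet,
    train_pairs: Sequence[ProteinPair],
    mu_rel: float,
) -> tuple[dict[str, BinPartition], pd.DataFrame]:
    """Build per-channel bin partitions on the training pairs only and
    return them with the Bin-Confidence features for *all* table pairs
    (test pairs get values by interval lookup)."""
    return transform_table(
        table, labels.positives, labels.negatives, mu_rel, training_pairs=train_pairs
    )


def _method_decisions(
    method: str,
    mode: str,
    raw: pd.DataFrame,
    bin_conf: pd.DataFrame,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Decision values on the test rows for one (method, feature-mode)."""
    feats = raw if mode == "raw" else bin_conf
    if method in INTEGRATED_METHODS:
        # in raw mode the model's training-fold min-max map supplies the
        # raw->probability normalization the noisy-OR needs
        model = train_classifier(feats.iloc[train_idx], y[train_idx], method, feature_mode=mode)
        return model.decision_values(feats.iloc[test_idx])
    if method not in feats.columns:
        raise ValueError(f"unknown method {method!r}; channels: {list(feats.columns)}")
    return feats.iloc[test_idx][method].to_numpy()


def cross_validate(
    table: EvidenceTable,
    labels: LabeledPairSet,
    k: int = 5,
    mu_rel: float = 0.01,
    methods: Sequence[tuple[str, str]] | None = None,
    seed: int = 0,
) -> list[CVReport]:
    """Stratified k-fold CV over the labeled pairs.

    Within each fold the bin partitions are built on the training fold
    only; test-fold Bin-Confidences come from interval lookup. Single
    channel methods use the score/confidence directly as the decision
    value; integrated models are trained on the fold.
    """
    train_pairs_all = sorted(labels.positives) + sorted(labels.negatives)
    present = set(table.pairs)
    train_pairs_all = [p for p in train_pairs_all if p in present]
    y = np.array([1 if p in labels.positives else 0 for p in train_pairs_all])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(f"need >= {k} pairs per class, have {n_pos} positives / {n_neg} negatives")
    if methods is None:
        methods = default_methods(table.channels)

    labeled_table = table.subset(train_pairs_all)
    raw = labeled_table.filled()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = {m: CVReport(m[0], m[1], mu_rel, []) for m in methods}
    for train_idx, test_idx in skf.split(raw.to_numpy(), y):
        fold_train_pairs = [train_pairs_all[i] for i in train_idx]
        _, bin_conf = fit_fold(labeled_table, labels, fold_train_pairs, mu_rel)
        for method, mode in methods:
            decisions = _method_decisions(
                method, mode, raw, bin_conf, train_idx, test_idx, y
            )
            reports[(method, mode)].fold_aucs.append(auc(decisions, y[test_idx]))
    return list(reports.values())


def mu_sweep(
    table: EvidenceTable,
    labels: LabeledPairSet,
    mu_grid: Sequence[float],
    methods: Sequence[tuple[str, str]] | None = None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV AUC per (method, feature mode, mu_rel) over a grid of
    relative group sizes."""
    if len(mu_grid) == 0:
        raise ValueError("mu grid is empty")
    rows = []
    for mu_rel in mu_grid:
        for report in cross_validate(table, labels, k=k, mu_rel=mu_rel, methods=methods, seed=seed):
            rows.append(
                {
                    "method": report.method,
                    "feature_mode": report.feature_mode,
                    "mu_rel": mu_rel,
                    "mean_auc": report.mean_auc,
                }
            )
    return pd.DataFrame(rows)


def fn_candidates(net: InteractionNetwork, min_common: int = 2) -> list[ProteinPair]:
    """Non-adjacent pairs with at least ``min_common`` common neighbors —
    the candidate pool for predicting undetected (false-negative)
    interactions. Deterministic canonical order."""
    if min_common < 1:
        raise ValueError(f"min_common must be >= 1, got {min_common}")
    counts: dict[ProteinPair, int] = {}
    for hub in net.proteins:
        nbrs = sorted(net.neighbors(hub))
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                pair = ProteinPair(nbrs[i], nbrs[j])
                counts[pair] = counts.get(pair, 0) + 1
    return sorted(
        p for p, c in counts.items() if c >= min_common and not net.has_edge(p)
    )


def topk_similarity_curve(
    ranked: pd.DataFrame,
    similarities: Mapping[ProteinPair, float],
    ks: Sequence[int],
) -> tuple[list[tuple[int, float]], int]:
    """Mean GO similarity of the top-k ranked pairs, for each k.

    ``ranked`` is a pair-indexed frame sorted by decision value
    descending (as produced by ``interclass.score_pairs``). Pairs with
    no similarity value are skipped (their count is returned); k beyond
    the usable list is truncated with a warning.
    """
    values = []
    skipped = 0
    for pair in ranked.index:
        sim = similarities.get(pair)
        if sim is None:
            skipped += 1
        else:
            values.append(float(sim))
    curve = []
    for k in ks:
        kk = min(k, len(values))
        if kk < k:
            warnings.warn(
                f"top-{k} requested but only {len(values)} pairs have similarity; truncating"
            )
        if kk == 0:
            curve.append((k, float("nan")))
        else:
            curve.append((k, float(np.mean(values[:kk]))))
    return curve, skipped
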
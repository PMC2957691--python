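"""Tie-respecting equal-frequency binning of raw evidence scores.

Training pairs are sorted by raw score (best first) and cut greedily
into groups of at least mu pairs; a group absorbs every pair tying the
score at its boundary, and a too-small final group is merged into its
predecessor. Each bin's confidence is the fraction of its training
pairs that are positive — the calibrated "Bin-Confidence" feature value
assigned to every pair whose score falls in that bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import EvidenceTable
from .net_io import ProteinPair

logger = logging.getLogger(__name__)


@dataclass
class Bin:
    """One score group: contiguous score interval, its training members,
    and the positive fraction (confidence)."""

    score_high: float
    score_low: float
    member_pairs: list[ProteinPair]
    size: int
    positives: int
    confidence: float


@dataclass
class BinPartition:
    """Ordered bins (best scores first) for one evidence channel."""

    channel: str
    mu_abs: int
    mu_rel: float
    bins: list[Bin]

    # cached lookup arrays, built lazily
    _thresholds: np.ndarray | None = field(default=None, repr=False, compare=False)
    _confidences: np.ndarray | None = field(default=None, repr=False, compare=False)

    def _lookup_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self._thresholds is None:
            # decision boundary between consecutive bins: midpoint of the
            # gap; exact midpoints resolve to the higher-score bin
            lows = np.array([b.score_low for b in self.bins])
            highs = np.array([b.score_high for b in self.bins])
            self._thresholds = (lows[:-1] + highs[1:]) / 2.0
            self._confidences = np.array([b.confidence for b in self.bins])
        return self._thresholds, self._confidences

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel,
                "bin": range(1, len(self.bins) + 1),
                "score_high": [b.score_high for b in self.bins],
                "score_low": [b.score_low for b in self.bins],
                "size": [b.size for b in self.bins],
                "positives": [b.positives for b in self.bins],
                "confidence": [b.confidence for b in self.bins],
            }
        )


def mu_absolute(n: int, mu_rel: float) -> int:
    """Convert the relative group size mu/n into an absolute count:
    ceil(n * mu_rel), floored at 1."""
    return max(1, math.ceil(n * mu_rel))


def partition_scores(
    scored_pairs: Sequence[tuple[ProteinPair, float]],
    positives: set[ProteinPair],
    mu_rel: float,
    channel: str = "",
) -> BinPartition:
    """Group labeled pairs by raw score into bins of >= mu members.

    ``scored_pairs`` must be the training pairs only (each labeled
    positive or negative; ``positives`` lists the positive ones). Pairs
    are sorted by score descending, ties broken by canonical pair for a
    deterministic partition. Groups are cut every mu pairs, extended to
    absorb all pairs tying the boundary score; if the final group falls
    short of mu it is merged into the penultimate one.
    """
    if not 0.0 < mu_rel <= 1.0:
        raise ValueError(f"mu_rel must be in (0, 1], got {mu_rel}")
    if len(scored_pairs) == 0:
        raise ValueError("cannot partition an empty score list")
    for pair, score in scored_pairs:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for {pair}")
    items = sorted(scored_pairs, key=lambda ps: (-ps[1], ps[0]))
    n = len(items)
    mu = mu_absolute(n, mu_rel)

    groups: list[list[tuple[ProteinPair, float]]] = []
    i = 0
    while i < n:
        j = min(i + mu, n)
        boundary = items[j - 1][1]
        while j < n and items[j][1] == boundary:
            j += 1
        groups.append(items[i:j])
        i = j
    if len(groups) > 1 and len(groups[-1]) < mu:
        groups[-2].extend(groups.pop())

    bins = []
    for group in groups:
        members = [p for p, _ in group]
        pos = sum(1 for p in members if p in positives)
        bins.append(
            Bin(
                score_high=group[0][1],
                score_low=group[-1][1],
                member_pairs=members,
                size=len(group),
                positives=pos,
                confidence=pos / len(group),
            )
        )
    if len(bins) == 1:
        logger.warning(
            "channel %s: a single bin covers all %d training pairs "
            "(scores carry no resolution at this mu)",
            channel,
            n,
        )
    return BinPartition(channel=channel, mu_abs=mu, mu_rel=mu_rel, bins=bins)


def bin_confidence_lookup(partition: BinPartition, score: float) -> float:
    """Confidence of the bin whose score interval contains ``score``.

    Scores above the global maximum clamp to the first bin, below the
    global minimum to the last; a score falling in the gap between two
    bins goes to the nearer boundary, exact midpoints to the
    higher-score bin.
    """
    return float(lookup_many(partition, np.array([score]))[0])


def lookup_many(partition: BinPartition, scores: np.ndarray) -> np.ndarray:
    """Vectorized :func:`bin_confidence_lookup`."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("NaN score in bin-confidence lookup")
    thresholds, confidences = partition._lookup_arrays()
    if len(thresholds) == 0:
        return np.full(scores.shape, confidences[0])
    # bin index = number of inter-bin thresholds strictly above the score
    idx = np.searchsorted(-thresholds, -scores, side="left")
    return confidences[idx]


def transform_table(
    table: EvidenceTable,
    positives: set[ProteinPair],
    negatives: set[ProteinPair],
    mu_rel: float,
    training_pairs: Sequence[ProteinPair] | None = None,
) -> tuple[dict[str, BinPartition], pd.DataFrame]:
    """Build one partition per channel on the labeled pairs and map every
    pair in the table to its per-channel Bin-Confidence.

    Missing raw scores are taken as 0 here (for both partitioning and
    lookup). ``training_pairs`` defaults to all of P u N that appear in
    the table; partitions never see any other pair's score.
    """
    if training_pairs is None:
        labeled = positives | negatives
        training_pairs = [p for p in table.pairs if p in labeled]
    training_pairs = list(training_pairs)
    missing = [p for p in training_pairs if p not in positives and p not in negatives]
    if missing:
        raise ValueError(f"{len(missing)} training pairs are unlabeled, e.g. {missing[0]}")
    if not training_pairs:
        raise ValueError("no labeled pairs present in the evidence table")

    filled = table.filled()
    train_filled = filled.loc[training_pairs]
    partitions: dict[str, BinPartition] = {}
    features = {}
    for channel in table.channels:
        scored = list(zip(training_pairs, train_filled[channel].to_numpy()))
        part = partition_scores(scored, positives, mu_rel, channel=channel)
        partitions[channel] = part
        features[channel] = lookup_many(part, filled[channel].to_numpy())
    feature_df = pd.DataFrame(features, index=table.pairs)
    return partitions, feature_df


def write_partitions(partitions: Mapping[str, BinPartition], path: str | Path) -> None:
    """Serialize partitions as one TSV (channel, bin, boundaries, size,
    positives, confidence)."""
    frames = [partitions[ch].to_frame() for ch in partitions]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
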
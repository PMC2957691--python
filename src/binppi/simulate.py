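"""Synthetic interactomes and evidence channels with planted truth.

The generator emulates the statistical regime the reliability method
assumes: a true interactome is drawn (Erdos-Renyi or a simple
duplication-divergence process), the *observed* network keeps each true
edge with probability ``1 - fn_rate`` and is contaminated with spurious
non-edges so that an expected ``fp_rate`` fraction of observed edges is
false; each evidence channel then draws a raw score per observed pair
from a Beta distribution conditional on the pair's true status
(true-pair scores skewed high, false-pair scores skewed low), withheld
for a ``1 - coverage`` fraction of pairs; training labels come from the
true status with an optional flip rate.

Because the conditional score densities are known in closed form, the
true interaction probability given a score is available exactly
(:func:`posterior_true_probability`), which is what calibration studies
compare empirical bin confidences against.

Randomness: one pseudo-random stream per component, spawned from the
master seed, so adding a channel never perturbs the network draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evidence import EvidenceTable
from .labels import LabeledPairSet
from .net_io import InteractionNetwork, ProteinPair


@dataclass(frozen=True)
class ChannelModel:
    """Score-generating model of one evidence channel.

    ``true_dist`` / ``false_dist`` are Beta(a, b) shape parameters for
    the raw score conditional on the pair's true status; ``coverage`` is
    the fraction of pairs for which the channel reports a value at all.
    """

    name: str
    true_dist: tuple[float, float]
    false_dist: tuple[float, float]
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must lie in [0, 1], got {self.coverage}")


#: channels of the default benchmark: three informative channels with
#: single-channel AUC engineered near 0.67-0.71, plus one uninformative
#: channel. Their score distributions deliberately differ wildly in
#: shape — ``topo_sparse`` masses near 0 (as common-neighbor scores do
#: on sparse networks), ``topo_path`` masses near 1 (as path-based
#: reliability scores do), ``genomic`` is middling with partial
#: coverage — the scale heterogeneity that makes raw-score integration
#: brittle and calibration worthwhile.
DEFAULT_CHANNELS = (
    ChannelModel("topo_sparse", (1.0, 2.4), (0.6, 3.2), coverage=1.0),
    ChannelModel("topo_path", (6.0, 0.7), (2.6, 0.8), coverage=1.0),
    ChannelModel("genomic", (2.6, 2.0), (2.0, 2.6), coverage=0.8),
    ChannelModel("uninformative", (6.0, 0.7), (6.0, 0.7), coverage=1.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; deterministic given ``seed``."""

    n_proteins: int = 1500
    model: str = "erdos_renyi"  # or "duplication_divergence"
    density: float = 0.0024  # ER edge probability / DD retention probability
    fp_rate: float = 0.5  # expected false fraction of observed edges
    fn_rate: float = 0.1  # probability a true edge goes undetected
    channels: tuple[ChannelModel, ...] = DEFAULT_CHANNELS
    label_noise: float = 0.0
    n_labeled_per_class: int | None = 1000  # None labels every observed edge
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.fp_rate, self.fn_rate, self.label_noise):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {rate}")
        if self.fp_rate >= 1.0:
            raise ValueError("fp_rate must be < 1")
        if not self.channels:
            raise ValueError("at least one evidence channel is required")
        if self.model not in ("erdos_renyi", "duplication_divergence"):
            raise ValueError(f"unknown interactome model {self.model!r}")


@dataclass
class SimulationResult:
    true_network: InteractionNetwork
    observed_network: InteractionNetwork
    evidence: EvidenceTable
    labels: LabeledPairSet
    true_status: dict[ProteinPair, bool]
    summary: dict = field(default_factory=dict)


def _protein_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"P{i:0{width}d}" for i in range(n)]


def _true_edges_er(names: Sequence[str], p: float, rng: np.random.Generator) -> set[ProteinPair]:
    n = len(names)
    edges: set[ProteinPair] = set()
    # draw the edge count, then sample distinct pairs by index
    n_possible = n * (n - 1) // 2
    m = rng.binomial(n_possible, p)
    if m > n_possible:
        raise ValueError("infeasible density")
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:
        i = rng.integers(0, n, size=m - len(chosen))
        j = rng.integers(0, n, size=m - len(chosen))
        for a, b in zip(i.tolist(), j.tolist()):
            if a != b:
                chosen.add((min(a, b), max(a, b)))
                if len(chosen) == m:
                    break
    for a, b in chosen:
        edges.add(ProteinPair(names[a], names[b]))
    return edges


def _true_edges_dd(
    names: Sequence[str], retention: float, rng: np.random.Generator
) -> set[ProteinPair]:
    """Duplication-divergence: each new protein copies a random anchor's
    neighbors, keeping each with the retention probability, and always
    links to its anchor."""
    adj: dict[int, set[int]] = {0: {1}, 1: {0}}
    for v in range(2, len(names)):
        anchor = int(rng.integers(0, v))
        kept = {u for u in adj[anchor] if rng.random() < retention}
        kept.add(anchor)
        adj[v] = kept
        for u in kept:
            adj[u].add(v)
    edges = set()
    for u, nbrs in adj.items():
        for v in nbrs:
            if u < v:
                edges.add(ProteinPair(names[u], names[v]))
    return edges


def generate(config: SimulationConfig) -> SimulationResult:
    """Draw one synthetic dataset; identical seeds give identical output."""
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(4 + len(config.channels))
    rng_net = np.random.default_rng(streams[0])
    rng_obs = np.random.default_rng(streams[1])
    rng_labels = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])
    channel_rngs = [np.random.default_rng(s) for s in streams[4:]]

    names = _protein_names(config.n_proteins)
    if config.model == "erdos_renyi":
        true_edges = _true_edges_er(names, config.density, rng_net)
    else:
        true_edges = _true_edges_dd(names, config.density, rng_net)

    true_net = InteractionNetwork()
    for pair in sorted(true_edges):
        true_net.add_edge(pair.a, pair.b, scale="unknown", sources=("truth",))

    # observation: drop true edges, add spurious non-edges
    kept = [p for p in sorted(true_edges) if rng_obs.random() >= config.fn_rate]
    n_kept = len(kept)
    spurious: set[ProteinPair] = set()
    if config.fp_rate > 0 and n_kept > 0:
        target_false = n_kept * config.fp_rate / (1.0 - config.fp_rate)
        n_idx = len(names)
        n_possible = n_idx * (n_idx - 1) // 2
        q = min(1.0, target_false / max(1, n_possible - len(true_edges)))
        # rejection-sample candidate pairs; expected count = target_false
        n_draw = rng_obs.binomial(n_possible, q)
        while len(spurious) < n_draw:
            i = rng_obs.integers(0, n_idx, size=2 * (n_draw - len(spurious)) + 8)
            j = rng_obs.integers(0, n_idx, size=i.size)
            for a, b in zip(i.tolist(), j.tolist()):
                if a == b:
                    continue
                pair = ProteinPair(names[a], names[b])
                if pair in true_edges or pair in spurious:
                    continue
                spurious.add(pair)
                if len(spurious) == n_draw:
                    break

    observed_net = InteractionNetwork()
    true_status: dict[ProteinPair, bool] = {}
    for pair in kept:
        observed_net.add_edge(pair.a, pair.b, scale="high_throughput", sources=("simulated",))
        true_status[pair] = True
    for pair in sorted(spurious):
        observed_net.add_edge(pair.a, pair.b, scale="high_throughput", sources=("simulated",))
        true_status[pair] = False

    pairs = sorted(true_status)
    truth = np.array([true_status[p] for p in pairs], dtype=bool)

    # evidence channels
    columns = {}
    for model, rng_ch in zip(config.channels, channel_rngs):
        scores = draw_channel_scores(model, truth, rng_ch)
        columns[model.name] = scores
    evidence = EvidenceTable(pd.DataFrame(columns, index=pairs, dtype=float))

    # labels from true status (optionally subsampled and/or flipped)
    true_pairs = [p for p, t in zip(pairs, truth.tolist()) if t]
    false_pairs = [p for p, t in zip(pairs, truth.tolist()) if not t]
    if config.n_labeled_per_class is None:
        lab_true, lab_false = true_pairs, false_pairs
    else:
        k = config.n_labeled_per_class
        if k > len(true_pairs) or k > len(false_pairs):
            raise ValueError(
                f"cannot label {k} per class: only {len(true_pairs)} true and "
                f"{len(false_pairs)} false observed edges"
            )
        lab_true = [true_pairs[i] for i in rng_labels.choice(len(true_pairs), k, replace=False)]
        lab_false = [false_pairs[i] for i in rng_labels.choice(len(false_pairs), k, replace=False)]

    labels = LabeledPairSet()
    for pair, is_true in [(p, True) for p in lab_true] + [(p, False) for p in lab_false]:
        flipped = config.label_noise > 0 and rng_noise.random() < config.label_noise
        positive = is_true != flipped
        (labels.positives if positive else labels.negatives).add(pair)
        labels.provenance[pair] = "planted" + ("_flipped" if flipped else "")
    labels.unknown = set(pairs) - labels.positives - labels.negatives

    n_obs = len(pairs)
    summary = {
        "n_true_edges": len(true_edges),
        "n_observed_edges": n_obs,
        "false_edge_fraction": float((~truth).mean()) if n_obs else 0.0,
        "realized_coverage": {
            name: float(np.isfinite(col).mean()) for name, col in columns.items()
        },
    }
    return SimulationResult(true_net, observed_net, evidence, labels, true_status, summary)


def draw_channel_scores(
    model: ChannelModel, truth: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Raw scores for one channel given per-pair true status; NaN where
    the channel does not cover the pair."""
    n = len(truth)
    scores = np.empty(n)
    at, bt = model.true_dist
    af, bf = model.false_dist
    scores[truth] = rng.beta(at, bt, size=int(truth.sum()))
    scores[~truth] = rng.beta(af, bf, size=int((~truth).sum()))
    if model.coverage < 1.0:
        scores[rng.random(n) >= model.coverage] = np.nan
    return scores


def posterior_true_probability(
    model: ChannelModel, scores: np.ndarray, prior: float = 0.5
) -> np.ndarray:
    """Exact P(true pair | observed score) under the channel's Beta
    mixture with the given class prior."""
    scores = np.asarray(scores, dtype=float)
    ft = stats.beta.pdf(scores, *model.true_dist)
    ff = stats.beta.pdf(scores, *model.false_dist)
    return prior * ft / (prior * ft + (1.0 - prior) * ff)


def sample_labeled_scores(
    n: int, model: ChannelModel, prior: float, seed: int
) -> tuple[list[ProteinPair], np.ndarray, np.ndarray]:
    """Light-weight draw of ``n`` labeled scored pairs from one channel
    (no network), for calibration studies: returns (pairs, scores,
    truth)."""
    rng = np.random.default_rng(seed)
    truth = rng.random(n) < prior
    scores = draw_channel_scores(replace(model, coverage=1.0), truth, rng)
    width = len(str(2 * n))
    pairs = [ProteinPair(f"A{i:0{width}d}", f"B{i:0{width}d}") for i in range(n)]
    return pairs, scores, truth


def default_benchmark(seed: int) -> SimulationResult:
    """The package's standard synthetic benchmark: a 1500-protein
    Erdos-Renyi interactome, 10% detection dropout, 50% spurious
    observed edges, the four default channels, and 1000 positive + 1000
    negative noise-free training labels."""
    return generate(SimulationConfig(seed=seed))
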
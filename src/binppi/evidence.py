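"""Per-pair raw evidence scores and their assembly into an evidence table.

Three channels are computed directly from loaded data: a common-neighbor
topology score (a simplified FS-weight), absolute Pearson correlation of
expression profiles, and a count of interacting Pfam domain pairs. Any
other channel (BLAST bit-scores, IRAP, PathRatio, homologous-interaction
counts, ...) is ingested as a precomputed per-pair score column.

Missing values are kept missing (NaN) in the table; the fill-to-zero
policy is applied downstream, at binning/classification time, so the raw
table stays lossless.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .net_io import DomainData, InteractionNetwork, ProteinPair, common_neighbors

logger = logging.getLogger(__name__)

#: channels this module can compute itself
COMPUTED_CHANNELS = ("fs_weight", "gene_expr", "domain_ddi")


def fs_weight(net: InteractionNetwork, pair: ProteinPair) -> float:
    """Simplified FS-weight of an unordered pair.

    With N_x, N_y the direct-neighbor sets (x itself excluded; when the
    pair is an edge, each endpoint sits in the other's difference set)::

        2|N_x ∩ N_y|                       2|N_x ∩ N_y|
        ------------------------------  x  ------------------------------
        |N_x - N_y| + 2|N_x ∩ N_y| + 1     |N_y - N_x| + 2|N_x ∩ N_y| + 1

    Symmetric, in [0, 1), and 0 iff the pair has no common neighbor.
    """
    nx_set = net.neighbors(pair.a)
    ny_set = net.neighbors(pair.b)
    inter = len(nx_set & ny_set)
    if inter == 0:
        return 0.0
    dx = len(nx_set - ny_set)
    dy = len(ny_set - nx_set)
    return (2 * inter / (dx + 2 * inter + 1)) * (2 * inter / (dy + 2 * inter + 1))


def gene_expression_corr(expr: pd.DataFrame, pair: ProteinPair) -> float | None:
    """Absolute Pearson correlation of the two expression profiles.

    Returns ``None`` (missing) if either protein is absent from the
    matrix. A zero-variance profile makes the correlation undefined; the
    pair scores 0 and a warning is logged.
    """
    if pair.a not in expr.index or pair.b not in expr.index:
        return None
    x = expr.loc[pair.a].to_numpy(dtype=float)
    y = expr.loc[pair.b].to_numpy(dtype=float)
    sx = x - x.mean()
    sy = y - y.mean()
    denom = math.sqrt((sx * sx).sum() * (sy * sy).sum())
    if denom == 0.0:
        logger.warning("zero-variance expression profile in pair %s; scoring 0", pair)
        return 0.0
    return abs(float((sx * sy).sum()) / denom)


def domain_interaction_score(dd: DomainData, pair: ProteinPair) -> int:
    """Number of interacting domain combinations between the two proteins:
    ordered pairs (d_i from x, d_j from y) whose unordered domain pair is
    a known DDI. Unannotated proteins contribute an empty domain set."""
    dx = dd.domains(pair.a)
    dy = dd.domains(pair.b)
    return sum(1 for di in dx for dj in dy if dd.interacts(di, dj))


@dataclass
class ChannelSpec:
    """One evidence channel: either computed here or ingested as a
    precomputed per-pair score Series."""

    name: str
    kind: str  # "computed" | "ingested"
    scores: pd.Series | None = None  # ingested only; index of ProteinPair


@dataclass
class EvidenceTable:
    """Per-pair x per-channel raw scores; NaN marks a missing value."""

    data: pd.DataFrame  # index: ProteinPair, columns: channel names

    @property
    def pairs(self) -> list[ProteinPair]:
        return list(self.data.index)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def coverage(self) -> pd.Series:
        """Fraction of pairs with a present value, per channel."""
        if len(self.data) == 0:
            return pd.Series(0.0, index=self.data.columns)
        return self.data.notna().mean()

    def filled(self) -> pd.DataFrame:
        """Raw scores with missing values taken as 0 (the policy applied
        for binning and classification)."""
        return self.data.fillna(0.0)

    def subset(self, pairs: Sequence[ProteinPair]) -> "EvidenceTable":
        return EvidenceTable(self.data.loc[list(pairs)])


def compile_evidence_table(
    pairs: Sequence[ProteinPair],
    channels: Iterable[ChannelSpec],
    *,
    net: InteractionNetwork | None = None,
    expr: pd.DataFrame | None = None,
    domains: DomainData | None = None,
) -> EvidenceTable:
    """Evaluate/join every configured channel for the requested pairs.

    Computed channels need their input loaded (``fs_weight`` -> ``net``,
    ``gene_expr`` -> ``expr``, ``domain_ddi`` -> ``domains``); ingested
    channels are joined on the canonical pair. Coverage per channel is
    logged.
    """
    channels = list(channels)
    pairs = list(pairs)
    columns: dict[str, list[float]] = {}
    for spec in channels:
        if spec.kind == "computed":
            if spec.name == "fs_weight":
                if net is None:
                    raise ValueError("fs_weight channel requires a network")
                col = [fs_weight(net, p) for p in pairs]
            elif spec.name == "gene_expr":
                if expr is None:
                    raise ValueError("gene_expr channel requires an expression matrix")
                col = [
                    v if (v := gene_expression_corr(expr, p)) is not None else np.nan
                    for p in pairs
                ]
            elif spec.name == "domain_ddi":
                if domains is None:
                    raise ValueError("domain_ddi channel requires domain data")
                col = [float(domain_interaction_score(domains, p)) for p in pairs]
            else:
                raise ValueError(
                    f"unknown computed channel {spec.name!r}; "
                    f"available: {', '.join(COMPUTED_CHANNELS)}"
                )
        elif spec.kind == "ingested":
            if spec.scores is None:
                raise ValueError(f"ingested channel {spec.name!r} has no score table")
            col = [spec.scores.get(p, np.nan) for p in pairs]
        else:
            raise ValueError(f"unknown channel kind {spec.kind!r}")
        columns[spec.name] = col
    df = pd.DataFrame(columns, index=pairs, dtype=float)
    table = EvidenceTable(df)
    for name, cov in table.coverage.items():
        logger.info("channel %s: coverage %.3f", name, cov)
    return table
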
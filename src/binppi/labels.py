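"""Construction of training labels from detection metadata and GO
cellular-component similarity.

Positives are detected edges with trustworthy provenance: found by a
small-scale experiment, supported by at least ``min_experiments``
(default 3) wet-lab records, or carrying a configured trusted-source
tag (standing in for curated high-quality subsets). Negatives are
detected edges whose two proteins localize to different cellular
components — their GO cellular-component similarity falls below a
threshold (default 0.4). Everything else is of unknown status and is
what the classifiers are asked to adjudicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .gosim import SemanticSimilarity
from .net_io import GOData, InteractionNetwork, ProteinPair

logger = logging.getLogger(__name__)


@dataclass
class LabeledPairSet:
    """Disjoint positive / negative / unknown pair sets with per-pair
    provenance of the rule that fired."""

    positives: set[ProteinPair] = field(default_factory=set)
    negatives: set[ProteinPair] = field(default_factory=set)
    unknown: set[ProteinPair] = field(default_factory=set)
    provenance: dict[ProteinPair, str] = field(default_factory=dict)

    @property
    def universe(self) -> set[ProteinPair]:
        return self.positives | self.negatives | self.unknown

    def label_of(self, pair: ProteinPair) -> str:
        if pair in self.positives:
            return "P"
        if pair in self.negatives:
            return "N"
        if pair in self.unknown:
            return "U"
        raise KeyError(pair)

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("# proteinA\tproteinB\tlabel\tprovenance\n")
            for pair in sorted(self.universe):
                fh.write(
                    f"{pair.a}\t{pair.b}\t{self.label_of(pair)}\t"
                    f"{self.provenance.get(pair, '')}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledPairSet":
        out = cls()
        for lineno, line in enumerate(open(path), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields")
            pair = ProteinPair(tokens[0], tokens[1])
            label = tokens[2]
            target = {"P": out.positives, "N": out.negatives, "U": out.unknown}.get(label)
            if target is None:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            target.add(pair)
            if len(tokens) > 3 and tokens[3]:
                out.provenance[pair] = tokens[3]
        return out


def select_positives(
    net: InteractionNetwork,
    min_experiments: int = 3,
    trusted_sources: Iterable[str] = (),
) -> dict[ProteinPair, str]:
    """Detected edges qualifying as positives, with the rule that fired.

    An edge is positive iff its detection scale is ``small_scale``, or
    it is supported by >= ``min_experiments`` records, or it carries one
    of the ``trusted_sources`` tags.
    """
    trusted = set(trusted_sources)
    out: dict[ProteinPair, str] = {}
    for pair in net.edges:
        data = net.edge_data(pair)
        if data["scale"] == "small_scale":
            out[pair] = "small_scale"
        elif data["experiments"] >= min_experiments:
            out[pair] = f"experiments>={min_experiments}"
        elif trusted & set(data["sources"]):
            tag = sorted(trusted & set(data["sources"]))[0]
            out[pair] = f"trusted_source:{tag}"
    return out


def select_negatives(
    net: InteractionNetwork,
    go: GOData,
    threshold: float = 0.4,
    method: str = "lin",
    exclude_evidence: Iterable[str] = (),
) -> dict[ProteinPair, str]:
    """Detected edges whose proteins localize differently.

    An edge is a candidate negative iff both proteins carry at least one
    cellular-component annotation and their best-match-average CC
    similarity is strictly below ``threshold``. Edges with an
    unannotated endpoint never become negatives.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    sem = SemanticSimilarity(
        go,
        namespace="cellular_component",
        method=method,
        exclude_evidence=exclude_evidence,
    )
    out: dict[ProteinPair, str] = {}
    for pair in net.edges:
        sim = sem.protein_similarity(pair.a, pair.b)
        if sim is not None and sim < threshold:
            out[pair] = f"cc_similarity={sim:.3f}<{threshold}"
    return out


def assemble_labels(
    net: InteractionNetwork,
    positives: dict[ProteinPair, str] | Iterable[ProteinPair],
    negatives: dict[ProteinPair, str] | Iterable[ProteinPair],
) -> LabeledPairSet:
    """Combine the rule outputs over the network's edges.

    A pair qualifying under both rules resolves to positive (detection
    provenance trumps localization dissimilarity) and the conflict is
    logged. Unknown = edges not in P or N.
    """
    pos = positives if isinstance(positives, dict) else {p: "positive" for p in positives}
    neg = negatives if isinstance(negatives, dict) else {p: "negative" for p in negatives}
    labels = LabeledPairSet()
    conflicts = 0
    for pair in net.edges:
        if pair in pos:
            labels.positives.add(pair)
            labels.provenance[pair] = pos[pair]
            if pair in neg:
                conflicts += 1
        elif pair in neg:
            labels.negatives.add(pair)
            labels.provenance[pair] = neg[pair]
        else:
            labels.unknown.add(pair)
            labels.provenance[pair] = "unlabeled"
    if conflicts:
        logger.warning(
            "%d pairs met both the positive and negative rules; kept as positives",
            conflicts,
        )
    if not labels.negatives:
        logger.warning("no negative pairs selected; classifier training is impossible")
    return labels
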
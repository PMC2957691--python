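"""Readers, writers and the canonical pair/network abstractions.

Every other module consumes the types defined here: :class:`ProteinPair`
(an unordered, canonicalized pair of distinct protein identifiers),
:class:`InteractionNetwork` (a simple undirected graph with per-edge
detection metadata), plus typed containers for expression matrices,
domain annotations and Gene Ontology data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("small_scale", "high_throughput", "unknown")
# higher rank wins when duplicate records disagree
_SCALE_RANK = {"small_scale": 2, "high_throughput": 1, "unknown": 0}


class ParseError(ValueError):
    """A file did not parse under the expected dialect."""


@dataclass(frozen=True, order=True)
class ProteinPair:
    """An unordered pair of distinct protein identifiers.

    The two identifiers are stored in canonical (case-sensitive
    lexicographic) order, so ``ProteinPair("B", "A") == ProteinPair("A", "B")``.
    Self-pairs are rejected.
    """

    a: str
    b: str

    def __init__(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-pair not allowed: ({a!r}, {b!r})")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Pair({self.a}--{self.b})"


class InteractionNetwork:
    """Simple undirected PPI network with detection metadata per edge.

    Each edge carries ``experiments`` (integer count of supporting
    records), ``scale`` (``small_scale`` / ``high_throughput`` /
    ``unknown``) and ``sources`` (tuple of free-text tags). Self-loops
    are never stored; the number dropped at load time is kept in
    :attr:`self_loops_removed`.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.self_loops_removed = 0

    # -- construction -------------------------------------------------
    def add_edge(
        self,
        a: str,
        b: str,
        *,
        scale: str = "unknown",
        sources: Iterable[str] = (),
        experiments: int = 1,
    ) -> None:
        """Add one detection record; duplicates merge (counts sum,
        sources union, scale upgraded to the most trusted seen)."""
        if scale not in _SCALE_RANK:
            raise ValueError(f"unknown detection scale {scale!r}")
        if a == b:
            self.self_loops_removed += 1
            return
        pair = ProteinPair(a, b)
        src = tuple(sources)
        if self.graph.has_edge(pair.a, pair.b):
            data = self.graph.edges[pair.a, pair.b]
            data["experiments"] += experiments
            if _SCALE_RANK[scale] > _SCALE_RANK[data["scale"]]:
                data["scale"] = scale
            data["sources"] = tuple(sorted(set(data["sources"]) | set(src)))
        else:
            self.graph.add_edge(
                pair.a,
                pair.b,
                experiments=experiments,
                scale=scale,
                sources=tuple(sorted(set(src))),
            )

    # -- queries ------------------------------------------------------
    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[ProteinPair]:
        return {ProteinPair(u, v) for u, v in self.graph.edges}

    def edge_data(self, pair: ProteinPair) -> dict:
        return dict(self.graph.edges[pair.a, pair.b])

    def has_edge(self, pair: ProteinPair) -> bool:
        return self.graph.has_edge(pair.a, pair.b)

    def neighbors(self, protein: str) -> set[str]:
        if protein not in self.graph:
            return set()
        return set(self.graph.neighbors(protein))

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self.graph


def common_neighbors(net: InteractionNetwork, pair: ProteinPair) -> set[str]:
    """Proteins adjacent to both members of ``pair`` (empty if either is
    absent from the network)."""
    return net.neighbors(pair.a) & net.neighbors(pair.b)


# ---------------------------------------------------------------------
# network file formats
# ---------------------------------------------------------------------

def _edge_tsv_records(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) < 2 or len(tokens) > 5:
                raise ParseError(f"{path}:{lineno}: expected 2-5 fields, got {len(tokens)}")
            a, b = tokens[0], tokens[1]
            scale, sources, experiments = "unknown", (), 1
            for tok in tokens[2:]:
                if tok in SCALES:
                    scale = tok
                elif tok.isdigit():
                    experiments = int(tok)
                else:
                    sources = tuple(t for t in tok.split(",") if t)
            yield a, b, scale, sources, experiments


def _psimitab_records(path: Path):
    def clean_id(raw: str) -> str:
        # "uniprotkb:P12345" -> "P12345"
        return raw.rsplit(":", 1)[-1]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ParseError(f"{path}:{lineno}: PSI-MI TAB needs >= 7 columns, got {len(cols)}")
            a, b = clean_id(cols[0]), clean_id(cols[1])
            method = cols[6]
            if "(" in method and method.endswith(")"):
                method = method[method.index("(") + 1 : -1]
            yield a, b, "unknown", (method,) if method and method != "-" else (), 1


def load_network(path: str | Path, format: str = "edge_tsv") -> InteractionNetwork:
    """Load a PPI network from ``edge_tsv`` or ``psimitab`` files.

    The edge TSV dialect is ``proteinA<TAB>proteinB[<TAB>scale]
    [<TAB>source,source...][<TAB>experiment_count]`` with ``#`` comments;
    whitespace-separated files are accepted too. Self-loops are dropped
    (and counted), duplicate records merged.
    """
    path = Path(path)
    if format == "edge_tsv":
        records = _edge_tsv_records(path)
    elif format == "psimitab":
        records = _psimitab_records(path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    net = InteractionNetwork()
    seen = False
    for a, b, scale, sources, experiments in records:
        seen = True
        net.add_edge(a, b, scale=scale, sources=sources, experiments=experiments)
    if not seen:
        raise ParseError(f"{path}: no interaction records found")
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write the edge TSV dialect; a round-trip preserves edges and
    their detection metadata."""
    with open(Path(path), "w") as fh:
        fh.write("# proteinA\tproteinB\tscale\tsources\texperiments\n")
        for pair in sorted(net.edges):
            data = net.edge_data(pair)
            fh.write(
                f"{pair.a}\t{pair.b}\t{data['scale']}\t"
                f"{','.join(data['sources'])}\t{data['experiments']}\n"
            )


# ---------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------

def load_expression(path: str | Path) -> pd.DataFrame:
    """Load a genes x conditions expression TSV (header row of condition
    labels, first column gene identifiers)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expression matrix needs >= 2 condition columns")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row identifiers {dups[:5]}")
    return df.astype(float)


# ---------------------------------------------------------------------
# domain annotations and domain-domain interactions
# ---------------------------------------------------------------------

def canonical_domain_pair(d1: str, d2: str) -> tuple[str, str]:
    """Unordered domain pair as a sorted tuple; (d, d) is permitted."""
    return (d1, d2) if d1 <= d2 else (d2, d1)


@dataclass
class DomainData:
    """Protein -> Pfam-domain annotations plus a set of unordered
    domain-domain interaction (DDI) pairs."""

    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    ddi: set[tuple[str, str]] = field(default_factory=set)

    def domains(self, protein: str) -> frozenset[str]:
        return self.annotations.get(protein, frozenset())

    def interacts(self, d1: str, d2: str) -> bool:
        return canonical_domain_pair(d1, d2) in self.ddi


def load_domain_data(annot_path: str | Path, ddi_path: str | Path) -> DomainData:
    """Load ``protein<TAB>domain`` annotations and ``domain<TAB>domain``
    interaction pairs."""
    annotations: dict[str, set[str]] = {}
    for lineno, line in enumerate(open(annot_path), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        if len(tokens) != 2:
            raise ParseError(f"{annot_path}:{lineno}: expected 2 fields")
        annotations.setdefault(tokens[0], set()).add(tokens[1])
    ddi: set[tuple[str, str]] = set()
    for lineno, line in enumerate(open(ddi_path), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        if len(tokens) != 2:
            raise ParseError(f"{ddi_path}:{lineno}: expected 2 fields")
        ddi.add(canonical_domain_pair(tokens[0], tokens[1]))
    return DomainData({p: frozenset(d) for p, d in annotations.items()}, ddi)


# ---------------------------------------------------------------------
# Gene Ontology
# ---------------------------------------------------------------------

_GAF_ASPECT = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}


@dataclass
class GOData:
    """A GO ontology DAG plus protein annotations.

    ``ontology`` is the obonet graph (edges run child -> parent, keyed by
    relation); ``annotations`` maps protein -> set of (term, evidence
    code) tuples.
    """

    ontology: nx.MultiDiGraph
    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def namespace(self, term: str) -> str:
        return self.ontology.nodes[term].get("namespace", "")

    def terms(
        self,
        protein: str,
        namespace: str | None = None,
        exclude_evidence: Iterable[str] = (),
    ) -> frozenset[str]:
        """Annotated terms for a protein, optionally restricted to one
        namespace and/or excluding evidence codes (e.g. ``{"IEA"}``)."""
        excluded = set(exclude_evidence)
        out = set()
        for term, code in self.annotations.get(protein, ()):
            if code in excluded:
                continue
            if namespace is not None and self.namespace(term) != namespace:
                continue
            out.add(term)
        return frozenset(out)


def load_go(
    obo_path: str | Path,
    gaf_path: str | Path,
    on_missing_term: str = "error",
) -> GOData:
    """Load an OBO 1.2 ontology and GAF 2.x annotations.

    Annotations to terms absent from the ontology raise by default;
    pass ``on_missing_term="drop"`` to discard them with a warning.
    """
    import obonet
    from Bio.UniProt import GOA

    ontology = obonet.read_obo(str(obo_path))
    if not nx.is_directed_acyclic_graph(ontology):
        raise ParseError(f"{obo_path}: ontology graph is cyclic")
    annotations: dict[str, set[tuple[str, str]]] = {}
    dropped = 0
    with open(gaf_path) as handle:
        try:
            for rec in GOA.gafiterator(handle):
                protein, term = rec["DB_Object_ID"], rec["GO_ID"]
                evidence, aspect = rec["Evidence"], rec["Aspect"]
                if aspect not in _GAF_ASPECT:
                    raise ParseError(f"{gaf_path}: unknown aspect {aspect!r}")
                if term not in ontology:
                    if on_missing_term == "drop":
                        dropped += 1
                        continue
                    raise ParseError(f"{gaf_path}: term {term} not in ontology")
                annotations.setdefault(protein, set()).add((term, evidence))
        except (ValueError, IndexError, KeyError) as exc:
            raise ParseError(f"{gaf_path}: malformed GAF record ({exc})") from exc
    if dropped:
        logger.warning("dropped %d annotations to terms absent from the ontology", dropped)
    return GOData(ontology, annotations)


# ---------------------------------------------------------------------
# precomputed per-pair evidence scores
# ---------------------------------------------------------------------

def load_raw_evidence(
    path: str | Path, column_name: str, format: str = "pair_score"
) -> pd.Series:
    """Load precomputed per-pair scores as a Series indexed by
    :class:`ProteinPair`.

    ``pair_score``: ``proteinA<TAB>proteinB<TAB>score``. ``blast6``:
    BLAST tabular (outfmt 6); the bit-score (last standard column) is
    the score. Duplicate pairs keep the maximum score; self-pairs are
    skipped.
    """
    scores: dict[ProteinPair, float] = {}
    for lineno, line in enumerate(open(path), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        if format == "pair_score":
            if len(tokens) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(tokens)}")
            a, b, raw = tokens
        elif format == "blast6":
            if len(tokens) < 12:
                raise ParseError(f"{path}:{lineno}: BLAST outfmt 6 needs 12 columns")
            a, b, raw = tokens[0], tokens[1], tokens[11]
        else:
            raise ValueError(f"unknown raw-evidence format {format!r}")
        if a == b:
            continue
        try:
            value = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad score {raw!r}") from exc
        pair = ProteinPair(a, b)
        if pair not in scores or value > scores[pair]:
            scores[pair] = value
    series = pd.Series(scores, name=column_name, dtype=float)
    return series.sort_index()


def write_pairs_tsv(
    path: str | Path,
    table: Mapping[ProteinPair, Mapping[str, object]] | pd.DataFrame,
    columns: list[str] | None = None,
) -> None:
    """Write a pair-indexed table as ``proteinA<TAB>proteinB<TAB>...``."""
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame.from_dict(table, orient="index")
    if columns is not None:
        df = df[columns]
    out = df.copy()
    out.insert(0, "proteinA", [p.a for p in df.index])
    out.insert(1, "proteinB", [p.b for p in df.index])
    out.to_csv(path, sep="\t", index=False)
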
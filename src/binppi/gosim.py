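"""GO semantic similarity: term-level IC measures and the protein-level
best-match average.

Term similarity is information-content (IC) based: IC(t) = -log of the
fraction of annotated proteins carrying t or any of its descendants
(propagated over is_a and part_of), so the namespace root has IC 0. Two
measures are available — Lin's ``2*IC(MICA)/(IC(g1)+IC(g2))`` (default)
and Resnik's IC(MICA) normalized by the corpus maximum — and the
term-level measure is pluggable.

Protein-level functional similarity is the symmetric best-match
average: for annotation sets of sizes m and n,

    S_GO(x, y) = [ sum_i max_j sim(g1i, g2j) + sum_j max_i sim(g1i, g2j) ] / (m + n)

used both to label negatives (cellular-component dissimilarity) and to
validate rankings (biological-process similarity of top pairs).
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable

import networkx as nx

from .net_io import GOData

logger = logging.getLogger(__name__)

#: ontology relations followed when propagating annotations upward
PROPAGATION_RELATIONS = ("is_a", "part_of")

TERM_METHODS = ("lin", "resnik_normalized")


class SemanticSimilarity:
    """IC-based term and protein similarity over one GO namespace.

    The annotation corpus is the ``GOData`` passed in; IC values, term
    ancestors and the per-protein term sets are cached on construction.
    ``exclude_evidence`` drops annotations by evidence code (e.g.
    ``{"IEA"}``) before computing frequencies.
    """

    def __init__(
        self,
        go: GOData,
        namespace: str = "biological_process",
        method: str = "lin",
        exclude_evidence: Iterable[str] = (),
        term_measure: Callable[[str, str], float] | None = None,
    ) -> None:
        if method not in TERM_METHODS and term_measure is None:
            raise ValueError(f"unknown term method {method!r}; options: {TERM_METHODS}")
        self.go = go
        self.namespace = namespace
        self.method = method
        self._term_measure = term_measure

        # restrict the DAG to upward-propagating relations in this namespace
        sub = nx.DiGraph()
        for node, data in go.ontology.nodes(data=True):
            if data.get("namespace") == namespace:
                sub.add_node(node)
        for u, v, key in go.ontology.edges(keys=True):
            if key in PROPAGATION_RELATIONS and u in sub and v in sub:
                sub.add_edge(u, v)
        self._dag = sub
        self._ancestors: dict[str, frozenset[str]] = {}

        # protein -> namespace term set (after evidence filtering)
        self.protein_terms: dict[str, frozenset[str]] = {}
        dropped_terms = set()
        for protein in go.annotations:
            terms = set()
            for term in go.terms(protein, exclude_evidence=exclude_evidence):
                if term not in go.ontology:
                    dropped_terms.add(term)
                    continue
                if go.namespace(term) == namespace:
                    terms.add(term)
            if terms:
                self.protein_terms[protein] = frozenset(terms)
        if dropped_terms:
            logger.warning(
                "dropped %d annotated terms absent from the ontology", len(dropped_terms)
            )

        # annotation frequency with descendant propagation
        counts: dict[str, int] = {}
        for terms in self.protein_terms.values():
            reached: set[str] = set()
            for term in terms:
                reached |= self.ancestors(term)
            for anc in reached:
                counts[anc] = counts.get(anc, 0) + 1
        self._total = len(self.protein_terms)
        self._ic: dict[str, float] = {}
        for term, count in counts.items():
            self._ic[term] = -math.log(count / self._total) if self._total else math.inf
        self._max_ic = max(self._ic.values(), default=0.0)

    # -- term level ---------------------------------------------------
    def ancestors(self, term: str) -> frozenset[str]:
        """The term itself plus all is_a/part_of ancestors."""
        if term not in self._ancestors:
            if term not in self._dag:
                raise ValueError(f"term {term!r} not in the {self.namespace} ontology")
            self._ancestors[term] = frozenset({term} | nx.descendants(self._dag, term))
        return self._ancestors[term]

    def ic(self, term: str) -> float:
        """IC of a term; +inf if nothing in the corpus reaches it."""
        if term not in self._dag:
            raise ValueError(f"term {term!r} not in the {self.namespace} ontology")
        return self._ic.get(term, math.inf)

    def term_similarity(self, g1: str, g2: str) -> float:
        """Similarity of two same-namespace terms, in [0, 1].

        Identical terms score 1 by convention. Terms whose only common
        ancestor is the namespace root score 0 (IC(root) = 0).
        """
        if self._term_measure is not None:
            return self._term_measure(g1, g2)
        if g1 == g2:
            self.ic(g1)  # raises for unknown terms
            return 1.0
        common = self.ancestors(g1) & self.ancestors(g2)
        if not common:
            return 0.0
        mica_ic = max((self._ic.get(t, 0.0) for t in common), default=0.0)
        if self.method == "resnik_normalized":
            return mica_ic / self._max_ic if self._max_ic > 0 else 0.0
        ic1, ic2 = self.ic(g1), self.ic(g2)
        if math.isinf(ic1) or math.isinf(ic2):
            return 0.0
        if ic1 + ic2 == 0.0:
            return 0.0
        return 2.0 * mica_ic / (ic1 + ic2)

    # -- protein level ------------------------------------------------
    def functional_similarity(
        self, terms_x: Iterable[str], terms_y: Iterable[str]
    ) -> float | None:
        """Symmetric best-match average over two term sets; ``None`` if
        either set is empty (caller decides how to treat it)."""
        tx = list(terms_x)
        ty = list(terms_y)
        if not tx or not ty:
            return None
        sim = [[self.term_similarity(a, b) for b in ty] for a in tx]
        row_max = sum(max(row) for row in sim)
        col_max = sum(max(sim[i][j] for i in range(len(tx))) for j in range(len(ty)))
        return (row_max + col_max) / (len(tx) + len(ty))

    def protein_similarity(self, protein_x: str, protein_y: str) -> float | None:
        """Best-match-average similarity of two proteins' corpus
        annotations in this namespace; ``None`` if either is
        unannotated."""
        tx = self.protein_terms.get(protein_x)
        ty = self.protein_terms.get(protein_y)
        if not tx or not ty:
            return None
        return self.functional_similarity(tx, ty)


def term_similarity(
    g1: str,
    g2: str,
    go: GOData,
    method: str = "lin",
    namespace: str | None = None,
) -> float:
    """Convenience one-shot term similarity (builds the corpus cache).

    Raises if the terms live in different namespaces.
    """
    ns1, ns2 = go.namespace(g1), go.namespace(g2)
    if ns1 != ns2:
        raise ValueError(f"cross-namespace comparison: {g1} ({ns1}) vs {g2} ({ns2})")
    sem = SemanticSimilarity(go, namespace=namespace or ns1, method=method)
    return sem.term_similarity(g1, g2)


def protein_functional_similarity(
    annots_x: Iterable[str],
    annots_y: Iterable[str],
    go: GOData,
    method: str = "lin",
    namespace: str = "biological_process",
) -> float | None:
    """One-shot best-match-average similarity of two annotation sets."""
    sem = SemanticSimilarity(go, namespace=namespace, method=method)
    return sem.functional_similarity(annots_x, annots_y)
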
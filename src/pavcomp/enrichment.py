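"""Term-enrichment testing over a GO-style DAG.

Implements the true-path rule (a gene annotated to a term is implicitly
annotated to every ancestor of that term), exact upper-tail hypergeometric
tests of a study (foreground) set against a background, and an optional
elim-style decorrelation pass that removes the genes of significantly
enriched descendant terms before testing their ancestors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "GoDag",
    "GeneAnnotation",
    "EnrichmentResult",
    "propagate_annotations",
    "fisher_term_test",
    "classic_enrichment",
    "elim_enrichment",
    "bh_qvalues",
]


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, dangling parent, ...)."""


@dataclass
class GoDag:
    """Directed acyclic graph of ontology terms linked by is_a edges.

    ``parents`` maps each term id to the ids of its direct is_a parents.
    Edges in the underlying graph point child -> parent, so ancestors of a
    term are the nodes reachable by following edges forward.
    """

    terms: dict[str, dict]  # term id -> {"name": ..., "namespace": ...}
    parents: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for term, pars in self.parents.items():
            if term not in self.terms:
                raise OntologyError(f"parent list for undeclared term {term!r}")
            for p in pars:
                if p not in self.terms:
                    raise OntologyError(
                        f"term {term!r} has undeclared is_a target {p!r}"
                    )
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle: {cycle}")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term, pars in self.parents.items():
            for p in pars:
                g.add_edge(term, p)
        return g

    @property
    def roots(self) -> list[str]:
        return sorted(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` (the term itself excluded)."""
        if term not in self.terms:
            raise OntologyError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def depth_first_order(self) -> list[str]:
        """Terms in reverse topological order: every child before its parents."""
        return list(nx.topological_sort(self.graph))

    def write_obo(self, path) -> None:
        """Write a minimal OBO 1.2 rendering ([Term], id, name, is_a)."""
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\nontology: pavcomp-synthetic\n")
            for term in sorted(self.terms):
                meta = self.terms[term]
                fh.write(f"\n[Term]\nid: {term}\nname: {meta.get('name', term)}\n")
                if meta.get("namespace"):
                    fh.write(f"namespace: {meta['namespace']}\n")
                for p in self.parents.get(term, ()):
                    pname = self.terms[p].get("name", p)
                    fh.write(f"is_a: {p} ! {pname}\n")


@dataclass
class GeneAnnotation:
    """Direct and true-path-propagated gene -> term annotations."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] = field(default_factory=dict)


def propagate_annotations(dag: GoDag, direct: dict[str, set[str]]) -> GeneAnnotation:
    """Apply the true-path rule: annotate each gene to all ancestors of its terms."""
    prop: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag.terms:
                raise OntologyError(f"gene {gene!r} annotated to unknown term {t!r}")
            closed.add(t)
            closed |= dag.ancestors(t)
        prop[gene] = frozenset(closed)
    return GeneAnnotation(
        direct={g: frozenset(t) for g, t in direct.items()}, propagated=prop
    )


def fisher_term_test(fg_annotated: int, fg_total: int, bg_annotated: int, bg_total: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X ~ Hypergeom(N=bg_total, K=bg_annotated, n=fg_total); the foreground is a
    draw of ``fg_total`` genes from the background and ``fg_annotated`` of them
    carry the term. Exact tail, no normal approximation.
    """
    k, n, K, N = fg_annotated, fg_total, bg_annotated, bg_total
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if n - k > N - K:
        raise ValueError(
            f"inconsistent counts: {n - k} unannotated foreground genes but "
            f"only {N - K} unannotated background genes"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term_id: str
    fg_annotated: int
    fg_total: int
    bg_annotated: int
    bg_total: int
    p_value: float
    q_value: float = math.nan
    name: str = ""


def _term_gene_index(annotation: GeneAnnotation, genes: set[str]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for gene in genes:
        for term in annotation.propagated.get(gene, ()):
            index.setdefault(term, set()).add(gene)
    return index


def _finalize(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    results.sort(key=lambda r: (r.p_value, r.term_id))
    qs = bh_qvalues([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    return results


def classic_enrichment(
    dag: GoDag,
    annotation: GeneAnnotation,
    fg: set[str],
    bg: set[str],
    min_count: int = 1,
) -> list[EnrichmentResult]:
    """Independent per-term hypergeometric tests of fg against bg.

    Raw p-values; a Benjamini-Hochberg q column is attached but nothing is
    filtered on it. Terms with fewer than ``min_count`` annotated background
    genes are skipped.
    """
    if not fg <= bg:
        raise ValueError("foreground gene set must be a subset of the background")
    fg_terms = _term_gene_index(annotation, fg)
    bg_terms = _term_gene_index(annotation, bg)
    results = []
    for term, bg_genes in bg_terms.items():
        if len(bg_genes) < min_count:
            continue
        k = len(fg_terms.get(term, ()))
        p = fisher_term_test(k, len(fg), len(bg_genes), len(bg))
        results.append(
            EnrichmentResult(
                term_id=term,
                fg_annotated=k,
                fg_total=len(fg),
                bg_annotated=len(bg_genes),
                bg_total=len(bg),
                p_value=p,
                name=dag.terms.get(term, {}).get("name", ""),
            )
        )
    return _finalize(results)


def elim_enrichment(
    dag: GoDag,
    annotation: GeneAnnotation,
    fg: set[str],
    bg: set[str],
    elim_alpha: float = 0.01,
    min_count: int = 1,
) -> list[EnrichmentResult]:
    """Elim-style decorrelated enrichment.

    Terms are processed children-before-parents (reverse topological order).
    When a term's p-value falls below ``elim_alpha``, the genes annotated to
    it are removed from all of its ancestors before those are tested, so a
    parent is not called enriched merely by inheriting a significant child's
    genes. With no term below ``elim_alpha`` the output equals
    :func:`classic_enrichment`.
    """
    if not fg <= bg:
        raise ValueError("foreground gene set must be a subset of the background")
    fg_terms = _term_gene_index(annotation, fg)
    bg_terms = _term_gene_index(annotation, bg)
    removed: dict[str, set[str]] = {}  # term -> genes eliminated from it
    results = []
    for term in dag.depth_first_order():
        bg_genes = bg_terms.get(term, set()) - removed.get(term, set())
        if len(bg_genes) < min_count:
            continue
        fg_genes = fg_terms.get(term, set()) - removed.get(term, set())
        p = fisher_term_test(len(fg_genes), len(fg), len(bg_genes), len(bg))
        results.append(
            EnrichmentResult(
                term_id=term,
                fg_annotated=len(fg_genes),
                fg_total=len(fg),
                bg_annotated=len(bg_genes),
                bg_total=len(bg),
                p_value=p,
                name=dag.terms.get(term, {}).get("name", ""),
            )
        )
        if p < elim_alpha:
            doomed = bg_terms.get(term, set())
            for anc in dag.ancestors(term):
                removed.setdefault(anc, set()).update(doomed)
    return _finalize(results)


def bh_qvalues(pvalues: list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q
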
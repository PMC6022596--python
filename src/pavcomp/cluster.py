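"""Orthologue-group construction: similarity graph, Markov clustering,
lineage-specific cluster selection.

The similarity graph is built from all-vs-all protein hits with edge weight
-log10(evalue) (capped for evalue 0, reciprocal hits merged by max). Markov
clustering (MCL) alternates expansion (matrix squaring) and inflation
(elementwise power + column renormalization) on the column-stochastic
adjacency until the matrix stops changing; clusters are the attractor basins
of the converged matrix and always partition the node set.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np

from .io import HspRecord

__all__ = [
    "OrthoGroupSet",
    "build_graph",
    "mcl",
    "select_lineage_specific",
    "read_species_map",
]


class OrthoGroupSet:
    """Orthologue clusters: group_id -> species -> member gene ids.

    Every gene belongs to at most one group; groups are never empty.
    """

    def __init__(self, groups: dict[str, dict[str, list[str]]] | None = None) -> None:
        self._groups: dict[str, dict[str, list[str]]] = {}
        if groups:
            for gid, members in groups.items():
                self.add_group(gid, members)

    def add_group(self, group_id: str, members: dict[str, list[str]]) -> None:
        members = {sp: list(genes) for sp, genes in members.items() if genes}
        if not members:
            raise ValueError(f"group {group_id!r} has no members")
        if group_id in self._groups:
            raise ValueError(f"duplicate group id {group_id!r}")
        new = {g for genes in members.values() for g in genes}
        for gid, existing in self._groups.items():
            clash = new & {g for genes in existing.values() for g in genes}
            if clash:
                raise ValueError(
                    f"genes {sorted(clash)} already in group {gid!r}"
                )
        self._groups[group_id] = members

    def __len__(self) -> int:
        return len(self._groups)

    def __iter__(self):
        return iter(sorted(self._groups))

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._groups

    def members(self, group_id: str) -> dict[str, list[str]]:
        return self._groups[group_id]

    def items(self):
        for gid in sorted(self._groups):
            yield gid, self._groups[gid]

    def species(self) -> list[str]:
        return sorted({sp for m in self._groups.values() for sp in m})

    def genes(self, group_id: str) -> list[str]:
        return sorted(g for genes in self._groups[group_id].values() for g in genes)

    def to_tsv(self, path) -> None:
        """group_id TAB species TAB gene_id, one gene per line."""
        with open(path, "w") as fh:
            for gid, members in self.items():
                for sp in sorted(members):
                    for gene in members[sp]:
                        fh.write(f"{gid}\t{sp}\t{gene}\n")

    @classmethod
    def from_tsv(cls, path) -> "OrthoGroupSet":
        staged: dict[str, dict[str, list[str]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 3:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 'group<TAB>species<TAB>gene'"
                    )
                gid, sp, gene = cols
                staged.setdefault(gid, {}).setdefault(sp, []).append(gene)
        return cls(staged)


def build_graph(
    hits: list[HspRecord],
    evalue_max: float = 1e-5,
    evalue_cap: float = 1e-200,
    species_map: dict[str, str] | None = None,
) -> nx.Graph:
    """Undirected similarity graph from all-vs-all protein hits.

    Edge weight is -log10(evalue); evalue 0 (or below ``evalue_cap``) is
    treated as ``evalue_cap``. Reciprocal A->B / B->A hits are merged keeping
    the maximum weight; self-hits are dropped. Node attribute ``species``
    comes from ``species_map`` when given.
    """
    g = nx.Graph()
    for h in hits:
        if h.evalue > evalue_max or h.query_id == h.subject_id:
            continue
        ev = max(h.evalue, evalue_cap)
        w = -math.log10(ev)
        a, b = h.query_id, h.subject_id
        for node in (a, b):
            if node not in g:
                g.add_node(node)
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    if species_map is not None:
        for node in g.nodes:
            g.nodes[node]["species"] = species_map.get(node, "unknown")
    return g


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    prune: float = 1e-5,
    tol: float = 1e-8,
    species_map: dict[str, str] | None = None,
    group_prefix: str = "OG",
) -> OrthoGroupSet:
    """Markov clustering of a weighted similarity graph.

    Self-loops (weight = the node's maximum incident edge weight, 1 for
    isolated nodes) are added before column normalization; expansion and
    inflation alternate, entries below ``prune`` are zeroed, and iteration
    stops when the largest elementwise change falls below ``tol``. Clusters
    are read off as attractor basins: rows with positive diagonal mass seed
    clusters, overlapping attractor sets are merged, and every node joins the
    cluster(s) it sends mass to — yielding a partition of the node set,
    invariant to node ordering.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return OrthoGroupSet({})
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({a!r}, {b!r})")
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        np.power(m, inflation, out=m)  # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "returning the current clustering",
            RuntimeWarning,
        )

    # attractor basins -> partition via union-find
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    attractors = [i for i in range(n) if m[i, i] > 0]
    attractor_set = set(attractors)
    for j in range(n):
        rows = [i for i in attractors if m[i, j] > 0]
        for i in rows:
            union(j, i)
        if not rows and j not in attractor_set:
            # no surviving mass (aggressive pruning): fall back to argmax row
            best = int(np.argmax(m[:, j]))
            if m[best, j] > 0:
                union(j, best)

    clusters: dict[int, list[str]] = {}
    for j in range(n):
        clusters.setdefault(find(j), []).append(nodes[j])

    def node_species(v: str) -> str:
        if species_map and v in species_map:
            return species_map[v]
        return graph.nodes[v].get("species", "unknown")

    ordered = sorted(clusters.values(), key=lambda c: min(c))
    width = max(5, len(str(len(ordered))))
    out: dict[str, dict[str, list[str]]] = {}
    for i, members in enumerate(ordered, start=1):
        by_sp: dict[str, list[str]] = {}
        for v in sorted(members):
            by_sp.setdefault(node_species(v), []).append(v)
        out[f"{group_prefix}{i:0{width}d}"] = by_sp
    return OrthoGroupSet(out)


def select_lineage_specific(
    groups: OrthoGroupSet,
    target_species: set[str],
    outgroup_species: set[str],
) -> OrthoGroupSet:
    """Keep groups with >= 1 member in every target species and none in any outgroup.

    This is the lineage-specific cluster selection (e.g. clusters unique to a
    clade of interest among a wider species panel).
    """
    target = set(target_species)
    outgroup = set(outgroup_species)
    if not target:
        raise ValueError("target species set is empty")
    if target & outgroup:
        raise ValueError("target and outgroup species sets overlap")
    selected: dict[str, dict[str, list[str]]] = {}
    for gid, members in groups.items():
        present = {sp for sp, genes in members.items() if genes}
        if target <= present and not (outgroup & present):
            selected[gid] = {sp: list(g) for sp, g in members.items()}
    return OrthoGroupSet(selected)


def read_species_map(path) -> dict[str, str]:
    """gene TAB species."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'gene<TAB>species'")
            out[cols[0]] = cols[1]
    return out
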
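"""Markov clustering of the protein similarity graph and phage grouping.

The similarity graph has proteins as nodes and retained-hit percent
identities as edge weights.  MCL iterates expansion (matrix squaring)
and inflation (entrywise power followed by column renormalisation) on a
column-stochastic matrix with self-loops until the matrix is idempotent;
clusters are read off the attractor structure.  Phage groups are then
derived from shared-family profiles via the Dice coefficient and
single-linkage at a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class SimilarityGraph:
    """Undirected weighted graph; weight = percent identity in (50, 100]."""

    nodes: list[str] = field(default_factory=list)
    edges: dict[frozenset[str], float] = field(default_factory=dict)

    def add_node(self, node: str) -> None:
        if node not in self._index():
            self.nodes.append(node)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        key = frozenset((a, b))
        # max over orientations when the same pair arrives twice
        self.edges[key] = max(self.edges.get(key, 0.0), weight)

    def _index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def adjacency(self) -> np.ndarray:
        idx = self._index()
        n = len(self.nodes)
        mat = np.zeros((n, n))
        for key, w in self.edges.items():
            a, b = tuple(key)
            i, j = idx[a], idx[b]
            mat[i, j] = mat[j, i] = w
        return mat


def graph_from_hits(hits, protein_ids: Iterable[str]) -> SimilarityGraph:
    """Build the similarity graph from retained hits.

    Every protein in ``protein_ids`` becomes a node (isolated proteins
    end up as singleton families); edge weight is percent identity,
    maximised over the two hit orientations.
    """
    graph = SimilarityGraph()
    for pid in protein_ids:
        graph.add_node(pid)
    known = set(graph.nodes)
    for hit in hits:
        if hit.query_id not in known or hit.subject_id not in known:
            raise ValueError(f"hit references unknown protein: {hit.query_id!r}")
        graph.add_edge(hit.query_id, hit.subject_id, 100.0 * hit.identity)
    return graph


@dataclass(frozen=True)
class ProteinFamily:
    family_id: str
    members: frozenset[str]


class MclConvergenceError(RuntimeError):
    pass


def _normalize_columns(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=0)
    sums[sums == 0] = 1.0
    return mat / sums


def mcl(graph: SimilarityGraph, params: MclParams | None = None) -> list[ProteinFamily]:
    """Run Markov clustering; returns a partition of the node set.

    Self-loops of weight equal to each node's maximum incident weight
    (or 1 for isolated nodes) are added before normalisation.  Raises
    :class:`MclConvergenceError` if the matrix is not idempotent within
    ``max_iterations``.
    """
    params = params or MclParams()
    if not graph.nodes:
        raise ValueError("graph is empty")
    adj = graph.adjacency()
    n = adj.shape[0]
    loop = adj.max(axis=0)
    loop[loop == 0] = 1.0
    adj = adj + np.diag(loop)
    mat = _normalize_columns(adj)
    for iteration in range(1, params.max_iterations + 1):
        prev = mat
        mat = np.linalg.matrix_power(mat, params.expansion)
        mat = np.power(mat, params.inflation)
        mat = _normalize_columns(mat)
        mat[mat < params.prune_threshold] = 0.0
        mat = _normalize_columns(mat)
        if np.max(np.abs(mat - prev)) < params.convergence_eps:
            break
    else:
        raise MclConvergenceError(
            f"MCL did not converge within {params.max_iterations} iterations"
        )
    return _read_clusters(mat, graph.nodes)


def _read_clusters(mat: np.ndarray, nodes: Sequence[str]) -> list[ProteinFamily]:
    n = len(nodes)
    attractors = [i for i in range(n) if mat[i, i] > 0]
    # attractor systems: attractors connected through shared columns
    clusters: list[set[int]] = []
    for a in attractors:
        members = set(np.nonzero(mat[a, :])[0]) | {a}
        merged = False
        for cl in clusters:
            if cl & members:
                cl |= members
                merged = True
                break
        if merged:
            # merging may chain clusters together
            clusters = _coalesce(clusters)
        else:
            clusters.append(members)
    assigned: set[int] = set()
    families: list[ProteinFamily] = []
    # deterministic: order clusters by smallest member node name
    keyed = sorted(
        clusters, key=lambda cl: min(nodes[i] for i in cl)
    )
    for cl in keyed:
        fresh = cl - assigned  # overlap resolved to earliest family
        if not fresh:
            continue
        assigned |= fresh
        families.append(
            ProteinFamily(
                family_id=f"fam{len(families) + 1:04d}",
                members=frozenset(nodes[i] for i in sorted(fresh)),
            )
        )
    for i in range(n):
        if i not in assigned:
            families.append(
                ProteinFamily(
                    family_id=f"fam{len(families) + 1:04d}",
                    members=frozenset({nodes[i]}),
                )
            )
    return families


def _coalesce(clusters: list[set[int]]) -> list[set[int]]:
    out: list[set[int]] = []
    for cl in clusters:
        hit = [o for o in out if o & cl]
        for o in hit:
            out.remove(o)
            cl = cl | o
        out.append(cl)
    return out


def phage_profiles(
    families: Sequence[ProteinFamily],
    proteomes: Mapping[str, Mapping[str, str]],
) -> dict[str, frozenset[str]]:
    """Per-phage set of family ids containing >= 1 of its proteins."""
    membership: dict[str, str] = {}
    for fam in families:
        for pid in fam.members:
            membership[pid] = fam.family_id
    profiles: dict[str, frozenset[str]] = {}
    for phage, prots in proteomes.items():
        fams = set()
        for pid in prots:
            if pid not in membership:
                raise ValueError(f"protein {pid!r} missing from all families")
            fams.add(membership[pid])
        profiles[phage] = frozenset(fams)
    return profiles


def dice(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


@dataclass
class PhageGrouping:
    phage_ids: list[str]
    groups: list[frozenset[str]]
    similarity_matrix: np.ndarray

    def group_of(self, phage_id: str) -> str:
        for gid, members in self.group_labels().items():
            if phage_id in members:
                return gid
        raise KeyError(phage_id)

    def group_labels(self) -> dict[str, frozenset[str]]:
        return {f"group{i + 1}": g for i, g in enumerate(self.groups)}


def group_phages(
    profiles: Mapping[str, frozenset[str]],
    link_threshold: float = 0.5,
) -> PhageGrouping:
    """Group phages by Dice similarity of family profiles.

    Groups are connected components of the graph with an edge wherever
    Dice >= ``link_threshold``.  Deterministic: phages and groups are
    ordered by smallest member id.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    ids = sorted(profiles)
    n = len(ids)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = dice(profiles[ids[i]], profiles[ids[j]])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= link_threshold:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(ids[i])
    groups = sorted((frozenset(c) for c in comps.values()), key=min)
    return PhageGrouping(phage_ids=ids, groups=list(groups), similarity_matrix=sim)


def write_families(families: Iterable[ProteinFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily_id\n")
        for fam in families:
            for pid in sorted(fam.members):
                fh.write(f"{pid}\t{fam.family_id}\n")


def write_grouping(grouping: PhageGrouping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phage_id\tgroup_id\n")
        for gid, members in grouping.group_labels().items():
            for pid in sorted(members):
                fh.write(f"{pid}\t{gid}\n")


def read_abc(path: str | Path) -> SimilarityGraph:
    """Read an mcl-style "abc" edge list (node node weight)."""
    graph = SimilarityGraph()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            a, b, w = line.split()[:3]
            graph.add_node(a)
            graph.add_node(b)
            if a != b:
                graph.add_edge(a, b, float(w))
    return graph
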
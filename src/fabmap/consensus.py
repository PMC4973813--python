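"""Weighted merging of per-population genetic maps into a consensus map.

Each input linkage group contributes a directed marker-order graph
(edge u -> v for consecutive loci, weighted by the map's weight).
Groups from different populations are matched when they share at least
two markers; the union graph of a matched cluster is made acyclic by
greedily deleting the cheapest conflicting marker *occurrence* (one
marker in one input map), and the remaining DAG is linearised by
topological order with weighted-mean rescaled positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .linkage import GeneticMap, LinkageGroup, Locus

__all__ = [
    "WeightedMapSet",
    "ConsensusGroup",
    "ConsensusMap",
    "ConflictDeletion",
    "merge_maps",
    "assign_chromosomes",
    "map_stats",
    "MapStats",
]


@dataclass
class WeightedMapSet:
    """Per-population maps with positive merge weights."""

    maps: list[tuple[GeneticMap, float, str]]  # (map, weight, population id)

    def __post_init__(self) -> None:
        if any(w <= 0 for _, w, _ in self.maps):
            raise ValueError("map weights must be positive")


@dataclass
class ConsensusGroup:
    name: str
    loci: list[Locus]
    support: dict[str, list[str]] = field(default_factory=dict)  # marker -> pops

    @property
    def markers(self) -> list[str]:
        return [m for locus in self.loci for m in locus.markers]

    @property
    def length(self) -> float:
        return self.loci[-1].position if self.loci else 0.0


@dataclass
class ConsensusMap:
    groups: list[ConsensusGroup]
    unmerged: list[str] = field(default_factory=list)  # group labels left alone

    @property
    def markers(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]


@dataclass(frozen=True)
class ConflictDeletion:
    marker: str
    population: str
    group: str
    weight: float


def _flatten(lg: LinkageGroup) -> list[tuple[str, float]]:
    """(marker, position) in map order; bin members in sorted order."""
    out = []
    for locus in lg.loci:
        for m in sorted(locus.markers):
            out.append((m, locus.position))
    return out


def _match_groups(
    entries: list[tuple[str, str, LinkageGroup, float]],
    min_shared: int = 2,
) -> list[list[int]]:
    """Cluster input groups (indices into entries) by >= min_shared markers."""
    n = len(entries)
    marker_sets = [set(m for m, _ in _flatten(e[2])) for e in entries]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if len(marker_sets[i] & marker_sets[j]) >= min_shared:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return sorted(clusters.values(), key=lambda c: min(c))


def _merge_cluster(
    entries: list[tuple[str, str, LinkageGroup, float]],
    name: str,
    log: list[ConflictDeletion],
) -> ConsensusGroup:
    # per-map marker sequences and positions (occurrences may be deleted)
    seqs: list[list[str]] = []
    positions: list[dict[str, float]] = []
    weights: list[float] = []
    pops: list[str] = []
    group_labels: list[str] = []
    for pop, label, lg, w in entries:
        flat = _flatten(lg)
        seqs.append([m for m, _ in flat])
        positions.append({m: p for m, p in flat})
        weights.append(w)
        pops.append(pop)
        group_labels.append(label)

    def build_graph() -> nx.DiGraph:
        g = nx.DiGraph()
        for seq, w in zip(seqs, weights):
            g.add_nodes_from(seq)
            for u, v in zip(seq, seq[1:]):
                if g.has_edge(u, v):
                    g[u][v]["weight"] += w
                else:
                    g.add_edge(u, v, weight=w)
        return g

    graph = build_graph()
    while not nx.is_directed_acyclic_graph(graph):
        cyclic = set()
        for scc in nx.strongly_connected_components(graph):
            if len(scc) > 1:
                cyclic.update(scc)
            else:
                (node,) = scc
                if graph.has_edge(node, node):
                    cyclic.add(node)
        # candidate occurrences: (marker in a cycle, map containing it)
        candidates = []
        for k, seq in enumerate(seqs):
            for m in seq:
                if m not in cyclic:
                    continue
                idx = seq.index(m)
                involvement = 0
                if idx > 0 and seq[idx - 1] in cyclic:
                    involvement += 1
                if idx < len(seq) - 1 and seq[idx + 1] in cyclic:
                    involvement += 1
                candidates.append((weights[k], -involvement, m, pops[k], k))
        assert candidates, "cyclic graph without deletable occurrence"
        w, _, marker, pop, k = sorted(candidates)[0]
        seqs[k] = [m for m in seqs[k] if m != marker]
        del positions[k][marker]
        log.append(ConflictDeletion(marker, pop, group_labels[k], w))
        graph = build_graph()

    # rescale each input group to the longest input length before averaging
    lengths = [
        (max(p.values()) - min(p.values())) if p else 0.0 for p in positions
    ]
    max_len = max(lengths) if lengths else 0.0
    scales = []
    for length in lengths:
        scales.append(max_len / length if length > 0 and max_len > 0 else 1.0)
    if len(entries) == 1:
        scales = [1.0]

    def mean_position(marker: str) -> float:
        num = den = 0.0
        for p, w, s in zip(positions, weights, scales):
            if marker in p:
                num += w * p[marker] * s
                den += w
        return num / den

    order = list(
        nx.lexicographical_topological_sort(
            graph, key=lambda m: (mean_position(m), m)
        )
    )
    support = {
        m: sorted(pop for pop, p in zip(pops, positions) if m in p) for m in order
    }
    # positions: weighted means made monotone along the topological order
    raw = [mean_position(m) for m in order]
    mono = []
    high = -float("inf")
    for x in raw:
        high = max(high, x)
        mono.append(high)
    offset = mono[0] if mono else 0.0
    loci: list[Locus] = []
    for m, x in zip(order, mono):
        pos = x - offset
        if loci and abs(pos - loci[-1].position) < 1e-9:
            loci[-1].markers.append(m)
            loci[-1].markers.sort()
        else:
            loci.append(Locus(position=pos, markers=[m]))
    return ConsensusGroup(name=name, loci=loci, support=support)


def merge_maps(ws: WeightedMapSet, min_shared: int = 2) -> tuple[ConsensusMap, list[ConflictDeletion]]:
    """Merge weighted per-population maps; returns map + conflict log."""
    entries: list[tuple[str, str, LinkageGroup, float]] = []
    for gmap, weight, pop in ws.maps:
        for lg in gmap.groups:
            entries.append((pop, lg.name, lg, weight))
    log: list[ConflictDeletion] = []
    groups = []
    unmerged = []
    for i, cluster in enumerate(_match_groups(entries, min_shared), start=1):
        sub = [entries[k] for k in cluster]
        if len(sub) == 1 and len(entries) > 1:
            pop, label, _, _ = sub[0]
            unmerged.append(f"{pop}:{label}")
        groups.append(_merge_cluster(sub, name=f"G{i}", log=log))
    groups.sort(key=lambda g: (-len(g.markers), g.name))
    for i, g in enumerate(groups, start=1):
        g.name = f"G{i}"
    return ConsensusMap(groups=groups, unmerged=unmerged), log


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def assign_chromosomes(
    cm: ConsensusMap,
    anchors: Mapping[str, str],
    warnings: list[str] | None = None,
) -> dict[str, str | None]:
    """Label consensus groups by majority vote of anchor markers.

    ``anchors`` maps marker id -> chromosome label.  A group with no
    anchors, or a tied vote, stays unlabelled (with a warning).  Two
    groups claiming the same label is an error.
    """
    labels: dict[str, str | None] = {}
    tallies: dict[str, dict[str, int]] = {}
    for g in cm.groups:
        votes: dict[str, int] = {}
        for m in g.markers:
            if m in anchors:
                votes[anchors[m]] = votes.get(anchors[m], 0) + 1
        tallies[g.name] = votes
        if not votes:
            labels[g.name] = None
            if warnings is not None:
                warnings.append(f"group {g.name}: no anchor markers")
            continue
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            labels[g.name] = None
            if warnings is not None:
                warnings.append(f"group {g.name}: tied anchor vote {votes}")
            continue
        labels[g.name] = ranked[0][0]
    claimed: dict[str, list[str]] = {}
    for group, label in labels.items():
        if label is not None:
            claimed.setdefault(label, []).append(group)
    for label, claimants in claimed.items():
        if len(claimants) > 1:
            detail = {g: tallies[g] for g in claimants}
            raise ValueError(f"chromosome {label} claimed by several groups: {detail}")
    return labels


@dataclass(frozen=True)
class MapStats:
    total_length: float
    group_lengths: dict[str, float]
    n_groups: int
    n_loci: int
    n_markers: int
    mean_gap: float
    max_gap: float


def mean_gap(total_length: float, n_loci: int, n_groups: int) -> float:
    """Mean adjacent-locus gap: total length / (unique loci - groups)."""
    denom = n_loci - n_groups
    if denom <= 0:
        raise ValueError("need more loci than groups")
    return total_length / denom


def map_stats(cm: ConsensusMap) -> MapStats:
    """Summary statistics of a consensus map.

    Mean gap = total length / (unique loci - number of groups); max gap
    is the largest adjacent-locus interval; markers count all binned
    members while loci count bins.
    """
    if not cm.groups:
        raise ValueError("empty map")
    total = 0.0
    n_loci = n_markers = 0
    max_gap = 0.0
    lengths: dict[str, float] = {}
    for g in cm.groups:
        lengths[g.name] = g.length
        total += g.length
        n_loci += len(g.loci)
        n_markers += len(g.markers)
        for a, b in zip(g.loci, g.loci[1:]):
            max_gap = max(max_gap, b.position - a.position)
    denom = n_loci - len(cm.groups)
    gap = mean_gap(total, n_loci, len(cm.groups)) if denom > 0 else 0.0
    return MapStats(
        total_length=total,
        group_lengths=lengths,
        n_groups=len(cm.groups),
        n_loci=n_loci,
        n_markers=n_markers,
        mean_gap=gap,
        max_gap=max_gap,
    )
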
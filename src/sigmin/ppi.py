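"""Shortest-path topology of signature probes on a protein interaction network.

Each unordered probe pair falls into one of three outcomes: *absent* (one or
both probes have no node in the network), *disconnected* (both mapped but no
path), or linked at BFS distance k (a "k-th level neighbor").  Summaries
report the per-level pair counts and the average length over linked pairs;
comparing the summary of a signature before and after minimization shows
whether minimization preserved the network topology of the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import networkx as nx

from .dataset import ValidationError

ABSENT = "absent"
DISCONNECTED = "disconnected"


@dataclass
class PPINetwork:
    """Undirected, unweighted interaction graph with a probe->node map.

    One probe may map to several nodes and several probes to one node;
    pair distances take the minimum over mapped node combinations.
    """

    graph: nx.Graph
    probe_map: dict[str, list[str]]
    n_self_loops_dropped: int = 0

    def nodes_for(self, probe: str) -> list[str]:
        return [n for n in self.probe_map.get(probe, []) if n in self.graph]


def load_network(edges_path: str, probe_map_path: str) -> PPINetwork:
    """Read a two-column edge TSV and a two-column probe->node TSV."""
    g = nx.Graph()
    dropped = 0
    with open(edges_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{edges_path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            a, b = parts
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
    if dropped:
        warnings.warn(f"dropped {dropped} self-loop edge(s)", stacklevel=2)
    probe_map: dict[str, list[str]] = {}
    with open(probe_map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{probe_map_path}:{lineno}: expected 2 columns, "
                    f"got {len(parts)}"
                )
            probe, node = parts
            probe_map.setdefault(probe, [])
            if node not in probe_map[probe]:
                probe_map[probe].append(node)
    return PPINetwork(graph=g, probe_map=probe_map, n_self_loops_dropped=dropped)


def pair_distance(net: PPINetwork, p1: str, p2: str):
    """BFS shortest-path outcome for one probe pair.

    Returns :data:`ABSENT`, :data:`DISCONNECTED`, or the hop distance (an
    int; 0 when both probes map to the same node).
    """
    nodes1, nodes2 = net.nodes_for(p1), net.nodes_for(p2)
    if not nodes1 or not nodes2:
        return ABSENT
    best = None
    for a in nodes1:
        lengths = nx.single_source_shortest_path_length(net.graph, a)
        for b in nodes2:
            if b in lengths and (best is None or lengths[b] < best):
                best = lengths[b]
    return DISCONNECTED if best is None else int(best)


@dataclass
class PPIDistanceMatrix:
    """Outcome per unordered probe pair."""

    probes: list[str]
    outcomes: dict[frozenset, object]

    def outcome(self, p1: str, p2: str):
        return self.outcomes[frozenset((p1, p2))]

    @property
    def n_pairs(self) -> int:
        return len(self.outcomes)


def distance_matrix(net: PPINetwork, probes: Sequence[str]) -> PPIDistanceMatrix:
    """All-pairs shortest-path outcomes for a probe list."""
    probes = list(dict.fromkeys(probes))
    if len(probes) < 2:
        raise ValidationError("distance matrix needs at least 2 probes")
    # One BFS per mapped node, shared across pairs.
    node_lengths: dict[str, dict] = {}
    needed = {n for p in probes for n in net.nodes_for(p)}
    for n in needed:
        node_lengths[n] = nx.single_source_shortest_path_length(net.graph, n)
    outcomes: dict[frozenset, object] = {}
    for p1, p2 in combinations(probes, 2):
        n1, n2 = net.nodes_for(p1), net.nodes_for(p2)
        if not n1 or not n2:
            outcomes[frozenset((p1, p2))] = ABSENT
            continue
        best = None
        for a, b in product(n1, n2):
            d = node_lengths[a].get(b)
            if d is not None and (best is None or d < best):
                best = d
        outcomes[frozenset((p1, p2))] = DISCONNECTED if best is None else int(best)
    return PPIDistanceMatrix(probes=probes, outcomes=outcomes)


@dataclass
class TopologySummary:
    """Aggregate of one distance matrix."""

    level_counts: dict[int, int]
    absent_pairs: int
    disconnected_pairs: int
    average_length: float | None = field(default=None)

    @property
    def n_linked(self) -> int:
        return sum(self.level_counts.values())

    @property
    def total_pairs(self) -> int:
        return self.n_linked + self.absent_pairs + self.disconnected_pairs


def topology_summary(m: PPIDistanceMatrix) -> TopologySummary:
    """Level counts, absent/disconnected tallies and mean linked distance."""
    if m.n_pairs == 0:
        raise ValidationError("empty distance matrix")
    levels: dict[int, int] = {}
    absent = disconnected = 0
    linked_sum = 0
    for outcome in m.outcomes.values():
        if outcome == ABSENT:
            absent += 1
        elif outcome == DISCONNECTED:
            disconnected += 1
        else:
            levels[outcome] = levels.get(outcome, 0) + 1
            linked_sum += outcome
    n_linked = sum(levels.values())
    avg = linked_sum / n_linked if n_linked else None
    return TopologySummary(
        level_counts=dict(sorted(levels.items())),
        absent_pairs=absent,
        disconnected_pairs=disconnected,
        average_length=avg,
    )


@dataclass
class TopologyDelta:
    level_deltas: dict[int, int]
    absent_delta: int
    disconnected_delta: int
    average_length_delta: float | None


def compare_topology(
    before: TopologySummary, after: TopologySummary
) -> TopologyDelta:
    """Per-level count changes (after - before) and average-length change."""
    levels = sorted(set(before.level_counts) | set(after.level_counts))
    deltas = {
        k: after.level_counts.get(k, 0) - before.level_counts.get(k, 0)
        for k in levels
    }
    if before.average_length is None or after.average_length is None:
        avg_delta = None
    else:
        avg_delta = after.average_length - before.average_length
    return TopologyDelta(
        level_deltas=deltas,
        absent_delta=after.absent_pairs - before.absent_pairs,
        disconnected_delta=after.disconnected_pairs - before.disconnected_pairs,
        average_length_delta=avg_delta,
    )


def summary_table_row(s: TopologySummary, max_level: int = 6) -> dict:
    """Flat report row: level_1..level_max, >max, disconnected, absent, avg."""
    row = {f"level_{k}": s.level_counts.get(k, 0) for k in range(1, max_level + 1)}
    row[f">{max_level}"] = sum(
        v for k, v in s.level_counts.items() if k > max_level
    )
    row["level_0"] = s.level_counts.get(0, 0)
    row["disconnected"] = s.disconnected_pairs
    row["absent"] = s.absent_pairs
    row["average_length"] = (
        "" if s.average_length is None else f"{s.average_length:.4f}"
    )
    return row
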
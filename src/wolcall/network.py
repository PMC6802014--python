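"""Parsimony networks, loop (recombinant) detection and nested-clade design.

Minimum-spanning networks generalise minimum spanning trees by retaining
*every* tie-minimal alternative connection, so closely related haplotypes,
alleles or sequence types form a graph whose edges are single mutational (or
allele-change) steps and whose cycles ("loops") flag homoplasy or
recombination.  Nested-clade hierarchies group network nodes into 1-step
clades working inward from the tips, then iterate on the clade graph, giving
the multi-level categorical frame used by nested-clade association tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import networkx as nx

Node = Hashable


@dataclass(frozen=True)
class LoopReport:
    """Cycle-basis cycles of a network and the nodes on multi-group cycles."""

    cycles: tuple[tuple[Node, ...], ...]
    recombinant_candidates: frozenset


class DuplicateItemError(ValueError):
    """Two distinct ids at distance zero; collapse identical items first."""


def build_network(
    items: Sequence[Node],
    distance: Mapping[tuple[Node, Node], int] | Callable[[Node, Node], int],
    connection_limit: int | None = None,
) -> nx.Graph:
    """Build a minimum-spanning network (union of all MSTs) over items.

    An edge (u, v, w) belongs to some minimum spanning tree iff u and v are
    disconnected in the subgraph of strictly lighter edges (the cut/cycle
    property); taking all such edges keeps every equally parsimonious
    alternative connection.  Every weight-1 pair is therefore always
    adjacent.  Edges heavier than ``connection_limit`` are dropped afterwards
    (statistical-parsimony style), possibly splitting the network into
    components.
    """
    items = list(items)
    if callable(distance):
        dist = {(u, v): distance(u, v) for u, v in itertools.combinations(items, 2)}
    else:
        dist = {}
        for u, v in itertools.combinations(items, 2):
            if (u, v) in distance:
                dist[(u, v)] = distance[(u, v)]
            else:
                dist[(u, v)] = distance[(v, u)]
    for (u, v), w in dist.items():
        if w == 0:
            raise DuplicateItemError(
                f"items {u!r} and {v!r} are at distance 0; collapse identical items first"
            )

    graph = nx.Graph()
    graph.add_nodes_from(items)
    # union of all MSTs via the cut property, one weight class at a time
    by_weight: dict[int, list[tuple[Node, Node]]] = {}
    for pair, w in dist.items():
        by_weight.setdefault(w, []).append(pair)
    lighter = nx.Graph()
    lighter.add_nodes_from(items)
    for w in sorted(by_weight):
        components = {node: i for i, comp in enumerate(nx.connected_components(lighter))
                      for node in comp}
        accepted = []
        for u, v in by_weight[w]:
            if components[u] != components[v]:
                accepted.append((u, v))
                if connection_limit is None or w <= connection_limit:
                    graph.add_edge(u, v, weight=w)
        lighter.add_edges_from(accepted)
    return graph


def find_loops(
    network: nx.Graph, groups: Mapping[Node, str] | None = None
) -> LoopReport:
    """Report a fundamental cycle basis and nodes on multi-group cycles.

    Recombinant candidates are the nodes participating in basis cycles that
    touch at least two distinct groups — an alternative minimal path between
    divergent items is the network signature of inter-locus recombination
    (or homoplasy).  Without a group map no node qualifies.
    """
    cycles = tuple(
        tuple(cycle) for cycle in nx.cycle_basis(network)
    )
    candidates: set[Node] = set()
    if groups is not None:
        for cycle in cycles:
            if len({groups[n] for n in cycle}) >= 2:
                candidates.update(cycle)
    return LoopReport(cycles=cycles, recombinant_candidates=frozenset(candidates))


# --------------------------------------------------------------------------
# Nested-clade hierarchy
# --------------------------------------------------------------------------


@dataclass
class NestedCladeHierarchy:
    """Multi-level partition of items: level k clades partition level k-1.

    ``levels[0]`` maps each item to its own singleton clade label; higher
    levels strictly coarsen the previous one.  Labels are free-form text
    (imported designs keep their published labels verbatim).
    """

    levels: list[dict[str, frozenset]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def items(self) -> frozenset:
        return frozenset().union(*self.levels[0].values()) if self.levels else frozenset()

    def clade_of(self, item, level: int) -> str:
        for label, members in self.levels[level].items():
            if item in members:
                return label
        raise KeyError(f"{item!r} not in hierarchy at level {level}")

    def children(self, label: str, level: int) -> list[str]:
        """Labels of the level-(k-1) clades nested inside a level-k clade."""
        if level == 0:
            raise ValueError("level-0 clades have no children")
        members = self.levels[level][label]
        return [
            sub
            for sub, sub_members in self.levels[level - 1].items()
            if sub_members <= members
        ]

    def validate(self) -> None:
        if not self.levels:
            return
        universe = self.items
        for k, partition in enumerate(self.levels):
            covered: set = set()
            for label, members in partition.items():
                overlap = covered & set(members)
                if overlap:
                    raise ValueError(
                        f"level {k}: item(s) {sorted(map(str, overlap))} in several clades"
                    )
                covered |= set(members)
            if covered != set(universe):
                raise ValueError(f"level {k}: partition does not cover all items")
        for k in range(1, len(self.levels)):
            for label, members in self.levels[k].items():
                for sub_label, sub_members in self.levels[k - 1].items():
                    inter = sub_members & members
                    if inter and inter != sub_members:
                        raise ValueError(
                            f"clade {label} (level {k}) splits {sub_label} (level {k - 1})"
                        )


def _nest_once(graph: nx.Graph) -> list[frozenset]:
    """One round of tip-inward nesting on an (unweighted) clade graph.

    Tips are grouped with the interior node one step inward; interior anchor
    nodes are processed in decreasing eccentricity (lexicographic id on
    ties), each absorbing its still-free tip neighbours.  Nodes left over
    (stranded tips, isolated nodes, or interior nodes away from any tip)
    become singleton clades of this level.
    """
    clades: list[frozenset] = []
    unassigned = set(graph.nodes)
    for component in nx.connected_components(graph):
        component = set(component)
        if len(component) <= 2:
            clades.append(frozenset(component))
            unassigned -= component
            continue
        sub = graph.subgraph(component)
        ecc = nx.eccentricity(sub)
        tips = {n for n in component if sub.degree(n) <= 1}
        anchors = sorted(
            (n for n in component - tips if any(t in tips for t in sub.neighbors(n))),
            key=lambda n: (-ecc[n], str(n)),
        )
        taken: set = set()
        n_before = len(clades)
        for anchor in anchors:
            members = {anchor} | {
                t for t in sub.neighbors(anchor) if t in tips and t not in taken
            }
            if len(members) == 1:
                continue  # this anchor's tips were absorbed already
            clades.append(frozenset(members))
            taken |= members
        if len(clades) == n_before:
            # tip-less component (a pure cycle): treat it as one clade
            clades.append(frozenset(component))
        else:
            for leftover in sorted(component - taken, key=str):
                clades.append(frozenset({leftover}))
        unassigned -= component
    for leftover in sorted(unassigned, key=str):
        clades.append(frozenset({leftover}))
    return clades


def nest_clades(network: nx.Graph, max_level: int) -> NestedCladeHierarchy:
    """Build a nested-clade hierarchy from a (haplotype) network.

    Level-1 clades union nodes within one step working inward from the tips;
    each following level repeats the procedure on the clade graph (clades
    adjacent iff any of their members are).  Nesting stops at ``max_level``
    or when a single clade per component remains.  Labels are ``"<k>-<i>"``
    with clades ordered by their smallest member id.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    items = sorted(network.nodes, key=str)
    levels: list[dict[str, frozenset]] = [
        {f"0-{i + 1}": frozenset({item}) for i, item in enumerate(items)}
    ]
    # work on a graph whose nodes are item sets; start from singletons
    graph = nx.Graph()
    singleton = {item: frozenset({item}) for item in items}
    graph.add_nodes_from(singleton.values())
    for u, v in network.edges:
        graph.add_edge(singleton[u], singleton[v])

    for k in range(1, max_level + 1):
        if graph.number_of_nodes() == nx.number_connected_components(graph):
            # fully nested: carry the partition unchanged up to max_level
            item_sets = sorted(graph.nodes, key=lambda s: min(map(str, s)))
        else:
            grouped = _nest_once(graph)  # list of frozensets of item-set nodes
            item_sets = sorted(
                (frozenset().union(*clade) for clade in grouped),
                key=lambda s: min(map(str, s)),
            )
            next_graph = nx.Graph()
            next_graph.add_nodes_from(item_sets)
            for a, b in itertools.combinations(item_sets, 2):
                if any(
                    graph.has_edge(u, v) for u in _parts(graph, a) for v in _parts(graph, b)
                ):
                    next_graph.add_edge(a, b)
            graph = next_graph
        levels.append({f"{k}-{i + 1}": members for i, members in enumerate(item_sets)})
    return NestedCladeHierarchy(levels=levels)


def _parts(graph: nx.Graph, merged: frozenset) -> list[frozenset]:
    """Nodes of ``graph`` whose items are inside the merged clade."""
    return [node for node in graph.nodes if node <= merged]


# --------------------------------------------------------------------------
# Nesting table I/O
# --------------------------------------------------------------------------

_DASHES = str.maketrans({"‐": "-", "‑": "-", "‒": "-", "–": "-"})


def import_nesting(rows: Iterable[Mapping[str, str]]) -> NestedCladeHierarchy:
    """Build a hierarchy from assignment rows (haplotype, clade_L1, ...).

    Each row assigns one item a clade label per level; labels are kept
    verbatim apart from normalising Unicode hyphens to ASCII.  Raises on
    overlapping or non-nested assignments, naming the offending item.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("empty nesting table")
    level_cols = sorted(
        (c for c in rows[0] if c.lower().startswith("clade_l")),
        key=lambda c: int(c.rsplit("l", 1)[-1].rsplit("L", 1)[-1]),
    )
    if not level_cols:
        raise ValueError("no clade_L<k> columns found")
    item_col = next(c for c in rows[0] if not c.lower().startswith("clade_l"))

    assignment: dict[str, list[str]] = {}
    for row in rows:
        item = row[item_col].strip()
        labels = [row[c].strip().translate(_DASHES) for c in level_cols]
        if item in assignment and assignment[item] != labels:
            raise ValueError(f"item {item!r} assigned to conflicting clades")
        assignment[item] = labels

    levels: list[dict[str, frozenset]] = [
        {f"0-{i + 1}": frozenset({item}) for i, item in enumerate(sorted(assignment))}
    ]
    for k in range(len(level_cols)):
        partition: dict[str, set] = {}
        for item, labels in assignment.items():
            partition.setdefault(labels[k], set()).add(item)
        levels.append({label: frozenset(members) for label, members in sorted(partition.items())})
    try:
        return NestedCladeHierarchy(levels=levels)
    except ValueError as exc:
        raise ValueError(f"invalid nesting table: {exc}") from exc


def read_nesting_table(path: str) -> NestedCladeHierarchy:
    import csv

    with open(path, newline="") as fh:
        return import_nesting(csv.DictReader(fh, delimiter="\t"))


def write_nesting_table(hierarchy: NestedCladeHierarchy, path: str) -> None:
    import csv

    n = hierarchy.n_levels - 1
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["haplotype"] + [f"clade_L{k}" for k in range(1, n + 1)])
        for item in sorted(hierarchy.items, key=str):
            writer.writerow(
                [item] + [hierarchy.clade_of(item, k) for k in range(1, n + 1)]
            )


def write_edge_list(network: nx.Graph, path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node1", "node2", "weight"])
        for u, v, data in sorted(network.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            writer.writerow([u, v, data.get("weight", 1)])
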
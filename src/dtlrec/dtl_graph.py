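"""The reconciliation graph: all canonical MPRs in one compact DAG.

The graph is bipartite: *mapping* nodes <u, x> associate a gene-tree node u
with a node x of the subdivided species tree, *event* nodes hang below them
and point to the mapping nodes of the event's children.  Every reconciliation
tree embedded in the graph (pick one event child per mapping node, all
mapping children of each chosen event) is a canonical MPR, and every
canonical MPR appears exactly once, so a single bottom-up/top-down traversal
counts, for every node, the number N(v) of MPRs through it -- the basis of
the event supports.

Built by re-reading the co-optimal cases of the dtl_core dynamic program
from all optimal roots (the gene root may be optimally placed on several
branches, hence multiple graph roots).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .dtl_core import (
    EPS,
    CostVector,
    DTLDynamicProgram,
    Event,
    Reconciliation,
)
from .trees_io import GeneTree, SubdividedSpeciesTree

__all__ = ["DTLGraph", "MappingNode", "EventNode", "build_mpr_graph", "annotate_counts", "extract_reconciliation"]

ROOT = 2  # cell flag for canonical root cells (dtl_core uses FRESH=0, STALE=1)

Cell = tuple[int, int, int]  # (gene node, S' node, flag)


@dataclass
class MappingNode:
    cell: Cell
    events: list["EventNode"] = field(default_factory=list)
    below: int = 0
    above: int = 0

    @property
    def count(self) -> int:
        return self.below * self.above

    @property
    def gene(self) -> int:
        return self.cell[0]

    @property
    def x(self) -> int:
        return self.cell[1]


@dataclass
class EventNode:
    event: Event  # gene node, type, x, receiver, child_x
    parent: MappingNode
    children: tuple[MappingNode, ...]
    below: int = 0
    above: int = 0

    @property
    def count(self) -> int:
        return self.below * self.above

    @property
    def etype(self) -> str:
        return self.event.etype


class DTLGraph:
    """All-canonical-MPR graph for one (gene tree, species tree, costs) triple."""

    def __init__(
        self,
        gene_tree: GeneTree,
        sprime: SubdividedSpeciesTree,
        costs: CostVector,
        opt_cost: float,
        mappings: dict[Cell, MappingNode],
        roots: list[MappingNode],
    ):
        self.gene_tree = gene_tree
        self.sprime = sprime
        self.costs = costs
        self.opt_cost = opt_cost
        self.mappings = mappings
        self.roots = roots
        self.N_total: int | None = None

    # -- iteration ---------------------------------------------------------
    def event_nodes(self):
        for m in self.mappings.values():
            yield from m.events

    def postorder(self):
        """Mapping and event nodes, children before parents, deterministic."""
        seen: set[int] = set()
        order: list = []
        stack: list[tuple[object, bool]] = [(m, False) for m in reversed(self.roots)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            kids = node.events if isinstance(node, MappingNode) else node.children
            for k in reversed(kids):
                stack.append((k, False))
        return order

    @property
    def n_mapping_nodes(self) -> int:
        return len(self.mappings)

    @property
    def n_event_nodes(self) -> int:
        return sum(len(m.events) for m in self.mappings.values())

    # -- display -----------------------------------------------------------
    def _mlabel(self, m: MappingNode) -> str:
        return f"<{self.gene_tree.ids[m.gene]},{self.sprime.node_id(m.x)}>"

    def _elabel(self, e: EventNode) -> str:
        ev = e.event
        lbl = f"{ev.etype} {self.gene_tree.ids[ev.gene]}@{self.sprime.node_id(ev.x)}"
        if ev.receiver is not None:
            lbl += f"->{self.sprime.node_id(ev.receiver)}"
        return lbl

    def to_dot(self) -> str:
        lines = ["digraph dtl {", "  node [fontsize=10];"]
        ids: dict[int, str] = {}

        def nid(node) -> str:
            if id(node) not in ids:
                ids[id(node)] = f"n{len(ids)}"
            return ids[id(node)]

        for m in self.mappings.values():
            n = f"{self._mlabel(m)}, {m.count}" if self.N_total else self._mlabel(m)
            lines.append(f'  {nid(m)} [shape=box, style=solid, label="{n}"];')
            for e in m.events:
                n = f"{self._elabel(e)}, {e.count}" if self.N_total else self._elabel(e)
                lines.append(f'  {nid(e)} [shape=box, style=dashed, label="{n}"];')
                lines.append(f"  {nid(m)} -> {nid(e)};")
                for c in e.children:
                    lines.append(f"  {nid(e)} -> {nid(c)};")
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        mapping_ids = {id(m): i for i, m in enumerate(self.mappings.values())}
        out = {
            "optimal_cost": self.opt_cost,
            "n_reconciliations": self.N_total,
            "roots": [mapping_ids[id(r)] for r in self.roots],
            "mapping_nodes": [],
        }
        for m in self.mappings.values():
            out["mapping_nodes"].append(
                {
                    "id": mapping_ids[id(m)],
                    "gene": self.gene_tree.ids[m.gene],
                    "species": self.sprime.node_id(m.x),
                    "count": m.count if self.N_total else None,
                    "events": [
                        {
                            "type": e.etype,
                            "label": self._elabel(e),
                            "count": e.count if self.N_total else None,
                            "children": [mapping_ids[id(c)] for c in e.children],
                        }
                        for e in m.events
                    ],
                }
            )
        return json.dumps(out, indent=1)


def build_mpr_graph(
    G: GeneTree, Sp: SubdividedSpeciesTree, costs: CostVector
) -> DTLGraph:
    """Build and annotate the graph of all canonical MPRs.

    Runs the dynamic program, keeps every locally co-optimal case, and
    prunes to the cells reachable from the optimal roots.
    """
    dp = DTLDynamicProgram(G, Sp, costs)
    opt = dp.opt_cost
    mappings: dict[Cell, MappingNode] = {}

    def get(cell: Cell) -> MappingNode:
        if cell not in mappings:
            mappings[cell] = MappingNode(cell)
        return mappings[cell]

    roots: list[MappingNode] = []
    queue: list[Cell] = []
    for x in range(len(Sp.children)):
        if dp.root_values[x] <= opt + EPS:
            cell = (G.root, x, ROOT)
            roots.append(get(cell))
            queue.append(cell)

    done: set[Cell] = set()
    while queue:
        cell = queue.pop()
        if cell in done:
            continue
        done.add(cell)
        u, x, flag = cell
        if flag == ROOT:
            opts = dp.root_options(x)
            target = dp.root_values[x]
        else:
            opts = dp.options(u, x, flag)
            target = dp.c[u][x][flag]
        m = mappings[cell]
        seen_specs = set()
        for value, etype, children, receiver in opts:
            if abs(value - target) > EPS:
                continue
            spec = (etype, children, receiver)
            if spec in seen_specs:  # e.g. symmetric S assignments that coincide
                continue
            seen_specs.add(spec)
            child_x = children[0][1] if etype in ("S", "SL") else None
            ev = Event(u, etype, x, receiver=receiver, child_x=child_x)
            enode = EventNode(ev, m, tuple(get(c) for c in children))
            m.events.append(enode)
            for c in children:
                if c not in done:
                    queue.append(c)
        if not m.events:
            raise RuntimeError("dangling mapping node: inconsistent DP values")

    graph = DTLGraph(G, Sp, costs, opt, mappings, roots)
    annotate_counts(graph)
    return graph


def annotate_counts(graph: DTLGraph) -> DTLGraph:
    """Fill below/above decomposition counts and N_total.

    below(v): partial reconciliation subtrees rooted at v; above(v):
    completions from a root down to v; N(v) = below * above is the number
    of encoded MPRs through v.
    """
    order = graph.postorder()
    for node in order:
        if isinstance(node, MappingNode):
            node.below = sum(e.below for e in node.events)
        else:
            p = 1
            for c in node.children:
                p *= c.below
            node.below = p
        node.above = 0
    for r in graph.roots:
        r.above = 1
    for node in reversed(order):  # parents before children
        if isinstance(node, MappingNode):
            for e in node.events:
                e.above = node.above
        else:
            for c in node.children:
                contrib = node.above
                for sib in node.children:
                    if sib is not c:
                        contrib *= sib.below
                c.above += contrib
    graph.N_total = sum(r.below for r in graph.roots)
    return graph


def extract_reconciliation(
    graph: DTLGraph,
    selector: str | dict = "random",
    rng: random.Random | None = None,
    root: MappingNode | None = None,
) -> Reconciliation:
    """Materialize one reconciliation tree of the graph.

    ``selector='random'`` draws uniformly over the encoded canonical MPRs
    (roots and event children weighted by their below-counts); a dict
    selector maps ``id(MappingNode) -> EventNode`` (the marks produced by
    the median backtrack).
    """
    if graph.N_total is None:
        annotate_counts(graph)
    if graph.N_total == 0:
        raise RuntimeError("empty graph")
    marks: dict[int, EventNode] | None = None
    if isinstance(selector, dict):
        marks = selector
        if root is None:
            root = next((r for r in graph.roots if id(r) in marks), None)
        if root is None:
            raise ValueError("marks do not cover any root")
    else:
        if selector != "random":
            raise ValueError(f"unknown selector {selector!r}")
        rng = rng or random.Random()
        weights = [r.below for r in graph.roots]
        root = rng.choices(graph.roots, weights=weights)[0]

    events: list[Event] = []

    def walk(m: MappingNode) -> None:
        if marks is not None:
            e = marks.get(id(m))
            if e is None or e not in m.events:
                raise ValueError("marks do not select a full reconciliation tree")
        else:
            e = rng.choices(m.events, weights=[c.below for c in m.events])[0]
        events.append(e.event)
        for c in e.children:
            walk(c)

    walk(root)
    R = Reconciliation(graph.gene_tree, graph.sprime, events)
    R.found_cost = R.cost(graph.costs)
    return R
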
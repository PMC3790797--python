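"""Median reconciliations.

With event identity taken with respect to S (C events excluded -- they are
shared by all reconciliations), the asymmetric distance between two
reconciliations counts the events of the second missing from the first,
d_asym(R1, R2) = |E(R2) \\ E(R1)|, and the symmetric distance is the size
of the symmetric difference.  The (a)symmetric median of a reconciliation
set minimizes the summed distance to the whole set, restricted to members
of the set; equivalently it maximizes sum_{e in E(R)} f(e) (asymmetric) or
sum_{e in E(R)} (f(e) - 1/2) (symmetric), f being the event frequencies in
the set.

On a reconciliation graph these maximizers are found in one bottom-up pass:
score every event node with its (offset) support, propagate best partial
scores (sum at event nodes, max at mapping nodes), and backtrack from the
best root -- linear in the size of the graph, despite the possibly
exponential number of encoded reconciliations.
"""

from __future__ import annotations

from typing import Iterable

from .dtl_core import Reconciliation
from .dtl_graph import DTLGraph, EventNode, extract_reconciliation
from .support import SCORED_TYPES, SupportTable, event_key, reconciliation_keys

__all__ = ["d_asym", "d_sym", "max_support_tree", "median_over_nprs"]


def _keys(R) -> frozenset:
    if isinstance(R, Reconciliation):
        return reconciliation_keys(R)
    return frozenset(R)


def _check_same_instance(R1, R2) -> None:
    if isinstance(R1, Reconciliation) and isinstance(R2, Reconciliation):
        if R1.gene_tree is not R2.gene_tree or R1.sprime is not R2.sprime:
            raise ValueError("distances require reconciliations of one (G, S) pair")


def d_asym(R1, R2) -> int:
    """Number of events of R2 missing from R1 (not symmetric)."""
    _check_same_instance(R1, R2)
    return len(_keys(R2) - _keys(R1))


def d_sym(R1, R2) -> int:
    """Size of the symmetric difference of the two event sets."""
    _check_same_instance(R1, R2)
    return len(_keys(R1) ^ _keys(R2))


# deterministic tie-break order on event nodes
_TYPE_RANK = {"S": 0, "D": 1, "T": 2, "TL": 3, "SL": 4, "NE": 5, "C": 6}


def _order_key(e: EventNode):
    ev = e.event
    return (
        _TYPE_RANK[ev.etype],
        ev.x,
        -1 if ev.receiver is None else ev.receiver,
        tuple(c.cell for c in e.children),
    )


def max_support_tree(
    graph: DTLGraph,
    supports: SupportTable,
    offset: float = 0.0,
) -> Reconciliation:
    """Reconciliation tree maximizing sum of (support - offset) over its events.

    ``offset=0`` solves the asymmetric median problem, ``offset=0.5`` the
    symmetric one (subtracting 1/2 from every support turns the one into
    the other).  Supports may come from the graph's own MPRs or from a
    pooled NPR table.  Ties are broken deterministically (event type order
    S < D < T < TL < SL < NE, then species node, then children).  The
    returned reconciliation carries its criterion value in
    ``support_score``.
    """
    if graph.N_total is None:
        raise ValueError("graph must be annotated with counts")
    score: dict[int, float] = {}
    marks: dict[int, EventNode] = {}
    for node in graph.postorder():
        if isinstance(node, EventNode):
            ev = node.event
            w = 0.0
            if ev.etype in SCORED_TYPES:
                k = event_key(ev, graph.gene_tree, graph.sprime)
                f = supports.f(k)
                if f <= 0.0:
                    raise ValueError(f"missing support for event {k}")
                w = f - offset
            score[id(node)] = w + sum(score[id(c)] for c in node.children)
        else:
            best = None
            for e in sorted(node.events, key=_order_key):
                s = score[id(e)]
                if best is None or s > best + 1e-12:
                    best = s
                    marks[id(node)] = e
            score[id(node)] = best
    root = None
    for r in sorted(graph.roots, key=lambda m: m.cell):
        if root is None or score[id(r)] > score[id(root)] + 1e-12:
            root = r
    R = extract_reconciliation(graph, selector=marks, root=root)
    R.support_score = score[id(root)]
    return R


def median_over_nprs(
    graphs: Iterable[DTLGraph],
    npr_table: SupportTable,
    mode: str = "sym",
) -> Reconciliation:
    """Best max-support tree across a set of perturbed-cost graphs.

    Runs the extraction on every graph with the pooled NPR supports and
    returns the overall best-scoring reconciliation (deterministic
    tie-break: first graph wins ties).
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("need at least one graph")
    if mode not in ("asym", "sym"):
        raise ValueError("mode must be 'asym' or 'sym'")
    offset = 0.0 if mode == "asym" else 0.5
    best: Reconciliation | None = None
    for g in graphs:
        R = max_support_tree(g, npr_table, offset)
        if best is None or R.support_score > best.support_score + 1e-12:
            best = R
    return best
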
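"""Event identity across reconciliations, and event-support tables.

Two events of different reconciliations of the same (G, S) pair are *the
same event* when they concern the same gene node, the same location on the
original species tree S (slices of S' collapse: an NE chain does not change
an event's identity), and matching child placements -- with transfers
identified by their (donor branch, receiver branch) pair and
speciation-losses by their surviving child branch.  ``EventKey`` is the
canonical hashable form of that identity.

Supports are frequencies in a reconciliation set: the MPR support of an
event is the fraction of canonical most-parsimonious reconciliations
containing it (computed from one reconciliation graph), the NPR support the
fraction of all sampled near-optimal reconciliations containing it (pooled
over many graphs built under perturbed costs).  C and NE events are shared
by every reconciliation and carry no information, so they are never tabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .dtl_core import Event, Reconciliation
from .trees_io import GeneTree, SubdividedSpeciesTree

__all__ = [
    "EventKey",
    "SupportTable",
    "event_key",
    "reconciliation_keys",
    "mpr_supports",
    "npr_supports",
    "filter_events",
]

#: event types that enter event sets / support tables
SCORED_TYPES = ("S", "D", "T", "TL", "SL")


class EventKey(NamedTuple):
    """Identity of an event with respect to the original species tree S.

    ``where`` is the id of the S node carrying the event (for S/SL: the
    speciation node; for D/T/TL: the S node at the bottom of the branch);
    ``extra`` is the receiver branch for T/TL and the surviving child
    branch for SL, else None.
    """

    gene: str
    etype: str
    where: str
    extra: str | None = None


def event_key(e: Event, gene_tree: GeneTree, sprime: SubdividedSpeciesTree) -> EventKey:
    """Project an event onto S; invariant under its placement along NE chains."""
    S = sprime.S
    g = gene_tree.ids[e.gene]
    branch = S.ids[sprime.s_branch[e.x]]
    if e.etype == "S":
        return EventKey(g, "S", branch)
    if e.etype == "SL":
        if e.child_x is None:
            raise ValueError("SL event needs its surviving child")
        return EventKey(g, "SL", branch, S.ids[sprime.s_branch[e.child_x]])
    if e.etype == "D":
        return EventKey(g, "D", branch)
    if e.etype in ("T", "TL"):
        if e.receiver is None:
            raise ValueError("transfer event needs a receiver")
        return EventKey(g, e.etype, branch, S.ids[sprime.s_branch[e.receiver]])
    raise ValueError(f"{e.etype} events have no identity across reconciliations")


def reconciliation_keys(R: Reconciliation) -> frozenset[EventKey]:
    """The event set E(R) of a reconciliation (C and NE excluded)."""
    return frozenset(
        event_key(e, R.gene_tree, R.sprime)
        for e in R.events
        if e.etype in SCORED_TYPES
    )


@dataclass
class SupportTable:
    """EventKey -> frequency in (0, 1], with its provenance.

    ``total`` is the number of reconciliations the frequencies refer to
    (N_total for MPR supports, the summed graph counts for NPR supports).
    """

    freqs: dict[EventKey, float]
    provenance: str = "MPR"
    total: int = 0
    meta: dict = field(default_factory=dict)

    def f(self, key: EventKey) -> float:
        return self.freqs.get(key, 0.0)

    def __iter__(self):
        return iter(self.freqs.items())

    def __len__(self) -> int:
        return len(self.freqs)

    def to_tsv(self) -> str:
        rows = [
            "gene_node_id\tevent_type\tspecies_branch\treceiver_branch\tsupport\tprovenance"
        ]
        for k in sorted(self.freqs):
            rows.append(
                "\t".join(
                    [k.gene, k.etype, k.where, k.extra or "", f"{self.freqs[k]:.6g}", self.provenance]
                )
            )
        return "\n".join(rows) + "\n"


def mpr_supports(graph) -> SupportTable:
    """Per-event frequencies among the canonical MPRs encoded in one graph."""
    if graph.N_total is None:
        raise ValueError("graph must be annotated with counts first")
    if graph.N_total <= 0:
        raise RuntimeError("empty reconciliation graph")
    sums = _key_counts(graph)
    freqs = {k: n / graph.N_total for k, n in sums.items() if n > 0}
    return SupportTable(freqs, provenance="MPR", total=graph.N_total)


def _key_counts(graph) -> dict[EventKey, int]:
    """Number of reconciliations of the graph containing each event."""
    sums: dict[EventKey, int] = {}
    for node in graph.event_nodes():
        ev = node.event
        if ev.etype not in SCORED_TYPES:
            continue
        k = event_key(ev, graph.gene_tree, graph.sprime)
        sums[k] = sums.get(k, 0) + node.count
    return sums


def npr_supports(graphs: Iterable, weighted: bool = True) -> SupportTable:
    """Pool event frequencies over graphs built under perturbed costs.

    With ``weighted=True`` (the definition used throughout: the fraction of
    all sampled near-optimal reconciliations containing the event)
    f(e) = sum_i count_i(e) / sum_i N_i.  ``weighted=False`` averages the
    per-graph frequencies instead, for sensitivity analysis.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("need at least one graph")
    if weighted:
        total = 0
        sums: dict[EventKey, int] = {}
        for g in graphs:
            total += g.N_total
            for k, n in _key_counts(g).items():
                sums[k] = sums.get(k, 0) + n
        freqs = {k: n / total for k, n in sums.items() if n > 0}
    else:
        total = sum(g.N_total for g in graphs)
        acc: dict[EventKey, float] = {}
        for g in graphs:
            for k, n in _key_counts(g).items():
                acc[k] = acc.get(k, 0.0) + n / g.N_total
        freqs = {k: v / len(graphs) for k, v in acc.items() if v > 0}
    return SupportTable(
        freqs,
        provenance=f"NPR(n={len(graphs)})",
        total=total,
        meta={"n_graphs": len(graphs)},
    )


def filter_events(
    events: Reconciliation | Iterable[EventKey],
    supports: SupportTable,
    threshold: float,
) -> set[EventKey]:
    """Keep the events whose support is not smaller than the threshold.

    The result is in general only a partial history (the retained events
    need not form a valid reconciliation).  Events absent from the table
    have support 0, so ``threshold=0`` is the identity.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if isinstance(events, Reconciliation):
        keys = events.event_keys()
    else:
        keys = set(events)
    return {k for k in keys if supports.f(k) >= threshold}
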
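"""The DTL parsimony model.

A reconciliation maps every gene-tree node to an ordered list of nodes of
the subdivided species tree S', each paired with one of seven atomic
events: speciation (S), duplication (D), transfer (T), transfer+loss of the
non-transferred copy (TL), speciation+loss of one copy (SL), no-event (NE,
crossing a time-slice boundary) and the contemporary event (C) tying an
extant gene to its species.  Its cost is d*delta + t*tau + l*lambda, where
d counts D events, t counts T and TL events, and l counts SL and TL events
(a TL is one transfer plus one loss; there is no standalone loss in this
vocabulary).  S, NE and C are free.

``mpr_cost`` / ``DTLDynamicProgram`` implement the slice-by-slice dynamic
program over cells (gene node u, S' node x); the graph module re-reads its
co-optimal cases.  ``enumerate_reconciliations_bruteforce`` is a separate,
deliberately naive bounded search used as a test oracle.

Canonical form.  Distinct reconciliations on S' can induce the same event
set with respect to S (a free NE chain lets a D, or a transfer, slide along
the slices of one S branch).  The DP therefore distinguishes, for every
cell, whether the lineage just *entered* the branch segment ("fresh") or
arrived through an NE ("stale"): a D is only allowed at fresh cells, and a
transfer below a fresh cell only when its receiver branch was not yet
available one slice earlier.  Together with pinning the root's first event
(never an NE, and pinned to its earliest feasible cell), every equivalence
class of MPRs is represented by exactly one reconciliation tree, which is
what makes graph counts counts *of canonical MPRs*.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass

from .trees_io import GeneTree, SubdividedSpeciesTree

__all__ = [
    "EPS",
    "FRESH",
    "STALE",
    "CostVector",
    "Event",
    "Reconciliation",
    "ReconciliationError",
    "reconciliation_cost",
    "event_census",
    "DTLDynamicProgram",
    "mpr_cost",
    "enumerate_reconciliations_bruteforce",
]

EPS = 1e-9  # cost-equality tolerance throughout the package

FRESH, STALE = 0, 1


class ReconciliationError(ValueError):
    pass


@dataclass(frozen=True)
class CostVector:
    """Costs of the chargeable atomic events (S, NE and C are free)."""

    dup: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dup > 0 and self.transfer > 0 and self.loss > 0):
            raise ValueError("duplication, transfer and loss costs must be positive")

    def scaled(self, k: float) -> "CostVector":
        return CostVector(self.dup * k, self.transfer * k, self.loss * k)


EVENT_TYPES = ("S", "D", "T", "TL", "SL", "NE", "C")


@dataclass(frozen=True)
class Event:
    """One atomic event of a reconciliation.

    ``x`` is the S' node whose branch segment carries the event; for T/TL,
    ``receiver`` is the S' node of the receiving branch (same slice as x);
    for S/SL, ``child_x`` is the S' child the surviving/first lineage
    continues into (SL: the surviving side).
    """

    gene: int
    etype: str
    x: int
    receiver: int | None = None
    child_x: int | None = None


class Reconciliation:
    """An explicit reconciliation: per-gene-node event chains on S'."""

    def __init__(
        self,
        gene_tree: GeneTree,
        sprime: SubdividedSpeciesTree,
        events: list[Event],
    ):
        self.gene_tree = gene_tree
        self.sprime = sprime
        self.events = list(events)

    # -- censuses and cost -------------------------------------------------
    def census(self) -> dict[str, int]:
        counts = Counter(e.etype for e in self.events)
        return {t: counts.get(t, 0) for t in EVENT_TYPES if counts.get(t, 0)}

    def dtl_counts(self) -> tuple[int, int, int]:
        c = Counter(e.etype for e in self.events)
        d = c.get("D", 0)
        t = c.get("T", 0) + c.get("TL", 0)
        l = c.get("SL", 0) + c.get("TL", 0)
        return d, t, l

    def cost(self, costs: CostVector) -> float:
        d, t, l = self.dtl_counts()
        return d * costs.dup + t * costs.transfer + l * costs.loss

    def event_keys(self):
        from .support import reconciliation_keys

        return reconciliation_keys(self)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        G, Sp = self.gene_tree, self.sprime
        by_gene: dict[int, list[Event]] = {}
        for e in self.events:
            if e.etype not in EVENT_TYPES:
                raise ReconciliationError(f"unknown event type {e.etype!r}")
            by_gene.setdefault(e.gene, []).append(e)
        for u in G.postorder():
            evs = by_gene.get(u)
            if not evs:
                raise ReconciliationError(f"gene node {G.ids[u]} has no events")
            last = evs[-1]
            if G.children[u]:
                if last.etype not in ("S", "D", "T"):
                    raise ReconciliationError(
                        f"internal gene node {G.ids[u]} must end with S, D or T"
                    )
            else:
                if last.etype != "C":
                    raise ReconciliationError(
                        f"gene leaf {G.ids[u]} must end with a C event"
                    )
                if Sp.orig[last.x] < 0 or Sp.S.labels[Sp.orig[last.x]] != G.species_of(u):
                    raise ReconciliationError(
                        f"gene leaf {G.ids[u]} maps to the wrong species"
                    )
            dates = [Sp.dates[e.x] for e in evs]
            if any(a < b for a, b in zip(dates, dates[1:])):
                raise ReconciliationError(
                    f"alpha({G.ids[u]}) is not time-consistent"
                )
            for e in evs:
                if e.etype in ("T", "TL"):
                    if e.receiver is None or e.receiver == e.x:
                        raise ReconciliationError("transfer needs a distinct receiver")
                    if Sp.dates[e.receiver] != Sp.dates[e.x]:
                        raise ReconciliationError(
                            "transfer endpoints must share a time slice"
                        )
                if e.etype == "NE" and not Sp.is_artificial[e.x]:
                    raise ReconciliationError("NE only occurs at artificial nodes")

    # -- serialization -----------------------------------------------------
    def to_tsv(self) -> str:
        Sp = self.sprime
        G = self.gene_tree
        rows = ["gene_node_id\tevent_type\tspecies_branch\treceiver_branch\tslice_index"]
        for e in self.events:
            recv = (
                Sp.S.ids[Sp.s_branch[e.receiver]] if e.receiver is not None else ""
            )
            rows.append(
                "\t".join(
                    [
                        G.ids[e.gene],
                        e.etype,
                        Sp.S.ids[Sp.s_branch[e.x]],
                        recv,
                        str(Sp.date_class[e.x]),
                    ]
                )
            )
        return "\n".join(rows) + "\n"

    def to_json(self) -> str:
        Sp = self.sprime
        G = self.gene_tree
        alpha: dict[str, list[dict]] = {}
        for e in self.events:
            alpha.setdefault(G.ids[e.gene], []).append(
                {
                    "node": Sp.node_id(e.x),
                    "event": e.etype,
                    "receiver": Sp.node_id(e.receiver) if e.receiver is not None else None,
                }
            )
        return json.dumps({"alpha": alpha}, indent=1)


def reconciliation_cost(R: Reconciliation, costs: CostVector, validate: bool = True) -> float:
    """Cost d*delta + t*tau + l*lambda of a reconciliation."""
    if validate:
        R.validate()
    return R.cost(costs)


def event_census(R: Reconciliation) -> dict[str, int]:
    """Counts of each atomic event type in a reconciliation."""
    return R.census()


# ---------------------------------------------------------------------------
# the dynamic program
# ---------------------------------------------------------------------------

INF = math.inf


class DTLDynamicProgram:
    """Minimum-cost DP over cells (gene node u, S' node x, fresh/stale).

    Values are exact minima over canonical reconciliations; ``options`` and
    ``root_options`` re-enumerate the locally co-optimal cases so the graph
    module can retain all of them.
    """

    def __init__(self, G: GeneTree, Sp: SubdividedSpeciesTree, costs: CostVector):
        self.G, self.Sp, self.costs = G, Sp, costs
        self._prepare()
        self._run()
        self._root_pass()

    # -- setup -------------------------------------------------------------
    def _prepare(self) -> None:
        G, Sp = self.G, self.Sp
        self.nx = len(Sp.children)
        # species leaf cell for each gene leaf
        self.leaf_x = {}
        for u in G.postorder():
            if not G.children[u]:
                sp = G.species_of(u)
                if sp not in Sp.label_index:
                    raise ReconciliationError(
                        f"gene leaf {G.labels[u]!r} maps to species {sp!r} "
                        "absent from the species tree"
                    )
                self.leaf_x[u] = Sp.label_index[sp]
        # per class: nodes, and nodes whose branch is newly available
        # (its S branch has no node one slice up)
        self.new_in_class: list[list[int]] = []
        for k, nodes in enumerate(Sp.classes):
            if k + 1 < Sp.n_slices:
                up = Sp.class_dates[k + 1]
                self.new_in_class.append(
                    [y for y in nodes if Sp.branch_top_date[y] == up]
                )
            else:
                self.new_in_class.append([])
        self.top_of_branch = [
            Sp.parent[x] == -1 or not Sp.is_artificial[Sp.parent[x]]
            for x in range(self.nx)
        ]

    # -- value recursion ---------------------------------------------------
    def _run(self) -> None:
        G, Sp, cv = self.G, self.Sp, self.costs
        nx = self.nx
        tl_cost = cv.transfer + cv.loss
        # c[u][x][flag]
        self.c = [[[INF, INF] for _ in range(nx)] for _ in G.postorder()]
        # per gene/class minima over fresh values (for T): (m1, m2) and new-only m1
        self._min_fresh = [[None] * Sp.n_slices for _ in G.postorder()]
        self._min_fresh_new = [[INF] * Sp.n_slices for _ in G.postorder()]

        for u in G.postorder():
            cu = self.c[u]
            for k, nodes in enumerate(Sp.classes):
                base = {}
                for x in nodes:
                    for flag in (FRESH, STALE):
                        if flag == STALE and self.top_of_branch[x]:
                            base[(x, flag)] = INF
                            continue
                        base[(x, flag)] = self._base_value(u, x, flag, k)
                # TL relaxation: one pass over pre-TL values
                vals = [base[(x, FRESH)] for x in nodes]
                m1, m2, a1 = _top2(vals)
                new_nodes = self.new_in_class[k]
                new_set = set(new_nodes)
                nm1, nm2, na1 = _top2([base[(y, FRESH)] for y in new_nodes])
                for i, x in enumerate(nodes):
                    bf = base[(x, FRESH)]
                    other = m2 if a1 == i else m1
                    cu[x][FRESH] = min(bf, tl_cost + other)
                    if self.top_of_branch[x]:
                        cu[x][STALE] = INF  # unreachable: no NE leads here
                        continue
                    bs = base[(x, STALE)]
                    if x in new_set:
                        j = new_nodes.index(x)
                        nother = nm2 if na1 == j else nm1
                    else:
                        nother = nm1
                    cu[x][STALE] = min(bs, tl_cost + nother)
                # per-class fresh minima for parents' T cases
                fv = [cu[x][FRESH] for x in nodes]
                f1, f2, fa = _top2(fv)
                self._min_fresh[u][k] = (f1, f2, fa)
                self._min_fresh_new[u][k] = min(
                    (cu[y][FRESH] for y in new_nodes), default=INF
                )

        self.opt_cost_any = min(
            min(cell) for cell in self.c[G.root]
        )  # not canonical; informational

    def _base_value(self, u: int, x: int, flag: int, k: int) -> float:
        """Min over all non-TL cases at cell (u, x, flag)."""
        G, Sp, cv = self.G, self.Sp, self.costs
        c = self.c
        best = INF
        kids = G.children[u]
        orig = Sp.orig[x]
        sp_kids = Sp.children[x]
        if orig >= 0 and not sp_kids:  # extant species leaf
            if not kids and self.leaf_x[u] == x:
                best = 0.0  # C
        if orig >= 0 and sp_kids:  # original speciation node
            x1, x2 = sp_kids
            if kids:
                a, b = kids
                best = min(
                    best,
                    c[a][x1][FRESH] + c[b][x2][FRESH],
                    c[a][x2][FRESH] + c[b][x1][FRESH],
                )
            best = min(
                best,
                cv.loss + c[u][x1][FRESH],
                cv.loss + c[u][x2][FRESH],
            )
        if orig < 0:  # artificial: NE
            (x1,) = sp_kids
            best = min(best, c[u][x1][STALE])
        if kids:
            a, b = kids
            if flag == FRESH:
                best = min(best, cv.dup + c[a][x][FRESH] + c[b][x][FRESH])
            # T: other child to some y != x in the slice
            best = min(best, self._t_value(u, x, flag, k))
        return best

    def _t_value(self, u: int, x: int, flag: int, k: int) -> float:
        G, Sp, cv = self.G, self.Sp, self.costs
        a, b = G.children[u]
        c = self.c
        nodes = Sp.classes[k]
        best = INF
        if flag == FRESH:
            for g_stay, g_move in ((a, b), (b, a)):
                f1, f2, fa = self._min_fresh[g_move][k]
                idx = nodes.index(x)
                other = f2 if fa == idx else f1
                best = min(best, c[g_stay][x][FRESH] + other)
        else:
            for g_stay, g_move in ((a, b), (b, a)):
                m = INF
                for y in self.new_in_class[k]:
                    if y != x:
                        m = min(m, c[g_move][y][FRESH])
                best = min(best, c[g_stay][x][FRESH] + m)
        return cv.transfer + best if best < INF else INF

    # -- root pass ---------------------------------------------------------
    def _root_pass(self) -> None:
        """Canonical root values: first event never NE, pinned earliest."""
        G = self.G
        r = G.root
        self.root_values = [
            self._cell_min(r, x, root=True) for x in range(self.nx)
        ]
        self.opt_cost = min(self.root_values)

    def _cell_min(self, u: int, x: int, root: bool) -> float:
        opts = self.options(u, x, FRESH if self.top_of_branch[x] else STALE, root=root)
        return min((v for v, *_ in opts), default=INF)

    # -- co-optimal option enumeration (for the graph builder) -------------
    def options(self, u: int, x: int, flag: int, root: bool = False):
        """All cases at a cell with their exact values.

        Returns tuples ``(value, etype, children, receiver)`` where children
        is a tuple of child cells ``(gene, x, flag)``.  For root cells the NE
        case is omitted (a canonical root's first event is a real event).
        """
        G, Sp, cv = self.G, self.Sp, self.costs
        c = self.c
        out = []
        kids = G.children[u]
        orig = Sp.orig[x]
        sp_kids = Sp.children[x]
        k = Sp.date_class[x]
        if orig >= 0 and not sp_kids and not kids and self.leaf_x[u] == x:
            out.append((0.0, "C", (), None))
        if orig >= 0 and sp_kids:
            x1, x2 = sp_kids
            if kids:
                a, b = kids
                out.append(
                    (
                        c[a][x1][FRESH] + c[b][x2][FRESH],
                        "S",
                        ((a, x1, FRESH), (b, x2, FRESH)),
                        None,
                    )
                )
                out.append(
                    (
                        c[a][x2][FRESH] + c[b][x1][FRESH],
                        "S",
                        ((a, x2, FRESH), (b, x1, FRESH)),
                        None,
                    )
                )
            out.append((cv.loss + c[u][x1][FRESH], "SL", ((u, x1, FRESH),), None))
            out.append((cv.loss + c[u][x2][FRESH], "SL", ((u, x2, FRESH),), None))
        if orig < 0 and not root:
            (x1,) = sp_kids
            out.append((c[u][x1][STALE], "NE", ((u, x1, STALE),), None))
        if kids:
            a, b = kids
            if flag == FRESH:
                out.append(
                    (
                        cv.dup + c[a][x][FRESH] + c[b][x][FRESH],
                        "D",
                        ((a, x, FRESH), (b, x, FRESH)),
                        None,
                    )
                )
            receivers = (
                Sp.classes[k] if flag == FRESH else self.new_in_class[k]
            )
            for y in receivers:
                if y == x:
                    continue
                for g_stay, g_move in ((a, b), (b, a)):
                    out.append(
                        (
                            cv.transfer + c[g_stay][x][FRESH] + c[g_move][y][FRESH],
                            "T",
                            ((g_stay, x, FRESH), (g_move, y, FRESH)),
                            y,
                        )
                    )
        # TL: uses final values (ties may legitimately chain transfers)
        tl_cost = cv.transfer + cv.loss
        receivers = Sp.classes[k] if flag == FRESH else self.new_in_class[k]
        for y in receivers:
            if y == x:
                continue
            out.append((tl_cost + c[u][y][FRESH], "TL", ((u, y, FRESH),), y))
        return out

    def root_options(self, x: int):
        flag = FRESH if self.top_of_branch[x] else STALE
        return self.options(self.G.root, x, flag, root=True)


def _top2(values):
    """(min1, min2, argmin1) of a list, INF-padded."""
    m1 = m2 = INF
    a1 = -1
    for i, v in enumerate(values):
        if v < m1:
            m1, m2, a1 = v, m1, i
        elif v < m2:
            m2 = v
    return m1, m2, a1


def mpr_cost(G: GeneTree, Sp: SubdividedSpeciesTree, costs: CostVector) -> float:
    """Minimum reconciliation cost over all (canonical) reconciliations."""
    return DTLDynamicProgram(G, Sp, costs).opt_cost


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

_BRUTE_MAX_GENE_LEAVES = 10
_BRUTE_MAX_SPECIES = 7


def enumerate_reconciliations_bruteforce(
    G: GeneTree,
    Sp: SubdividedSpeciesTree,
    costs: CostVector,
    cost_bound: float,
) -> list[Reconciliation]:
    """Exhaustively list all valid reconciliations with cost <= cost_bound.

    A deliberately naive bounded depth-first search over the full (non
    canonical) reconciliation space, independent of the dynamic program; it
    exists to verify costs, graph counts, supports and medians on small
    instances and refuses anything bigger.  Duplicate NE placements are not
    collapsed here; callers deduplicate by projected event set
    (see :func:`dtlrec.support.reconciliation_keys`).
    """
    if G.n_leaves > _BRUTE_MAX_GENE_LEAVES or Sp.S.n_leaves > _BRUTE_MAX_SPECIES:
        raise ValueError(
            "brute-force enumeration is a small-instance oracle "
            f"(<= {_BRUTE_MAX_GENE_LEAVES} gene leaves, <= {_BRUTE_MAX_SPECIES} species)"
        )
    if not math.isfinite(cost_bound):
        raise ValueError("cost_bound must be finite")

    leaf_x = {}
    for u in G.postorder():
        if not G.children[u]:
            leaf_x[u] = Sp.label_index[G.species_of(u)]
    cv = costs
    tl = cv.transfer + cv.loss

    def go(u: int, x: int, budget: float):
        """Yield (cost, events tuple) for the subtree of u starting at x."""
        res = []
        kids = G.children[u]
        sp_kids = Sp.children[x]
        orig = Sp.orig[x]
        if orig >= 0 and not sp_kids:
            if not kids and leaf_x[u] == x:
                res.append((0.0, (Event(u, "C", x),)))
        if orig >= 0 and sp_kids:
            x1, x2 = sp_kids
            if kids:
                a, b = kids
                for xa, xb in ((x1, x2), (x2, x1)):
                    ev = Event(u, "S", x, child_x=xa)
                    for c1, E1 in go(a, xa, budget):
                        for c2, E2 in go(b, xb, budget - c1):
                            res.append((c1 + c2, (ev,) + E1 + E2))
            for keep in (x1, x2):
                if cv.loss <= budget + EPS:
                    ev = Event(u, "SL", x, child_x=keep)
                    for c1, E1 in go(u, keep, budget - cv.loss):
                        res.append((cv.loss + c1, (ev,) + E1))
        if orig < 0:
            (x1,) = sp_kids
            ev = Event(u, "NE", x)
            for c1, E1 in go(u, x1, budget):
                res.append((c1, (ev,) + E1))
        if kids:
            a, b = kids
            if cv.dup <= budget + EPS:
                ev = Event(u, "D", x)
                for c1, E1 in go(a, x, budget - cv.dup):
                    for c2, E2 in go(b, x, budget - cv.dup - c1):
                        res.append((cv.dup + c1 + c2, (ev,) + E1 + E2))
            if cv.transfer <= budget + EPS:
                for y in Sp.classes[Sp.date_class[x]]:
                    if y == x:
                        continue
                    ev = Event(u, "T", x, receiver=y)
                    for xa, xb in ((x, y), (y, x)):
                        ga, gb = a, b
                        for c1, E1 in go(ga, xa, budget - cv.transfer):
                            for c2, E2 in go(
                                gb, xb, budget - cv.transfer - c1
                            ):
                                res.append(
                                    (cv.transfer + c1 + c2, (ev,) + E1 + E2)
                                )
        if tl <= budget + EPS:
            for y in Sp.classes[Sp.date_class[x]]:
                if y == x:
                    continue
                ev = Event(u, "TL", x, receiver=y)
                for c1, E1 in go(u, y, budget - tl):
                    res.append((tl + c1, (ev,) + E1))
        return [(cc, E) for cc, E in res if cc <= budget + EPS]

    out: list[Reconciliation] = []
    for x in range(len(Sp.children)):
        for cost, events in go(G.root, x, cost_bound):
            R = Reconciliation(G, Sp, list(events))
            R.found_cost = cost
            out.append(R)
    return out
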
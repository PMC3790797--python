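"""Synthetic gene-family histories: a birth-death DTL process along a dated
species tree.

A single gene lineage starts at the species root and evolves down the
tree: along every branch, duplications, transfers and losses strike as a
Poisson process with per-gene, per-time-unit rates; at every speciation
node the lineage splits; transfer receivers are drawn uniformly among the
species branches alive at the event time (excluding the donor).  Extinct
subtrees are pruned away and the surviving history is re-read as a
reconciliation of the pruned gene tree with the species tree: a
duplication or transfer with one dead side becomes invisible (or a TL when
only the transferred copy survives), a speciation with one dead side
becomes an SL.  The recorded true event set is therefore exactly the event
set a perfect reconciliation method should recover.

Rates follow the scheme used for the experiments: the loss rate is drawn
uniformly in [0.001, 0.0018] events/gene/My, the birth rate (duplication +
transfer) is loss x U[0.5, 1.1], and the duplication share of the birth
rate is U[0.7, 1].

The module also derives parsimony costs from a history's event-type
frequencies (cost of type E = -log10 of its relative frequency, speciations
free) and provides the NNI-based gene-tree perturbation used as a stand-in
for sequence simulation plus tree inference: it degrades the true gene
tree to a requested Robinson-Foulds distance, emulating reconstruction
error without modelling sequences.
"""

from __future__ import annotations

import json
import math
import random
import warnings
from dataclasses import dataclass, field

from .dtl_core import CostVector, Event, Reconciliation
from .support import EventKey
from .trees_io import DatedSpeciesTree, GeneTree, SubdividedSpeciesTree

__all__ = [
    "RateSet",
    "SimulatedHistory",
    "draw_rates",
    "random_dated_species_tree",
    "simulate_history",
    "derive_costs",
    "costs_from_event_counts",
    "perturb_gene_tree",
    "rf_distance",
]


@dataclass(frozen=True)
class RateSet:
    """Per-gene per-time-unit event rates (units: events/gene/My)."""

    loss: float
    dup: float
    transfer: float

    @property
    def birth(self) -> float:
        return self.dup + self.transfer

    @property
    def total(self) -> float:
        return self.loss + self.dup + self.transfer


def draw_rates(rng: random.Random) -> RateSet:
    """Draw a rate set from the study's sampling scheme."""
    loss = rng.uniform(0.001, 0.0018)
    birth = loss * rng.uniform(0.5, 1.1)
    dup = birth * rng.uniform(0.7, 1.0)
    return RateSet(loss=loss, dup=dup, transfer=birth - dup)


def random_dated_species_tree(
    n_leaves: int,
    height: float,
    rng: random.Random,
    label_prefix: str = "S",
) -> DatedSpeciesTree:
    """Random dated tree: sequential uniform merges, root pinned at ``height``."""
    if n_leaves < 2:
        raise ValueError("need at least two species")
    while True:
        dates = sorted(rng.uniform(0.0, height) for _ in range(n_leaves - 2))
        dates.append(height)
        if len(set(dates)) == n_leaves - 1 and (not dates[:-1] or dates[0] > 0):
            break
    store: list[tuple[tuple[int, ...], float, str | None]] = [
        ((), 0.0, f"{label_prefix}{i + 1}") for i in range(n_leaves)
    ]
    avail = list(range(n_leaves))
    for d in dates:
        i = avail.pop(rng.randrange(len(avail)))
        j = avail.pop(rng.randrange(len(avail)))
        store.append(((i, j), d, None))
        avail.append(len(store) - 1)
    order: list[int] = []

    def post(k: int) -> None:
        for c in store[k][0]:
            post(c)
        order.append(k)

    post(avail[0])
    remap = {k: i for i, k in enumerate(order)}
    children = [tuple(remap[c] for c in store[k][0]) for k in order]
    dts = [store[k][1] for k in order]
    labels = [store[k][2] for k in order]
    ids = [labels[i] if labels[i] else f"N{i}" for i in range(len(order))]
    return DatedSpeciesTree(children, dts, ids, labels)


# ---------------------------------------------------------------------------
# the birth-death process
# ---------------------------------------------------------------------------


class _Extinct(Exception):
    pass


class _TooLarge(Exception):
    pass


@dataclass
class _Lineage:
    """A pruned (surviving) gene lineage.

    ``chain`` holds the single-copy events the lineage experienced before
    its final event, in time order: ("SL", species node, surviving branch)
    and ("TL", donor branch, receiver branch, time).  ``final`` is one of
    ("C", leaf node), ("S", species node), ("D", branch, time),
    ("T", donor, receiver, time).
    """

    chain: list[tuple] = field(default_factory=list)
    final: tuple = ()
    children: list["_Lineage"] = field(default_factory=list)
    gene: int = -1  # index in the pruned gene tree, set later


@dataclass
class SimulatedHistory:
    """True gene tree plus the true (observable) event set."""

    species: DatedSpeciesTree
    gene_tree: GeneTree
    rates: RateSet
    true_events: frozenset  # EventKeys w.r.t. S, gene ids of gene_tree
    counts: dict[str, int]  # D / T / L totals (T counts T+TL, L counts SL+TL)
    _root: _Lineage = field(repr=False, default=None)

    @property
    def n_dtl_events(self) -> int:
        return self.counts["D"] + self.counts["T"] + self.counts["L"]

    # -- full reconciliation (with NE chains) for validation/inspection ----
    def to_reconciliation(self, Sp: SubdividedSpeciesTree) -> Reconciliation:
        if Sp.S is not self.species:
            raise ValueError("subdivision must belong to this history's species tree")
        node_at = {}
        for x in range(len(Sp.children)):
            node_at[(Sp.s_branch[x], Sp.date_class[x])] = x
        events: list[Event] = []

        def descend_to(pos: int, stop) -> int:
            """Emit NE events down the current branch until ``stop`` holds."""
            while not stop(pos):
                assert Sp.is_artificial[pos], "ran past an original node"
                events.append(Event(self._lin_gene, "NE", pos))
                (pos,) = Sp.children[pos]
            return pos

        def at_node(target: int):
            return lambda pos: pos == target

        def below(t: float):
            return lambda pos: Sp.dates[pos] < t

        def walk(lin: _Lineage, entry: int) -> None:
            self._lin_gene = lin.gene
            pos = entry
            for ev in lin.chain:
                if ev[0] == "SL":
                    _, snode, keep = ev
                    pos = descend_to(pos, at_node(self._orig_x(Sp, snode)))
                    keep_x = self._branch_top(Sp, pos, keep)
                    events.append(Event(lin.gene, "SL", pos, child_x=keep_x))
                    pos = keep_x
                else:  # TL
                    _, donor, recv, t = ev
                    pos = descend_to(pos, below(t))
                    y = node_at[(recv, Sp.date_class[pos])]
                    events.append(Event(lin.gene, "TL", pos, receiver=y))
                    pos = y
                self._lin_gene = lin.gene
            f = lin.final
            if f[0] == "C":
                pos = descend_to(pos, at_node(self._orig_x(Sp, f[1])))
                events.append(Event(lin.gene, "C", pos))
            elif f[0] == "S":
                pos = descend_to(pos, at_node(self._orig_x(Sp, f[1])))
                x1, x2 = Sp.children[pos]
                events.append(Event(lin.gene, "S", pos, child_x=x1))
                walk(lin.children[0], x1)
                walk(lin.children[1], x2)
            elif f[0] == "D":
                pos = descend_to(pos, below(f[2]))
                events.append(Event(lin.gene, "D", pos))
                walk(lin.children[0], pos)
                walk(lin.children[1], pos)
            else:  # T
                _, donor, recv, t = f
                pos = descend_to(pos, below(t))
                y = node_at[(recv, Sp.date_class[pos])]
                events.append(Event(lin.gene, "T", pos, receiver=y))
                walk(lin.children[0], pos)
                walk(lin.children[1], y)

        walk(self._root, len(Sp.children) - 1)
        return Reconciliation(self.gene_tree, Sp, events)

    @staticmethod
    def _orig_x(Sp: SubdividedSpeciesTree, s_node: int) -> int:
        # original S node -> its S' index (S' stores orig per node)
        for x in range(len(Sp.children)):
            if Sp.orig[x] == s_node:
                return x
        raise KeyError(s_node)

    @staticmethod
    def _branch_top(Sp: SubdividedSpeciesTree, p_x: int, s_child: int) -> int:
        for c in Sp.children[p_x]:
            if Sp.s_branch[c] == s_child:
                return c
        raise KeyError(s_child)

    # -- plain-text export -------------------------------------------------
    def mapping_tsv(self) -> str:
        G = self.gene_tree
        return "".join(f"{lab}\t{G.s[lab]}\n" for lab in sorted(G.s))

    def events_tsv(self) -> str:
        rows = ["gene_node_id\tevent_type\tspecies_branch\treceiver_branch"]
        for k in sorted(self.true_events):
            rows.append("\t".join([k.gene, k.etype, k.where, k.extra or ""]))
        return "\n".join(rows) + "\n"

    def meta_json(self) -> str:
        return json.dumps(
            {
                "rates": {"loss": self.rates.loss, "dup": self.rates.dup, "transfer": self.rates.transfer},
                "counts": self.counts,
                "n_gene_leaves": self.gene_tree.n_leaves,
            },
            indent=1,
        )


def simulate_history(
    S: DatedSpeciesTree,
    rates: RateSet,
    rng: random.Random,
    min_leaves: int = 1,
    max_leaves: int = 500,
    max_retries: int = 100,
) -> SimulatedHistory:
    """Simulate one gene family; redraw extinct/too-small families.

    Raises ``RuntimeError`` after ``max_retries`` failed draws (can only
    happen under extreme rates).
    """
    for _ in range(max_retries):
        try:
            return _simulate_once(S, rates, rng, min_leaves, max_leaves)
        except (_Extinct, _TooLarge):
            continue
    raise RuntimeError(
        f"no surviving family with {min_leaves}-{max_leaves} leaves "
        f"in {max_retries} draws; rates {rates} look degenerate"
    )


def _simulate_once(S, rates, rng, min_leaves, max_leaves) -> SimulatedHistory:
    n = len(S.children)
    total = rates.total
    alive_cache: dict[int, list[int]] = {}
    counter = {"leaves": 0}

    def alive(t: float) -> list[int]:
        return [
            b
            for b in range(n)
            if S.parent[b] >= 0 and S.dates[b] < t < S.dates[S.parent[b]]
        ]

    def evolve(b: int, t: float):
        """History of one gene copy on the branch above node b from time t."""
        while True:
            t2 = t - (rng.expovariate(total) if total > 0 else math.inf)
            if t2 <= S.dates[b]:
                if not S.children[b]:
                    counter["leaves"] += 1
                    if counter["leaves"] > max_leaves:
                        raise _TooLarge
                    return ("leaf", b)
                return (
                    "S",
                    b,
                    [evolve(c, S.dates[b]) for c in S.children[b]],
                )
            r = rng.random() * total
            if r < rates.dup:
                return ("D", b, t2, [evolve(b, t2), evolve(b, t2)])
            if r < rates.dup + rates.transfer:
                cands = [y for y in alive(t2) if y != b]
                if not cands:
                    t = t2
                    continue
                y = rng.choice(cands)
                return ("T", b, y, t2, [evolve(b, t2), evolve(y, t2)])
            return ("L", b, t2)

    root_date = S.dates[S.root]
    raw = ("S", S.root, [evolve(c, root_date) for c in S.children[S.root]])

    pruned = _prune(raw)
    if pruned is None:
        raise _Extinct
    gene_tree, events, counts = _read_out(S, pruned, min_leaves)
    return SimulatedHistory(S, gene_tree, rates, events, counts, pruned)


def _prune(node) -> _Lineage | None:
    kind = node[0]
    if kind == "leaf":
        return _Lineage(final=("C", node[1]))
    if kind == "L":
        return None
    if kind == "S":
        _, b, kids = node
        sub = [_prune(k) for k in kids]
        left, right = sub
        if left and right:
            return _Lineage(final=("S", b), children=[left, right])
        keep = left or right
        if keep is None:
            return None
        # surviving child branch: the one whose subtree survived
        keep_branch = None
        from_raw = node[2]
        for raw_child, p in zip(from_raw, sub):
            if p is keep:
                keep_branch = _entry_branch(raw_child)
        keep.chain.insert(0, ("SL", b, keep_branch))
        return keep
    if kind == "D":
        _, b, t, kids = node
        sub = [_prune(k) for k in kids]
        left, right = sub
        if left and right:
            return _Lineage(final=("D", b, t), children=[left, right])
        return left or right  # invisible duplication
    # transfer
    _, b, y, t, kids = node
    donor, recv = (_prune(k) for k in kids)
    if donor and recv:
        return _Lineage(final=("T", b, y, t), children=[donor, recv])
    if recv is not None:  # only the transferred copy survives
        recv.chain.insert(0, ("TL", b, y, t))
        return recv
    return donor  # invisible transfer (or None)


def _entry_branch(raw_node) -> int:
    """Species branch on which a raw history subtree starts."""
    return raw_node[1]


def _read_out(S: DatedSpeciesTree, root: _Lineage, min_leaves: int):
    """Build the pruned GeneTree and the true EventKey set."""
    children: list[tuple[int, ...]] = []
    labels: list[str | None] = []
    ids: list[str] = []
    counter = {"leaf": 0, "internal": 0}

    def build(lin: _Lineage) -> int:
        kid_idx = tuple(build(c) for c in lin.children)
        if kid_idx:
            counter["internal"] += 1
            name = f"n{counter['internal']}"
            lab = None
        else:
            counter["leaf"] += 1
            sp = S.labels[lin.final[1]]
            name = f"g{counter['leaf']}_{sp}"
            lab = name
        children.append(kid_idx)
        labels.append(lab)
        ids.append(name)
        lin.gene = len(children) - 1
        return lin.gene

    build(root)
    if counter["leaf"] < min_leaves:
        raise _Extinct
    s_map = {}

    def collect(lin: _Lineage, out: list) -> None:
        g = ids[lin.gene]
        for ev in lin.chain:
            if ev[0] == "SL":
                out.append(EventKey(g, "SL", S.ids[ev[1]], S.ids[ev[2]]))
            else:
                out.append(EventKey(g, "TL", S.ids[ev[1]], S.ids[ev[2]]))
        f = lin.final
        if f[0] == "C":
            s_map[g] = S.labels[f[1]]
        elif f[0] == "S":
            out.append(EventKey(g, "S", S.ids[f[1]]))
        elif f[0] == "D":
            out.append(EventKey(g, "D", S.ids[f[1]]))
        else:
            out.append(EventKey(g, "T", S.ids[f[1]], S.ids[f[2]]))
        for c in lin.children:
            collect(c, out)

    evs: list[EventKey] = []
    collect(root, evs)
    gene_tree = GeneTree(children, ids, labels, s_map)
    counts = {
        "D": sum(1 for e in evs if e.etype == "D"),
        "T": sum(1 for e in evs if e.etype in ("T", "TL")),
        "L": sum(1 for e in evs if e.etype in ("SL", "TL")),
    }
    return gene_tree, frozenset(evs), counts


# ---------------------------------------------------------------------------
# cost derivation
# ---------------------------------------------------------------------------


def costs_from_event_counts(d: float, t: float, l: float) -> CostVector:
    """Cost of each chargeable type = -log10 of its relative frequency.

    Types with zero occurrences get a 0.5 pseudocount (capping the cost
    instead of making it infinite); speciations stay free.
    """
    if d + t + l <= 0:
        raise ValueError("need at least one D, T or L event")
    d, t, l = (v if v > 0 else 0.5 for v in (d, t, l))
    tot = d + t + l
    return CostVector(
        -math.log10(d / tot), -math.log10(t / tot), -math.log10(l / tot)
    )


def derive_costs(h: SimulatedHistory) -> CostVector:
    """Parsimony costs implied by a simulated history's event frequencies."""
    return costs_from_event_counts(h.counts["D"], h.counts["T"], h.counts["L"])


# ---------------------------------------------------------------------------
# gene-tree perturbation (stand-in for sequence simulation + inference)
# ---------------------------------------------------------------------------


def _splits(children, labels) -> set[frozenset]:
    n_leaves = sum(1 for ch in children if not ch)
    all_leaves = frozenset(l for l in labels if l is not None)
    ref = min(all_leaves)
    out = set()
    below = [None] * len(children)
    for i, ch in enumerate(children):
        if not ch:
            below[i] = frozenset([labels[i]])
        else:
            below[i] = frozenset().union(*(below[c] for c in ch))
        side = below[i] if ref not in below[i] else all_leaves - below[i]
        if 2 <= len(side) <= n_leaves - 2:
            out.add(side)
    return out


def rf_distance(G1: GeneTree, G2: GeneTree, normalize: bool = True) -> float:
    """Robinson-Foulds distance on the unrooted topologies (shared leaf set)."""
    if set(G1.s) != set(G2.s):
        raise ValueError("trees must share their leaf set")
    s1 = _splits(G1.children, G1.labels)
    s2 = _splits(G2.children, G2.labels)
    d = len(s1 ^ s2)
    if not normalize:
        return float(d)
    n = G1.n_leaves
    return d / (2 * (n - 3)) if n > 3 else 0.0


def _nni(children: list[list[int]], rng: random.Random) -> None:
    """One random NNI in place: swap a child of an internal non-root node
    with that node's sibling."""
    root = len(children) - 1
    parent = [-1] * len(children)
    for i, ch in enumerate(children):
        for c in ch:
            parent[c] = i
    cands = [v for v in range(len(children)) if children[v] and v != root]
    v = rng.choice(cands)
    p = parent[v]
    sib = children[p][0] if children[p][1] == v else children[p][1]
    ci = rng.randrange(2)
    moved = children[v][ci]
    children[v] = [children[v][1 - ci], sib]
    children[p] = [v, moved]


def perturb_gene_tree(
    G: GeneTree,
    n_moves: int | None = None,
    target_rf: float | None = None,
    rng: random.Random | None = None,
    max_moves: int | None = None,
) -> GeneTree:
    """Degrade a gene tree by random NNI moves.

    Either apply exactly ``n_moves`` moves, or keep applying moves until
    the normalized RF distance to the original reaches ``target_rf``
    (best-effort within ``max_moves``, default 10 moves per leaf).  Leaf
    labels and the species mapping are untouched.
    """
    if (n_moves is None) == (target_rf is None):
        raise ValueError("give exactly one of n_moves / target_rf")
    if n_moves == 0 or target_rf == 0.0:
        return GeneTree(list(G.children), list(G.ids), list(G.labels), dict(G.s))
    if G.n_leaves < 4:
        raise ValueError("NNI perturbation needs at least 4 leaves")
    rng = rng or random.Random()
    work = [list(ch) for ch in G.children]

    def as_tree() -> GeneTree:
        # re-normalize to postorder tables
        order: list[int] = []

        def post(i: int) -> None:
            for c in work[i]:
                post(c)
            order.append(i)

        post(len(work) - 1)
        remap = {o: i for i, o in enumerate(order)}
        children = [tuple(remap[c] for c in work[o]) for o in order]
        labels = [G.labels[o] for o in order]
        ids = [G.ids[o] for o in order]
        return GeneTree(children, ids, labels, dict(G.s))

    if n_moves is not None:
        for _ in range(n_moves):
            _nni(work, rng)
        return as_tree()

    budget = max_moves if max_moves is not None else 10 * G.n_leaves
    best = as_tree()
    best_rf = 0.0
    for _ in range(budget):
        if best_rf >= target_rf:
            break
        _nni(work, rng)
        cand = as_tree()
        rf = rf_distance(G, cand)
        if rf > best_rf:
            best, best_rf = cand, rf
    if best_rf < target_rf - 0.05:
        warnings.warn(
            f"reached RF {best_rf:.3f} < target {target_rf:.3f} "
            f"within {budget} moves; returning best effort"
        )
    return best
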
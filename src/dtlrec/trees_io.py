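"""Dated species trees, gene trees, leaf maps, and the time-sliced subdivision.

The reconciliation model works on a rooted binary *dated* species tree S:
every node carries a date (time before present; leaves at 0) and transfers
are only allowed between branches that co-exist in time.  To make "co-exist"
a purely combinatorial notion, S is refined into its *subdivision* S': for
every internal-node date d and every branch of S spanning d, an artificial
degree-2 node is inserted at date d.  All nodes of equal date then delimit a
*time slice*, and two branches co-exist iff they carry nodes of the same
date.

Trees are stored in flat integer-indexed tables (postorder), which is what
the dynamic program and the reconciliation graph need; newick I/O goes
through dendropy.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TreeError",
    "DatedSpeciesTree",
    "GeneTree",
    "SubdividedSpeciesTree",
    "parse_dated_species_tree",
    "parse_gene_tree",
    "parse_leaf_mapping",
    "parse_date_table",
    "subdivide",
]


class TreeError(ValueError):
    """Structural, labeling or dating problem in an input tree."""


# ---------------------------------------------------------------------------
# basic rooted-binary tree table
# ---------------------------------------------------------------------------


def _from_dendropy(tree: dendropy.Tree, what: str):
    """Flatten a dendropy tree into postorder tables; enforce binary+unique labels."""
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    children: list[tuple[int, ...]] = []
    labels: list[str | None] = []
    lengths: list[float | None] = []
    names: list[str | None] = []
    for nd in nodes:
        ch = nd.child_nodes()
        if len(ch) not in (0, 2):
            raise TreeError(
                f"{what}: non-binary node with {len(ch)} children "
                "(only rooted binary trees are supported)"
            )
        children.append(tuple(index[id(c)] for c in ch))
        if ch:
            labels.append(None)
            names.append(nd.label)
        else:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError(f"{what}: unlabeled leaf")
            labels.append(nd.taxon.label)
            names.append(None)
        lengths.append(nd.edge.length)
    leaf_labels = [l for l in labels if l is not None]
    if len(set(leaf_labels)) != len(leaf_labels):
        dup = sorted({l for l in leaf_labels if leaf_labels.count(l) > 1})
        raise TreeError(f"{what}: duplicate leaf label(s): {', '.join(dup)}")
    return children, labels, names, lengths


def _read_newick(text: str, what: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeError(f"{what}: cannot parse newick: {exc}") from None


@dataclass
class DatedSpeciesTree:
    """Rooted binary species tree with a strictly ordered node dating.

    ``children[i]`` is ``()`` for leaves or a pair of node indices; nodes are
    in postorder, the root is the last index.  ``dates[i]`` is the time
    before present of node ``i`` (0 at every leaf); internal dates are
    pairwise distinct so that time slices are totally ordered.  ``ids[i]``
    is a stable string identifier: the leaf label, or the internal newick
    label when given, or a generated ``N<k>``.
    """

    children: list[tuple[int, ...]]
    dates: list[float]
    ids: list[str]
    labels: list[str | None]

    def __post_init__(self) -> None:
        self.parent = [-1] * len(self.children)
        for i, ch in enumerate(self.children):
            for c in ch:
                self.parent[c] = i
        self.root = len(self.children) - 1
        self.leaf_index = {
            lab: i for i, lab in enumerate(self.labels) if lab is not None
        }
        self._validate()

    def _validate(self) -> None:
        for i, ch in enumerate(self.children):
            if not ch and self.dates[i] != 0.0:
                raise TreeError(f"leaf {self.ids[i]} has nonzero date {self.dates[i]}")
            for c in ch:
                if not self.dates[i] > self.dates[c]:
                    raise TreeError(
                        f"dates must strictly decrease towards the leaves: "
                        f"{self.ids[i]} ({self.dates[i]}) -> {self.ids[c]} ({self.dates[c]})"
                    )
        internal = sorted(d for i, d in enumerate(self.dates) if self.children[i])
        for a, b in zip(internal, internal[1:]):
            if a == b:
                raise TreeError(
                    f"tied internal dates ({a}); distinct dates are required for the "
                    "subdivision -- supply a date table or enable jitter"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_index)

    def leaves(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    def postorder(self) -> range:
        return range(len(self.children))

    def newick(self) -> str:
        """Newick string with branch lengths recovered from the dates."""

        def rec(i: int) -> str:
            if not self.children[i]:
                name = self.labels[i]
            else:
                a, b = self.children[i]
                name = f"({rec(a)},{rec(b)}){self.ids[i]}"
            if i == self.root:
                return name
            bl = self.dates[self.parent[i]] - self.dates[i]
            return f"{name}:{bl:.12g}"

        return rec(self.root) + ";"


@dataclass
class GeneTree:
    """Rooted binary gene tree plus the species labeling s: gene leaf -> species leaf.

    ``s`` maps each leaf label of the gene tree to a species leaf label; it
    need not be injective (several gene copies may live in one species).
    """

    children: list[tuple[int, ...]]
    ids: list[str]
    labels: list[str | None]
    s: dict[str, str]

    def __post_init__(self) -> None:
        self.parent = [-1] * len(self.children)
        for i, ch in enumerate(self.children):
            for c in ch:
                self.parent[c] = i
        self.root = len(self.children) - 1
        for i, lab in enumerate(self.labels):
            if lab is not None and lab not in self.s:
                raise TreeError(f"gene leaf {lab!r} missing from the species mapping")

    @property
    def n_leaves(self) -> int:
        return sum(1 for ch in self.children if not ch)

    def postorder(self) -> range:
        return range(len(self.children))

    def species_of(self, i: int) -> str:
        lab = self.labels[i]
        if lab is None:
            raise ValueError("species_of is defined on leaves only")
        return self.s[lab]

    def newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                return self.labels[i]
            a, b = self.children[i]
            return f"({rec(a)},{rec(b)})"

        return rec(self.root) + ";"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_date_table(text: str) -> dict[str, float]:
    """2-column TSV ``node_id<TAB>date``; '#' starts a comment."""
    table: dict[str, float] = {}
    for ln, line in enumerate(io.StringIO(text), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TreeError(f"date table line {ln}: expected 2 tab-separated columns")
        table[parts[0]] = float(parts[1])
    return table


def parse_leaf_mapping(text: str) -> dict[str, str]:
    """2-column TSV ``gene_leaf<TAB>species_leaf``; '#' starts a comment."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(io.StringIO(text), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TreeError(f"mapping line {ln}: expected 2 tab-separated columns")
        if parts[0] in mapping:
            raise TreeError(f"mapping line {ln}: gene leaf {parts[0]!r} mapped twice")
        mapping[parts[0]] = parts[1]
    return mapping


def parse_dated_species_tree(
    newick_text: str,
    dates: dict[str, float] | str | None = None,
    *,
    rel_tol: float = 1e-6,
    jitter_ties: bool = False,
    jitter_seed: int = 0,
) -> DatedSpeciesTree:
    """Parse a dated species tree.

    Dates come either from ultrametric branch lengths (root-to-leaf path
    lengths must agree within ``rel_tol`` relative tolerance) or from an
    explicit node->date table covering every internal node.  Tied internal
    dates are rejected unless ``jitter_ties`` applies a tiny seeded,
    deterministic perturbation (the subdivision needs a strict slice order).
    """
    tree = _read_newick(newick_text, "species tree")
    children, labels, names, lengths = _from_dendropy(tree, "species tree")
    n = len(children)
    ids = _assign_ids(children, labels, names)

    if isinstance(dates, str):
        dates = parse_date_table(dates)

    if dates is not None:
        date_list = [0.0] * n
        for i in range(n):
            if children[i]:
                if ids[i] not in dates:
                    raise TreeError(f"date table misses internal node {ids[i]!r}")
                date_list[i] = float(dates[ids[i]])
            elif labels[i] in dates and dates[labels[i]] != 0.0:
                raise TreeError(f"extant leaf {labels[i]!r} must have date 0")
    else:
        date_list = _dates_from_lengths(children, labels, lengths, rel_tol)

    date_list = _maybe_jitter(children, date_list, jitter_ties, jitter_seed)
    return DatedSpeciesTree(children, date_list, ids, labels)


def _assign_ids(children, labels, names) -> list[str]:
    ids: list[str] = []
    used = {l for l in labels if l is not None}
    k = 0
    for i, ch in enumerate(children):
        if not ch:
            ids.append(labels[i])
        elif names[i] and names[i] not in used:
            ids.append(names[i])
            used.add(names[i])
        else:
            k += 1
            while f"N{k}" in used:
                k += 1
            ids.append(f"N{k}")
            used.add(f"N{k}")
    return ids


def _dates_from_lengths(children, labels, lengths, rel_tol) -> list[float]:
    n = len(children)
    # depth of each node from the root along branch lengths
    parent = [-1] * n
    for i, ch in enumerate(children):
        for c in ch:
            parent[c] = i
    depth = [0.0] * n
    for i in reversed(range(n)):  # preorder
        if parent[i] >= 0:
            bl = lengths[i]
            if bl is None:
                raise TreeError(
                    "species tree has no branch lengths; supply a date table"
                )
            depth[i] = depth[parent[i]] + bl
    leaf_depths = [depth[i] for i in range(n) if not children[i]]
    height = max(leaf_depths)
    scale = max(height, 1.0)
    for i, d in enumerate(leaf_depths):
        if abs(d - height) > rel_tol * scale:
            raise TreeError(
                "species tree branch lengths are not ultrametric "
                f"(leaf depths range over [{min(leaf_depths):g}, {height:g}]); "
                "supply an explicit date table"
            )
    dates = [0.0 if not children[i] else height - depth[i] for i in range(n)]
    return dates


def _maybe_jitter(children, dates, jitter_ties, seed) -> list[float]:
    internal = [i for i, ch in enumerate(children) if ch]
    seen: dict[float, list[int]] = {}
    for i in internal:
        seen.setdefault(dates[i], []).append(i)
    ties = [v for v in seen.values() if len(v) > 1]
    if not ties or not jitter_ties:
        return dates
    import random

    rng = random.Random(seed)
    span = max(dates) - min(dates) or 1.0
    out = list(dates)
    for group in ties:
        for i in group[1:]:
            out[i] += (rng.random() - 0.5) * 2e-9 * span
    return out


def parse_gene_tree(
    newick_text: str,
    mapping: dict[str, str] | str,
    species_tree: DatedSpeciesTree | None = None,
) -> GeneTree:
    """Parse a gene tree with its gene-leaf -> species-leaf mapping.

    Every gene leaf must appear in the mapping; when a species tree is
    given, mapped species must be leaves of it.
    """
    tree = _read_newick(newick_text, "gene tree")
    children, labels, names, _ = _from_dendropy(tree, "gene tree")
    ids = _assign_ids(children, labels, names)
    if isinstance(mapping, str):
        mapping = parse_leaf_mapping(mapping)
    for lab in labels:
        if lab is not None and lab not in mapping:
            raise TreeError(f"gene leaf {lab!r} missing from the species mapping")
    if species_tree is not None:
        for g, sp in mapping.items():
            if sp not in species_tree.leaf_index:
                raise TreeError(
                    f"gene leaf {g!r} mapped to unknown species {sp!r}"
                )
    used = {lab for lab in labels if lab is not None}
    mapping = {g: sp for g, sp in mapping.items() if g in used}
    return GeneTree(children, ids, labels, mapping)


# ---------------------------------------------------------------------------
# subdivision
# ---------------------------------------------------------------------------


@dataclass
class SubdividedSpeciesTree:
    """The time-sliced refinement S' of a dated species tree.

    Nodes of S plus one artificial degree-1 node per (internal date d,
    branch of S spanning d) incidence.  ``s_branch[x]`` maps each S' node to
    the S node at the bottom of its S branch (the back-map; the root stem
    maps to the S root).  ``date_class[x]`` indexes the totally ordered
    slices (0 = the leaf date).  ``orig[x]`` is the S node index for
    original nodes, -1 for artificial ones.
    """

    S: DatedSpeciesTree
    children: list[tuple[int, ...]] = field(default_factory=list)
    dates: list[float] = field(default_factory=list)
    orig: list[int] = field(default_factory=list)
    s_branch: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.children:
            self._finish()

    def _finish(self) -> None:
        n = len(self.children)
        self.parent = [-1] * n
        for i, ch in enumerate(self.children):
            for c in ch:
                self.parent[c] = i
        self.root = n - 1
        # slice structure
        levels = sorted(set(self.dates))
        self.class_dates = levels
        lookup = {d: k for k, d in enumerate(levels)}
        self.date_class = [lookup[d] for d in self.dates]
        self.classes: list[list[int]] = [[] for _ in levels]
        for x in range(n):
            self.classes[self.date_class[x]].append(x)
        # date of the S-parent of each node's S branch (inf for the root stem)
        sp = self.S
        self.branch_top_date = [
            math.inf
            if sp.parent[self.s_branch[x]] == -1
            else sp.dates[sp.parent[self.s_branch[x]]]
            for x in range(n)
        ]
        self.is_artificial = [o < 0 for o in self.orig]
        self.label_index = {
            sp.labels[self.orig[x]]: x
            for x in range(n)
            if self.orig[x] >= 0 and not sp.children[self.orig[x]]
        }

    # number of slices == number of distinct dates
    @property
    def n_slices(self) -> int:
        return len(self.class_dates)

    @property
    def n_artificial(self) -> int:
        return sum(self.is_artificial)

    def node_id(self, x: int) -> str:
        if self.orig[x] >= 0:
            return self.S.ids[self.orig[x]]
        return f"{self.S.ids[self.s_branch[x]]}@{self.dates[x]:g}"

    def collapse(self) -> DatedSpeciesTree:
        """Remove artificial nodes; must recover S exactly."""
        keep = [x for x in range(len(self.children)) if self.orig[x] >= 0]
        remap = {x: i for i, x in enumerate(keep)}

        def down(x: int) -> int:
            while self.orig[x] < 0:
                (x,) = self.children[x]
            return x

        children = []
        for x in keep:
            children.append(tuple(remap[down(c)] for c in self.children[x]))
        dates = [self.dates[x] for x in keep]
        ids = [self.S.ids[self.orig[x]] for x in keep]
        labels = [self.S.labels[self.orig[x]] for x in keep]
        return DatedSpeciesTree(children, dates, ids, labels)


def subdivide(S: DatedSpeciesTree) -> SubdividedSpeciesTree:
    """Build the subdivision S' of a dated species tree.

    For each internal date d of S and each branch (p, c) with
    date(c) < d < date(p), one artificial node is inserted at date d; the
    root stem gets none (nothing exists above the root's date).
    """
    internal_dates = sorted(
        {S.dates[i] for i in range(len(S.children)) if S.children[i]}
    )
    children: list[tuple[int, ...]] = []
    dates: list[float] = []
    orig: list[int] = []
    s_branch: list[int] = []

    def build(s_node: int) -> int:
        """Create the chain for branch ending at s_node; return its top S' index."""
        if S.children[s_node]:
            kids = tuple(build(c) for c in S.children[s_node])
        else:
            kids = ()
        children.append(kids)
        dates.append(S.dates[s_node])
        orig.append(s_node)
        s_branch.append(s_node)
        x = len(children) - 1
        if S.parent[s_node] >= 0:
            top = S.dates[S.parent[s_node]]
            for d in internal_dates:
                if S.dates[s_node] < d < top:
                    children.append((x,))
                    dates.append(d)
                    orig.append(-1)
                    s_branch.append(s_node)
                    x = len(children) - 1
        return x

    build(S.root)
    return SubdividedSpeciesTree(S, children, dates, orig, s_branch)
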
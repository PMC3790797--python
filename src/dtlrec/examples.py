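"""Bundled worked examples.

Three tiny hand-checkable instances used in the documentation, the test
suite and the acceptance script.  Each returns freshly parsed objects, so
callers may mutate them freely.

``two_mpr_example``
    A 3-species / 4-gene instance whose reconciliation graph has a single
    root mapping node (gene root at the species root) traversed by exactly
    2 canonical MPRs, one reaching it through a speciation and one through
    a duplication (counts 2; 1 and 1, hence both root events have support
    1/2).  Optimal cost 1.1 under (0.9, 1.1, 0.1): the two MPRs are
    {2 S, 1 T} and {2 S, 1 D, 2 SL}.

``unique_mpr_example``
    A 4-species / 4-gene instance with a unique MPR of census
    {2 S, 1 D, 1 SL, 4 C}, cost 0.9 + 0.1 = 1.0 under the same costs: a
    duplication of an ancestral gene with one copy lost along a speciation.

``three_mpr_example``
    A 5-species / 5-gene instance with exactly 3 canonical MPRs under
    costs (0.60205, 0.74818, 0.24303) in which four events have support
    above 50% yet *no single MPR contains all of them* -- the
    counterexample showing that, unlike majority-rule consensus trees,
    highly supported events need not be jointly realizable.
"""

from __future__ import annotations

from .dtl_core import CostVector
from .trees_io import (
    DatedSpeciesTree,
    GeneTree,
    parse_dated_species_tree,
    parse_gene_tree,
)

__all__ = ["two_mpr_example", "unique_mpr_example", "three_mpr_example"]


def two_mpr_example() -> tuple[DatedSpeciesTree, GeneTree, CostVector]:
    S = parse_dated_species_tree("((A:1,B:1):1,C:2);")
    G = parse_gene_tree(
        "((g1,g2),(g3,g4));",
        {"g1": "A", "g2": "B", "g3": "A", "g4": "C"},
        S,
    )
    return S, G, CostVector(0.9, 1.1, 0.1)


def unique_mpr_example() -> tuple[DatedSpeciesTree, GeneTree, CostVector]:
    S = parse_dated_species_tree("(((A:1,B:1):1,C:2):1,D:3);")
    G = parse_gene_tree(
        "(((g1,g2),g3),g4);",
        {"g1": "A", "g2": "A", "g3": "C", "g4": "D"},
        S,
    )
    return S, G, CostVector(0.9, 1.1, 0.1)


def three_mpr_example() -> tuple[DatedSpeciesTree, GeneTree, CostVector]:
    S = parse_dated_species_tree("((B:6,((C:1,D:1):2,E:3):3):3,A:9);")
    G = parse_gene_tree(
        "((g1,(g2,(g3,g4))),g5);",
        {"g1": "D", "g2": "D", "g3": "B", "g4": "E", "g5": "A"},
        S,
    )
    return S, G, CostVector(0.60205, 0.74818, 0.24303)
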
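import random

import pytest

from dtlrec.dtl_core import CostVector
from dtlrec.simulate import random_dated_species_tree
from dtlrec.trees_io import DatedSpeciesTree, GeneTree, subdivide


def random_species_tree(rng: random.Random, n: int) -> DatedSpeciesTree:
    return random_dated_species_tree(n, rng.uniform(5, 10), rng, label_prefix="L")


def random_gene_tree(rng: random.Random, n: int, species_labels) -> GeneTree:
    """Random rooted binary gene tree with leaves mapped to random species."""
    store: list[tuple[tuple[int, ...], str | None]] = [((), f"g{i}") for i in range(n)]
    avail = list(range(n))
    while len(avail) > 1:
        i = avail.pop(rng.randrange(len(avail)))
        j = avail.pop(rng.randrange(len(avail)))
        store.append(((i, j), None))
        avail.append(len(store) - 1)
    order: list[int] = []

    def post(k: int) -> None:
        for c in store[k][0]:
            post(c)
        order.append(k)

    post(avail[0])
    remap = {k: i for i, k in enumerate(order)}
    children = [tuple(remap[c] for c in store[k][0]) for k in order]
    labels = [store[k][1] for k in order]
    ids = [labels[i] or f"n{i}" for i in range(len(order))]
    s = {lab: rng.choice(list(species_labels)) for lab in labels if lab}
    return GeneTree(children, ids, labels, s)


def random_instance(seed: int, max_species: int = 5, max_genes: int = 6):
    """A small random reconciliation instance (tree pair + costs)."""
    rng = random.Random(seed)
    S = random_species_tree(rng, rng.randint(3, max_species))
    Sp = subdivide(S)
    G = random_gene_tree(rng, rng.randint(3, max_genes), sorted(S.leaf_index))
    costs = CostVector(
        round(rng.uniform(0.3, 3), 2),
        round(rng.uniform(0.3, 3), 2),
        round(rng.uniform(0.2, 2), 2),
    )
    return S, Sp, G, costs


@pytest.fixture
def rng():
    return random.Random(1234)
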
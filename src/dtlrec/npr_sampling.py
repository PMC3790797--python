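"""Sampling near-optimal reconciliations by perturbing event costs.

Optimal reconciliations under slightly altered costs are near-optimal ones
under the original costs.  Each replicate draws new duplication, transfer
and loss costs independently from Normal(cost, (Delta * cost)^2) -- Delta
is the relative dispersion -- and builds the full MPR graph for the drawn
costs; the resulting graph set is a sample of the near-optimal solution
space from which pooled event supports and medians are computed.

Non-positive draws are rejected and redrawn (positivity is required by the
parsimony model; at Delta <= 0.4 the rejection probability is ~Phi(-2.5),
a negligible truncation bias).  Each replicate runs on its own derived
random substream, so replicate i is reproducible regardless of how many
replicates are requested.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .dtl_core import CostVector
from .dtl_graph import DTLGraph, build_mpr_graph
from .trees_io import GeneTree, SubdividedSpeciesTree

__all__ = ["PerturbationConfig", "perturb_costs", "sample_npr_graphs"]


@dataclass(frozen=True)
class PerturbationConfig:
    """Dispersion Delta (relative sd), replicate count, and base seed."""

    delta: float = 0.2
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def perturb_costs(costs: CostVector, delta: float, rng: random.Random) -> CostVector:
    """Draw a perturbed cost vector; Delta = 0 returns the costs unchanged."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0:
        return costs

    def draw(mean: float) -> float:
        while True:
            v = rng.gauss(mean, delta * mean)
            if v > 0:
                return v

    return CostVector(draw(costs.dup), draw(costs.transfer), draw(costs.loss))


def _replicate_rng(seed: int, i: int) -> random.Random:
    return random.Random((seed * 1_000_003 + i) % (2**31 - 1))


def sample_npr_graphs(
    G: GeneTree,
    Sp: SubdividedSpeciesTree,
    costs: CostVector,
    config: PerturbationConfig,
) -> list[DTLGraph]:
    """One annotated MPR graph per perturbed cost vector."""
    out = []
    for i in range(config.replicates):
        rng = _replicate_rng(config.seed, i)
        ci = perturb_costs(costs, config.delta, rng)
        out.append(build_mpr_graph(G, Sp, ci))
    return out
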
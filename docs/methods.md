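# Methods

## The reconciliation model

A species tree S is rooted, binary, uniquely leaf-labeled and *dated*:
every node carries a time before present (any consistent unit; leaves at
0), internal dates strictly decrease towards the leaves and are pairwise
distinct.  Only the relative order of the dates matters — it defines which
lineages co-exist, hence which transfers are allowed.  The *subdivision*
S′ inserts an artificial degree-2 node wherever a branch of S spans an
internal-node date, so nodes of equal date delimit totally ordered time
slices and two branches co-exist exactly when they carry nodes of one
slice.  Collapsing the artificial nodes recovers S; this is asserted in
the tests.

A reconciliation maps each gene-tree node u to an ordered, time-consistent
list of S′ nodes, each paired with one of seven atomic events: S, D, T,
TL (transfer whose non-transferred copy is lost), SL (speciation with loss
of one copy), NE (crossing a slice boundary) and C (extant gene ↔ extant
species).  Transfers connect two distinct branches of the same slice.
Cost = d·δ + t·τ + l·λ with d = #D, t = #T + #TL, l = #SL + #TL; S, NE
and C are free; δ, τ, λ must be positive.  Losses occur only inside SL
and TL — there is no standalone loss event in this vocabulary.

### Dynamic program

For gene node u (postorder) and S′ node x (by ascending date), the
minimum cost c(u, x) of embedding the subtree of u with u's lineage
ending at x combines the cases: C (matching extant leaves, 0); S at an
original node (both child assignments); SL (λ + cheaper child branch); NE
at an artificial node; D (δ + both gene children at x); T (τ + one child
at x, the other at some y ≠ x in x's slice); TL (τ + λ + the lineage
continues at y ≠ x in the slice).  TL couples cells of one slice; a
single relaxation pass over the pre-TL values is exact because a chain of
two TLs costs 2(τ+λ) and is therefore never strictly better than one
(ties with chained TLs can still enter the *graph*, and do, correctly —
the relaxation only computes values).  Cost equality uses an absolute
tolerance of 1e-9 throughout, far below any realistic cost resolution.

### Canonical form

Distinct S′-reconciliations can induce identical event sets with respect
to S: a free NE chain lets a D or a transfer slide across the slices of
one S branch.  Supports must weigh each S-level history once, so the DP
counts *canonical* representatives only, enforced locally by a
fresh/stale flag per cell: a lineage is *fresh* where it just entered a
branch segment (after S, SL, D, T, TL) and *stale* after an NE.  D is
allowed only at fresh cells; a transfer below an NE only when its
receiver branch has no node one slice up (i.e. the same transfer was
impossible a slice earlier); the gene root's first event is never an NE,
and root placements of D/T/TL are pinned to their earliest feasible cell
by giving non-top-of-branch root cells stale semantics.  Every S-level
history then has exactly one surviving realization, with unchanged cost.
This construction is *verified, not assumed*: on batches of random
instances the graph's reconciliation count and every per-event support
equal brute-force tallies of distinct projected event sets exactly.

### The reconciliation graph

Mapping nodes ⟨u, x⟩ (keyed by gene node, S′ node and freshness) point to
event nodes (keyed by type, children and receiver, merging shared
sub-solutions), built by retaining every locally co-optimal DP case and
pruning to cells reachable from the optimal roots (several roots are
possible).  below(v) = number of partial reconciliation trees under v,
above(v) = number of completions from the roots; N(v) = below·above, and
N_total = Σ_roots below.  Uniform sampling over encoded MPRs draws roots
and event children proportionally to below.

### Event identity and supports

Two events are the same when they share the gene node, the event type and
the S-location: D by branch, S by speciation node, SL by node plus
surviving child branch, T/TL by (donor, receiver) branch pair.  Swapped
child assignments of one S or T are equivalent (the symmetric condition),
which the keying realizes by omitting the assignment.  MPR support =
Σ N(e) over event nodes sharing a key / N_total.  NPR support pools
graphs built under perturbed costs: Σᵢ countᵢ / Σᵢ Nᵢ
(reconciliation-weighted, matching "fraction of sampled reconciliations";
an unweighted per-graph mean is available for sensitivity analysis).
C and NE events are never tabled — all reconciliations share them.
Filtering keeps events with f(e) ≥ T ("not smaller than"); the filtered
set is generally only a partial history.

### Medians

d_asym(R₁, R₂) = |E(R₂)∖E(R₁)| and d_sym = |E(R₁)△E(R₂)| on event keys
(C excluded).  The summed-distance minimizer within the MPR set maximizes
Σ_{e∈E(R)} f(e) (asymmetric) or Σ (f(e)−½) (symmetric); both are found by
one graph traversal: event nodes score their (offset) support plus their
children, mapping nodes take the best event child, and a backtrack from
the best root marks one tree.  Ties break deterministically (event type
order S < D < T < TL < SL < NE, then species node, then children), so
outputs are reproducible.  Over NPR graph sets the extraction runs per
graph with the pooled supports and the best overall tree is returned.

### Near-optimal sampling

Each replicate draws δ, τ, λ independently from Normal(c, (Δ·c)²),
rejecting non-positive draws (at Δ ≤ 0.4 the rejection probability is
≈ Φ(−2.5) ≈ 0.006, a negligible truncation); Δ = 0 short-circuits to the
exact costs, making NPR supports collapse to MPR supports exactly.
Replicates run on derived substreams, so replicate i is identical
regardless of the replicate count.  Default replicates: 1000;
desk-scale analyses in the tests use 50.

## The simulator

One gene lineage starts at the species root; along each branch, D, T and
L strike as a Poisson process with per-gene per-My rates; speciations
split the lineage; receivers are drawn uniformly among co-existing
branches other than the donor (including, if contemporaneous, branches
ancestral to extant species of the donor's clade).  Rates: loss ~
U[0.001, 0.0018] events/gene/My; birth (D+T) = loss × U[0.5, 1.1];
duplication share of birth ~ U[0.7, 1].  Extinct subtrees are pruned and
the history re-read as a reconciliation of the pruned tree: a one-sided
speciation becomes SL (loss on the dead child branch), a transfer whose
donor copy dies becomes TL (loss on the donor branch), and events with no
surviving descendants vanish.  The recorded true event set is therefore
exactly realizable by a reconciliation — re-scoring it through the cost
function validates every invariant — and events invisible in the pruned
gene tree are, by construction, not demanded of any method.  Families
with no survivors (or fewer than a requested minimum of leaves) are
redrawn, with a bounded retry count.

Per-family parsimony costs derive from the true history: cost of type E =
−log₁₀(|E| / (|D|+|T|+|L|)), speciations free; zero counts get a 0.5
pseudocount so costs stay finite.

Sequence evolution and gene-tree inference are *not* modelled.  Instead,
true gene trees are degraded by random NNI moves until a target
normalized (unrooted) Robinson–Foulds distance — 17.7% in the study
protocol — is reached, emulating the average reconstruction error of
ML trees without a sequence layer.  This stand-in reproduces the *amount*
of topological error but not its structure (real inference errors
concentrate on short branches and low-support clades), so the study
trends below demonstrate behaviour under topological noise, not under any
specific inference method.

## Evaluation

Only D, T and L components are scored, by species-tree location (gene
position disregarded): D by branch, T by (donor, receiver) pair, L by the
branch carrying the loss (TL → its T plus an L on the donor; SL → an L on
the non-surviving child).  Multiset min-matching gives TP, FP, FN;
D_DTL = FP + FN; precision = TP/(TP+FP), recall = TP/(TP+FN).  True
negatives are not computable here, so precision–recall (not ROC) curves
are used, pooling counts across families by default (per-family averaging
optional) and excluding, at each threshold, families whose filtered
prediction is empty.

## Study protocol and problem sizes

The packaged study (tests) runs on a generated 12-leaf dated species tree
of height 1000 My with 50 families of ≥ 4 surviving genes, NPR supports
at Δ = 0.2 with 50 replicates, and a fixed seed; at these rates a family
carries on the order of a dozen true D/T/L events, and on a 37-leaf tree
of height 300 My the simulator produces family sizes and event loads of
the same order as the motivating dataset.  Checked trends: filtering a
random MPR at full support does not increase the mean D_DTL; NPR-based
supports reach at least the precision of MPR-only supports at the 90%
threshold; and unfiltered reconciliations sampled under perturbed costs
are not significantly more accurate than unfiltered MPRs (paired
one-sided test, α = 0.05) — the gain comes from the supports, not from
the sampling itself.  Trend checks are statistical statements at n = 50,
not exact identities; all exact claims (counts, supports, medians,
degeneracies) are tested against brute-force enumeration on instances
small enough to enumerate (≤ ~6 gene leaves, ≤ ~5 species — the
enumerator refuses larger inputs).

## Known limitations

* Gene trees and species trees must be rooted and binary; tied internal
  species dates are rejected (an optional seeded jitter of ±1e-9 of the
  date range resolves ties deterministically when requested).
* Extant species absent from a gene family stay in S; losses explain the
  absences.  This is the model's reading, not an option.
* The NNI stand-in for gene-tree inference, and the smaller simulated
  trees, mean the study reproduces qualitative behaviour; absolute error
  levels depend on tree sizes, rates and the error model.
* Transfers to extinct or unsampled lineages ("to the dead") are outside
  the model, as are polytomies and probabilistic reconciliation.
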
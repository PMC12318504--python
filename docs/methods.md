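# Methods

## Parsimony scoring

Characters are unordered (non-additive) with equal unit costs between any
two states, the convention for morphological matrices scored with equal
weights; ordered characters are deliberately out of scope. A missing or
inapplicable tip (`?` or `-`) is assigned the full state set at the leaf; a
polymorphic tip (`{01}`) its declared set — both mean "any member state"
during optimization.

Binary trees are scored by the Fitch intersection/union pass, vectorised
with numpy bitmasks across characters. A rooted representation whose root
has three children (the unrooted reading) is scored by sequential pairwise
combination at the root, which is exact there because it equals rooting
along one of the three incident edges. Trees with hard polytomies
(degree ≥ 4) are scored by a unit-cost dynamic program over states
(Sankoff with a uniform cost matrix); sequential Fitch would overcount on a
star tree, the DP does not. Scores are invariant to rooting and to
leaf-order permutation (tested).

Per-character bounds: `m_i` is one less than the smallest number of states
that intersects every non-missing cell (a hitting set, found by brute force
over the ≤ 10 observed states — polymorphism is thereby resolved to
minimize), and `g_i = (non-missing cells) − max_state (cells containing
that state)`, the score on the completely unresolved bush with polymorphism
resolved to maximise the plurality state. A character is
parsimony-informative exactly when `g_i > m_i` (its steps can vary across
trees) and constant when `m_i = 0`. Ensemble CI/RI/HI/RC sum over **all**
characters, including uninformative ones, which is the convention that
matches the values usually printed by PAUP-style analyses; an all-constant
matrix reports CI = RI = 1 with a warning. Display values round to three
decimals half-up; full precision is retained on the result object.

**ACCTRAN.** On a rooted binary tree the down-pass unit-cost DP gives each
node's per-state subtree cost; the up-pass then chooses states greedily in
preorder, minimising (subtree cost + change indicator against the parent),
breaking ties by *preferring a change* — which accelerates transformations
rootward — and then by the smallest state symbol. The root takes its
cheapest state (smallest symbol on ties). The greedy choice on this DP is
optimal, so the implied change count always equals the Fitch length
(tested), and the tie-break reproduces rootward placement of ambiguous
changes. Exact traversal-order quirks of legacy programs are not emulated.

## Heuristic search

Stepwise addition inserts taxa in input-file order ("simple" sequence;
random order with replicates is available), trying every edge and keeping
the first best attachment in a sorted edge traversal. TBR then bisects the
tree at every branch, suppresses the stub vertices, and reconnects every
edge of one fragment to every edge of the other (a lone-leaf fragment
reattaches at the leaf). Neighbor topologies are deduplicated by canonical
bipartition sets. The optimal set is a FIFO queue with a seen-topology hash:
every tree at the current best length is swapped; any strictly better
neighbor restarts the process; equally long unseen neighbors join the queue
("swap on all"). A `maxtrees` cap (default 10,000) guards flat landscapes
and logs a warning when hit. On highly homoplastic matrices a single start
can be trapped on a plateau whose trees have no shorter TBR neighbor;
`n_starts > 1` adds random-addition-sequence replicates, and the
exhaustive-agreement checks run with 20 starts for that reason.

At n = 5 the TBR neighborhood coincides with SPR (one fragment of any
internal bisection is a cherry, so rerooting it adds nothing): 12 of the
other 14 topologies are one move away, the remaining 2 require two moves.
The test suite checks the neighborhood against a brute-force oracle built
from the definition (a topology is one move away iff some edge-cut leaf
partition of the start tree is displayed with identical restrictions on
both fragments).

**MPT counting and the collapse rule.** Distinct most-parsimonious trees
are counted after collapsing branches whose minimum optimized length is
zero (`collapse="ambzero"`); a branch qualifies exactly when contracting it
leaves the tree length unchanged, which is how it is implemented (contract
and rescore). `collapse="none"` counts binary resolutions instead. Both are
exposed because published MPT counts depend on the convention.

**Bootstrap.** Each replicate resamples character indices with replacement
and rescores via a resampled weight vector (equivalent to resampling
columns, with no re-encoding); replicate *r* draws from a substream seeded
by `(seed, r)`, so runs are reproducible and parallelizable. Support for a
clade is the percentage of replicates whose strict consensus of that
replicate's MPT set contains the corresponding bipartition.

## Consensus

Majority-rule consensus keeps exactly the splits occurring in more than the
cutoff fraction of trees (strict at the boundary by default — a split in
exactly half the trees is dropped; configurable). For cutoff ≥ 0.5 the kept
splits are mutually compatible, and the tree is assembled by nesting clades
by containment, rooted on the first taxon's side; retained nodes carry
their percentage. dendropy's consensus serves as an independent oracle in
the tests, never as the implementation.

## Time-scaling and richness

Tip ranges under the **max** scenario are `[fad_old, lad_young]` (broadest)
and under **min** `[fad_young, lad_old]` (narrowest); an inverted minimum
range collapses to a point at its midpoint. Multi-formation taxa are merged
before scaling: oldest formation brackets the FAD, youngest the LAD, so the
maximal span runs from the oldest old-bound to the youngest young-bound.

Node ages follow the basic paleontological rule — a node is as old as the
oldest origination among its descendants — because the input data are time
*constraints*, not a dating model. A zero-length internal branch is
extended rootward by `min_branch` (default 0.1 Ma) so parents are strictly
older; soft polytomies attach children directly at the polytomy's age.
Lineage counting is per branch with the half-open convention: a branch
`[older, younger)` contains `t` iff `older ≥ t > younger`; ghost segments
(the part of a tip's branch older than its own origination) count in both
scenarios, since the topology forces them regardless. Curves are evaluated
at slice midpoints on a `[t_start, t_end]` grid (default 35.0 → 5.0 Ma at
0.1 Ma = 300 slices); across a tree set the per-slice maximum of the max
scenario and minimum of the min scenario are reported.

A consistency caveat the tests make explicit: oldest-descendant-FAD
time-scaling recovers the *true* node ages from complete, uncertainty-free
tip data only when every internal node has a direct leaf descendant to
witness its age (`ages_identifiable`). At balanced nodes (two internal
children) the witness is lost and the estimated curves are a lower bound on
true diversity. Exactness is therefore asserted on identifiable records and
the bound (plus min = max) on all records.

**Stage bins.** Stages are half-open `[old, young)`; an occurrence interval
touches a stage only where the overlap has positive width (an endpoint
sitting on a boundary does not leak into the adjacent stage), and a point
occurrence belongs to the stage whose old boundary it touches. Each taxon
then occupies every stage from the oldest to the youngest it touches
(range-through), and counts aggregate per family. The bundled rounded
stage table (Rupelian 33.9–28.1 … Messinian 7.2–5.3) is the default; an
ICS-2023 table ships as an alternative.

## Bundled data

The bundled desmostylian range/occurrence tables and family topologies are
**synthetic stage-level reconstructions** (marked `_synthetic` in their
filenames): per-taxon stage spans compiled from published per-stage species
compositions for Paleoparadoxiidae and Desmostylidae, with placeholder unit
names. They reproduce the published stage-binned counts (five
paleoparadoxiid species in the Langhian; desmostylids at 2–2–3–2–2–2–1–0
from Rupelian to Messinian) by recomputation, but they are not the original
locality-level compilation, which is not redistributed; analyses needing
locality resolution should substitute the original tables via the same TSV
schema. Likewise the original 19 × 112 character matrix is not included:
the acceptance tests that verify the published tree length (206), fit
indices (CI 0.623, RI 0.652, HI 0.377, RC 0.407) and MPT count (136)
against it report a clear failure until the file is placed at
`src/paleodiv/data/desmostylia_matrix.nex`.

## Synthetic records

The generator is a forward Gillespie birth–death process started from one
lineage (defaults: birth 0.25, death 0.18 per lineage per Ma — species
durations of a few Ma in a slowly diversifying clade), stopped at the birth
event that brings the total tip count to `n_tips`; surviving lineages are
truncated at the stop time and the stem below the first divergence is
dropped (the record starts at the crown). Retries on early extinction are
bounded. Characters evolve by a symmetric k-state Markov jump process
(k ∈ {2, 3}) at `change_rate` expected changes per character per Ma
(default 0.02 — about one to two changes per character over the whole tree,
i.e. low homoplasy); an optional variable-only filter mimics collecting
only varying characters. Defaults mirror the study scale: 16 tips,
112 characters, three states, a 35 Ma origin.

Sampling: each 1 Ma of a lineage's duration yields a dateable find with
probability `sampling_prob` (1.0 = complete: the exact endpoints are
observed); the observed FAD/LAD are the oldest/youngest finds — ranges are
eroded inward, never extended — and each endpoint is wrapped in a symmetric
uncertainty envelope of fixed half-width (default 0.5 Ma, a typical
formation-level dating uncertainty). Taxa with no finds leave no observed
range. `synapomorphy_matrix` additionally builds homoplasy-free matrices
(five diagnostic characters per clade by default) for the clean-signal
bootstrap checks: with c diagnostic characters a clade survives a resample
with probability ≈ 1 − e^(−c), so c = 5 puts true-clade support near 99%.

What the simulator does *not* emulate: correlated character evolution,
ascertainment bias beyond the optional filter, geographically structured
sampling, and anagenetic (budding) taxon identity — tips are taxa and a
taxon's origination is its divergence from its sister. Passing tests
therefore show correctness of the machinery under these idealisations, not
robustness to every feature of real fossil data.

**Recovery expectations (pilot-calibrated).** Birth–death trees routinely
contain internal branches short enough to carry zero character changes
(probability e^(−rate·length·n_chars)), which no method can resolve; full
recovery of the true topology by the strict consensus of MPTs therefore
plateaus near 25% at study scale, while the *recall* of true splits sits
near 75% and recovered splits are mostly true. The recovery tests assert
those pilot-calibrated levels rather than a near-perfect rate.

## Problem sizes used in the checks

The automated checks run at the sizes stated in their docstrings: 200
random ≤ 6-leaf instances against the exhaustive internal-assignment
oracle; 50 random ≤ 7-taxon matrices against full topology enumeration
(≤ 945 trees); 1,000 simulated records for the min ≤ max bracketing; 200
bootstrap replicates on clean matrices of 8 taxa. These sizes make every
oracle exact by enumeration while keeping the whole suite fast.
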
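# Methods

This note documents the models and procedures implemented in `astomecoev`,
the assumptions they make, the parameters that matter, and the numerical and
design choices taken where the design was genuinely open.

## Corrected unweighted PINA similarity (`astomecoev.pina`)

The unweighted phylogenetic interaction-adjusted index scores two host
communities by the summed pairwise association Φ between their symbiont
members.  The corrected form divides the cross-community sum by the
geometric mean of the two within-community sums, which is the unique
normalisation under which a community compared with itself scores exactly 1.
That axiom (identity of indiscernibles) is the reason the corrected form
exists, and the test suite enforces it to 1e-12 over random strictly
positive association matrices.

Two constructions of Φ from a distance matrix are provided, because the
transformation from distances to associations is not canonical:

* `linear` — Φ_ij = 1 − d_ij, appropriate for p-distances, which already lie
  in [0, 1];
* `max_rescaled` — Φ_ij = 1 − d_ij / max(d), appropriate for cophenetic
  (path-length) distances, which are unbounded.

The mode used is recorded on the returned matrix.  The two constructions
give concordant but not identical host orderings: on simulated communities
the Spearman correlation of the resulting similarity matrices is typically
0.8–0.95.  The residual disagreement is structural — the two transforms are
different monotone maps of distance, and the index sums Φ entries, so
per-entry monotonicity does not transfer to the summed scores — and not a
consequence of sequence-sampling noise.

Properties worth knowing: P_U is symmetric; with Φ = I it reduces to the
cosine (Ochiai) index |A∩B|/√(|A||B|); it is bounded by 1 when Φ is positive
semidefinite but may exceed 1 for indefinite Φ (this is documented
behaviour, not an error).  Only the presence/absence (unweighted) form is
implemented; abundances are ignored by construction.

Ordination uses metric MDS via scikit-learn's SMACOF.  The configured
defaults (2 components, 20 000 iterations, 250 random initialisations,
convergence ε = 1e-8) are strict enough that the embedding sits at the
SMACOF fixed point for matrices of this size; tests use far smaller
settings because the embedded matrices are tiny.  Similarities are converted to dissimilarities as
δ = 1 − s, the simplest monotone choice.  The best embedding over the random
initialisations is selected by final stress, with the whole procedure
reproducible under a fixed seed.

## Event-based reconciliation (`astomecoev.reconcile`)

The reconciliation model maps a rooted binary symbiont tree onto a rooted
binary host tree whose internal nodes are totally ordered in time (a
"timing").  Five events carry nonnegative costs: cospeciation, duplication,
duplication followed by host switching, loss (sorting), and failure to
diverge.  The total cost of a reconciliation is the dot product of its event
counts with the cost vector, and ten preset vectors are provided (the Jane,
TreeMap and TreeFitter defaults, adjusted and prohibitive variants, and
equal weights).

Semantics:

* a cospeciation places a symbiont divergence at a host node, with the two
  symbiont children following the two host children;
* a duplication places a divergence on a host edge, both children remaining
  in that host lineage;
* a duplication + host switch sends one child to any host edge alive in the
  same time slice (contemporaneous switching);
* a loss is a symbiont lineage crossing a host speciation into only one
  child lineage;
* failure to diverge is a symbiont lineage crossing a host speciation into
  both children without diverging.  It arises exactly when a symbiont tip is
  linked to more than one host tip: the tip is expanded into a fan across
  its linked hosts, each spanned host speciation contributing one
  failure-to-diverge event and each one-sided crossing a loss.  The fan is
  unique given the host set, so its cost is computed once per (tip, edge).

For a fixed timing the optimal placement is found by dynamic programming
over states (symbiont node, host edge, time slice), processed bottom-up in
the symbiont tree and backwards in time.  The switch transition uses
best/second-best bookkeeping over edges per slice, making the DP
O(|symbiont nodes| × slices × edges).  A virtual root-stem edge above the
host root allows the symbiont root to cospeciate at the host root or to be
lost into one side of it.

The exact solver enumerates every linear extension of the host internal-node
ancestry partial order (every timing) and keeps all timings achieving the
global minimum; it is restricted to instances of at most `exact_threshold`
(default 8) tips per side, where the timing space is small.  Co-optimal
event-count vectors are collected by backtracking every cost-tied transition
(capped at 500 distinct vectors), which is what produces range entries such
as "0–2" cospeciations across co-optima.  The heuristic solver searches
timing space with a seeded (μ+λ)-style evolutionary algorithm — adjacent
transpositions respecting ancestry as the mutation operator, truncation
selection, random restarts, early stopping after 25 stagnant generations —
and solves each candidate timing exactly with the same DP, so its cost can
never undercut the exact solver and equals it on every instance small enough
for both (enforced on 200 simulated tanglegrams).  The `SolverConfig`
defaults (10 000 generations, population 1 000) are a deliberately generous
search budget; because the library is exercised on small simulated instances whose
timing spaces hold at most a few hundred orders, tests and scripts pass
explicitly smaller budgets (tens of generations, populations of a few dozen)
that already saturate the search space.

Significance of an observed optimal cost is assessed against random
symbiont trees on the same tip label set with the links retained.  The
default null draws uniformly from rooted binary labeled topologies (PDA
model, by Rémy-style uniform edge insertion); a label-shuffle null (permute
which host set each symbiont tip carries, topology fixed) is available
behind a flag, since the choice of randomisation is not canonical.
p = (1 + #{null cost ≤ observed}) / (n_samples + 1).  On small instances the
cost statistic is strongly discrete — a third or more of the null samples
can tie the observed value — so this conservative convention yields null
p-values whose mean sits above 0.5 (typically 0.6–0.7).  The test remains
valid (its rejection rate at α = 0.05 is at or below nominal, verified in
the suite); it simply loses power to the ties on very small tanglegrams.

## ParaFit-type global test (`astomecoev.parafit`)

Principal coordinates are computed by Gower double-centring of −½D²; when
the smallest eigenvalue is below −1e-10 × λ_max, the Lingoes constant
c = |λ_min| is added to all off-diagonal squared distances (d′² = d² + 2c)
and the decomposition is repeated, after which no eigenvalue is meaningfully
negative.  All axes with eigenvalues above the relative tolerance are
retained (the number of axes to keep is not specified anywhere
authoritative; keeping all positive axes loses no information).  The
coordinates reconstruct the corrected distances to 1e-8, which the suite
checks directly.

The global statistic is ΣD²_ij with D = P′A′H, where H and P are host and
symbiont principal coordinates and A the binary host × symbiont incidence.
The permutation unit is each symbiont's host-association vector: every
column of A is independently permuted over hosts, and
p = (1 + #{null ≥ observed}) / (n_permutations + 1) (999 permutations by
default).  Per-link statistics use the difference form — the drop in the
global statistic when the link is removed — computed against the same
permutation null; the rank-one identity D′ = D − p_s h_h′ makes the removal
cheap.  When a permuted matrix lacks the focal cell, removing it changes
nothing and the null contribution is zero.  The ratio form of the link
statistic is not implemented.  Calibration (near-uniform p under links
independent of both trees) and power (codivergence detected far more often
than the false-positive rate) are both exercised in the acceptance suite.

## Sequence handling (`astomecoev.seqio`)

p-distances use pairwise deletion: for each pair, columns where either
sequence has a gap, an `N` or any IUPAC ambiguity code are excluded, and the
distance is mismatches over compared sites.  Excluding ambiguity codes like
gaps matches the usual treatment of missing data in pairwise-deletion mode.
Pairs with zero comparable sites are reported as undefined (NaN) and never
imputed.  Internal values are proportions; presentation multiplies by 100.
`U` is normalised to `T` on read so RNA and DNA inputs are comparable.
COI translation uses NCBI table 5 (invertebrate mitochondrial: AGA/AGG→Ser,
ATA→Met, TGA→Trp) via biopython, with all-gap codons rendered `-`, partially
gapped or ambiguous codons `X`, and the incomplete trailing codon dropped.
Cophenetic distances are tip-to-tip path lengths extracted with dendropy.
Divergence summaries report within-group and between-group (min, max)
ranges; singleton groups have no within-group range and are reported absent.

## ITS2 structures (`astomecoev.its2`)

Structures are sequence + dot-bracket pairs with optional helix spans
(helices I–III; helix III genuinely absent in one taxon, so spans are
annotations, not assumptions).  Feature extraction counts base pairs per
helix, the terminal loop as the unpaired stretch enclosed by the innermost
pair, remaining unpaired span positions as bulge/internal-loop nucleotides,
unannotated unpaired positions as the central loop, GU wobble pairs, and GC
content.  CBC counting compares two aligned sequences under a shared pairing
annotation: a pair enters the comparison only if both taxa form canonical
pairs (AU, UA, GC, CG, GU, UG) at it; both partners differing is a CBC,
exactly one a hemi-CBC.  Pair↔unpaired transitions are neither counted nor
compared — the stricter convention, chosen because the alternatives are not
defined anywhere authoritative; gap-containing pairs are likewise invalid.
Folding free energies are accepted as input annotations only; thermodynamic
computation is out of scope.

## Diagnostics and prevalence (`astomecoev.diagnostics`)

A diagnostic signature lists 1-based alignment columns where every query row
shares one state and no reference row carries it.  The shared state must be
an unambiguous nucleotide, or — on by default — a gap shared by all query
rows (real diagnoses do include gap states).  Ambiguity codes in the
reference are expanded and block their expansions, a conservative rule that
can only remove candidate positions; consequently adding reference sequences
never adds diagnostic positions (a property the suite checks).  Barcode-gap
classification flags a group pair `distinct` when the smallest between-group
divergence exceeds the marker threshold and no within-group divergence does,
`conflict` when a within-group range itself exceeds the threshold (the
cryptic-lineage situation), and `ambiguous` otherwise; default thresholds
are 1% for mitochondrial 16S and 3% for COI.  Prevalence is reported
per host, pooled over all examined individuals, and pooled over the hosts
with at least one infection; rounding (two decimals, half-up) is applied at
presentation only.

## Synthetic data (`astomecoev.simulate`)

The host tree is a Yule (pure-birth) tree with unit speciation rate,
conditioned on the tip count; because the standard simulation stops exactly
at the n-th speciation, terminal branches are extended by the waiting time
to the unrealised next speciation before rescaling the root depth to 1.
Symbiont lineages evolve top-down along this timed tree.  At each host
speciation an incumbent single-host lineage cospeciates with probability
`cospeciation_prob`, follows both children without diverging with
probability `ftd_prob`, or follows one child (a loss) with probability
`loss_prob`; the three must sum to 1.  Along edges, duplications and
duplication+host-switch events arrive as independent Poisson processes with
per-lineage rates `duplication_rate` and `switch_rate` per unit tree time; a
switching daughter jumps to a uniformly chosen other edge alive at that
moment (if none is alive the draw is discarded).  A lineage that has failed
to diverge occupies several host lineages and undergoes no further
divergence events; at later speciations of any edge it occupies it spans the
speciation again (failure to diverge) with probability
`ftd_prob`/(`ftd_prob`+`loss_prob`), else follows one child (loss).  This
freezing rule keeps failure to diverge a property of tip lineages, matching
the reconciliation semantics, at the price of not modelling re-diversifying
multi-host lineages.  Extinction cannot occur — a loss leaves the lineage in
the other child — so every simulation yields a valid tanglegram whose logged
history is a feasible reconciliation; its cost therefore upper-bounds the
solver's optimum under any scheme, one of the strongest end-to-end checks in
the suite.

The default generator settings (8 host tips, cospeciation 0.6 / loss 0.3 /
failure to diverge 0.1, duplication and switch rates 0.5 per unit time)
produce mixed histories in which codivergence dominates but every event type
occurs — the regime the reconciliation analyses are designed to
discriminate.  Solver-equivalence and upper-bound checks run on 4–7-tip
hosts because the exact solver's timing enumeration is the oracle there.

Alignments evolve under Jukes–Cantor along the given branch lengths
(expected substitutions/site): per site and branch the replacement
probability is ¾(1 − e^(−4d/3)), so the expected p-distance between tips at
path length d has the closed form used as the recovery target in the tests.
No rate heterogeneity, no indels.  Occurrence tables draw per-host examined
counts as Poisson around a configurable mean (default 30, the order of the
per-species sample sizes in earthworm surveys), infected counts as binomial
at the requested prevalence, and give each positive host one or two symbiont
species, emulating the small per-host astome communities.

What the generator does *not* emulate: alignment gaps and ambiguity codes
(gap handling is tested on hand-built fixtures), rate variation across sites
and lineages, host extinction, within-host symbiont abundances, and
sampling error in tree estimation (trees are passed to the analyses
noise-free except through the simulated sequences).  Passing tests
demonstrate the correctness of the computations under the stated model, not
robustness of the biological conclusions to violations of it.

## Problem sizes and determinism

Tests and the acceptance script run the exact reconciliation oracle on 4–7
tip instances (hundreds of timings at most), the heuristic with small
explicit budgets, permutation tests at 99–999 permutations, and sequence
lengths of 2 000–20 000 sites — sizes at which every check completes in
seconds while the quantities under test (costs, counts, p-value
calibration, closed-form expectations) are already fully expressed.  Every
stochastic component takes an explicit seed: the simulators use per-call
seeds, the searches and permutation tests seed their own generators, and
repeated runs are bit-identical.
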
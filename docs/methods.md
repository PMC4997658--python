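# Methods

This note documents the models, algorithms, defaults and design decisions
behind `osteoasr`, and what the synthetic experiments do and do not
establish about real data.

## The inference problem

Two osteological characters track the detachment of the mammalian middle
ear from the jaw: the **postdentary trough** (a lingual channel of the
dentary housing the attached ear-precursor bones; its absence marks
detachment) and **Meckel's groove** (holding Meckel's cartilage; its loss
marks the final ear–jaw separation). Parsimony mappings of these characters
on published phylogenies imply up to seven independent losses or even
regains of the trough. The package implements the model-based alternative:
estimate phylogeny and ancestral states jointly under a probabilistic model
of discrete character evolution, and report Bayesian posterior
probabilities (BPPs) of each state at named ancestors, integrating over
topology, branch-length and parameter uncertainty.

## Likelihood model

Characters evolve independently under the **Mk model**: a k-state
continuous-time Markov chain with equal exchange rates and stationary
frequencies 1/k, scaled so branch lengths are expected changes per
character. Transition probabilities are closed-form:

    p_same(t) = 1/k + (k-1)/k · exp(-k·t/(k-1)),
    p_diff(t) = (1 - p_same(t)) / (k-1).

**Ascertainment (Mkv).** Morphological matrices contain no constant
characters, so every partition is, by default, conditioned on variability:
the likelihood of each character is divided by one minus the summed
probability of the k constant patterns. The correction is computed per
partition with that partition's rates, inside the same pruning pass (the
constant patterns ride along as pseudo-characters).

**Rate heterogeneity.** Multi-character partitions get discrete-gamma rate
variation with equal-probability categories and category-mean rates, four
categories by default (the standard discretisation; category count and
means-vs-medians are conventions, both configurable in principle but means
are used throughout). Single-character partitions (the trough, the groove)
get no gamma — among-character rate variation is meaningless for one
character.

**Partitions.** Character matrices carry a partition label per character
(defaults: mandibulodental, postcranial, cranial, meckels_groove,
postdentary_trough). Each partition has a free positive rate multiplier;
multipliers are normalised to weighted mean 1 (weights = character counts)
at evaluation time, so the overall rate is confounded with branch lengths
exactly once. A consequence worth noting: scaling all raw multipliers by a
constant is the identity, and only the product of normalised rate and
branch length is identifiable.

**Tip data.** Missing entries contribute all-ones partials; uncertainty
sets `{01}` and polymorphism `(01)` both contribute indicator partials
(identical likelihood treatment; the notation is preserved on round-trip
output). Uncertainty counts toward taxon completeness — it constrains the
likelihood — while missing data do not.

Likelihoods are computed by Felsenstein pruning, vectorised over characters
and categories with a specialised closed-form kernel for binary characters,
and periodic (every 8th internal node) per-character rescaling against
underflow on large matrices.

## Priors and MCMC

* Topology: uniform over rooted binary labelled topologies compatible with
  the constraints. (Uniform-rooted induces uniform-unrooted, since every
  unrooted topology on n tips has the same number of rootings.)
* Branch lengths: iid exponential, mean 0.1 (configurable).
* Gamma shapes: exponential, mean 1.
* Raw partition-rate multipliers: iid exponential(1); only their
  normalisation enters the likelihood.

Sampling is Metropolis-coupled MCMC: each run has one cold chain plus
heated chains (default three chains, incremental heating 1/(1+0.1·j)), with
one swap attempt between a random adjacent pair per generation. Default
two independent runs with seeds derived from the master seed via
`numpy.random.SeedSequence.spawn`, making every run exactly reproducible.

Proposals: NNI (weight 0.25); rooted SPR with uniform reattachment along a
uniformly chosen branch (0.15; the Hastings factor is the ratio of the
split target branch length to the merged source length); single-branch
multipliers (0.35); gamma-shape and partition-rate multipliers (0.10/0.15).
The NNI move graph is verified exactly symmetric by enumeration of all 105
rooted five-taxon topologies (a test in the suite), and prior-only
sampling reproduces the uniform topology distribution (chi-square check in
the acceptance suite; note that the chi-square statistic assumes
independent draws, so the check thins the chain to one sample per 50
generations).

**Constraints.** Positive constraints require a taxon set to be
monophyletic; a negative constraint (clade, excluded-taxon) requires the
clade *minus* the taxon to be monophyletic, which forces the taxon outside.
Proposals violating a constraint have prior zero and are rejected; the
starting tree is built by grouping required clades (smallest first) and
randomly resolving, which also detects unsatisfiable constraint sets.
Specifying an outgroup adds an ingroup-monophyly constraint, anchoring the
root — necessary because the Mk likelihood alone cannot identify the root
(pulley principle).

**Diagnostics.** Burn-in defaults to 25% of retained samples. Per-scalar
ESS uses the initial-positive-sequence autocorrelation estimator; a
constant trace reports ESS = n (degenerate, flagged by the caller's
threshold). Between-run convergence is the mean absolute split-frequency
deviation across the union of observed splits (ASDSF-style); the pipeline's
default thresholds are ESS > 100 and deviation < 0.05, and failing them
flags the report as non-converged rather than aborting it.

**Consensus.** Majority-rule (>50%) consensus from rooted clade
frequencies, with mean subtending branch lengths and posterior labels;
cross-checked against dendropy's consensus in the test suite.

## Ancestral states and BPP tables

Marginal reconstruction at a node multiplies the inside (pruning) and
outside conditional likelihoods per gamma category, sums over categories,
and normalises. Mkv conditioning scales inside and outside by the same
constant and cancels.

A *named ancestor* is defined by a taxon set; its node is the MRCA of that
set located **on each posterior draw separately** (not on the consensus),
so the BPP integrates over topological uncertainty. When the set is not
monophyletic in a draw, the MRCA of the full set still exists and is used;
the fraction of draws in which the set is monophyletic is reported in the
table, making such cases auditable. Reconstruction on the consensus instead
is possible by passing consensus draws explicitly, but the per-draw choice
is the default and the one the acceptance experiments use.

## Parsimony mapping

Fitch counting (with the Hartigan majority generalisation on polytomies,
e.g. consensus trees) and Sankoff minimum-cost mapping over an arbitrary
cost matrix, with three packaged regimes: symmetric, asymmetric
(loss/regain priced separately) and Dollo (regain forbidden; cost
infinity). Polarity convention: state 0 = present (plesiomorphic), 1 =
absent; a loss is a 0→1 edge, a regain 1→0.

The reported decomposition is the most-parsimonious reconstruction with
the **fewest losses, then fewest regains** (the order loss/regain mappings
are conventionally presented in). Exact min/max ranges of both counts over
all MPRs come from lexicographic (cost, secondary-count) dynamic programmes
— valid because lexicographic minimisation distributes over the sum of
independent child contributions — so the ranges stay exact even when
explicit MPR enumeration is capped (10,000, deterministic order, cap
reported). The root state can be pinned to compare ancestrally-present
vs ancestrally-absent scenarios; note that pinning can cost up to one extra
change per root-child subtree (a constant character pinned to the other
state costs +2 on a binary root), not one overall.

## Erosion simulation

The phantom emulates the relevant architecture of a juvenile monotreme
dentary: an elongated half-cylinder with a denser outer shell, an internal
mandibular-canal tube running near the lingual surface, a shallow seam
notch (default 2 voxels) on the surface directly over the canal, and a
poorly-mineralised wall (reduced intensity) between seam floor and canal.
Greyscale is normalised to [0,1]; voxel size defaults to 30 µm and only
affects reporting units.

Two attrition routes both fabricate a groove: raising the segmentation
threshold strips the low-intensity wall before anything else, and binary
erosion (6-connected by default — "removing the external voxel layer" —
26-connected optional) thins the wall from both sides (the surface recedes
while the canal dilates) until the canal opens into a deep channel. A
plain surface notch in homogeneous material would *not* deepen under
uniform erosion — offsetting a surface moves a notch tip and a flat face
by the same amount — so the subsurface canal is the essential,
anatomically motivated ingredient.

The groove metric measures, per slice, the deviation of the lingual
contour from its convex envelope at the seam row (minus the sub-voxel
median deviation that voxelising a smooth convex contour produces), and
the control roughness as the RMS deviation of the *buccal* contour from
its convex envelope. Uniform erosion of the convex buccal side leaves the
control under half a voxel while the artifact groove grows severalfold —
the quantitative form of "an artifact without noticeable damage". Hull
discretisation limits the metric's floor to about half a voxel.

## Synthetic data

`simulate_tree` draws uniform rooted topologies (sequential addition, all
attachment positions equiprobable — verified by chi-square) with iid
exponential branch lengths. `simulate_characters` evolves states from a
uniform root down the tree, with per-character gamma rate draws, optional
variable-only rejection (cap 10^6 per character), and missingness applied
completely at random; all internal states and change edges are recorded as
ground truth.

`two_loss_scenario` is the flagship experiment: 14 taxa (an outgroup, four
trough-bearing stem taxa, a four-taxon southern clade and a five-taxon
northern clade), with the stem taxa placed *between* the two troughless
clades so that no single loss can explain the tip pattern. The trough
history is constructed, not simulated: present at the root, lost exactly
once on each clade's stem edge, no regains. Background partitions (90
binary characters across mandibulodental/postcranial/cranial, gamma shape
1, Mkv-conditioned) are simulated on the same tree; 10% of entries are
masked at random. Branch lengths keep root-to-tip depth below ~0.8
expected changes — binary characters saturate quickly, and a saturated
tree cannot anchor the queried clades — with clade stem edges of 0.3
carrying the grouping signal. The matrix size and the default run length
(12,000 generations, sampled every 25, two runs of three chains) are
chosen so the whole experiment is a desk-scale computation while still
passing its convergence diagnostics.

**What passing does and does not show.** The generator matches the
inference model's assumptions (Mk process, MCAR missingness, independent
characters), so recovery demonstrates correctness of the machinery, not
robustness to model violation. Real morphological matrices have
phylogenetically structured missingness (fossils lack postcrania),
correlated characters, and coding ambiguity; an optional per-taxon
missingness profile approximates the first, and none of the experiments
address the other two.

## Numerical choices

* Likelihood rescaling every 8th internal node (safe for hundreds of taxa
  at double precision; exact, since scales are tracked in log space).
* Gamma category means via the regularised incomplete-gamma identity, then
  renormalised to mean exactly 1.
* Consensus ties: clades at exactly 50% are excluded (strict majority).
* MPR enumeration: deterministic DFS order; the reported counts come from
  the DP, not the enumeration, so the cap cannot bias them.
* Trace files print fixed 6-decimal floats; identical seeds reproduce them
  byte for byte.
* Sub-seeds for independent runs stay below 2^31.

## Known limitations

* No tip-dating or clock models; branch lengths are in expected changes.
* No asymmetric-rate Mk variants or character correlation.
* Rooted SPR never regrafts above the root (NNI covers root-adjacent
  rearrangements); fine for mixing, but SPR alone would not be irreducible
  over rootings.
* The BPP of an ancestor defined by a non-monophyletic set is an average
  over varying MRCAs; the monophyly fraction must be consulted when
  interpreting it.
* The erosion phantom is a geometric idealisation; it demonstrates the
  artifact mechanism parametrically and does not reproduce any real
  specimen's anatomy or scanner characteristics.
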
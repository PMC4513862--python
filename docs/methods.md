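# Methods

`hpk` studies how stable hairpins in two complementary DNA strands change
the kinetics of duplex formation and dissociation. The central physical
statement is the detailed-balance relation for a second-order association
reaction,

    k+ / k- = exp(-dG0 / kBT) / c0,        c0 = 1 M,

so any stabilization of the single strands (a less negative dG0 of duplex
formation) must be absorbed by slower hybridization (k+), faster melting
(k-), or both. The package measures k+ directly with forward flux sampling,
measures dG0 from equilibrium landscapes, and infers k- from the relation
above; the interesting result is *how* the stabilization splits between the
two rates.

## State space

A configuration of a one- or two-strand system is a set of Watson-Crick
base pairs; each base joins at most one pair, intra-strand pairs enclose a
loop of at least 3 nt, and mismatches/wobbles are not representable.
Configurations are manipulated as bitmasks over the precomputed list of
feasible pairs. For energy evaluation the strands are concatenated 5'->3'
(probe then target) with a nick, and the pair set becomes a set of arcs
over this line. A greedy maximal non-crossing subset (arcs taken in linear
order) forms a nested skeleton whose faces carry nearest-neighbor terms;
arcs excluded from the skeleton are pseudoknotted ("kissing") contacts.

Order parameters are pair counts: for two strands, (n_inter, n_intra) with
n_intra summed over both strands; for a single strand,
(n_other_intra, n_intended_stem), where the intended stem is the designed
hairpin helix. For the experimental strands the intended stems are not
available in machine-readable form and are recovered as the most stable
contiguous self-complementary run under the energy model; the recovered
P4 stem (4 bp closing a 10-nt loop, with a 6-nt tail on one side) matches
the geometry described for those sequences.

## Energy model

The model is a secondary-structure-level stand-in for a nucleotide-level
3D force field. Every term is a (dH, dS) pair, so free energies are exact
at any temperature and single-histogram reweighting is well defined:

- **Stacks.** Unified nearest-neighbor dH/dS for the 10 unique dinucleotide
  steps at 0.5 M monovalent salt (the regime the reference systems were
  measured in), shipped as `hpk/data/nn_stacks.csv`.
- **Loops.** Hairpin, bulge and interior penalties tabulated at 37 C and
  treated as purely entropic; lengths beyond the tables extrapolate as
  1.75 RT ln(l/30). Multibranch loops use a generic affine penalty
  (2.5 + 0.4 per branch + 0.05 per unpaired nt, kcal/mol at 37 C).
- **Hairpin closing term** (dH = -5 kcal/mol, dS = -12 cal/mol/K): the
  terminal stack of the first loop bases on the closing pair of a stacked
  helix. Without it a bare pair-subset model underestimates the stability
  of short designed stems by roughly 20 C in Tm; with it the best-stem
  melting temperatures of the three probe strands come out 58/48/20 C —
  the ordering and spacing expected for 4-bp-stem > 3-bp-stem >
  unstructured designs.
- **Lonely-pair term** (dH = -6 kcal/mol, dS = -24 cal/mol/K): an isolated
  (unstacked) pair. NN tables carry all pairing enthalpy inside stacks, so
  a bare subset model would make lonely pairs athermal in units of kBT and
  leave a temperature-independent spurious "hairpin" population at any
  temperature; the term makes isolated pairs mildly penalized (about
  +1.4 kcal/mol at 37 C), in the spirit of secondary-structure tools that
  penalize or forbid lonely pairs.
- **Duplex initiation** (dH = +0.2 kcal/mol, dS = -5.7 cal/mol/K), applied
  once to any state with at least one inter-strand pair.
- **Pseudoknots.** Each crossing pair-pair combination costs a fixed
  penalty (default 2.0 kBT, configurable). This reproduces the qualitative
  finding that kissing intermediates are metastable but less stable than
  the equivalent nested states, without a 3D model.
- **Translational standard state.** Bound states additionally carry
  +ln(N_A V c0) kBT with V the simulation box volume (default
  3.96e-23 m^3, ln(N_A V c0) ~ 10.08). In-box Boltzmann occupancies,
  Keq = (P_bound/P_unbound) N_A V c0, and the association propensities are
  then mutually consistent, and dG0 = -ln Keq is volume independent.

Faces open at the nick or at strand ends are exterior and free. Known
limitation: for pseudoknotted states the greedy skeleton (and hence the
loop context of the crossing arcs) depends on which strand is listed
first; nested states are exactly symmetric under relabeling.

All numeric outputs of the model are stand-in values: the reference
work's force-field-specific numbers (rate ratios of 2.1/10.6, inferred
melting accelerations of 100/1934, etc.) are directional expectations
here, not quantitative targets.

## Exact oracle

Systems with at most 24 feasible pairs are solved exactly: depth-first
subset enumeration with one-pair-per-base pruning yields every valid
state; partition functions, binned landscapes, melting curves (recomputed
from dH/dS at each temperature), and mean first-passage times (dense
linear solve below 2000 states, sparse above, refusal above 1e5) follow
directly. The toy generator emits complementary pairs of at most 14 nt
whose feasible-pair count respects the bound, optionally with an embedded
2-3 bp stem. Every stochastic stage of the package is validated against
this oracle in the test suite.

## Equilibrium sampling

Metropolis Monte Carlo over single-pair add/remove moves plus
helix-toggle moves (adding or removing a whole maximal complementary run
at once). The toggle moves are needed because, once lonely pairs carry an
enthalpy, stem formation through a lonely intermediate is an activated
event and the pure single-pair chain decorrelates far too slowly for
equilibrium work; proposals are drawn uniformly from the fixed combined
move list, so detailed balance is preserved. The kinetic simulations use
single-pair moves only (cooperative moves would not be physical dynamics).

Umbrella windows restrict the order parameter. Bias weights are learned
adaptively and then frozen for production, so the production chain
satisfies detailed balance exactly and any imperfection in the learned
bias costs variance, never correctness. Two learning schedules are used:
Wang-Landau-style additive updates, which are aggressive enough to push
the chain over the ~13-15 kBT in-box association barrier, followed (or for
single strands, replaced) by multicanonical-recursion stages that sample
with fixed weights and flatten against the stage histogram, whose update
noise shrinks with stage length. Learned biases are capped 16 kBT above
the relevant floor so the chain is not wasted on bins that are censored in
the output anyway, and duplex windows are warm-started from an analytic
zippering profile and from the previous window's weights.

Duplex landscapes tile n_inter with nested windows anchored at zero for
small systems (every window stays ergodic through the unbound state) and
with a staircase of width-3 windows for the 25-mers; windows that fail to
cover their overlap columns are retried with a fresh, longer pre-pass.
Window histograms are unbiased, stitched by inverse-variance least squares
on shared bins, and referenced to the (0, 0) bin. Standard errors combine
independent production replicas (started from decorrelated
configurations), the stitch-offset covariance, and the observed
cross-window mismatch as an empirical error floor. Bins with dG more than
10 kBT above the reference, or with no samples, are reported censored.

Two refinements matter for hairpin-rich systems:

- For the 25-mers the fully unpaired bin can be a rarely visited corner of
  the unbound basin, so the stitched landscape is anchored to the
  best-sampled unbound bin and then shifted onto the (0, 0) reference
  using the exact strand-independence of the n_inter = 0 column (the
  combined intra-count distribution is the convolution of the two
  single-strand ensembles, each sampled with the fast single-strand
  machinery).
- dG0/Keq for the 25-mers uses a bound-anchor factorization,
  dG0 = G_full + ln p_full + ln z_P + ln z_T: the full duplex's
  standard-state free energy G_full is a closed-form sum of stack and
  initiation terms, its conditional occupancy p_full within the bound
  basin comes from a short unbiased run confined to n_inter >= 15 (states
  below that floor sit tens of kBT above the duplex and contribute
  negligibly to Keq), and the z are the single-strand configurational
  partition functions from umbrella runs. This estimator involves no
  window ladder at all and reproduces to a few tenths of kBT across
  seeds, whereas a stitched ladder across the full n_inter range
  accumulates a random-walk drift of several kBT at desk-scale budgets
  (that drift is propagated into the ladder landscapes' errors as a
  per-hop term). The direct landscape route (`duplex_dg0_keq`) is
  validated against exact enumeration on toys.

Melting curves sample anchors every 10 C and reweight each scan
temperature from the nearest anchor (trust range 5 C, effective-sample-size
diagnostic, low-ESS flag); Tm is linearly interpolated at yield 0.5 on a
2 C scan grid. A state counts as a hairpin if it has at least one
intra-strand pair.

## Kinetics

Dynamics is a continuous-time Markov chain with Metropolis rates
k0 min(1, e^{-dG}) per single-pair move; k0 = 1 defines the reduced time
unit, and only relative rates are reported. Because in-box energies
already include the initiation and box terms, detailed balance against
the sampled landscapes holds edge-exactly by construction. The simulator
uses the uniformized formulation (uniform proposals over the fixed move
list, exponential waiting times at the total proposal rate), which
realizes exactly the same process law as a direct per-move Gillespie
simulation.

Hybridization rates use direct FFS with interfaces on n_inter (default
{1, 2, 4, 6, 9, 12, 16, 20, 25}): the basin A is every state with no
inter-strand pair, B is the full duplex. The flux through the first
interface is computed as the basin-equilibrium average of the
instantaneous association propensity, and first-contact configurations
are banked with probability proportional to their rate — the exact
flux-weighted ensemble, without waiting out the ~e^13 uphill association
in brute-force dynamics. Each later interface's crossing probability
comes from shooting continuations (round-robin over the banked ensemble,
so success attribution is the mean outcome over each configuration's
continuations); k+ = flux x prod(p_i) = r+ x P+ holds exactly. Melting
rates on toys use the same machinery run in the dissociation direction.

Under the physical single-pair dynamics, opening an intact stem takes of
order e^(barrier) steps, so shooting trials that reach a hairpin-blocked
partial duplex can be metastable on time scales far beyond any affordable
step budget. Trials unresolved within the per-trial step cap are reported
as truncated and *excluded* from the conditional-probability estimates
(censoring). This is an approximation — the censored trajectories are
precisely the blocked ones, so the estimated crossing probabilities
describe the resolved (unblocked or quickly-opening) lineages — and the
censored fraction is always reported alongside the rates. Counting the
blocked trials as failures instead would be strictly worse: it would
misread metastability as dissociation.

Attachment statistics resolve the banked first-contact ensemble by
P-strand site and register (aligned iff i_P + i_T = N - 1); per-site
success multiplies the site's conditional crossing probabilities across
stages. Pathway records carry the intact-stem flags at association (both
the all-stem-pairs-present headline criterion and the >= 1-pair variant),
four-way-junction and kissing flags evaluated at interface crossings, and
KMC time stamps. By microscopic reversibility the same records read in
reverse describe the melting ensemble, which is how the package explains
melting acceleration without simulating melting of the 25-mers.

## Problem sizes and reproducibility

Desk-scale defaults (the `default_config()` budgets) run the three
experimental systems end to end in roughly ten minutes: ~60k production
steps per umbrella window and per melting-curve anchor, 350 FFS trials
per interface, 600 basin samples. Toy validations in the test suite use
larger budgets (up to 1e6 steps) because exactness is being asserted
there. All randomness flows through explicit integer seeds; stage seeds
derive deterministically from the master seed, and a rerun with the same
configuration reproduces every number exactly.

## What the synthetic data does and does not emulate

The generator reproduces the study design: complementary 25-mer pairs
whose probes carry one designed self-complementary stem of configurable
length/loop/tail geometry, screened against unintended complementary
runs of 3+ pairs, plus exactly solvable toys. It does not emulate
sequence chemistry beyond Watson-Crick pairing (no mismatches, wobbles,
salt dependence or modified bases), and the energy model omits coaxial
stacking across nicks, dangling ends and 3D geometry. Passing tests
therefore demonstrate the internal correctness of the sampling and rate
machinery and the qualitative hairpin physics, not force-field-level
agreement with experiment.
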
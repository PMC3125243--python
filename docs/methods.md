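# Methods

`netcomm` is an individual-based simulator of two competing species in a
three-patch landscape, in which each individual's single quantitative trait
is produced by a heritable Boolean gene network. This note describes the
model, its parameters and defaults, the numerical choices made where the
design was genuinely open, and what the simulator's behavior under its
default conditions does and does not show.

## The gene-network genotype–phenotype map

An individual's genome is one chromosome encoding a directed Boolean
network of *n* genes. Every gene except the basal-most (gene 0) has exactly
one upstream regulator ("head"); construction attaches each new gene to a
previously added gene, so `heads[i] < i` and the network is a rooted tree.
Topology is built either by uniform attachment (*random*) or by a lottery
rule in which an existing gene acquires the new downstream edge with
probability proportional to its current out-degree plus one (*scale-free*).
The +1 keeps zero-degree genes eligible for a first edge; without it,
attachment would freeze on the first edge drawn. Random attachment yields
an approximately Poisson out-degree distribution; the lottery rule yields
heavy-tailed, hub-dominated distributions.

Gene states are binary. Gene 0 carries a heritable `root_state` bit fixed
at the founding of a lineage; every other gene is *on* exactly when its
head's state equals its function bit (activator = 1, repressor = 0) — an
XNOR. Because the network is a tree, one pass from the root resolves all
states; no attractor iteration is needed or modeled.

The trait is the count *S* of terminal genes (out-degree 0) in the on
state, rescaled to the environmental range: `z = (env_max / T) · S` with
`env_max = 140` by default. Networks of any size can reach any part of the
range, but a network with *T* terminals can express at most *T* + 1 distinct
values — small networks are coarse, large networks fine-grained. This
resolution difference, together with the size-dependence of transmission
fidelity under recombination (below), is the entire genetic basis of
between-species differences in the model.

## Reproduction, recombination, mutation

Individuals are hermaphrodites mating at random within species and patch.
Each resident seeds one mating with a uniformly drawn distinct conspecific
partner (partners may be re-used; selfing is not allowed) and produces a
Poisson(λ) brood, λ = 1.5. Seeding per capita rather than by disjoint
pairing keeps the per-capita growth factor at λ (disjoint pairs would give
λ/2 < 1, which no population could survive). A lone resident produces
nothing and its line ends when parents are killed.

The offspring chromosome is built element-wise over the *n* gene blocks:
copying starts from a randomly chosen parent and switches to the other
parent at each block boundary independently with probability *r* (the
recombination rate). The root-state bit follows the parent contributing
the first block. The probability that an offspring is an exact copy of one
parent is therefore `(1 − r)^(n−1)`: about 0.46 for *n* = 16 at *r* = 0.05
but ~2·10⁻⁶ for *n* = 256. Between unrelated genomes, a recombinant mosaic
has an essentially random phenotype, so *parent–offspring resemblance at
the trait level declines steeply with network size* — the mechanistic core
of the size/heritability relationship the simulator expresses.

Mutation tests each of the 2(n−1) mutable elements (head and function of
every non-basal gene) against rate μ. A hit function bit flips; a hit head
entry is resampled uniformly among the *other* earlier genes, which always
changes the topology and preserves the single-input tree. Gene 1 is the
one exception: its only legal head is gene 0, so a hit there cannot
realize a change. Root state is not mutable.

## Selection, death, and resources

Viability selection is Gaussian and individual-absolute:
`RF = exp(−Δ²/(2ω²))` where Δ is the distance between the individual's
trait and its patch's resource quality, and ω (default 2) sets the breadth.
Each offspring survives independently with probability RF. Death happens in
three stages per generation: parents die (non-overlapping generations),
offspring face the viability test, and a per-patch carrying capacity
K = 200 is enforced on the *joint* census of both species by uniform random
removal down to exactly K. The capacity stage is neutral with respect to
species and fitness; competition acts purely through the viability stage.

Each patch's resource quality starts at 70 and moves at a configured rate
(defaults 1e−3, 2.5e−4 and 1e−4 units per generation across the three
patches), reflecting off the [0, env_max] boundaries. Direction is
configurable (`increase` default, `decrease`, or `random_walk` with step =
rate). Landscape heterogeneity is the number of unique patch rates (1–3).

## Landscape and dispersal

Three circular patches (radius 10 by default) sit at the vertices of an
equilateral triangle with 50 units between patch edges (center spacing 70).
After a canalization phase of 20 generations with no movement, each
survivor disperses with its species' probability *d*: it departs from a
uniform-random point in its patch, flies a uniform distance in [0, 100] at
a uniform angle, and survives only if it lands inside some patch (closed
disc). With the default geometry most flights end in the matrix and die, so
colonization is possible but costly: among movers from one patch, roughly
1–2% land in each other patch.

## Scheduling, runs, and experiments

Stage order per generation: resource update → reproduction → parent death →
viability cull → dispersal (post-canalization) → capacity cull → census.
Dispersal sits between the viability and capacity stages so that colonists
face the shared K immediately on arrival. A run founds each species with
100 random genomes in its own patch (the third patch empty), steps at most
750 generations, and stops early at the first region-wide extinction of a
founded species. All randomness flows from one integer seed; identical
seeds replay bit-identically. Per-run seeds in experiments derive from
`SeedSequence([master_seed, cell_index, replicate])`.

The experiment driver expands arbitrary factor grids (competitor
architecture and dispersal, focal dispersal, landscape rate assignment)
into a full crossing with replicates, and summarizes each run by
coexistence, persistence time, maximum regional census, and the
trait–environment mismatch. The single-species metapopulation arm runs the
focal species alone over a configurable set of landscape arrangements;
the default set of seven comprises the three homogeneous landscapes, one
two-rate arrangement per rate pair, and the all-different arrangement.

## Measured quantities

* **Heritability** h² is the OLS slope of offspring trait on mid-parent
  trait, computed per species per generation on the post-viability,
  pre-dispersal cohort; additive variance is h² times the phenotypic
  variance. Degenerate cohorts (fewer than 3 pairs, or zero mid-parent
  variance, as happens when a small-network population canalizes exactly
  onto the optimum) report NaN rather than a clipped value.
* **Coexistence** means both founded species have positive regional census
  at the 750-generation horizon; **persistence time** is the generation of
  the first regional extinction, capped at the horizon.
* **Critical population size** is 0.9 × the maximum regional census over a
  set of runs; the **time-to** and **proportion-above** metrics are
  computed over each run's recorded generations (runs end at extinction, so
  early-extinction runs are scored over their realized length).
* **Mismatch** is the census-weighted mean of |patch mean trait − patch
  resource quality| over species, patches and post-canalization
  generations.
* `fit_summary_models` fits the standard cross-run models — binomial-logit
  GLM of coexistence and OLS of persistence — reporting sequential (Type I)
  deviance or percent-variance per factor via nested statsmodels fits.

## Behavior under the default conditions, and its limits

The defaults are deliberately the canonical study conditions: ω = 2,
λ = 1.5, K = 200, trait range [0, 140], founding census 100, rates
{1e−3, 2.5e−4, 1e−4} units/generation. Two consequences of this parameter
set are worth stating plainly, because they bound what the simulator's
default-condition output shows:

1. **Founding is a severe bottleneck that filters by network size.** A
   founding cohort's phenotypic SD is ≈ 70/√T (22, 10.5 and 5.3 units for
   n = 16, 64, 256), far wider than ω = 2, so mean founding survival is
   0.11–0.36 and early per-capita growth is below 1. Populations crash to
   a handful of individuals and either homogenize by drift and rescue, or
   die. Coarse-resolution 16-gene networks rescue reliably (survivors sit
   exactly on the optimum); 64- and 256-gene networks usually do not
   (measured establishment ≈ 7–13% over 30 seeds). Community outcomes
   involving large-network competitors are therefore dominated by
   establishment failure rather than by post-establishment adaptation.
2. **The environment is nearly static on the run timescale.** At the
   default rates the optimum moves at most 0.75 units per 750-generation
   run and patches diverge by < 1 unit, so sustained adaptation is rarely
   required and migrant swamping carries almost no fitness differential.
   Dispersal consequently acts mainly through mover mortality, not through
   maladaptive gene flow.

Sensitivity runs during development showed that a uniform ×10 rescaling of
the selection breadth and resource rates (ω = 20, rates ×10) removes both
effects — every network size establishes, heritability is 0.75–0.86 and
declines with network size, and optima move enough to require tracking —
at the cost of making within-horizon competitive exclusion rare. The
package keeps the canonical values as defaults and exposes ω, the rates,
and the drift mode in the configuration so users can explore either
regime.

## What the tests show (and don't)

All inputs are self-generated; there is no external data. The test suite
checks the operators against closed-form expectations (Poisson brood
sizes, Bernoulli switch counts, binomial mutation counts, planted
regression slopes, hypergeometric capacity sampling), structural
invariants (tree genomes under arbitrary mutation, carrying-capacity
bounds, determinism, absorbing extinctions), and — at reduced replication —
the community-level directional contrasts. Because the synthetic study
conditions are the canonical defaults above, the community-level results
inherit their limits: they characterize this parameter regime, not any
empirical system, and the two default-condition pathologies described in
the previous section are visible in the community-level test outcomes
(establishment failure of large networks dominates persistence variance,
and the dispersal axis alone does not separate coexistence frequencies).
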
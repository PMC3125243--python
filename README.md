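# netcomm

Individual-based simulation of two competing species in a three-patch
metacommunity, where each species' limiting quantitative trait is encoded
by a heritable single-input Boolean gene network. The package is for
theoretical ecologists and evolutionary biologists studying how the
genetic architecture of a trait (network size and topology, mutation and
recombination rates) trades off against dispersal ability in determining
coexistence, persistence, and regional population size.

## The model

Each individual carries one chromosome describing a rooted tree of *n*
genes: every gene except the basal-most has exactly one upstream regulator
("head") and a function bit (activator/repressor). States are binary and
resolved in one pass from the heritable root state: a gene is *on* iff its
head's state equals its function bit (XNOR). The trait is

> z = (env_max / T) · S,

where *T* is the number of terminal genes (out-degree 0) and *S* how many
of them are on, with env_max = 140 — so a network with *T* terminals
expresses at most *T* + 1 distinct trait values, making small networks
coarse and large ones fine-grained.

Individuals mate at random within species and patch, produce Poisson(λ)
broods (λ = 1.5), recombine chromosomes by a per-element Markov switching
rule at rate *r*, and mutate heads and function bits at rate μ per
element. Generations do not overlap; offspring survive viability selection

> RF = exp(−Δ² / (2ω²)), ω = 2,

against their patch's evolving resource quality Δ away from their trait,
and a joint carrying capacity K = 200 per patch is enforced by uniform
random removal. Three circular patches sit 50 units apart edge-to-edge;
after 20 canalization generations individuals disperse with species-
specific probability *d*, flying 0–100 units at a random angle and dying
in the matrix if they miss every patch. Runs last 750 generations or until
a species is extinct region-wide. See `docs/methods.md` for the full
model description, parameter table, and known limitations of the default
parameter regime.

## Worked example

```python
import numpy as np
from netcomm import *
from netcomm.metrics_analysis import persistence_time, mismatch

# a 13-gene network: genes 0-4 internal, genes 5-12 terminal
g = Genome(heads=[-1, 0, 1, 2, 3, 0, 0, 0, 1, 1, 2, 3, 4],
           functions=[0, 1, 1, 1, 1, 1, 0, 1, 0, 1, 0, 1, 0],
           root_state=1)
states = evaluate_states(g)
deg = out_degree_distribution(g)
print("terminals:", int((deg == 0).sum()), " on:", int(states[deg == 0].sum()))
print("phenotype:", phenotype(g, env_max=140.0))

cfg = SimConfig()                                   # canonical defaults
focal = SpeciesParams(name="focal", start_patch=0, d=0.05)
competitor = SpeciesParams(name="competitor", start_patch=1, d=0.05, n=16)
rec = run_simulation(cfg, focal, competitor, seed=42)
print("generations run:", rec.generations_run)
print("coexistence:", rec.coexistence)
print("persistence time:", persistence_time(rec))
print("final regional census:",
      int(rec.regional_census("focal").iloc[-1]),
      int(rec.regional_census("competitor").iloc[-1]))
print("trait-environment mismatch: %.3f" % mismatch(rec))
```

prints

```
terminals: 8  on: 4
phenotype: 70.0
generations run: 750
coexistence: True
persistence time: 750
final regional census: 219 381
trait-environment mismatch: 0.179
```

The 13-gene network has eight terminal genes of which four are on, so its
trait value is (140/8)·4 = 70 — exactly the shared initial resource
quality. The two 16-gene species then coexist for the full 750
generations, ending with 219 and 381 individuals region-wide (the joint
regional cap is 3K = 600), and the census-weighted gap between mean trait
and local optimum averages 0.18 trait units — both populations track
their patches closely.

The same machinery is available from the shell:

```sh
netcomm run --seed 42 --competitor-n 16 --out results/run42
netcomm experiment --config examples/metacommunity.yaml
netcomm metapop --replicates 3 --master-seed 1 --out results/metapop
```

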
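# osteoasr

Bayesian inference of mammalian middle-ear character evolution: partitioned
Mkv+gamma phylogenetics, ancestral-state posterior probabilities, parsimony
loss/regain mapping, and a voxel taphonomy simulator.

## The problem

The mammalian middle ear bones began as load-bearing jaw elements. Their
detachment left two traceable osteological characters on fossil dentaries:
the **postdentary trough** (houses the still-attached ear precursors; its
absence marks detachment) and **Meckel's groove** (holds Meckel's
cartilage; its loss marks the final ear–jaw separation). Parsimony mappings
of these characters across Mesozoic mammal phylogenies allow up to seven
independent trough losses — or regains of a lost middle-ear attachment —
depending on coding and topology. `osteoasr` is a toolkit for asking the
question probabilistically instead: under a model of discrete character
evolution, what is the posterior probability that a given ancestor (the
ancestor of mammals, of australosphenidans, of crown monotremes, …) still
carried a postdentary trough or a developed Meckel's groove?

It is aimed at morphological phylogeneticists who have a discrete character
matrix in NEXUS format and want, end to end:

* character **re-scoring** rules applied reproducibly (state collapses and
  per-fossil overrides, with provenance logged),
* taxon filtering by **completeness** (strict `< 12.5%` exclusion, with
  uncertainty sets counting as scored),
* **Bayesian inference** under the Mkv + discrete-gamma model with
  anatomical partitions, monophyly constraints, and two independent
  Metropolis-coupled runs,
* **BPP tables** at MRCA-defined ancestors, integrating over the posterior
  sample of trees and parameters,
* **parsimony loss/regain counts** on any fixed tree under symmetric,
  asymmetric and Dollo cost regimes, and
* a **3D erosion simulator** showing how diagenetic attrition of a dentary
  with a subsurface mandibular canal fabricates an artifact "Meckel's
  groove" without damaging the rest of the anatomy.

## The model

Characters evolve under the k-state symmetric Markov model (Mk):
`p_same(t) = 1/k + (k−1)/k · e^{−kt/(k−1)}`, with stationary frequencies
1/k and branch lengths in expected changes. The Mkv variant conditions
each character on being variable — the ascertainment correction for
morphological matrices. Multi-character partitions get discrete-gamma rate
heterogeneity (4 equal-probability categories, category means); each
partition has a free rate multiplier, normalised to weighted mean 1. The
posterior over rooted topologies (uniform prior, optional constraints),
exponential branch lengths and model parameters is sampled by
Metropolis-coupled MCMC; marginal ancestral states are computed per draw
at the MRCA of the query taxon set and averaged. Details, priors and all
defaults: [docs/methods.md](docs/methods.md).

## Worked example

Ancestral state of the trough above two trough-bearing taxa on a fixed
tree (half-branch lengths of 0.5 expected changes each):

```python
from osteoasr import Tree, marginal_asr
from osteoasr.matrix_io import CharacterMatrix

tree = Tree.from_newick("(Morganucodon:0.5,Hadrocodium:0.5);")
matrix = CharacterMatrix(
    taxa=["Hadrocodium", "Morganucodon"],
    states=[[frozenset({0})], [frozenset({0})]],   # 0 = trough present
    k=[2],
    character_labels=["postdentary_trough"],
    partition_of=["postdentary_trough"],
)
posterior = marginal_asr(tree, matrix, 0)
print(f"P(trough present at ancestor) = {posterior[0]:.4f}")
print(f"P(trough absent at ancestor)  = {posterior[1]:.4f}")
```

```
P(trough present at ancestor) = 0.8240
P(trough absent at ancestor)  = 0.1760
```

Both tips carry the trough, yet the ancestor is only ~82% likely to: with
0.5 expected changes per branch, parallel gain from a troughless ancestor
retains real probability. That gap between "parsimony says 0 changes" and
a calibrated posterior is the point of the package.

The full pipeline on the packaged synthetic study system — a 14-taxon tree
whose trough character was constructed with exactly two independent losses
(one per clade) and no regains, plus 90 simulated background characters:

```bash
osteoasr run --scenario two_loss --seed 1 -o out/
```

writes `consensus.nwk`, `bpp.tsv`, `parsimony.tsv`, MrBayes-style trace
files and a summary, and prints the BPP table: the root ancestor keeps the
trough with BPP ≈ 0.99, both post-loss clade ancestors lack it with BPP
< 0.06, and Dollo mapping on the consensus recovers exactly 2 losses and
0 regains. Reruns with the same seed reproduce every output byte for byte.

The erosion experiment from the command line:

```bash
$ osteoasr erode --layers 3
groove depth: 2.20 -> 11.86 voxels (5.4-fold) after 3 layers; buccal control RMS 0.24 voxels
```

A faint 2-voxel seam over the mandibular canal becomes a deep groove after
three layers of simulated attrition, while the control side of the bone
stays smooth to a quarter voxel — an artifact that would read as a genuine
Meckel's groove.

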
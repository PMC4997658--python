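"""Bayesian inference of topology, branch lengths and Mk model parameters.

Metropolis-coupled MCMC (one cold chain plus incrementally heated chains
per run, with state swaps) over rooted binary trees under the partitioned
Mkv+gamma likelihood, a uniform prior on (constraint-compatible) rooted
topologies, exponential priors on branch lengths, gamma shapes and raw
partition rates, and optional monophyly constraints enforced by rejection
(violating proposals have prior zero).

The user surface follows the model/results idiom:

>>> model = MkBayesModel(matrix, outgroup="Out")           # doctest: +SKIP
>>> results = model.fit(McmcConfig(n_generations=20000, seed=1))
>>> print(results.summary())
>>> table = results.ancestral_states([AncestorQuery(...)])

Proposals
---------
* NNI and rooted SPR topology moves (SPR reattaches uniformly along a
  uniformly chosen branch; the Hastings factor is the target/merged branch
  length ratio),
* branch-length, gamma-shape and partition-rate multiplier moves.

Two independent runs (distinct seeds derived from the master seed) allow
between-run convergence checks: potential-scale-style ESS per scalar
parameter and the mean absolute split-frequency deviation between runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .ancestral_states import AncestorQuery, BppTable, bpp
from .matrix_io import CharacterMatrix, PartitionScheme
from .mk_likelihood import MkParameters, PartitionLikelihood
from .trees import Node, Tree

__all__ = [
    "McmcConfig",
    "ConstraintSet",
    "PosteriorSample",
    "Sample",
    "MkBayesModel",
    "MkBayesResults",
    "run_mcmc",
    "ess",
    "clade_convergence",
    "consensus",
    "McmcError",
]


class McmcError(RuntimeError):
    pass


@dataclass
class McmcConfig:
    n_generations: int = 20_000
    sample_interval: int = 20
    n_runs: int = 2
    n_chains: int = 3
    heating: float = 0.1
    seed: int = 0
    burn_in: float = 0.25
    branch_prior_mean: float = 0.1
    alpha_prior_mean: float = 1.0
    likelihood_on: bool = True

    def validate(self) -> None:
        if self.n_generations % self.sample_interval:
            raise McmcError("n_generations must be a multiple of sample_interval")
        if self.n_chains < 1 or self.n_runs < 1:
            raise McmcError("need at least one chain and one run")
        if not 0 <= self.burn_in < 1:
            raise McmcError("burn_in must be in [0, 1)")


@dataclass(frozen=True)
class ConstraintSet:
    """Monophyly constraints.

    ``positive`` sets are required monophyletic.  A ``negative`` entry
    (clade_taxa, excluded) requires the clade *minus* the excluded taxon to
    be monophyletic — i.e. the group must exist without that taxon, forcing
    it outside.
    """

    positive: tuple[frozenset, ...] = ()
    negative: tuple[tuple[frozenset, str], ...] = ()

    @classmethod
    def make(cls, positive=(), negative=()) -> "ConstraintSet":
        return cls(
            positive=tuple(frozenset(s) for s in positive),
            negative=tuple((frozenset(s), t) for s, t in negative),
        )

    def required_clades(self) -> list[frozenset]:
        clades = [frozenset(s) for s in self.positive]
        for s, excl in self.negative:
            clades.append(frozenset(s) - {excl})
        return [c for c in clades if len(c) >= 2]

    def masks(self, taxon_index: dict[str, int]) -> list[int]:
        out = []
        for clade in self.required_clades():
            m = 0
            for t in clade:
                if t not in taxon_index:
                    raise McmcError(f"constraint taxon {t!r} not in matrix")
                m |= 1 << taxon_index[t]
            out.append(m)
        return out

    @property
    def empty(self) -> bool:
        return not self.required_clades()


@dataclass
class Sample:
    tree: Tree
    params: MkParameters
    log_likelihood: float
    log_prior: float
    generation: int


@dataclass
class PosteriorSample:
    """Retained draws of ``n_runs`` independent analyses."""

    runs: list[list[Sample]]
    config: McmcConfig
    taxa: list[str]

    def retained(self, run: int = 0, burn_in: "float | None" = None) -> list[Sample]:
        b = self.config.burn_in if burn_in is None else burn_in
        samples = self.runs[run]
        return samples[int(np.ceil(b * len(samples))):]

    def pooled(self, burn_in: "float | None" = None) -> list[Sample]:
        out: list[Sample] = []
        for r in range(len(self.runs)):
            out.extend(self.retained(r, burn_in))
        return out


# ----------------------------------------------------------- constraints


def satisfies(tree: Tree, constraint_masks: list[int], index: dict[str, int]) -> bool:
    if not constraint_masks:
        return True
    clades = set(tree.clade_masks(index).values())
    return all(m in clades for m in constraint_masks)


def build_constrained_tree(
    taxa: list[str],
    constraints: ConstraintSet,
    rng: np.random.Generator,
    branch_mean: float,
) -> Tree:
    """Random rooted binary starting tree satisfying all constraints.

    Required clades are grouped bottom-up (smallest first); failure to
    group reports the constraints as mutually unsatisfiable.
    """
    leaves = {t: Node(label=t) for t in taxa}
    root = Node()
    for t in sorted(taxa):
        root.add_child(leaves[t])

    for clade in sorted(constraints.required_clades(), key=len):
        missing = clade - set(taxa)
        if missing:
            raise McmcError(f"constraint names unknown taxa {sorted(missing)}")
        tipsets = {}
        for child in root.children:
            tips = frozenset(
                n.label for n in Tree(child).postorder() if n.is_tip
            )
            tipsets[child] = tips
        members = [c for c, ts in tipsets.items() if ts <= clade]
        covered = frozenset().union(*(tipsets[c] for c in members)) if members else frozenset()
        if covered != clade:
            raise McmcError(
                f"constraints unsatisfiable: cannot make {sorted(clade)} monophyletic"
            )
        group = Node()
        for c in members:
            c.detach()
            group.add_child(c)
        root.add_child(group)

    def resolve(node: Node) -> None:
        for child in list(node.children):
            resolve(child)
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            a.detach()
            b.detach()
            mid = Node()
            mid.add_child(a)
            mid.add_child(b)
            node.add_child(mid)

    resolve(root)
    tree = Tree(root)
    for n in tree.postorder():
        if n.parent is not None:
            n.length = float(rng.exponential(branch_mean)) + 1e-6
    return tree


# --------------------------------------------------------------- moves


def _nni(tree: Tree, rng: np.random.Generator) -> float:
    """Nearest-neighbour interchange around a random internal edge."""
    candidates = [
        n for n in tree.postorder() if not n.is_tip and n.parent is not None
    ]
    if not candidates:
        return -np.inf
    v = candidates[rng.integers(len(candidates))]
    p = v.parent
    sib = p.children[0] if p.children[1] is v else p.children[1]
    c = v.children[rng.integers(2)]
    ci, si = v.children.index(c), p.children.index(sib)
    v.children[ci], p.children[si] = sib, c
    sib.parent, c.parent = v, p
    return 0.0


def _spr(tree: Tree, rng: np.random.Generator) -> float:
    """Rooted subtree-prune-regraft; returns the log Hastings factor."""
    prunable = [
        n
        for n in tree.postorder()
        if n.parent is not None and n.parent.parent is not None
    ]
    if not prunable:
        return -np.inf
    v = prunable[rng.integers(len(prunable))]
    p = v.parent
    g = p.parent
    sib = p.children[0] if p.children[1] is v else p.children[1]
    merged = sib.length + p.length
    # detach v, splice sib into p's place
    gi = g.children.index(p)
    sib.length = merged
    sib.parent = g
    g.children[gi] = sib
    v.parent = None

    targets = [n for n in tree.postorder() if n.parent is not None]
    e = targets[rng.integers(len(targets))]
    u = rng.random()
    parent = e.parent
    ei = parent.children.index(e)
    mid = Node(length=u * e.length)
    log_hastings = float(np.log(e.length) - np.log(merged))
    e.length = (1.0 - u) * e.length
    mid.parent = parent
    parent.children[ei] = mid
    mid.children = [e, v]
    e.parent = mid
    v.parent = mid
    return log_hastings


def _multiplier(x: float, rng: np.random.Generator, lam: float = 2.0) -> tuple[float, float]:
    f = float(np.exp(lam * (rng.random() - 0.5)))
    return x * f, float(np.log(f))


# ---------------------------------------------------------------- chains


class _Chain:
    """One (possibly heated) chain state."""

    def __init__(self, tree: Tree, params: MkParameters, beta: float):
        self.tree = tree
        self.params = params
        self.beta = beta
        self.log_likelihood = 0.0
        self.log_prior = 0.0

    @property
    def score(self) -> float:
        return self.log_likelihood + self.log_prior


class _Sampler:
    def __init__(
        self,
        matrix: CharacterMatrix,
        scheme: PartitionScheme,
        config: McmcConfig,
        constraints: ConstraintSet,
        params0: MkParameters,
        rng: np.random.Generator,
    ):
        self.matrix = matrix
        self.scheme = scheme
        self.config = config
        self.constraints = constraints
        self.rng = rng
        self.index = {t: i for i, t in enumerate(sorted(matrix.taxa))}
        self.constraint_masks = constraints.masks(self.index)
        self.engine = (
            PartitionLikelihood(matrix, scheme) if config.likelihood_on else None
        )
        self.alpha_parts = sorted(params0.alpha)
        self.rate_parts = sorted(scheme.partitions)
        self.params0 = params0

        weights = {"nni": 0.25, "spr": 0.15, "brlen": 0.35}
        if self.alpha_parts:
            weights["alpha"] = 0.10
        if len(self.rate_parts) > 1:
            weights["rate"] = 0.15
        total = sum(weights.values())
        self.move_names = sorted(weights)
        self.move_probs = np.array([weights[m] / total for m in self.move_names])

    # ---- densities

    def log_prior(self, tree: Tree, params: MkParameters) -> float:
        mean = self.config.branch_prior_mean
        lp = 0.0
        n_branch = 0
        for n in tree.postorder():
            if n.parent is not None:
                if n.length <= 0:
                    return -np.inf
                lp -= n.length / mean
                n_branch += 1
        lp -= n_branch * np.log(mean)
        am = self.config.alpha_prior_mean
        for a in params.alpha.values():
            if a <= 0:
                return -np.inf
            lp += -a / am - np.log(am)
        for v in params.partition_rate.values():
            if v <= 0:
                return -np.inf
            lp += -v
        if not satisfies(tree, self.constraint_masks, self.index):
            return -np.inf
        return lp

    def log_likelihood(self, tree: Tree, params: MkParameters) -> float:
        if self.engine is None:
            return 0.0
        return self.engine.log_likelihood(tree, params)

    # ---- one proposal on a chain

    def step(self, chain: _Chain) -> None:
        move = self.move_names[
            self.rng.choice(len(self.move_names), p=self.move_probs)
        ]
        tree = chain.tree
        params = chain.params
        new_params = params
        if move in ("nni", "spr"):
            tree = tree.copy()
            log_h = _nni(tree, self.rng) if move == "nni" else _spr(tree, self.rng)
        elif move == "brlen":
            tree = tree.copy()
            branches = [n for n in tree.postorder() if n.parent is not None]
            b = branches[self.rng.integers(len(branches))]
            b.length, log_h = _multiplier(b.length, self.rng)
        elif move == "alpha":
            new_params = params.copy()
            p = self.alpha_parts[self.rng.integers(len(self.alpha_parts))]
            new_params.alpha[p], log_h = _multiplier(params.alpha[p], self.rng)
        else:  # rate
            new_params = params.copy()
            p = self.rate_parts[self.rng.integers(len(self.rate_parts))]
            new_params.partition_rate[p], log_h = _multiplier(
                params.partition_rate[p], self.rng
            )
        if not np.isfinite(log_h):
            return
        new_prior = self.log_prior(tree, new_params)
        if not np.isfinite(new_prior):
            return
        new_like = (
            chain.log_likelihood
            if (move in ("alpha", "rate") and self.engine is None)
            else self.log_likelihood(tree, new_params)
        )
        delta = (new_like + new_prior) - chain.score
        if np.log(self.rng.random()) < chain.beta * delta + log_h:
            chain.tree = tree
            chain.params = new_params
            chain.log_likelihood = new_like
            chain.log_prior = new_prior

    # ---- one full run

    def run(self) -> list[Sample]:
        cfg = self.config
        chains = []
        for j in range(cfg.n_chains):
            tree = build_constrained_tree(
                self.matrix.taxa, self.constraints, self.rng, cfg.branch_prior_mean
            )
            params = self.params0.copy()
            beta = 1.0 / (1.0 + cfg.heating * j)
            ch = _Chain(tree, params, beta)
            ch.log_prior = self.log_prior(tree, params)
            if not np.isfinite(ch.log_prior):
                raise McmcError("starting tree violates constraints")
            ch.log_likelihood = self.log_likelihood(tree, params)
            chains.append(ch)

        samples: list[Sample] = []
        for gen in range(1, cfg.n_generations + 1):
            for ch in chains:
                self.step(ch)
            if len(chains) > 1:
                j = int(self.rng.integers(len(chains) - 1))
                a, b = chains[j], chains[j + 1]
                log_r = (a.beta - b.beta) * (b.score - a.score)
                if np.log(self.rng.random()) < log_r:
                    a.beta, b.beta = b.beta, a.beta
                    chains[j], chains[j + 1] = b, a
            if gen % cfg.sample_interval == 0:
                cold = chains[0]
                samples.append(
                    Sample(
                        tree=cold.tree.copy(),
                        params=cold.params.copy(),
                        log_likelihood=cold.log_likelihood,
                        log_prior=cold.log_prior,
                        generation=gen,
                    )
                )
        return samples


def run_mcmc(
    matrix: CharacterMatrix,
    scheme: "PartitionScheme | None" = None,
    config: "McmcConfig | None" = None,
    constraints: "ConstraintSet | None" = None,
    params0: "MkParameters | None" = None,
) -> PosteriorSample:
    """Run ``config.n_runs`` independent Metropolis-coupled analyses."""
    if matrix.n_taxa < 4:
        raise McmcError("need at least 4 taxa")
    scheme = scheme or matrix.partition_scheme()
    config = config or McmcConfig()
    config.validate()
    constraints = constraints or ConstraintSet()
    params0 = params0 or _default_params(matrix, scheme)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    runs = []
    for r in range(config.n_runs):
        rng = np.random.default_rng(seeds[r])
        sampler = _Sampler(matrix, scheme, config, constraints, params0, rng)
        runs.append(sampler.run())
    return PosteriorSample(runs=runs, config=config, taxa=list(matrix.taxa))


def _default_params(matrix: CharacterMatrix, scheme: PartitionScheme) -> MkParameters:
    """Mkv everywhere; gamma (alpha free) on multi-character partitions."""
    alpha = {
        name: 1.0
        for name, chars in scheme.partitions.items()
        if len(chars) > 1
    }
    return MkParameters(
        alpha=alpha,
        n_cat=4,
        partition_rate={name: 1.0 for name in scheme.partitions},
        ascertainment={name: "variable" for name in scheme.partitions},
    )


# ------------------------------------------------------------ diagnostics


def ess(trace: "np.ndarray | list[float]") -> float:
    """Effective sample size via the initial positive sequence estimator."""
    x = np.asarray(trace, float)
    n = len(x)
    if n < 10:
        raise McmcError("need at least 10 samples for an ESS")
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var == 0:
        return float(n)  # constant trace: degenerate, no autocorrelation
    # autocovariances via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    # sum paired autocorrelations while the pair sums stay positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(n / max(tau, 1.0 / n))


def clade_convergence(
    run_a: "list[Sample] | list[Tree]",
    run_b: "list[Sample] | list[Tree]",
) -> float:
    """Mean absolute split-frequency deviation between two runs."""

    def freqs(samples) -> dict[int, float]:
        counts: dict[int, int] = {}
        n = 0
        index = None
        for s in samples:
            tree = s.tree if isinstance(s, Sample) else s
            index = index or tree.taxon_index()
            for split in tree.splits(index):
                counts[split] = counts.get(split, 0) + 1
            n += 1
        if n == 0:
            raise McmcError("no post-burn-in samples")
        return {k: v / n for k, v in counts.items()}

    fa, fb = freqs(run_a), freqs(run_b)
    keys = set(fa) | set(fb)
    if not keys:
        return 0.0
    return float(np.mean([abs(fa.get(k, 0.0) - fb.get(k, 0.0)) for k in keys]))


def consensus(samples: "list[Sample] | list[Tree]", min_freq: float = 0.5) -> Tree:
    """Majority-rule consensus with clade posterior annotations.

    Internal node labels carry the clade's posterior frequency; branch
    lengths are the mean lengths of the clade's subtending edge over the
    samples containing that clade.
    """
    trees = [s.tree if isinstance(s, Sample) else s for s in samples]
    if not trees:
        raise McmcError("empty retained sample")
    index = trees[0].taxon_index()
    n_tax = len(index)
    counts: dict[int, int] = {}
    lengths: dict[int, float] = {}
    for tree in trees:
        masks = tree.clade_masks(index)
        for node, m in masks.items():
            if node.parent is None:
                continue
            counts[m] = counts.get(m, 0) + 1
            lengths[m] = lengths.get(m, 0.0) + node.length
    n = len(trees)
    full = (1 << n_tax) - 1
    majority = {
        m: c / n
        for m, c in counts.items()
        if c / n > min_freq and bin(m).count("1") >= 2
    }

    labels = {i: lab for lab, i in index.items()}
    nodes: dict[int, Node] = {}
    for lab, i in index.items():
        m = 1 << i
        node = Node(label=lab)
        if m in counts:
            node.length = lengths[m] / counts[m]
        nodes[m] = node
    root = Node(label="1.000")
    nodes[full] = root
    ordered = sorted(majority, key=lambda m: bin(m).count("1"), reverse=True)
    for m in ordered:
        if m == full:
            root.label = f"{majority[m]:.3f}"
            continue
        node = Node(label=f"{majority[m]:.3f}")
        node.length = lengths[m] / counts[m]
        nodes[m] = node
    # attach each node under the smallest strict superset present
    members = sorted(nodes, key=lambda m: bin(m).count("1"))
    for m in members:
        if m == full:
            continue
        best = None
        for cand in nodes:
            if cand != m and (cand & m) == m:
                if best is None or bin(cand).count("1") < bin(best).count("1"):
                    best = cand
        nodes[best].add_child(nodes[m])
    return Tree(root)


# ------------------------------------------------------- model / results


class MkBayesModel:
    """Partitioned Mkv+gamma Bayesian phylogenetic model of a matrix.

    Parameters
    ----------
    matrix : CharacterMatrix
    scheme : PartitionScheme, optional
        Defaults to the matrix's own partition labels.
    constraints : ConstraintSet, optional
    outgroup : str, optional
        Root anchor: adds a positive constraint that all other taxa form a
        clade, so sampled rootings are identifiable for ancestor queries.
    likelihood_on : bool
        Switch the likelihood off to sample from the prior (diagnostics).
    """

    def __init__(
        self,
        matrix: CharacterMatrix,
        scheme: "PartitionScheme | None" = None,
        constraints: "ConstraintSet | None" = None,
        outgroup: "str | None" = None,
        likelihood_on: bool = True,
    ):
        matrix.validate()
        self.matrix = matrix
        self.scheme = scheme or matrix.partition_scheme()
        constraints = constraints or ConstraintSet()
        if outgroup is not None:
            if outgroup not in matrix.taxa:
                raise McmcError(f"outgroup {outgroup!r} not in matrix")
            ingroup = frozenset(matrix.taxa) - {outgroup}
            constraints = ConstraintSet(
                positive=constraints.positive + (ingroup,),
                negative=constraints.negative,
            )
        self.constraints = constraints
        self.outgroup = outgroup
        self.likelihood_on = likelihood_on
        self.params0 = _default_params(matrix, self.scheme)

    def fit(self, config: "McmcConfig | None" = None, **kw) -> "MkBayesResults":
        config = replace(config or McmcConfig(), **kw) if kw else (config or McmcConfig())
        if not self.likelihood_on:
            config = replace(config, likelihood_on=False)
        posterior = run_mcmc(
            self.matrix, self.scheme, config, self.constraints, self.params0
        )
        return MkBayesResults(self, posterior)


class MkBayesResults:
    """Posterior sample plus diagnostics, summaries and reconstructions."""

    def __init__(self, model: MkBayesModel, posterior: PosteriorSample):
        self.model = model
        self.posterior = posterior
        self.config = posterior.config

    # ---- diagnostics

    def trace(self, name: str, run: int = 0, burn_in: "float | None" = None) -> np.ndarray:
        samples = self.posterior.retained(run, burn_in)
        if name == "log_likelihood":
            return np.array([s.log_likelihood for s in samples])
        if name == "log_posterior":
            return np.array([s.log_likelihood + s.log_prior for s in samples])
        if name == "tree_length":
            return np.array([s.tree.total_length() for s in samples])
        if name.startswith("alpha:"):
            p = name.split(":", 1)[1]
            return np.array([s.params.alpha[p] for s in samples])
        if name.startswith("rate:"):
            p = name.split(":", 1)[1]
            return np.array(
                [
                    s.params.normalized_rates(self.model.scheme)[p]
                    for s in samples
                ]
            )
        raise KeyError(name)

    def ess(self, name: str = "log_posterior", run: int = 0) -> float:
        return ess(self.trace(name, run))

    def min_ess(self, run: int = 0) -> float:
        names = ["log_posterior", "tree_length"]
        names += [f"alpha:{p}" for p in sorted(self.model.params0.alpha)]
        if len(self.model.scheme.partitions) > 1:
            names += [f"rate:{p}" for p in sorted(self.model.scheme.partitions)]
        return min(self.ess(n, run) for n in names)

    def asdsf(self, burn_in: "float | None" = None) -> float:
        if len(self.posterior.runs) < 2:
            raise McmcError("need two runs for a between-run diagnostic")
        return clade_convergence(
            self.posterior.retained(0, burn_in), self.posterior.retained(1, burn_in)
        )

    # ---- summaries

    def consensus(self, burn_in: "float | None" = None) -> Tree:
        return consensus(self.posterior.pooled(burn_in))

    def ancestral_states(
        self,
        queries: "list[AncestorQuery]",
        characters: tuple = (),
        burn_in: "float | None" = None,
        thin: int = 1,
    ) -> BppTable:
        draws = [
            (s.tree, s.params)
            for s in self.posterior.pooled(burn_in)[::max(thin, 1)]
        ]
        return bpp(draws, self.model.matrix, queries, default_characters=characters)

    def parameter_means(self) -> dict[str, float]:
        out: dict[str, float] = {}
        names = ["log_likelihood", "tree_length"]
        names += [f"alpha:{p}" for p in sorted(self.model.params0.alpha)]
        names += [f"rate:{p}" for p in sorted(self.model.scheme.partitions)]
        for n in names:
            vals = np.concatenate(
                [self.trace(n, r) for r in range(len(self.posterior.runs))]
            )
            out[n] = float(vals.mean())
        return out

    def summary(self) -> str:
        out = io.StringIO()
        cfg = self.config
        n_ret = len(self.posterior.retained(0))
        out.write("Mkv+gamma Bayesian inference\n")
        out.write("=" * 60 + "\n")
        out.write(
            f"taxa: {len(self.posterior.taxa)}   characters: {self.model.matrix.n_char}   "
            f"partitions: {len(self.model.scheme.partitions)}\n"
        )
        out.write(
            f"runs: {cfg.n_runs} x {cfg.n_chains} chains, "
            f"{cfg.n_generations} generations, sampled every {cfg.sample_interval}\n"
        )
        out.write(f"retained per run (after {cfg.burn_in:.0%} burn-in): {n_ret}\n\n")
        out.write(f"{'parameter':<28}{'mean':>12}{'ESS(run0)':>12}\n")
        for name, mean in self.parameter_means().items():
            try:
                e = f"{self.ess(name):.0f}"
            except Exception:
                e = "-"
            out.write(f"{name:<28}{mean:>12.4f}{e:>12}\n")
        if len(self.posterior.runs) >= 2:
            out.write(f"\nmean |split freq deviation| between runs: {self.asdsf():.4f}\n")
        return out.getvalue()

    # ---- trace files

    def write_traces(self, outdir, prefix: str = "osteoasr") -> None:
        """MrBayes-like .p/.t trace files, byte-stable for a given seed."""
        import os

        os.makedirs(outdir, exist_ok=True)
        alpha_names = sorted(self.model.params0.alpha)
        rate_names = sorted(self.model.scheme.partitions)
        for r, samples in enumerate(self.posterior.runs, start=1):
            with open(os.path.join(outdir, f"{prefix}.run{r}.p"), "w") as fh:
                cols = ["Gen", "LnL", "LnPr", "TL"]
                cols += [f"alpha_{p}" for p in alpha_names]
                cols += [f"m_{p}" for p in rate_names]
                fh.write("\t".join(cols) + "\n")
                for s in samples:
                    norm = s.params.normalized_rates(self.model.scheme)
                    row = [
                        str(s.generation),
                        f"{s.log_likelihood:.6f}",
                        f"{s.log_prior:.6f}",
                        f"{s.tree.total_length():.6f}",
                    ]
                    row += [f"{s.params.alpha[p]:.6f}" for p in alpha_names]
                    row += [f"{norm[p]:.6f}" for p in rate_names]
                    fh.write("\t".join(row) + "\n")
            with open(os.path.join(outdir, f"{prefix}.run{r}.t"), "w") as fh:
                for s in samples:
                    fh.write(f"{s.tree.to_newick(precision=8)}\n")
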
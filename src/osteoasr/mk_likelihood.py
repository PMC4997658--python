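"""Partitioned Mk/Mkv likelihood with discrete-gamma rate heterogeneity.

The Mk model (Lewis 2001) is the k-state symmetric continuous-time Markov
chain: all exchange rates equal, stationary frequencies 1/k, rate matrix
scaled so branch lengths are expected changes per character.  Its transition
probabilities have the closed form

    p_same(t) = 1/k + (k-1)/k * exp(-k t / (k-1))
    p_diff(t) = (1 - p_same(t)) / (k-1)

The Mkv variant conditions on a character being variable (the standard
ascertainment correction for morphological matrices, which never contain
constant characters): the likelihood is divided by one minus the summed
probability of the k constant patterns.

Likelihoods are computed by Felsenstein pruning, vectorised over characters
and gamma rate categories, with per-node rescaling so matrices with many taxa
do not underflow.  Missing tips contribute all-ones partials; uncertainty
sets contribute indicator partials over their codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .matrix_io import CharacterMatrix, PartitionScheme
from .trees import Node, Tree

__all__ = [
    "MkParameters",
    "transition_matrix",
    "gamma_category_rates",
    "character_likelihood",
    "mkv_correct",
    "total_log_likelihood",
    "PartitionLikelihood",
    "LikelihoodError",
]


class LikelihoodError(ValueError):
    pass


@dataclass
class MkParameters:
    """Model parameters shared across the likelihood and the samplers.

    alpha
        Gamma shape per partition; partitions absent from the dict get no
        rate heterogeneity (appropriate for single-character partitions,
        where among-character rate variation is meaningless).
    n_cat
        Number of equal-probability discrete gamma categories.
    partition_rate
        Raw positive rate multiplier per partition; the likelihood uses the
        normalised multipliers (weighted mean 1 over characters), so the
        overall rate stays confounded with branch lengths exactly once.
    ascertainment
        Per partition, "none" (Mk) or "variable" (Mkv conditioning).
    """

    alpha: dict[str, float] = field(default_factory=dict)
    n_cat: int = 4
    partition_rate: dict[str, float] = field(default_factory=dict)
    ascertainment: dict[str, str] = field(default_factory=dict)

    def rate_for(self, partition: str) -> float:
        return self.partition_rate.get(partition, 1.0)

    def normalized_rates(self, scheme: PartitionScheme) -> dict[str, float]:
        """Multipliers rescaled to weighted mean 1 (weights = char counts)."""
        names = list(scheme.partitions)
        counts = np.array([len(scheme.partitions[n]) for n in names], float)
        raw = np.array([self.rate_for(n) for n in names], float)
        if np.any(raw <= 0):
            raise LikelihoodError("partition rates must be positive")
        mean = float((counts * raw).sum() / counts.sum())
        return {n: float(r / mean) for n, r in zip(names, raw)}

    def copy(self) -> "MkParameters":
        return MkParameters(
            alpha=dict(self.alpha),
            n_cat=self.n_cat,
            partition_rate=dict(self.partition_rate),
            ascertainment=dict(self.ascertainment),
        )


def transition_matrix(k: int, t: float) -> np.ndarray:
    """Mk transition probabilities after branch length ``t``.

    ``t`` is in expected changes per character (total rate of the generator
    normalised to 1).
    """
    if k < 2:
        raise LikelihoodError("Mk model needs at least 2 states")
    if t < 0:
        raise LikelihoodError("branch length must be non-negative")
    e = np.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * e
    p_diff = (1.0 - p_same) / (k - 1)
    out = np.full((k, k), p_diff)
    np.fill_diagonal(out, p_same)
    return out


def _transition_matrices(k: int, ts: np.ndarray) -> np.ndarray:
    """Vectorised transition matrices, shape ``ts.shape + (k, k)``."""
    ts = np.asarray(ts, float)
    e = np.exp(-k * ts / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * e
    p_diff = (1.0 - p_same) / (k - 1)
    out = np.broadcast_to(p_diff[..., None, None], ts.shape + (k, k)).copy()
    idx = np.arange(k)
    out[..., idx, idx] = p_same[..., None]
    return out


def gamma_category_rates(alpha: float, n_cat: int) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability gamma(alpha, alpha) categories.

    The Yang (1994) discretisation: category boundaries are gamma quantiles,
    category rates are conditional means, so the mean rate is exactly 1.
    """
    if alpha <= 0:
        raise LikelihoodError("gamma shape must be positive")
    if n_cat < 1:
        raise LikelihoodError("need at least one rate category")
    if n_cat == 1:
        return np.ones(1)
    probs = np.arange(1, n_cat) / n_cat
    bounds = stats.gamma.ppf(probs, a=alpha, scale=1.0 / alpha)
    # conditional means via the incomplete-gamma identity:
    # E[X; X<b] for gamma(a, 1/a) = I(a+1, a*b) where I is the regularised
    # lower incomplete gamma function
    full = np.concatenate([[0.0], bounds * alpha, [np.inf]])
    cum = special.gammainc(alpha + 1.0, full)
    rates = n_cat * np.diff(cum)
    return rates / rates.mean() * 1.0  # exact mean 1 despite rounding


# ----------------------------------------------------------------- pruning


def _tip_partial(entry: "frozenset[int] | None", k: int) -> np.ndarray:
    if entry is None:
        return np.ones(k)
    v = np.zeros(k)
    v[sorted(entry)] = 1.0
    return v


def _prune(
    tree: Tree,
    tip_partials: dict[str, np.ndarray],
    k: int,
    rates: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Return (root partials over (n_cat, k), log scale factor).

    ``tip_partials`` maps tip label -> length-k indicator vector.
    """
    n_cat = len(rates)
    partials: dict[Node, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            try:
                base = tip_partials[node.label]
            except KeyError:
                raise LikelihoodError(f"tip {node.label!r} has no character data")
            partials[node] = np.broadcast_to(base, (n_cat, k)).copy()
            continue
        acc = np.ones((n_cat, k))
        for child in node.children:
            P = _transition_matrices(k, child.length * rates)  # (n_cat, k, k)
            acc *= np.einsum("ckl,cl->ck", P, partials.pop(child))
        m = acc.max()
        if m <= 0:
            return acc, -np.inf
        acc /= m
        log_scale += np.log(m)
        partials[node] = acc
    return partials[tree.root], log_scale


def character_likelihood(
    tree: Tree,
    matrix: CharacterMatrix,
    char_index: int,
    params: "MkParameters | None" = None,
    rate: float = 1.0,
    alpha: "float | None" = None,
) -> float:
    """Likelihood of one character, marginalised over gamma categories.

    ``rate`` multiplies all branch lengths (the partition multiplier);
    ``alpha`` switches on discrete-gamma averaging.  When ``params`` is
    given, the character's partition determines both.
    """
    params = params or MkParameters()
    k = matrix.k[char_index]
    if alpha is None and params.alpha:
        pname = matrix.partition_of[char_index]
        alpha = params.alpha.get(pname)
    if params.partition_rate:
        pname = matrix.partition_of[char_index]
        rate = rate * params.normalized_rates(matrix.partition_scheme())[pname]

    rates = (
        gamma_category_rates(alpha, params.n_cat) if alpha is not None else np.ones(1)
    ) * rate
    tip_partials = {}
    for i, tax in enumerate(matrix.taxa):
        tip_partials[tax] = _tip_partial(matrix.states[i][char_index], k)
    for lab in tree.tip_labels():
        if lab not in tip_partials:
            raise LikelihoodError(f"tip {lab!r} absent from matrix")
    root, log_scale = _prune(tree, tip_partials, k, rates)
    like = float(root.sum(axis=1).mean() / k)
    return like * np.exp(log_scale)


def constant_pattern_likelihoods(
    tree: Tree, k: int, rates: np.ndarray
) -> np.ndarray:
    """Likelihood of each of the k constant patterns (gamma-averaged)."""
    tips = tree.tip_labels()
    out = np.empty(k)
    for s in range(k):
        base = np.zeros(k)
        base[s] = 1.0
        root, log_scale = _prune(tree, {t: base for t in tips}, k, rates)
        out[s] = float(root.sum(axis=1).mean() / k) * np.exp(log_scale)
    return out


def mkv_correct(
    tree: Tree,
    params: "MkParameters | None",
    k: int,
    uncorrected: float,
    rate: float = 1.0,
    alpha: "float | None" = None,
) -> float:
    """Condition a character likelihood on the character being variable."""
    params = params or MkParameters()
    rates = (
        gamma_category_rates(alpha, params.n_cat) if alpha is not None else np.ones(1)
    ) * rate
    p_const = constant_pattern_likelihoods(tree, k, rates).sum()
    denom = 1.0 - p_const
    if denom <= 0:
        raise LikelihoodError(
            "degenerate tree: no probability mass on variable patterns "
            "(are all branch lengths zero?)"
        )
    return uncorrected / denom


def total_log_likelihood(
    tree: Tree,
    matrix: CharacterMatrix,
    scheme: "PartitionScheme | None" = None,
    params: "MkParameters | None" = None,
) -> float:
    """Summed log-likelihood over all characters under the partitioned model."""
    scheme = scheme or matrix.partition_scheme()
    params = params or MkParameters()
    engine = PartitionLikelihood(matrix, scheme)
    return engine.log_likelihood(tree, params)


# ------------------------------------------------------ vectorised engine


class PartitionLikelihood:
    """Vectorised pruning over all characters of a partitioned matrix.

    Characters sharing a state count ``k`` and a gamma-category count are
    evaluated in one tree walk with per-character rate profiles (partition
    multiplier times gamma category rates), so the number of traversals per
    likelihood call is the number of distinct (k, n_cat) shapes, not the
    number of partitions.  For each Mkv partition the k constant patterns
    are appended as pseudo-characters to the same walk, providing the
    variable-only normaliser at no extra traversal.
    """

    def __init__(self, matrix: CharacterMatrix, scheme: "PartitionScheme | None" = None):
        self.matrix = matrix
        self.scheme = scheme or matrix.partition_scheme()
        self._tax_index = {t: i for i, t in enumerate(matrix.taxa)}
        # groups keyed by (k, with_gamma); built lazily against params at
        # first call because gamma presence is a parameter property
        self._built_for: "tuple | None" = None
        self._groups: list[dict] = []

    def _build(self, params: MkParameters) -> None:
        matrix = self.matrix
        key = (tuple(sorted(params.alpha)), params.n_cat)
        if self._built_for == key:
            return
        # flat-rate partitions are padded to n_cat identical categories so
        # that everything with the same k shares a single tree walk
        shapes: dict[tuple[int, int], dict] = {}
        for name, chars in self.scheme.partitions.items():
            n_cat = params.n_cat
            for c in chars:
                k = matrix.k[c]
                g = shapes.setdefault(
                    (k, n_cat), {"k": k, "n_cat": n_cat, "chars": [], "parts": []}
                )
                g["chars"].append((c, name))
        for (k, n_cat), g in shapes.items():
            part_names = sorted({name for _, name in g["chars"]})
            g["parts"] = part_names
            # constant pseudo-characters, k per Mkv-capable partition
            n = len(g["chars"])
            n_tot = n + k * len(part_names)
            tip = np.empty((matrix.n_taxa, n_tot, k))
            for i in range(matrix.n_taxa):
                for j, (c, _) in enumerate(g["chars"]):
                    tip[i, j] = _tip_partial(matrix.states[i][c], k)
                col = n
                for _ in part_names:
                    tip[i, col:col + k] = np.eye(k)
                    col += k
            g["tip"] = tip
            g["n"] = n
        self._groups = list(shapes.values())
        self._built_for = key

    def _rates_for(self, g: dict, params: MkParameters, norm: dict) -> np.ndarray:
        """Per-(pseudo)character rate profiles, shape (n_tot, n_cat)."""
        n_cat = g["n_cat"]
        k = g["k"]
        profiles = {}
        for name in {nm for _, nm in g["chars"]}:
            base = (
                gamma_category_rates(params.alpha[name], params.n_cat)
                if name in params.alpha
                else np.ones(n_cat)
            )
            profiles[name] = base * norm[name]
        rows = [profiles[name] for _, name in g["chars"]]
        for name in g["parts"]:
            rows.extend([profiles[name]] * k)
        return np.vstack(rows) if rows else np.zeros((0, n_cat))

    def log_likelihood(self, tree: Tree, params: MkParameters) -> float:
        self._build(params)
        norm = params.normalized_rates(self.scheme)
        total = 0.0
        for g in self._groups:
            k, n, n_cat = g["k"], g["n"], g["n_cat"]
            rates = self._rates_for(g, params, norm)  # (n_tot, n_cat)
            tip = g["tip"]
            n_tot = tip.shape[1]

            partials: dict[Node, np.ndarray] = {}
            log_scale = np.zeros(n_tot)
            n_internal = 0
            for node in tree.postorder():
                if node.is_tip:
                    i = self._tax_index[node.label]
                    partials[node] = np.broadcast_to(
                        tip[i][:, None, :], (n_tot, n_cat, k)
                    )
                    continue
                acc = None
                for child in node.children:
                    part = partials.pop(child)
                    if k == 2:
                        # closed-form binary kernel, avoids einsum overhead
                        e = np.exp(-2.0 * child.length * rates)
                        ps = 0.5 + 0.5 * e
                        pd = 1.0 - ps
                        term = np.empty((n_tot, n_cat, 2))
                        term[..., 0] = ps * part[..., 0] + pd * part[..., 1]
                        term[..., 1] = pd * part[..., 0] + ps * part[..., 1]
                    else:
                        P = _transition_matrices(k, child.length * rates)
                        term = np.einsum("nckl,ncl->nck", P, part)
                    acc = term if acc is None else acc * term
                n_internal += 1
                # periodic rescaling is enough to stay inside double range
                if n_internal % 8 == 0:
                    m = acc.max(axis=(1, 2))
                    bad = m <= 0
                    if np.any(bad):
                        m = np.where(bad, 1.0, m)
                    acc = acc / m[:, None, None]
                    with np.errstate(divide="ignore"):
                        log_scale += np.log(m)
                    if np.any(bad):
                        log_scale[bad] = -np.inf
                partials[node] = acc
            root = partials[tree.root]
            site = root.sum(axis=2).mean(axis=1) / k
            with np.errstate(divide="ignore"):
                loglikes = np.log(site) + log_scale

            # assemble per partition: data chars minus Mkv normaliser
            const_log = {}
            col = n
            for name in g["parts"]:
                block = loglikes[col:col + k]
                cmax = block.max()
                const_log[name] = cmax + np.log(np.exp(block - cmax).sum())
                col += k
            for j, (c, name) in enumerate(g["chars"]):
                ll = loglikes[j]
                if params.ascertainment.get(name, "none") == "variable":
                    p_const = np.exp(const_log[name])
                    if p_const >= 1.0:
                        return -np.inf
                    ll -= np.log1p(-p_const)
                total += float(ll)
        return total
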
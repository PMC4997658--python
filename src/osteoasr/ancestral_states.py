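"""Marginal ancestral-state reconstruction and posterior BPP tables.

For one tree and one parameter draw, the marginal posterior of the state at
an internal node is the normalised product of the "inside" (Felsenstein
pruning, below the node) and "outside" (everything above) conditional
likelihoods, averaged over gamma rate categories.  For Mkv characters the
variable-only conditioning multiplies inside and outside by the same
constant and cancels in the normalisation, so no explicit correction is
applied here.

Bayesian posterior probabilities (BPPs) at a *named ancestor* — defined as
the MRCA of a taxon set — are obtained by locating that MRCA on every
posterior draw, reconstructing with that draw's parameters, and averaging
the state vectors.  The fraction of draws in which the defining set is
actually monophyletic is reported alongside, making constraint-dependent
shifts auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import CharacterMatrix
from .mk_likelihood import (
    LikelihoodError,
    MkParameters,
    _prune,
    _tip_partial,
    _transition_matrices,
    gamma_category_rates,
)
from .trees import Node, Tree

__all__ = ["AncestorQuery", "marginal_asr", "bpp", "BppTable"]


@dataclass(frozen=True)
class AncestorQuery:
    """A named ancestor (MRCA of ``taxa``) with queried characters."""

    name: str
    taxa: tuple[str, ...]
    characters: tuple = ()

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise ValueError(f"query {self.name!r} needs at least two taxa")


@dataclass
class BppTable:
    """Long-format table of (ancestor, character, state) -> BPP."""

    frame: pd.DataFrame
    monophyly: dict[str, float] = field(default_factory=dict)

    def probability(self, ancestor: str, character, state: int) -> float:
        f = self.frame
        sel = f[
            (f.ancestor == ancestor)
            & (f.character.astype(str) == str(character))
            & (f.state == state)
        ]
        if sel.empty:
            raise KeyError((ancestor, character, state))
        return float(sel.bpp.iloc[0])

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["monophyly_fraction"] = out.ancestor.map(self.monophyly)
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _char_rates(
    matrix: CharacterMatrix, char_index: int, params: MkParameters
) -> np.ndarray:
    pname = matrix.partition_of[char_index]
    mult = 1.0
    if params.partition_rate:
        mult = params.normalized_rates(matrix.partition_scheme())[pname]
    alpha = params.alpha.get(pname)
    base = gamma_category_rates(alpha, params.n_cat) if alpha is not None else np.ones(1)
    return base * mult


def marginal_asr(
    tree: Tree,
    matrix: CharacterMatrix,
    char_index: int,
    params: "MkParameters | None" = None,
    node: "Node | None" = None,
) -> np.ndarray:
    """Posterior state probabilities at ``node`` for one character.

    A tip with an observed single state returns the degenerate vector; a
    tip with an uncertainty set returns its normalised posterior given the
    rest of the data.
    """
    params = params or MkParameters()
    k = matrix.k[char_index]
    rates = _char_rates(matrix, char_index, params)
    n_cat = len(rates)
    if node is None:
        node = tree.root

    tip_partials = {
        tax: _tip_partial(matrix.states[i][char_index], k)
        for i, tax in enumerate(matrix.taxa)
    }
    for lab in tree.tip_labels():
        if lab not in tip_partials:
            raise LikelihoodError(f"tip {lab!r} absent from matrix")

    # inside (upward) partials, per node — unscaled products are fine at
    # the tree sizes used here; per-node max rescaling guards bigger trees
    inside: dict[Node, np.ndarray] = {}
    for n in tree.postorder():
        if n.is_tip:
            inside[n] = np.broadcast_to(tip_partials[n.label], (n_cat, k)).copy()
            continue
        acc = np.ones((n_cat, k))
        for child in n.children:
            P = _transition_matrices(k, child.length * rates)
            acc *= np.einsum("ckl,cl->ck", P, inside[child])
        inside[n] = acc

    # outside partials, rootward pass; root outside = stationary 1/k
    outside: dict[Node, np.ndarray] = {tree.root: np.full((n_cat, k), 1.0 / k)}
    for n in tree.preorder():
        for child in n.children:
            acc = outside[n].copy()
            for sib in n.children:
                if sib is child:
                    continue
                P = _transition_matrices(k, sib.length * rates)
                acc *= np.einsum("ckl,cl->ck", P, inside[sib])
            P = _transition_matrices(k, child.length * rates)
            outside[child] = np.einsum("ckl,ck->cl", P, acc)

    joint = inside[node] * outside[node]  # (n_cat, k)
    total = joint.sum()
    if total <= 0:
        raise LikelihoodError("zero likelihood at queried node")
    return joint.sum(axis=0) / total


def bpp(
    draws: "list[tuple[Tree, MkParameters]]",
    matrix: CharacterMatrix,
    queries: "list[AncestorQuery]",
    default_characters: tuple = (),
) -> BppTable:
    """Average marginal reconstructions over posterior draws.

    Each query's MRCA is located per draw (so the BPP integrates over
    topological uncertainty); queries whose taxon set spans the root in
    every draw are still answered (the MRCA is then the root) but their
    monophyly fraction exposes it.
    """
    if not draws:
        raise ValueError("no posterior draws supplied")
    rows = []
    mono: dict[str, float] = {}
    for q in queries:
        chars = q.characters or default_characters
        if not chars:
            raise ValueError(f"query {q.name!r} has no characters to reconstruct")
        char_idx = [matrix.char_index(c) for c in chars]
        vecs = {c: np.zeros(matrix.k[c]) for c in char_idx}
        mono_count = 0
        for tree, params in draws:
            node = tree.mrca(q.taxa)
            if tree.is_monophyletic(q.taxa):
                mono_count += 1
            for c in char_idx:
                vecs[c] += marginal_asr(tree, matrix, c, params, node)
        mono[q.name] = mono_count / len(draws)
        for lab, c in zip(chars, char_idx):
            v = vecs[c] / len(draws)
            for s in range(matrix.k[c]):
                rows.append(
                    {
                        "ancestor": q.name,
                        "character": lab,
                        "state": s,
                        "bpp": float(v[s]),
                    }
                )
    return BppTable(frame=pd.DataFrame(rows), monophyly=mono)
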
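"""Parsimony transformation counting: losses vs regains on fixed trees.

For a presence/absence character (convention: state 0 = present, the
plesiomorphic condition; state 1 = absent) a "loss" is a 0->1 change along
an edge and a "regain" is 1->0.  Sankoff's dynamic programme over an
arbitrary cost matrix supports three regimes:

* symmetric   — all changes cost 1 (equivalent to Fitch counting),
* asymmetric  — loss and regain costs differ,
* Dollo       — regains are forbidden (infinite cost), so a complex
                structure can only be lost, never re-evolved.

Beyond the minimal cost, the module reports how that cost decomposes into
losses and regains across most-parsimonious reconstructions (MPRs): the
reported decomposition minimises losses first and then regains, and the
exact min/max ranges of both counts over all MPRs are obtained by
lexicographic DP passes, so they remain exact even when explicit MPR
enumeration is capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import Node, Tree

__all__ = [
    "CostRegime",
    "TransformationCount",
    "fitch",
    "sankoff",
    "ancestral_fixing",
    "ParsimonyError",
]

INF = math.inf
MPR_CAP = 10_000


class ParsimonyError(ValueError):
    pass


@dataclass(frozen=True)
class CostRegime:
    """A k x k transformation cost matrix with a human-readable label."""

    costs: tuple[tuple[float, ...], ...]
    label: str

    def __post_init__(self) -> None:
        k = len(self.costs)
        for i, row in enumerate(self.costs):
            if len(row) != k:
                raise ParsimonyError("cost matrix must be square")
            if row[i] != 0:
                raise ParsimonyError("cost matrix diagonal must be zero")
            if any(c < 0 for c in row):
                raise ParsimonyError("costs must be non-negative")

    @property
    def k(self) -> int:
        return len(self.costs)

    @classmethod
    def symmetric(cls, k: int = 2) -> "CostRegime":
        costs = tuple(
            tuple(0.0 if i == j else 1.0 for j in range(k)) for i in range(k)
        )
        return cls(costs, "symmetric")

    @classmethod
    def asymmetric(cls, loss_cost: float, regain_cost: float) -> "CostRegime":
        """Binary regime: loss (0->1) and regain (1->0) priced separately."""
        return cls(
            ((0.0, float(loss_cost)), (float(regain_cost), 0.0)),
            f"asymmetric(loss={loss_cost:g}, regain={regain_cost:g})",
        )

    @classmethod
    def dollo(cls, loss_cost: float = 1.0) -> "CostRegime":
        """Binary Dollo: the lost structure cannot be re-gained."""
        return cls(((0.0, float(loss_cost)), (INF, 0.0)), "dollo")


@dataclass(frozen=True)
class TransformationCount:
    """Minimal cost and its loss/regain decomposition over MPRs.

    ``losses``/``regains`` give the reported MPR (fewest regains, then
    fewest losses); the ``*_range`` fields are exact bounds over all MPRs.
    """

    cost: float
    losses: int
    regains: int
    losses_range: tuple[int, int]
    regains_range: tuple[int, int]
    n_mpr: int
    ambiguous: bool
    cap_hit: bool
    regime: str

    @property
    def dollo_infeasible(self) -> bool:
        return math.isinf(self.cost)


def _tip_state_sets(
    tree: Tree, tip_states: dict, k: int
) -> dict[Node, frozenset[int]]:
    out = {}
    full = frozenset(range(k))
    any_scored = False
    for tip in tree.tips():
        raw = tip_states.get(tip.label)
        if raw is None:
            out[tip] = full
            continue
        if isinstance(raw, int):
            raw = {raw}
        s = frozenset(int(x) for x in raw)
        if not s:
            out[tip] = full
            continue
        if max(s) >= k or min(s) < 0:
            raise ParsimonyError(f"tip {tip.label!r} state {set(s)} out of range")
        out[tip] = s
        any_scored = True
    if not any_scored:
        raise ParsimonyError("no scored tips")
    return out


def fitch(tree: Tree, tip_states: dict, k: int = 2) -> int:
    """Minimal number of state changes under equal costs (Fitch counting).

    ``tip_states`` maps tip label -> code, set of codes, or ``None``
    (missing; contributes the full state set).  Polytomies are handled by
    the Hartigan generalisation (keep the states attained by the maximal
    number of children; each child outside that majority costs one change).
    """
    sets = _tip_state_sets(tree, tip_states, k)
    changes = 0
    node_sets: dict[Node, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            node_sets[node] = sets[node]
            continue
        counts = np.zeros(k, dtype=int)
        for child in node.children:
            for s in node_sets[child]:
                counts[s] += 1
        k_max = counts.max()
        node_sets[node] = frozenset(int(s) for s in np.flatnonzero(counts == k_max))
        changes += len(node.children) - int(k_max)
    return changes


# ----------------------------------------------------------- Sankoff DP


def _sankoff_tables(
    tree: Tree,
    sets: dict[Node, frozenset[int]],
    costs: np.ndarray,
    weights: "np.ndarray | None" = None,
) -> dict[Node, np.ndarray]:
    """Lexicographic Sankoff: per node, per state, a (cost, secondary) pair.

    ``weights[i, j]`` is the secondary objective contribution of an i->j
    change (e.g. 1 for regains to minimise them, -1 to maximise).  When
    ``weights`` is None the secondary component is zero.
    """
    k = costs.shape[0]
    if weights is None:
        weights = np.zeros_like(costs)
    g: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            tab = np.full((k, 2), INF)
            for s in sets[node]:
                tab[s] = (0.0, 0.0)
            g[node] = tab
            continue
        tab = np.zeros((k, 2))
        for child in node.children:
            ctab = g[child]
            # for each parent state i: lexicographic min over child state j
            cand_cost = costs + ctab[None, :, 0]  # (i, j)
            cand_sec = weights + ctab[None, :, 1]
            best_cost = cand_cost.min(axis=1)
            with np.errstate(invalid="ignore"):
                mask = cand_cost == best_cost[:, None]
            sec = np.where(mask, cand_sec, INF).min(axis=1)
            finite = np.isfinite(best_cost)
            tab[:, 0] += np.where(finite, best_cost, INF)
            tab[:, 1] += np.where(finite, np.where(np.isfinite(sec), sec, 0.0), 0.0)
        g[node] = tab
    return g


def _root_pick(tab: np.ndarray, root_state: "int | None") -> tuple[float, float, list[int]]:
    if root_state is not None:
        return tab[root_state, 0], tab[root_state, 1], [root_state]
    best = tab[:, 0].min()
    states = [int(s) for s in np.flatnonzero(tab[:, 0] == best)]
    sec = min(tab[s, 1] for s in states)
    states = [s for s in states if tab[s, 1] == sec]
    return best, sec, states


def _enumerate_mprs(
    tree: Tree,
    sets: dict[Node, frozenset[int]],
    costs: np.ndarray,
    root_state: "int | None",
    cap: int,
) -> tuple[list[dict[Node, int]], bool]:
    """All minimum-cost state assignments (deterministic order, capped)."""
    g = _sankoff_tables(tree, sets, costs)
    tab = g[tree.root]
    best, _, root_states = _root_pick(tab, root_state)
    if math.isinf(best):
        return [], False
    if root_state is not None and math.isinf(tab[root_state, 0]):
        return [], False

    assignments: list[dict[Node, int]] = []
    cap_hit = False

    def descend(partial: dict[Node, int], nodes: list[Node]) -> bool:
        """DFS over per-node optimal child choices; returns False at cap."""
        if not nodes:
            assignments.append(dict(partial))
            return len(assignments) < cap
        node, rest = nodes[0], nodes[1:]
        s = partial[node]
        children = node.children
        # optimal states per child given parent state s
        options = []
        for child in children:
            cand = costs[s] + g[child][:, 0]
            m = cand.min()
            options.append([int(j) for j in np.flatnonzero(cand == m)])

        def choose(ci: int) -> bool:
            if ci == len(children):
                return descend(partial, [c for c in children if not c.is_tip] + rest)
            for j in options[ci]:
                child = children[ci]
                partial[child] = j
                if child.is_tip and j not in sets[child]:
                    # a tip forced off its observed set can only happen with
                    # infinite-cost regimes; DP already excluded it
                    del partial[child]
                    continue
                if not choose(ci + 1):
                    return False
                del partial[child]
            return True

        ok = choose(0)
        return ok

    # tips with ambiguity also get assignments (their optimal state given parent)
    for s0 in (root_states if root_state is None else [root_state]):
        partial = {tree.root: s0}
        if not descend(partial, [tree.root] if not tree.root.is_tip else []):
            cap_hit = True
            break
    return assignments, cap_hit


def _count_changes(
    tree: Tree, assignment: dict[Node, int]
) -> tuple[int, int]:
    """(losses, regains): 0->non-0 and non-0->0 edges, respectively."""
    losses = regains = 0
    for node in tree.postorder():
        if node.parent is None:
            continue
        a, b = assignment[node.parent], assignment[node]
        if a == b:
            continue
        if a == 0:
            losses += 1
        elif b == 0:
            regains += 1
        else:
            losses += 1  # change between two derived states counted as loss-side
    return losses, regains


def sankoff(
    tree: Tree,
    tip_states: dict,
    regime: CostRegime,
    root_state: "int | None" = None,
    cap: int = MPR_CAP,
) -> TransformationCount:
    """Minimal-cost mapping of a character under a cost regime.

    ``root_state`` optionally pins the ancestral state at the root.  The
    reported loss/regain decomposition is the MPR minimising regains first
    and losses second; exact ranges over all MPRs come from auxiliary
    lexicographic DP passes.
    """
    k = regime.k
    costs = np.array(regime.costs, float)
    sets = _tip_state_sets(tree, tip_states, k)
    if root_state is not None and not 0 <= root_state < k:
        raise ParsimonyError(f"root_state {root_state} out of range")

    base = _sankoff_tables(tree, sets, costs)
    cost, _, _ = _root_pick(base[tree.root], root_state)
    if math.isinf(cost):
        return TransformationCount(
            cost=INF, losses=0, regains=0, losses_range=(0, 0),
            regains_range=(0, 0), n_mpr=0, ambiguous=False, cap_hit=False,
            regime=regime.label,
        )

    # secondary-objective weight matrices
    w_loss = np.zeros((k, k))
    w_regain = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if i == 0:
                w_loss[i, j] = 1.0
            elif j == 0:
                w_regain[i, j] = 1.0
            else:
                w_loss[i, j] = 1.0

    def bound(weights: np.ndarray) -> int:
        g = _sankoff_tables(tree, sets, costs, weights)
        _, sec, _ = _root_pick(g[tree.root], root_state)
        return int(round(sec))

    min_losses = bound(w_loss)
    max_losses = -bound(-w_loss)
    min_regains = bound(w_regain)
    max_regains = -bound(-w_regain)

    # reported MPR: lexicographic (cost, losses, regains) — fewest losses
    # first, then fewest regains, the order in which loss/regain mappings
    # are conventionally presented; realised by one DP with a combined
    # secondary weight losses*(big) + regains
    big = 4 * tree.n_tips + 4
    combined = bound(w_loss * big + w_regain)
    rep_losses = combined // big
    rep_regains = combined % big

    assignments, cap_hit = _enumerate_mprs(tree, sets, costs, root_state, cap)
    decomps = sorted({_count_changes(tree, a) for a in assignments})
    ambiguous = len(decomps) > 1

    return TransformationCount(
        cost=float(cost),
        losses=rep_losses,
        regains=rep_regains,
        losses_range=(min_losses, max_losses),
        regains_range=(min_regains, max_regains),
        n_mpr=len(assignments),
        ambiguous=ambiguous,
        cap_hit=cap_hit,
        regime=regime.label,
    )


def ancestral_fixing(
    tree: Tree,
    tip_states: dict,
    regime: CostRegime,
    root_state: int,
) -> TransformationCount:
    """Sankoff mapping with the root state pinned.

    Used to compare "ancestrally present" against "ancestrally absent"
    scenarios for the postdentary trough.
    """
    return sankoff(tree, tip_states, regime, root_state=root_state)
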
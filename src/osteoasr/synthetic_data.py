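"""Synthetic character matrices and trees with known ground truth.

Because the two published morphological matrices the middle-ear analyses
were run on are external supplementary data without accessions, every
pipeline stage here is exercised on simulated data instead: characters
evolved under the same model family the inference assumes (partitioned
Mk/Mkv with discrete-gamma rate heterogeneity), on trees with known
topology, branch lengths and internal-node states.

The flagship fixture is :func:`two_loss_scenario`: a binary
presence/absence "postdentary trough" character whose true history has the
state present at the root and exactly two independent losses on disjoint
subtrees (mirroring the monotreme-side and therian-side detachments), no
regains, embedded among ordinary simulated background partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CharacterMatrix
from .mk_likelihood import gamma_category_rates, transition_matrix
from .trees import Node, Tree

__all__ = [
    "PartitionSpec",
    "SimulationScenario",
    "GroundTruth",
    "simulate_tree",
    "simulate_characters",
    "two_loss_scenario",
    "SimulationError",
]

REJECTION_CAP = 1_000_000


class SimulationError(RuntimeError):
    pass


@dataclass
class PartitionSpec:
    """One partition of simulated characters."""

    name: str
    n_char: int
    k: int = 2
    alpha: "float | None" = None  # None: no rate heterogeneity
    rate: float = 1.0
    variable_only: bool = False


@dataclass
class GroundTruth:
    """True generating history recorded during simulation.

    ``internal_states[c]`` maps each tree node to its true state for
    character ``c``; ``change_edges[c]`` lists (parent_state, child_state,
    child clade mask) for every edge on which the state changed.
    """

    internal_states: dict[int, dict[Node, int]] = field(default_factory=dict)
    change_edges: dict[int, list[tuple[int, int, int]]] = field(default_factory=dict)
    char_rates: dict[int, float] = field(default_factory=dict)

    def losses_regains(self, c: int) -> tuple[int, int]:
        losses = sum(1 for a, b, _ in self.change_edges.get(c, []) if a == 0)
        regains = sum(1 for a, b, _ in self.change_edges.get(c, []) if a != 0 and b == 0)
        return losses, regains


@dataclass
class SimulationScenario:
    tree: Tree
    partitions: list[PartitionSpec]
    missing_fraction: float = 0.0
    seed: int = 0
    #: taxa the trough queries are defined by (two_loss_scenario only)
    queries: dict[str, list[str]] = field(default_factory=dict)
    outgroup: "str | None" = None


# ----------------------------------------------------------------- trees


def simulate_tree(
    n_tips: int,
    length_scale: float = 0.1,
    seed: "int | np.random.Generator" = 0,
    labels: "list[str] | None" = None,
) -> Tree:
    """Uniform rooted binary topology with iid exponential branch lengths.

    Uniformity over the (2n-3)!! rooted labelled topologies is obtained by
    sequential addition: each new tip attaches to any existing branch or
    above the root, all positions equiprobable.
    """
    if n_tips < 2:
        raise SimulationError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = labels or [f"t{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise SimulationError("label count mismatch")

    root = Node()
    root.add_child(Node(label=labels[0]))
    root.add_child(Node(label=labels[1]))
    tree = Tree(root)
    for i in range(2, n_tips):
        attachable = [n for n in tree.postorder() if n.parent is not None]
        pos = rng.integers(0, len(attachable) + 1)
        new_tip = Node(label=labels[i])
        if pos == len(attachable):  # above the root
            new_root = Node()
            new_root.add_child(tree.root)
            new_root.add_child(new_tip)
            tree.root = new_root
        else:
            edge_child = attachable[pos]
            parent = edge_child.parent
            idx = parent.children.index(edge_child)
            mid = Node()
            mid.parent = parent
            parent.children[idx] = mid
            edge_child.parent = mid
            mid.children = [edge_child, new_tip]
            new_tip.parent = mid
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.exponential(length_scale))
    return tree


# ------------------------------------------------------------ characters


def _evolve_once(
    tree: Tree, k: int, rate: float, rng: np.random.Generator
) -> dict[Node, int]:
    """One realisation of the Mk process down the tree; returns node states."""
    states: dict[Node, int] = {tree.root: int(rng.integers(0, k))}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = transition_matrix(k, node.length * rate)
        parent_state = states[node.parent]
        states[node] = int(rng.choice(k, p=P[parent_state]))
    return states


def simulate_characters(
    tree: Tree,
    scenario: SimulationScenario,
) -> tuple[CharacterMatrix, GroundTruth]:
    """Forward-simulate all partitions of a scenario on a tree.

    Root states are stationary (uniform); per-character rates are the
    partition multiplier times a gamma draw when the partition has a shape
    parameter.  Variable-only partitions are simulated by rejecting
    constant characters (the ascertainment process the Mkv likelihood
    corrects for).  Missingness is applied completely at random.
    """
    rng = np.random.default_rng(scenario.seed)
    taxa = sorted(tree.tip_labels())
    tips = {t.label: t for t in tree.tips()}
    states_rows: dict[str, list["frozenset[int] | None"]] = {t: [] for t in taxa}
    ks: list[int] = []
    partition_of: list[str] = []
    labels: list[str] = []
    truth = GroundTruth()
    masks = tree.clade_masks()

    c = 0
    for part in scenario.partitions:
        for j in range(part.n_char):
            r = part.rate
            if part.alpha is not None:
                r *= float(rng.gamma(part.alpha, 1.0 / part.alpha))
            attempts = 0
            while True:
                attempts += 1
                if attempts > REJECTION_CAP:
                    raise SimulationError(
                        f"variable-only rejection cap exceeded for partition "
                        f"{part.name!r} (rate {r:g} too small?)"
                    )
                node_states = _evolve_once(tree, part.k, r, rng)
                tip_states = {lab: node_states[tips[lab]] for lab in taxa}
                if not part.variable_only or len(set(tip_states.values())) > 1:
                    break
            truth.internal_states[c] = node_states
            truth.char_rates[c] = r
            truth.change_edges[c] = [
                (node_states[n.parent], node_states[n], masks[n])
                for n in tree.postorder()
                if n.parent is not None and node_states[n.parent] != node_states[n]
            ]
            for lab in taxa:
                states_rows[lab].append(frozenset({tip_states[lab]}))
            ks.append(part.k)
            partition_of.append(part.name)
            labels.append(f"{part.name}_{j + 1}")
            c += 1

    matrix = CharacterMatrix(
        taxa=list(taxa),
        states=[states_rows[t] for t in taxa],
        k=ks,
        character_labels=labels,
        partition_of=partition_of,
    )
    if scenario.missing_fraction > 0:
        mask = rng.random((matrix.n_taxa, matrix.n_char)) < scenario.missing_fraction
        for i in range(matrix.n_taxa):
            for cc in range(matrix.n_char):
                if mask[i, cc]:
                    matrix.states[i][cc] = None
    matrix.validate()
    return matrix, truth


# ------------------------------------------------------- two-loss fixture


def two_loss_scenario(seed: int = 0) -> tuple[SimulationScenario, CharacterMatrix, GroundTruth]:
    """A 14-taxon study system with a trough lost exactly twice.

    Structure (all ingroup relative to the outgroup taxon ``Out``):

    * trough-bearing stem taxa (``Stem1..Stem4``) placed so that they
      *separate* the two troughless clades — the losses are therefore
      genuinely independent and no single-loss mapping can explain them,
    * a southern clade ``Aus1..Aus4`` (trough lost on its stem edge),
    * a northern clade ``Ther1..Ther5`` (trough lost on its stem edge).

    Topology: (Out,(Stem1,((Stem2,Aus),(Stem3,(Stem4,Ther)))))

    The trough character's history is constructed, not simulated: present
    (state 0) at the root and every stem node, changing to absent (1)
    exactly once on each of the two clades' stem edges — so the true loss
    count is 2 and the true regain count 0.  Background partitions
    (mandibulodental, postcranial, cranial) are simulated under Mkv+gamma,
    and a single-character Meckel's groove partition is simulated under Mk.

    Returns the scenario (with ancestor queries and ground truth), the
    full character matrix, and the ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2105]))
    aus = [f"Aus{i}" for i in range(1, 5)]
    ther = [f"Ther{i}" for i in range(1, 6)]
    stems = [f"Stem{i}" for i in range(1, 5)]

    def balanced(labels: list[str], scale: float) -> Node:
        nodes = [Node(label=lab, length=float(rng.exponential(scale)) + 0.02)
                 for lab in labels]
        while len(nodes) > 1:
            b = nodes.pop()
            a = nodes.pop()
            p = Node()
            p.add_child(a)
            p.add_child(b)
            p.length = float(rng.exponential(scale)) + 0.02
            nodes.insert(0, p)
        return nodes[0]

    # depth is kept below ~0.8 expected changes root-to-tip: binary
    # characters saturate quickly, and a saturated tree cannot anchor the
    # clades whose ancestors are queried
    scale = 0.04
    aus_clade = balanced(aus, scale)
    ther_clade = balanced(ther, scale)

    def pair(a: Node, b: Node, length: float) -> Node:
        p = Node(length=length)
        p.add_child(a)
        p.add_child(b)
        return p

    def tip(lab: str) -> Node:
        return Node(label=lab, length=0.06)

    aus_clade.length = 0.3
    ther_clade.length = 0.3
    south = pair(tip("Stem2"), aus_clade, 0.12)      # (Stem2, Aus)
    north_in = pair(tip("Stem4"), ther_clade, 0.12)  # (Stem4, Ther)
    north = pair(tip("Stem3"), north_in, 0.12)       # (Stem3, (Stem4, Ther))
    crown = pair(south, north, 0.1)
    ingroup_root = pair(tip("Stem1"), crown, 0.1)
    root = Node()
    root.add_child(ingroup_root)
    root.add_child(Node(label="Out", length=0.15))
    tree = Tree(root)

    partitions = [
        PartitionSpec("mandibulodental", n_char=40, k=2, alpha=1.0,
                      rate=1.0, variable_only=True),
        PartitionSpec("postcranial", n_char=25, k=2, alpha=1.0,
                      rate=1.0, variable_only=True),
        PartitionSpec("cranial", n_char=25, k=2, alpha=1.0,
                      rate=1.0, variable_only=True),
        PartitionSpec("meckels_groove", n_char=1, k=2, variable_only=True),
    ]
    scenario = SimulationScenario(
        tree=tree,
        partitions=partitions,
        missing_fraction=0.10,
        seed=int(np.random.SeedSequence([seed, 0x51D]).generate_state(1)[0] % (2**31)),
        queries={
            "root_ancestor": sorted(aus + ther + stems),
            "australosphenida": sorted(aus),
            "theriiformes": sorted(ther),
        },
        outgroup="Out",
    )
    matrix, truth = simulate_characters(tree, scenario)

    # constructed trough history: present everywhere except the two clades
    masks = tree.clade_masks()
    index = tree.taxon_index()
    aus_mask = sum(1 << index[t] for t in aus)
    ther_mask = sum(1 << index[t] for t in ther)
    trough_states: dict[Node, int] = {}
    for node in tree.postorder():
        m = masks[node]
        inside = (m & aus_mask == m) or (m & ther_mask == m)
        trough_states[node] = 1 if inside else 0
    c = matrix.n_char
    for i, lab in enumerate(matrix.taxa):
        tip = next(t for t in tree.tips() if t.label == lab)
        matrix.states[i].append(frozenset({trough_states[tip]}))
    matrix.k.append(2)
    matrix.partition_of.append("postdentary_trough")
    matrix.character_labels.append("postdentary_trough")
    matrix.validate()
    truth.internal_states[c] = trough_states
    truth.change_edges[c] = [
        (trough_states[n.parent], trough_states[n], masks[n])
        for n in tree.postorder()
        if n.parent is not None and trough_states[n.parent] != trough_states[n]
    ]
    truth.char_rates[c] = 1.0
    assert truth.losses_regains(c) == (2, 0)
    return scenario, matrix, truth
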
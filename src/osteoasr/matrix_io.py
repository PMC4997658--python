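"""Discrete morphological character matrices: NEXUS I/O, completeness, filtering.

A :class:`CharacterMatrix` holds taxa x characters of discrete states.  Each
entry is either a frozenset of integer codes (singleton = an observed state,
larger = an uncertainty/polymorphism set) or ``None`` for missing data ("?").
Characters carry a partition label (anatomical region or single key character,
e.g. the postdentary trough), which drives the partitioned likelihood model.

Parsing of NEXUS DATA/CHARACTERS and SETS blocks is delegated to dendropy;
writing is done here so that round trips are exact and the emitted files are
readable by mainstream phylogenetics software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .trees import Tree

__all__ = [
    "CharacterMatrix",
    "PartitionScheme",
    "MatrixError",
    "MatrixParseError",
    "read_nexus",
    "write_nexus",
    "completeness",
    "filter_taxa",
    "read_newick",
    "write_newick",
    "DEFAULT_PARTITION",
]

logger = logging.getLogger(__name__)

#: Characters not named by any charset fall into this partition.
DEFAULT_PARTITION = "unassigned"

#: Partition names used for the middle-ear analyses.
STANDARD_PARTITIONS = (
    "mandibulodental",
    "postcranial",
    "cranial",
    "meckels_groove",
    "postdentary_trough",
)


class MatrixError(ValueError):
    pass


class MatrixParseError(MatrixError):
    pass


Entry = "frozenset[int] | None"  # documentation alias


@dataclass
class CharacterMatrix:
    """Taxa x characters table of discrete states.

    ``states[i][c]`` is ``None`` (missing) or a nonempty frozenset of codes,
    each ``< k[c]``.  ``polymorphic`` records which multi-code entries were
    written with ``(..)`` rather than ``{..}`` so that round trips preserve
    the notation (both are treated identically in the likelihood).
    """

    taxa: list[str]
    states: list[list["frozenset[int] | None"]]
    k: list[int]
    character_labels: list[str]
    partition_of: list[str]
    polymorphic: set[tuple[int, int]] = field(default_factory=set)

    # ------------------------------------------------------------- basics

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.k)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise MatrixError(f"unknown taxon {taxon!r}") from None

    def entry(self, taxon: str, char: int) -> "frozenset[int] | None":
        return self.states[self.taxon_index(taxon)][char]

    def char_index(self, name_or_index: "str | int") -> int:
        """Resolve a character given its label, partition name, or index."""
        if isinstance(name_or_index, int):
            return name_or_index
        if name_or_index in self.character_labels:
            return self.character_labels.index(name_or_index)
        members = [i for i, p in enumerate(self.partition_of) if p == name_or_index]
        if len(members) == 1:
            return members[0]
        raise MatrixError(
            f"{name_or_index!r} does not name a unique character "
            f"({len(members)} partition members)"
        )

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon labels")
        if len(self.states) != self.n_taxa:
            raise MatrixError("row count does not match taxa")
        for i, row in enumerate(self.states):
            if len(row) != self.n_char:
                raise MatrixError(
                    f"taxon {self.taxa[i]!r} has {len(row)} entries, "
                    f"expected {self.n_char}"
                )
            for c, entry in enumerate(row):
                if entry is None:
                    continue
                if not entry:
                    raise MatrixError(f"empty state set at ({self.taxa[i]}, char {c + 1})")
                # a set covering the full state space is allowed (it can
                # arise from state collapses) and is equivalent to MISSING
                # in the likelihood
                if max(entry) >= self.k[c] or min(entry) < 0:
                    raise MatrixError(
                        f"code out of range at ({self.taxa[i]}, char {c + 1})"
                    )
        if len(self.partition_of) != self.n_char or len(self.character_labels) != self.n_char:
            raise MatrixError("per-character metadata length mismatch")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.states == other.states
            and self.character_labels == other.character_labels
            and self.partition_of == other.partition_of
        )

    # -------------------------------------------------------- derived info

    def partition_scheme(self) -> "PartitionScheme":
        parts: dict[str, list[int]] = {}
        for c, name in enumerate(self.partition_of):
            parts.setdefault(name, []).append(c)
        return PartitionScheme({name: tuple(idx) for name, idx in parts.items()})

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            states=[list(row) for row in self.states],
            k=list(self.k),
            character_labels=list(self.character_labels),
            partition_of=list(self.partition_of),
            polymorphic=set(self.polymorphic),
        )


@dataclass(frozen=True)
class PartitionScheme:
    """Disjoint, exhaustive grouping of character indices by partition name."""

    partitions: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, idx in self.partitions.items():
            overlap = seen & set(idx)
            if overlap:
                raise MatrixError(f"partition {name!r} overlaps characters {overlap}")
            seen |= set(idx)

    @property
    def single_character_flags(self) -> dict[str, bool]:
        return {name: len(idx) == 1 for name, idx in self.partitions.items()}

    def name_of(self, char: int) -> str:
        for name, idx in self.partitions.items():
            if char in idx:
                return name
        raise MatrixError(f"character {char} not covered by partition scheme")


# ---------------------------------------------------------------- NEXUS I/O


def _entry_from_dendropy(state) -> "tuple[frozenset[int] | None, bool]":
    """Map a dendropy state to (entry, is_polymorphic)."""
    sym = state.symbol
    if sym in ("?", "-"):
        return None, False
    fundamentals = sorted(s for s in state.fundamental_symbols if s not in ("-", "?"))
    if sym is not None and len(fundamentals) <= 1:
        return frozenset({int(sym)}), False
    codes = frozenset(int(s) for s in fundamentals)
    if not codes or any(s in state.fundamental_symbols for s in ("-",)) and len(codes) == 0:
        return None, False
    poly = getattr(state, "state_denomination", None) == dendropy.StateAlphabet.POLYMORPHIC_STATE
    return codes, poly


def read_nexus(path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block (plus optional SETS) into a matrix.

    ``?`` becomes missing; ``{01}`` and ``(01)`` become uncertainty sets
    (the notation is remembered for round-trip output).  Charsets become
    partitions; uncovered characters fall into ``DEFAULT_PARTITION``.
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:
        raise MatrixParseError(f"failed to parse NEXUS {path}: {exc}") from exc

    taxa = [t.label for t in dm.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise MatrixParseError("duplicate taxon labels in NEXUS file")

    rows: list[list["frozenset[int] | None"]] = []
    poly: set[tuple[int, int]] = set()
    n_char = None
    for i, tax in enumerate(dm.taxon_namespace):
        seq = dm[tax]
        row: list["frozenset[int] | None"] = []
        for c, st in enumerate(seq):
            entry, is_poly = _entry_from_dendropy(st)
            row.append(entry)
            if is_poly:
                poly.add((i, c))
        if n_char is None:
            n_char = len(row)
        elif len(row) != n_char:
            raise MatrixParseError(
                f"ragged matrix: taxon {tax.label!r} has {len(row)} characters, "
                f"expected {n_char}"
            )
        rows.append(row)
    n_char = n_char or 0

    k = []
    for c in range(n_char):
        observed = [max(rows[i][c]) for i in range(len(taxa)) if rows[i][c] is not None]
        k.append(max(observed, default=0) + 1 if observed else 2)
        k[-1] = max(k[-1], 2)

    partition_of = [DEFAULT_PARTITION] * n_char
    for name, subset in dm.character_subsets.items():
        # NEXUS unquoted tokens read underscores as spaces; map them back
        name = name.replace(" ", "_")
        for idx in subset.character_indices:
            if idx < n_char:
                partition_of[idx] = name

    labels = [f"char{c + 1}" for c in range(n_char)]
    mat = CharacterMatrix(
        taxa=taxa, states=rows, k=k, character_labels=labels,
        partition_of=partition_of, polymorphic=poly,
    )
    mat.validate()
    return mat


def _format_entry(entry: "frozenset[int] | None", poly: bool) -> str:
    if entry is None:
        return "?"
    if len(entry) == 1:
        return str(next(iter(entry)))
    inner = "".join(str(s) for s in sorted(entry))
    return f"({inner})" if poly else "{" + inner + "}"


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Emit a NEXUS file readable by :func:`read_nexus` and by MrBayes/PAUP."""
    matrix.validate()
    max_k = max(matrix.k, default=2)
    symbols = "".join(str(i) for i in range(max_k))
    name_w = max((len(t) for t in matrix.taxa), default=1) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for i, tax in enumerate(matrix.taxa):
        row = "".join(
            _format_entry(matrix.states[i][c], (i, c) in matrix.polymorphic)
            for c in range(matrix.n_char)
        )
        lines.append(f"{tax.replace(' ', '_'):<{name_w}}{row}")
    lines += [";", "END;"]

    scheme = matrix.partition_scheme()
    named = {n: idx for n, idx in scheme.partitions.items() if n != DEFAULT_PARTITION}
    if named:
        lines.append("BEGIN SETS;")
        for name, idx in named.items():
            spans = " ".join(_index_ranges([i + 1 for i in idx]))
            lines.append(f"CHARSET {name} = {spans};")
        lines.append("END;")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _index_ranges(indices: list[int]) -> list[str]:
    """Compress sorted 1-based indices into NEXUS range tokens."""
    out: list[str] = []
    start = prev = None
    for i in sorted(indices):
        if start is None:
            start = prev = i
        elif i == prev + 1:
            prev = i
        else:
            out.append(str(start) if start == prev else f"{start}-{prev}")
            start = prev = i
    if start is not None:
        out.append(str(start) if start == prev else f"{start}-{prev}")
    return out


# ------------------------------------------------- completeness & filtering


def completeness(matrix: CharacterMatrix, taxon: str) -> float:
    """Fraction of characters scored for a taxon.

    Uncertainty sets count as scored (they constrain the likelihood);
    missing entries do not.
    """
    i = matrix.taxon_index(taxon)
    if matrix.n_char == 0:
        return 1.0
    scored = sum(1 for e in matrix.states[i] if e is not None)
    return scored / matrix.n_char


def filter_taxa(
    matrix: CharacterMatrix,
    min_completeness: float = 0.0,
    exclusions: "list[str] | None" = None,
) -> CharacterMatrix:
    """Drop taxa below a completeness threshold, then named exclusions.

    Exclusion is strict (``completeness < min_completeness``): a taxon scored
    for exactly the threshold fraction is retained.  Every removal is logged
    with its reason.  Refuses to leave fewer than four taxa (no resolvable
    topology below that).
    """
    if not 0.0 <= min_completeness <= 1.0:
        raise MatrixError("min_completeness must be within [0, 1]")
    exclusions = list(exclusions or [])
    for tax in exclusions:
        if tax not in matrix.taxa:
            logger.warning("exclusion %r not present in matrix; ignored", tax)

    keep: list[int] = []
    for i, tax in enumerate(matrix.taxa):
        frac = completeness(matrix, tax)
        if frac < min_completeness:
            logger.info(
                "removing %s: completeness %.4f < %.4f", tax, frac, min_completeness
            )
            continue
        if tax in exclusions:
            logger.info("removing %s: listed exclusion", tax)
            continue
        keep.append(i)

    if len(keep) < 4:
        raise MatrixError(
            f"filtering would leave {len(keep)} taxa (<4); refusing"
        )

    old_index = {i: new for new, i in enumerate(keep)}
    poly = {
        (old_index[i], c) for (i, c) in matrix.polymorphic if i in old_index
    }
    return CharacterMatrix(
        taxa=[matrix.taxa[i] for i in keep],
        states=[list(matrix.states[i]) for i in keep],
        k=list(matrix.k),
        character_labels=list(matrix.character_labels),
        partition_of=list(matrix.partition_of),
        polymorphic=poly,
    )


# ------------------------------------------------------------------- trees


def read_newick(path) -> Tree:
    return Tree.read(path)


def write_newick(tree: Tree, path) -> None:
    tree.write(path)


def validate_tree_matrix(tree: Tree, matrix: CharacterMatrix) -> None:
    """Require the tree's tip set to be a subset of the matrix taxa."""
    missing = set(tree.tip_labels()) - set(matrix.taxa)
    if missing:
        raise MatrixError(f"tree tips absent from matrix: {sorted(missing)}")
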
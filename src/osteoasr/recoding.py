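"""Character re-scoring: state collapses and per-taxon overrides.

Two kinds of edit are supported, both non-destructive (they return a new
matrix) and both logged entry by entry:

* ``collapse_states`` merges states of one character under an old->new code
  map — e.g. collapsing a three-state Meckel's groove (well developed /
  weakly developed / vestigial-or-absent) to binary developed vs not, on the
  grounds that "weakly developed" cannot be told apart from erosion damage
  in sub-optimally preserved fossils.

* ``apply_overrides`` rewrites individual (taxon, character) cells — the
  fossil-by-fossil re-interpretations of the postdentary trough and
  Meckel's groove (Hadrocodium, Asfaltomylos, Ausktribosphenos, Bishops,
  Steropodon, Teinolophos), each carrying a provenance string.

Packaged rule sets for the two source data sets (``ds21``, ``ds22``) live in
``data/recoding_*.yaml``, including the named alternative-coding variants.
State polarity convention throughout: for presence/absence characters,
code 0 = present/developed, 1 = absent/not developed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .matrix_io import CharacterMatrix, MatrixError

__all__ = [
    "Override",
    "Collapse",
    "RecodingRuleSet",
    "collapse_states",
    "apply_overrides",
    "load_packaged_recoding",
    "apply_recoding",
    "RecodingError",
]

logger = logging.getLogger(__name__)


class RecodingError(ValueError):
    pass


@dataclass(frozen=True)
class Override:
    """One cell rewrite: taxon x character -> new entry.

    ``new`` is a frozenset of codes, or ``None`` for missing ("uncertain").
    ``group`` marks group-derived rules whose member list is configuration,
    not package data.
    """

    taxon: str
    character: "str | int"
    new: "frozenset[int] | None"
    provenance: str
    group: "str | None" = None


@dataclass(frozen=True)
class Collapse:
    character: "str | int"
    state_map: dict[int, int]
    provenance: str


@dataclass
class RecodingRuleSet:
    dataset: str
    collapses: list[Collapse] = field(default_factory=list)
    overrides: list[Override] = field(default_factory=list)
    variants: dict[str, list[Override]] = field(default_factory=dict)

    def with_variant(self, variant: "str | None") -> "RecodingRuleSet":
        """Overrides with a named variant's cells replacing the defaults."""
        if variant is None:
            return self
        if variant not in self.variants:
            raise RecodingError(
                f"unknown variant {variant!r}; have {sorted(self.variants)}"
            )
        replaced = {(o.taxon, o.character) for o in self.variants[variant]}
        merged = [
            o for o in self.overrides if (o.taxon, o.character) not in replaced
        ] + self.variants[variant]
        return RecodingRuleSet(
            dataset=self.dataset, collapses=list(self.collapses),
            overrides=merged, variants=dict(self.variants),
        )


# ------------------------------------------------------------- operations


def collapse_states(
    matrix: CharacterMatrix,
    character: "str | int",
    state_map: dict[int, int],
) -> CharacterMatrix:
    """Merge states of one character under ``state_map``.

    Uncertainty sets are mapped elementwise and deduplicated; a set whose
    image is a single code becomes that code.  Every observed code must be
    mapped.
    """
    c = matrix.char_index(character)
    out = matrix.copy()
    observed: set[int] = set()
    for row in matrix.states:
        if row[c] is not None:
            observed |= row[c]
    unmapped = observed - set(state_map)
    if unmapped:
        raise RecodingError(
            f"state_map for character {c + 1} misses observed codes {sorted(unmapped)}"
        )
    new_k = max(state_map.values(), default=0) + 1
    out.k[c] = max(new_k, 2)
    for i, row in enumerate(out.states):
        if row[c] is None:
            continue
        image = frozenset(state_map[s] for s in row[c])
        row[c] = image
        if len(image) == 1:
            out.polymorphic.discard((i, c))
    out.validate()
    return out


def apply_overrides(
    matrix: CharacterMatrix, rules: "list[Override]"
) -> CharacterMatrix:
    """Rewrite cells exactly as listed, logging (taxon, char, old, new, why).

    Overrides naming a taxon absent from this matrix produce a warning, not
    a failure: the two source data sets have different taxon coverage and
    share one rule vocabulary.
    """
    out = matrix.copy()
    for rule in rules:
        if rule.group and not rule.taxon:
            logger.warning(
                "group-derived rule %r has no member taxa configured; skipped",
                rule.group,
            )
            continue
        if rule.taxon not in out.taxa:
            logger.warning(
                "override target %r absent from this matrix; skipped", rule.taxon
            )
            continue
        i = out.taxa.index(rule.taxon)
        c = out.char_index(rule.character)
        old = out.states[i][c]
        if rule.new is not None:
            bad = {s for s in rule.new if s >= out.k[c] or s < 0}
            if bad:
                raise RecodingError(
                    f"override ({rule.taxon}, char {c + 1}) uses codes {bad} "
                    f"outside 0..{out.k[c] - 1}"
                )
        out.states[i][c] = rule.new
        if rule.new is None or len(rule.new) == 1:
            out.polymorphic.discard((i, c))
        logger.info(
            "recode %s char %d: %s -> %s (%s)",
            rule.taxon, c + 1,
            "?" if old is None else sorted(old),
            "?" if rule.new is None else sorted(rule.new),
            rule.provenance,
        )
    out.validate()
    return out


def apply_recoding(
    matrix: CharacterMatrix,
    rules: RecodingRuleSet,
    variant: "str | None" = None,
) -> CharacterMatrix:
    """Collapses first, then overrides (optionally with a named variant)."""
    rules = rules.with_variant(variant)
    out = matrix
    for col in rules.collapses:
        try:
            out = collapse_states(out, col.character, col.state_map)
        except MatrixError as exc:
            raise RecodingError(str(exc)) from exc
    return apply_overrides(out, rules.overrides)


# ------------------------------------------------------- packaged rule sets


def _parse_entry(value) -> "frozenset[int] | None":
    if value is None or value == "?":
        return None
    if isinstance(value, int):
        return frozenset({value})
    if isinstance(value, (list, tuple, set)):
        return frozenset(int(v) for v in value)
    raise RecodingError(f"cannot interpret override value {value!r}")


def _parse_overrides(raw: list, dataset: str) -> list[Override]:
    out = []
    for item in raw:
        out.append(
            Override(
                taxon=item.get("taxon", ""),
                character=item["character"],
                new=_parse_entry(item.get("new")),
                provenance=item.get("provenance", f"packaged rule ({dataset})"),
                group=item.get("group"),
            )
        )
    return out


def load_packaged_recoding(dataset_id: str) -> RecodingRuleSet:
    """Load the packaged middle-ear re-scoring rules for ``ds21`` or ``ds22``."""
    if dataset_id not in ("ds21", "ds22"):
        raise RecodingError(f"unknown dataset id {dataset_id!r}")
    ref = resources.files("osteoasr.data") / f"recoding_{dataset_id}.yaml"
    raw = yaml.safe_load(ref.read_text())
    collapses = [
        Collapse(
            character=c["character"],
            state_map={int(a): int(b) for a, b in c["state_map"].items()},
            provenance=c.get("provenance", ""),
        )
        for c in raw.get("collapse", [])
    ]
    overrides = _parse_overrides(raw.get("overrides", []), dataset_id)
    variants = {
        name: _parse_overrides(items, dataset_id)
        for name, items in (raw.get("variants") or {}).items()
    }
    return RecodingRuleSet(
        dataset=dataset_id, collapses=collapses,
        overrides=overrides, variants=variants,
    )
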
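"""The Knowledge Model: declarative relationship types and their expansion.

A relationship is a (Modulator, Source, Target) triple: the Source biomarker
stimulates or suppresses the Target, optionally modulated by the Modulator.
An absent Modulator (the ``n.a.`` sentinel) makes the relationship linear in
the source concentration; a present one makes it bi-linear
(``x_modulator * x_source``).  Relationship *types* state which biomarker
class may fill each role, whether cellular roles must share one cell
(autocrine only — paracrine signalling is excluded, except that a cell may
modulate a different cell when the target is a cytokine), and whether the
``n.a.`` modulator is admitted as an additional, non-biomarker modulation.

The default seven-type rule table expands the 35-cytokine / 15-cell study
panel into 28,605 relationships:

====  ===========================  ========================  =======
type  modulator                    source -> target          count
====  ===========================  ========================  =======
R1    cytokine                     cell -> cytokine          18,375
R2    cell (may differ)            cell -> cytokine           7,875
R3    target cell itself or n.a.   cytokine -> cell           1,050
R4    cytokine or n.a.             cell -> same cell            540
R5    n.a.                         cell -> cytokine             525
R6    n.a.                         cell -> cell                 225
R7    the cell itself              cell -> same cell             15
====  ===========================  ========================  =======

Relationship identity is per (type, modulator, source, target): the 15
unmodulated autocrine loops (n.a., c, c) appear both as the n.a. variant of
R4 and as the self-pairs of R6, and are kept as distinct model entries (and
hence distinct system-matrix columns).  `validate_model` reports these
cross-type collisions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .panel import BiomarkerClass, Panel

__all__ = [
    "NA",
    "ModulatorDomain",
    "CellConstraint",
    "RelationshipType",
    "Relationship",
    "KnowledgeModel",
    "default_ruleset",
    "load_ruleset",
    "save_ruleset",
    "enumerate_relationships",
    "validate_model",
]

#: Sentinel biomarker name for an absent (non-biomarker) modulator.
NA = "n.a."


class ModulatorDomain(str, enum.Enum):
    CYTOKINE = "cytokine"
    CELL = "cell"
    NONE = "none"                    # n.a. only -> linear relationships
    CYTOKINE_OR_NONE = "cytokine_or_none"
    CELL_OR_NONE = "cell_or_none"


class CellConstraint(str, enum.Enum):
    #: no tying between cellular roles
    NONE = "none"
    #: every cellular role must name the same cell (autocrine)
    ALL_CELL_ROLES_SAME = "all_cell_roles_same"


@dataclass(frozen=True)
class RelationshipType:
    """One row of the rule table: a class signature for relationships."""

    type_id: str
    modulator_domain: ModulatorDomain
    source_domain: BiomarkerClass
    target_domain: BiomarkerClass
    same_cell_constraint: CellConstraint = CellConstraint.NONE
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "modulator_domain",
                           ModulatorDomain(self.modulator_domain))
        object.__setattr__(self, "source_domain",
                           BiomarkerClass(self.source_domain))
        object.__setattr__(self, "target_domain",
                           BiomarkerClass(self.target_domain))
        object.__setattr__(self, "same_cell_constraint",
                           CellConstraint(self.same_cell_constraint))
        if (self.source_domain is not BiomarkerClass.CELL
                and self.target_domain is not BiomarkerClass.CELL):
            raise ValueError(
                f"type {self.type_id!r}: a cell is required as source or "
                "target")


@dataclass(frozen=True)
class Relationship:
    """One enumerated relationship; ``modulator == NA`` means linear."""

    index: int
    type_id: str
    modulator: str
    source: str
    target: str
    kind: str  # "linear" | "bilinear"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.modulator, self.source, self.target)


def default_ruleset() -> list[RelationshipType]:
    """The shipped seven-type rule table (see module docstring)."""
    C = BiomarkerClass
    M = ModulatorDomain
    S = CellConstraint
    return [
        RelationshipType("R1", M.CYTOKINE, C.CELL, C.CYTOKINE, S.NONE,
                         "cytokine-modulated cell source driving a cytokine"),
        RelationshipType("R2", M.CELL, C.CELL, C.CYTOKINE, S.NONE,
                         "cell-modulated cell source driving a cytokine; the "
                         "modulator cell may differ from the source cell "
                         "because the target is a cytokine"),
        RelationshipType("R3", M.CELL_OR_NONE, C.CYTOKINE, C.CELL,
                         S.ALL_CELL_ROLES_SAME,
                         "a cytokine drives a cell, modulated by that same "
                         "cell (feedback) or unmodulated (n.a.)"),
        RelationshipType("R4", M.CYTOKINE_OR_NONE, C.CELL, C.CELL,
                         S.ALL_CELL_ROLES_SAME,
                         "autocrine self-action of a cell, cytokine-"
                         "modulated or unmodulated (n.a.)"),
        RelationshipType("R5", M.NONE, C.CELL, C.CYTOKINE, S.NONE,
                         "unmodulated cell source driving a cytokine"),
        RelationshipType("R6", M.NONE, C.CELL, C.CELL, S.NONE,
                         "unmodulated cell source driving a cell"),
        RelationshipType("R7", M.CELL, C.CELL, C.CELL,
                         S.ALL_CELL_ROLES_SAME,
                         "fully autocrine loop: a cell modulates its own "
                         "self-action"),
    ]


def load_ruleset(source: str | Path) -> list[RelationshipType]:
    """Load relationship types from a YAML rule table."""
    with open(source, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError("rule table must be a non-empty list of types")
    types = []
    for rec in raw:
        try:
            types.append(RelationshipType(
                type_id=str(rec["type_id"]),
                modulator_domain=rec["modulator_domain"],
                source_domain=rec["source_domain"],
                target_domain=rec["target_domain"],
                same_cell_constraint=rec.get("same_cell_constraint", "none"),
                notes=str(rec.get("notes", "")),
            ))
        except KeyError as exc:
            raise ValueError(f"rule record missing field {exc}") from exc
    ids = [t.type_id for t in types]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate type_id in rule table")
    return types


def save_ruleset(types: Sequence[RelationshipType], path: str | Path) -> None:
    recs = [{
        "type_id": t.type_id,
        "modulator_domain": t.modulator_domain.value,
        "source_domain": t.source_domain.value,
        "target_domain": t.target_domain.value,
        "same_cell_constraint": t.same_cell_constraint.value,
        "notes": t.notes,
    } for t in types]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(recs, fh, sort_keys=False)


class KnowledgeModel:
    """The expanded, canonically ordered relationship list for one panel."""

    def __init__(self, panel: Panel, ruleset: Sequence[RelationshipType],
                 relationships: Sequence[Relationship]):
        self.panel = panel
        self.ruleset = list(ruleset)
        self.relationships = list(relationships)
        self._by_full_key = {
            (r.type_id, r.modulator, r.source, r.target): r
            for r in self.relationships}
        # index arrays for vectorized system assembly
        idx = panel._index
        self.modulator_idx = np.array(
            [-1 if r.modulator == NA else idx[r.modulator]
             for r in self.relationships], dtype=np.int64)
        self.source_idx = np.array(
            [idx[r.source] for r in self.relationships], dtype=np.int64)
        self.target_idx = np.array(
            [idx[r.target] for r in self.relationships], dtype=np.int64)
        self.is_linear = self.modulator_idx < 0
        # map (M, S, T) -> list of column indices (>1 only for cross-type
        # collisions, i.e. duplicate system-matrix columns)
        groups: dict[tuple[str, str, str], list[int]] = {}
        for j, r in enumerate(self.relationships):
            groups.setdefault(r.key, []).append(j)
        self.triple_groups = groups

    def __len__(self) -> int:
        return len(self.relationships)

    @property
    def n_distinct_triples(self) -> int:
        return len(self.triple_groups)

    @property
    def duplicate_triples(self) -> dict[tuple[str, str, str], list[int]]:
        return {k: v for k, v in self.triple_groups.items() if len(v) > 1}

    def by_target(self, target: str) -> list[Relationship]:
        t = self.panel.index(target)
        return [self.relationships[j]
                for j in np.nonzero(self.target_idx == t)[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": [r.index for r in self.relationships],
            "type_id": [r.type_id for r in self.relationships],
            "modulator": [r.modulator for r in self.relationships],
            "source": [r.source for r in self.relationships],
            "target": [r.target for r in self.relationships],
            "kind": [r.kind for r in self.relationships],
        })


def _expand_type(t: RelationshipType, panel: Panel):
    cells = panel.cells
    cyts = panel.cytokines
    sources = cyts if t.source_domain is BiomarkerClass.CYTOKINE else cells
    targets = cyts if t.target_domain is BiomarkerClass.CYTOKINE else cells
    tie = t.same_cell_constraint is CellConstraint.ALL_CELL_ROLES_SAME

    def modulators(s: str, tgt: str):
        md = t.modulator_domain
        if md is ModulatorDomain.NONE:
            return (NA,)
        if md is ModulatorDomain.CYTOKINE:
            return cyts
        if md is ModulatorDomain.CYTOKINE_OR_NONE:
            return (*cyts, NA)
        # cell-domain modulators: under the same-cell tie the modulator must
        # equal the cellular source/target
        cell_roles = [b for b in (s, tgt) if panel.klass_of(b)
                      is BiomarkerClass.CELL]
        if md is ModulatorDomain.CELL:
            if tie:
                return (cell_roles[0],) if len(set(cell_roles)) == 1 else ()
            return cells
        if md is ModulatorDomain.CELL_OR_NONE:
            if tie:
                base = (cell_roles[0],) if len(set(cell_roles)) == 1 else ()
                return (*base, NA)
            return (*cells, NA)
        raise AssertionError(md)

    for s in sources:
        for tgt in targets:
            if tie:
                # source/target cellular roles must coincide
                sc = panel.klass_of(s) is BiomarkerClass.CELL
                tc = panel.klass_of(tgt) is BiomarkerClass.CELL
                if sc and tc and s != tgt:
                    continue
            for m in modulators(s, tgt):
                yield m, s, tgt


def enumerate_relationships(
    panel: Panel, ruleset: Sequence[RelationshipType] | None = None
) -> KnowledgeModel:
    """Expand every type over the panel into the canonical relationship list.

    Order is deterministic: by type (rule-table order), then modulator,
    source, target in panel order (``n.a.`` modulators first).  Duplicates
    within a type are impossible by construction; the same (M, S, T) triple
    generated by two *different* types is retained under both (distinct
    model entries, hence distinct system-matrix columns).
    """
    if ruleset is None:
        ruleset = default_ruleset()
    order = {n: i for i, n in enumerate(panel.names)}
    order[NA] = -1
    rels: list[Relationship] = []
    for t in ruleset:
        triples = sorted(set(_expand_type(t, panel)),
                         key=lambda mst: (order[mst[0]], order[mst[1]],
                                          order[mst[2]]))
        for m, s, tgt in triples:
            rels.append(Relationship(
                index=len(rels), type_id=t.type_id, modulator=m, source=s,
                target=tgt, kind="linear" if m == NA else "bilinear"))
    return KnowledgeModel(panel, ruleset, rels)


@dataclass
class ValidationReport:
    per_type_counts: dict[str, int]
    total: int
    n_distinct_triples: int
    n_cross_type_collisions: int
    expected_total: int | None
    passed: bool
    delta: int | None

    def __str__(self) -> str:
        lines = [f"  {tid}: {n}" for tid, n in self.per_type_counts.items()]
        status = ("" if self.expected_total is None else
                  f"\nexpected {self.expected_total}: "
                  f"{'PASS' if self.passed else f'FAIL (delta {self.delta})'}")
        return (f"knowledge model: {self.total} relationships "
                f"({self.n_distinct_triples} distinct triples, "
                f"{self.n_cross_type_collisions} cross-type collisions)\n"
                + "\n".join(lines) + status)


def validate_model(
    km: KnowledgeModel, expected_total: int | None = None
) -> ValidationReport:
    """Report per-type counts and check the total against an expectation."""
    counts: dict[str, int] = {t.type_id: 0 for t in km.ruleset}
    for r in km.relationships:
        counts[r.type_id] += 1
    total = len(km)
    collisions = sum(len(v) - 1 for v in km.duplicate_triples.values())
    passed = expected_total is None or total == expected_total
    delta = None if expected_total is None else total - expected_total
    return ValidationReport(counts, total, km.n_distinct_triples, collisions,
                            expected_total, passed, delta)
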
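"""Frame-based object model: categories, slots, facets and instances.

The model follows the frame paradigm: *categories* (classes) carry
*template slots*; *slots* are constrained by *facets* (cardinality,
minimum/maximum, defaults, allowed values); *instances* carry slot values.
Every project is built on a bootstrapped *task ontology* (TO) — the
application-generic category system for study metadata — into which an
organization-specific *domain ontology* (DO: Study, Module, Item, ...) is
embedded as subcategories.  Category names of the task ontology start with
an underscore; configuration categories (``_CONFIG`` and descendants) are
hidden from end users.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from .errors import (
    DuplicateNameError,
    HiddenParentError,
    ModelError,
    UnknownEntityError,
    ValueKindError,
)

VALUE_KINDS = frozenset(
    {"string", "number", "boolean", "instance_ref", "concept_ref", "expression_ref"}
)

LAYERS = ("TLO", "TO", "DO")

#: slot on annotation records listing the annotated element conditions
ANNOTATED_ELEMENTS_SLOT = "_annotated_elements"
ANNOTATION_TYPE_SLOT = "_annotation_type"
ANNOTATING_CONCEPTS_SLOT = "_annotating_concepts"
ANNOTATIONS_SLOT = "_annotations"
CONTAINS_SLOT = "_contains"


def _is_number(value: Any) -> bool:
    return isinstance(value, numbers.Real) and not isinstance(value, bool)


@dataclass
class FacetSet:
    """Constraints on a slot: numeric bounds, default, allowed categories/values."""

    minimum: Optional[float] = None
    maximum: Optional[float] = None
    default: Any = None
    allowed_categories: Optional[list[str]] = None
    allowed_values: Optional[list] = None

    def __post_init__(self):
        if self.minimum is not None and self.maximum is not None:
            if self.minimum > self.maximum:
                raise ModelError(
                    f"facet minimum {self.minimum} exceeds maximum {self.maximum}"
                )
        if self.default is not None and not self.value_ok(self.default):
            raise ModelError(f"facet default {self.default!r} violates other facets")

    def value_ok(self, value: Any) -> bool:
        """True iff *value* satisfies the numeric-bound and allowed-value facets."""
        if self.minimum is not None and _is_number(value) and value < self.minimum:
            return False
        if self.maximum is not None and _is_number(value) and value > self.maximum:
            return False
        if self.allowed_values is not None and value not in self.allowed_values:
            return False
        return True

    def is_trivial(self) -> bool:
        return (
            self.minimum is None
            and self.maximum is None
            and self.default is None
            and self.allowed_categories is None
            and self.allowed_values is None
        )

    def to_dict(self) -> dict:
        out: dict = {}
        for key in ("minimum", "maximum", "default", "allowed_categories", "allowed_values"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "FacetSet":
        return cls(**data)


@dataclass
class SlotDefinition:
    """A named property with a value kind, cardinality bounds and facets.

    ``cardinality_max`` of ``None`` means unbounded.  ``inverse_of`` may name
    another slot of kind ``instance_ref`` or ``concept_ref``.
    """

    name: str
    value_kind: str = "string"
    cardinality_min: int = 0
    cardinality_max: Optional[int] = 1
    facets: FacetSet = field(default_factory=FacetSet)
    inverse_of: Optional[str] = None

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ModelError(f"unknown value kind {self.value_kind!r} on slot {self.name!r}")
        if self.cardinality_min < 0:
            raise ModelError(f"slot {self.name!r}: cardinality_min must be >= 0")
        if self.cardinality_max is not None and self.cardinality_min > self.cardinality_max:
            raise ModelError(
                f"slot {self.name!r}: cardinality_min {self.cardinality_min} "
                f"exceeds cardinality_max {self.cardinality_max}"
            )

    def value_kind_ok(self, value: Any) -> bool:
        kind = self.value_kind
        if kind == "string":
            return isinstance(value, str)
        if kind == "number":
            return _is_number(value)
        if kind == "boolean":
            return isinstance(value, bool)
        # references and expression text are carried as strings
        return isinstance(value, str)

    def to_dict(self) -> dict:
        out: dict = {"name": self.name, "value_kind": self.value_kind}
        if self.cardinality_min != 0:
            out["cardinality_min"] = self.cardinality_min
        out["cardinality_max"] = self.cardinality_max
        if not self.facets.is_trivial():
            out["facets"] = self.facets.to_dict()
        if self.inverse_of is not None:
            out["inverse_of"] = self.inverse_of
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SlotDefinition":
        data = dict(data)
        if "facets" in data:
            data["facets"] = FacetSet.from_dict(data["facets"])
        data.setdefault("cardinality_max", 1)
        return cls(**data)


@dataclass
class CategoryDef:
    """A named class in the TO/DO tree.

    ``layer`` records the ontological stratum (top-level, task or domain
    ontology); ``hidden`` marks configuration categories invisible to end
    users; ``abstract`` categories cannot be instantiated; ``template_slots``
    lists slot names (definitions live in the model-wide slot registry and
    are inherited down the parent chain).
    """

    name: str
    parent: Optional[str] = None
    layer: str = "DO"
    hidden: bool = False
    abstract: bool = False
    template_slots: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ModelError(f"unknown layer {self.layer!r} on category {self.name!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parent": self.parent,
            "layer": self.layer,
            "hidden": self.hidden,
            "abstract": self.abstract,
            "template_slots": list(self.template_slots),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CategoryDef":
        return cls(**data)


@dataclass
class InstanceRecord:
    """An identified instance of a category carrying slot values.

    All slot values are ordered lists, even for single-valued slots; order is
    preserved across save/load.
    """

    id: str
    category: str
    slot_values: dict[str, list] = field(default_factory=dict)

    def first(self, slot: str, default: Any = None) -> Any:
        values = self.slot_values.get(slot)
        return values[0] if values else default

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "category": self.category,
            "slot_values": {k: list(v) for k, v in self.slot_values.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InstanceRecord":
        return cls(
            id=data["id"],
            category=data["category"],
            slot_values={k: list(v) for k, v in data.get("slot_values", {}).items()},
        )


@dataclass
class Violation:
    """One breached constraint; violations are data, not exceptions."""

    kind: str  # missing-value | too-many-values | facet | value-kind | dangling-ref | hierarchy | unlicensed-edge
    message: str
    instance: Optional[str] = None
    slot: Optional[str] = None
    edge: Optional[tuple] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = self.instance or (f"{self.edge[0]}->{self.edge[1]}" if self.edge else "")
        return f"[{self.kind}] {where}: {self.message}"


class OntologyModel:
    """The whole project: categories, slots, instances, containment, config.

    Mutating operations live in the sibling modules (``hierarchy``,
    ``annotation``, ``mapping``); this class provides the registries and the
    navigation primitives they share.
    """

    FORMAT_VERSION = "1.0"

    def __init__(self):
        self.categories: dict[str, CategoryDef] = {}
        self.slots: dict[str, SlotDefinition] = {}
        self.instances: dict[str, InstanceRecord] = {}
        # containment forest; edge objects live in hierarchy.ContainsEdge
        self.contains_edges: list = []
        self.hierarchy_rules: list = []
        self.mappings: dict = {}  # name -> FormatMapping
        self.concepts: dict = {}  # concept id -> annotation.Concept
        self.annotations: dict = {}  # annotation id -> annotation.Annotation
        # inverse index realizing the _annotations slot: concept id -> [annotation ids]
        self.concept_annotations: dict[str, list[str]] = {}
        self.extras: dict = {}  # unknown top-level fields, preserved on save
        self._next_id = 1

    # -- category / slot registry -------------------------------------------------

    def add_category(self, cat: CategoryDef) -> CategoryDef:
        if cat.name in self.categories:
            raise DuplicateNameError(f"category {cat.name!r} already defined")
        if cat.parent is not None and cat.parent not in self.categories:
            raise UnknownEntityError(f"unknown parent category {cat.parent!r}")
        self.categories[cat.name] = cat
        return cat

    def category(self, name: str) -> CategoryDef:
        try:
            return self.categories[name]
        except KeyError:
            raise UnknownEntityError(f"unknown category {name!r}") from None

    def add_slot(self, slot: SlotDefinition) -> SlotDefinition:
        existing = self.slots.get(slot.name)
        if existing is not None:
            # identical re-declarations are harmless (shared DO slots);
            # conflicting ones would silently change semantics elsewhere
            if existing.to_dict() != slot.to_dict():
                raise DuplicateNameError(
                    f"slot {slot.name!r} already defined with a different definition"
                )
            return existing
        if slot.inverse_of is not None:
            target = self.slots.get(slot.inverse_of)
            if target is None:
                raise UnknownEntityError(
                    f"inverse_of names unknown slot {slot.inverse_of!r}"
                )
            if target.value_kind not in ("instance_ref", "concept_ref"):
                raise ModelError(
                    f"inverse_of target {slot.inverse_of!r} must be a reference slot"
                )
        self.slots[slot.name] = slot
        return slot

    def slot(self, name: str) -> SlotDefinition:
        try:
            return self.slots[name]
        except KeyError:
            raise UnknownEntityError(f"unknown slot {name!r}") from None

    def ancestors(self, category_name: str) -> list[str]:
        """Parent chain of *category_name*, nearest first, excluding itself."""
        out = []
        current = self.category(category_name).parent
        seen = {category_name}
        while current is not None:
            if current in seen:
                raise ModelError(f"category parent cycle at {current!r}")
            seen.add(current)
            out.append(current)
            current = self.category(current).parent
        return out

    def descends_from(self, category_name: str, ancestor: str) -> bool:
        """True iff *category_name* is *ancestor* or one of its descendants."""
        return category_name == ancestor or ancestor in self.ancestors(category_name)

    def children_categories(self, name: str) -> list[str]:
        return [c.name for c in self.categories.values() if c.parent == name]

    def effective_slots(self, category_name: str) -> list[SlotDefinition]:
        """Template slots of the category and all ancestors, ancestor-first."""
        chain = list(reversed(self.ancestors(category_name))) + [category_name]
        names: list[str] = []
        for cat in chain:
            for slot_name in self.category(cat).template_slots:
                if slot_name not in names:
                    names.append(slot_name)
        return [self.slot(n) for n in names]

    def effective_slot_map(self, category_name: str) -> dict[str, SlotDefinition]:
        return {s.name: s for s in self.effective_slots(category_name)}

    # -- instances ----------------------------------------------------------------

    def instance(self, instance_id: str) -> InstanceRecord:
        try:
            return self.instances[instance_id]
        except KeyError:
            raise UnknownEntityError(f"unknown instance {instance_id!r}") from None

    def instance_of(self, inst: InstanceRecord, category_name: str) -> bool:
        """Instantiation with subcategory closure: ``x :: Cat`` counts
        instances of Cat's subcategories too."""
        return self.descends_from(inst.category, category_name)

    def instances_of(self, category_name: str) -> list[InstanceRecord]:
        return [
            inst
            for inst in self.instances.values()
            if self.descends_from(inst.category, category_name)
        ]

    def fresh_id(self, category_name: str) -> str:
        """Deterministic opaque id from a per-model counter (no timestamps)."""
        prefix = category_name.lstrip("_").lower() or "x"
        out = f"{prefix}-{self._next_id:05d}"
        self._next_id += 1
        return out

    def find_by_slot(self, category_name: str, slot: str, value: Any) -> Optional[InstanceRecord]:
        for inst in self.instances_of(category_name):
            if value in inst.slot_values.get(slot, ()):
                return inst
        return None


# ---------------------------------------------------------------------------
# Task-ontology bootstrap
# ---------------------------------------------------------------------------

#: children of _ELEMENT, the visible study-element roots
ELEMENT_SUBCLASSES = ("_CONSTANT", "_OBJECT", "_GROUP", "_ANNOTATION", "_EXPORT")


def bootstrap_task_ontology() -> OntologyModel:
    """Build the task ontology every project starts from.

    Top-level classes: ``_CONFIG`` (hidden configuration: format mappings and
    annotation types), ``_ELEMENT`` (visible study elements: constants,
    objects, groups, annotations, export formats), ``_ANNOTATING_ONTOLOGY_ROOT``
    (external ontologies are inserted below it) and the ``_MATH`` subtree used
    by the expression engine.  Also registers the shared TO slots, including
    ``_annotations`` as the inverse of ``_annotating_concepts``.
    """
    m = OntologyModel()

    def cat(name, parent=None, *, hidden=False, abstract=False, slots=()):
        m.add_category(
            CategoryDef(
                name=name,
                parent=parent,
                layer="TO",
                hidden=hidden,
                abstract=abstract,
                template_slots=list(slots),
            )
        )

    cat("_ELEMENT", abstract=True)
    for child in ELEMENT_SUBCLASSES:
        cat(child, "_ELEMENT", abstract=True)

    cat("_CONFIG", hidden=True, abstract=True)
    cat("_FORMAT_MAPPING", "_CONFIG", hidden=True)
    cat("_ROOT_TAG", "_FORMAT_MAPPING", hidden=True)
    cat("_TAG", "_FORMAT_MAPPING", hidden=True)
    cat("_ANNOTATION_TYPE", "_CONFIG", hidden=True)

    cat("_ANNOTATING_ONTOLOGY_ROOT", abstract=True)

    cat("_MATH", abstract=True)
    cat("_MATH_EXPRESSION_RELATOR", "_MATH")
    cat("_NUMBER", "_MATH")
    cat("_STUDY_ELEMENT", "_MATH")

    m.add_slot(SlotDefinition(CONTAINS_SLOT, "instance_ref", cardinality_max=None))
    m.add_slot(
        SlotDefinition(ANNOTATED_ELEMENTS_SLOT, "instance_ref", 1, None)
    )
    m.add_slot(SlotDefinition(ANNOTATION_TYPE_SLOT, "instance_ref", 1, 1))
    m.add_slot(
        SlotDefinition(ANNOTATING_CONCEPTS_SLOT, "concept_ref", 1, None)
    )
    m.add_slot(
        SlotDefinition(
            ANNOTATIONS_SLOT,
            "instance_ref",
            cardinality_max=None,
            inverse_of=ANNOTATING_CONCEPTS_SLOT,
        )
    )
    m.category("_ANNOTATION").template_slots.extend(
        [ANNOTATED_ELEMENTS_SLOT, ANNOTATION_TYPE_SLOT, ANNOTATING_CONCEPTS_SLOT]
    )
    m.category("_GROUP").template_slots.append(CONTAINS_SLOT)
    m.add_slot(SlotDefinition("name", "string", cardinality_max=1))
    m.category("_ANNOTATION_TYPE").template_slots.append("name")
    return m


def define_category(
    model: OntologyModel,
    name: str,
    parent: str,
    slots: Iterable[SlotDefinition] = (),
    *,
    allow_hidden_parent: bool = False,
) -> CategoryDef:
    """Define a domain-ontology category under an existing parent.

    The new category sits at layer DO, inherits the parent's template slots
    (through :meth:`OntologyModel.effective_slots`) and adds its own.  Study
    elements may not be placed under hidden (configuration) parents.
    """
    if name in model.categories:
        raise DuplicateNameError(f"category {name!r} already defined")
    parent_cat = model.category(parent)
    if parent_cat.hidden and not allow_hidden_parent:
        raise HiddenParentError(
            f"cannot place study-element category {name!r} under hidden parent {parent!r}"
        )
    slot_names = []
    for slot in slots:
        model.add_slot(slot)
        slot_names.append(slot.name)
    return model.add_category(
        CategoryDef(
            name=name,
            parent=parent,
            layer="DO",
            hidden=parent_cat.hidden,
            template_slots=slot_names,
        )
    )


def create_instance(
    model: OntologyModel, category: str, slot_values: Optional[dict] = None
) -> InstanceRecord:
    """Instantiate a category; values are checked against slot value kinds.

    Scalars are wrapped into single-element lists.  Strings that parse as
    numbers are NOT coerced — the value kind is authoritative, so codelist
    codes like ``"01"`` survive round-trips.
    """
    cat = model.category(category)
    if cat.abstract:
        raise ModelError(f"category {category!r} is abstract and cannot be instantiated")
    slot_map = model.effective_slot_map(category)
    values: dict[str, list] = {}
    for slot_name, raw in (slot_values or {}).items():
        if slot_name not in slot_map:
            raise UnknownEntityError(
                f"category {category!r} has no slot {slot_name!r}"
            )
        slot = slot_map[slot_name]
        as_list = list(raw) if isinstance(raw, (list, tuple)) else [raw]
        for v in as_list:
            if not slot.value_kind_ok(v):
                raise ValueKindError(
                    f"value {v!r} does not match kind {slot.value_kind!r} of slot {slot_name!r}"
                )
        values[slot_name] = as_list
    inst = InstanceRecord(id=model.fresh_id(category), category=category, slot_values=values)
    model.instances[inst.id] = inst
    return inst


def validate_instance(model: OntologyModel, instance: InstanceRecord) -> list[Violation]:
    """Check an instance against its category's slots; never mutates the model.

    Returns one :class:`Violation` per breached cardinality bound, facet, or
    dangling reference; an empty list iff the instance is conformant.
    """
    violations: list[Violation] = []
    slot_map = model.effective_slot_map(instance.category)
    for slot in slot_map.values():
        values = instance.slot_values.get(slot.name, [])
        if len(values) < slot.cardinality_min:
            violations.append(
                Violation(
                    "missing-value",
                    f"slot {slot.name!r} requires at least {slot.cardinality_min} value(s), "
                    f"found {len(values)}",
                    instance=instance.id,
                    slot=slot.name,
                )
            )
        if slot.cardinality_max is not None and len(values) > slot.cardinality_max:
            violations.append(
                Violation(
                    "too-many-values",
                    f"slot {slot.name!r} allows at most {slot.cardinality_max} value(s), "
                    f"found {len(values)}",
                    instance=instance.id,
                    slot=slot.name,
                )
            )
        for v in values:
            if not slot.value_kind_ok(v):
                violations.append(
                    Violation(
                        "value-kind",
                        f"value {v!r} does not match kind {slot.value_kind!r}",
                        instance=instance.id,
                        slot=slot.name,
                    )
                )
                continue
            if not slot.facets.value_ok(v):
                violations.append(
                    Violation(
                        "facet",
                        f"value {v!r} violates facets of slot {slot.name!r}",
                        instance=instance.id,
                        slot=slot.name,
                    )
                )
            if slot.value_kind == "instance_ref" and v not in model.instances:
                violations.append(
                    Violation(
                        "dangling-ref",
                        f"instance reference {v!r} does not resolve",
                        instance=instance.id,
                        slot=slot.name,
                    )
                )
            if slot.value_kind == "concept_ref" and v not in model.concepts:
                violations.append(
                    Violation(
                        "dangling-ref",
                        f"concept reference {v!r} does not resolve",
                        instance=instance.id,
                        slot=slot.name,
                    )
                )
    for slot_name in instance.slot_values:
        if slot_name not in slot_map:
            violations.append(
                Violation(
                    "value-kind",
                    f"category {instance.category!r} has no slot {slot_name!r}",
                    instance=instance.id,
                    slot=slot_name,
                )
            )
    return violations
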
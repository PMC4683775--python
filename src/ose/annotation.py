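"""Semantic annotation of study elements with external ontology concepts.

An *annotating ontology* (HPO, LOINC, ...) is loaded from an OBO flat file
and inserted below ``_ANNOTATING_ONTOLOGY_ROOT``.  An *annotation* links a
set of AND-connected element conditions to one or more concepts via a typed
relation (``symptom_of``, ``risk_factor_of``, ...).  A condition is an item
alone (presence), an item plus a codelist answer ("DYSPNEA_AT_REST = YES"),
or — for items without a codelist — an item plus an inclusive numeric range
("SYSTOLIC_BLOOD_PRESURE in [121;]", i.e. >= 121).

The concept → annotation direction (the ``_annotations`` inverse slot) is
maintained as an index on the model, so "all annotations of Congestive
heart failure, possibly including its subclasses" is a direct lookup.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Any, Optional, Union

import networkx as nx
import obonet

from .errors import AnnotationError, UnknownEntityError
from .frames import (
    ANNOTATING_CONCEPTS_SLOT,
    ANNOTATED_ELEMENTS_SLOT,
    ANNOTATION_TYPE_SLOT,
    CategoryDef,
    InstanceRecord,
    OntologyModel,
)

logger = logging.getLogger(__name__)

#: conventional DO slot names used to look up an item's codelist
CODELIST_SLOT = "codelist"
CODES_SLOT = "codes"


@dataclass
class Concept:
    """A term of an annotating ontology (id, label, is_a parents)."""

    id: str
    label: str
    parents: list[str] = field(default_factory=list)
    ontology: str = ""

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "label": self.label,
            "parents": list(self.parents),
            "ontology": self.ontology,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Concept":
        return cls(**data)


_RANGE_RE = re.compile(r"\[\s*([^;\[\]]*?)\s*;\s*([^;\[\]]*?)\s*\]\Z")


@dataclass
class RangeLiteral:
    """Inclusive numeric interval written ``[lower;upper]``; either bound
    may be omitted (``[121;]`` means >= 121), but not both."""

    lower: Optional[float] = None
    upper: Optional[float] = None
    text: str = ""

    def contains(self, value: float) -> bool:
        if self.lower is not None and value < self.lower:
            return False
        if self.upper is not None and value > self.upper:
            return False
        return True

    def format(self) -> str:
        def fmt(bound):
            if bound is None:
                return ""
            return repr(int(bound)) if float(bound).is_integer() else repr(bound)

        return f"[{fmt(self.lower)};{fmt(self.upper)}]"


def parse_range_literal(text: str) -> RangeLiteral:
    """Parse ``"[121;]"``-style literals; both bounds inclusive."""
    match = _RANGE_RE.match(text.strip())
    if not match:
        raise AnnotationError(f"malformed range literal {text!r}")
    raw_lower, raw_upper = match.groups()

    def bound(raw: str, side: str) -> Optional[float]:
        if raw == "":
            return None
        try:
            return int(raw) if re.fullmatch(r"[+-]?\d+", raw) else float(raw)
        except ValueError:
            raise AnnotationError(
                f"non-numeric {side} bound {raw!r} in range literal {text!r}"
            ) from None

    lower, upper = bound(raw_lower, "lower"), bound(raw_upper, "upper")
    if lower is None and upper is None:
        raise AnnotationError(f"range literal {text!r} has no bounds")
    if lower is not None and upper is not None and lower > upper:
        raise AnnotationError(f"range literal {text!r} has lower > upper")
    return RangeLiteral(lower=lower, upper=upper, text=text.strip())


@dataclass
class ElementCondition:
    """One AND-conjunct: an element, optionally restricted to a codelist
    answer or (codelist-free items only) a numeric range."""

    element: str
    code: Optional[str] = None
    range: Optional[RangeLiteral] = None

    def __post_init__(self):
        if self.code is not None and self.range is not None:
            raise AnnotationError("a condition may carry a code or a range, not both")

    def to_dict(self) -> dict:
        out: dict = {"element": self.element}
        if self.code is not None:
            out["code"] = self.code
        if self.range is not None:
            out["range"] = self.range.format()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ElementCondition":
        rng = parse_range_literal(data["range"]) if "range" in data else None
        return cls(element=data["element"], code=data.get("code"), range=rng)


@dataclass
class Annotation:
    """AND-connected element conditions linked to concepts via a typed relation."""

    id: str
    conditions: list[ElementCondition]
    annotation_type: str  # instance id of an _ANNOTATION_TYPE instance
    concepts: list[str]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "conditions": [c.to_dict() for c in self.conditions],
            "annotation_type": self.annotation_type,
            "concepts": list(self.concepts),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Annotation":
        return cls(
            id=data["id"],
            conditions=[ElementCondition.from_dict(c) for c in data["conditions"]],
            annotation_type=data["annotation_type"],
            concepts=list(data["concepts"]),
        )

    def slot_view(self) -> dict:
        """The annotation rendered as frame slots (for display/export)."""
        return {
            ANNOTATED_ELEMENTS_SLOT: [c.to_dict() for c in self.conditions],
            ANNOTATION_TYPE_SLOT: [self.annotation_type],
            ANNOTATING_CONCEPTS_SLOT: list(self.concepts),
        }


# -- annotating-ontology loading ------------------------------------------------


def _scan_duplicate_ids(text: str) -> Optional[str]:
    seen = set()
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term and line.startswith("id:"):
            term_id = line[3:].strip()
            if term_id in seen:
                return term_id
            seen.add(term_id)
    return None


def load_obo(
    model: OntologyModel,
    source: Union[str, io.TextIOBase],
    name: Optional[str] = None,
) -> int:
    """Load an OBO 1.2-style ontology below ``_ANNOTATING_ONTOLOGY_ROOT``.

    ``source`` is a path, OBO text, or an open stream.  Only ``id``, ``name``
    and ``is_a`` are honored; obsolete terms are skipped; a term lacking a
    name gets its id as label.  Duplicate ids and ``is_a`` cycles are errors.
    Returns the number of concepts loaded.
    """
    if isinstance(source, str):
        text = source if "[Term]" in source else open(source, encoding="utf-8").read()
    else:
        text = source.read()
    duplicate = _scan_duplicate_ids(text)
    if duplicate is not None:
        raise AnnotationError(f"duplicate term id {duplicate!r} in OBO input")
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise AnnotationError(f"is_a cycle in OBO input: {cycle}")
    ontology_name = name or graph.graph.get("ontology") or "annotating-ontology"
    if ontology_name not in model.categories:
        model.add_category(
            CategoryDef(
                name=ontology_name,
                parent="_ANNOTATING_ONTOLOGY_ROOT",
                layer="DO",
            )
        )
    count = 0
    for term_id in graph.nodes:
        if term_id in model.concepts:
            raise AnnotationError(f"term id {term_id!r} already loaded")
        data = graph.nodes[term_id]
        parents = [
            v for _, v, key in graph.out_edges(term_id, keys=True) if key == "is_a"
        ]
        model.concepts[term_id] = Concept(
            id=term_id,
            label=data.get("name", term_id),
            parents=sorted(parents),
            ontology=ontology_name,
        )
        count += 1
    logger.info("loaded %d concepts from ontology %s", count, ontology_name)
    return count


def concept_descendants(model: OntologyModel, concept_id: str) -> list[str]:
    """All is_a descendants of *concept_id* (excluding itself), sorted."""
    if concept_id not in model.concepts:
        raise UnknownEntityError(f"unknown concept {concept_id!r}")
    children: dict[str, list[str]] = {}
    for c in model.concepts.values():
        for p in c.parents:
            children.setdefault(p, []).append(c.id)
    out: set[str] = set()
    stack = list(children.get(concept_id, []))
    while stack:
        node = stack.pop()
        if node not in out:
            out.add(node)
            stack.extend(children.get(node, []))
    return sorted(out)


# -- annotation types and annotations -------------------------------------------


def define_annotation_type(model: OntologyModel, name: str) -> str:
    """Register a typed annotation relation (e.g. ``symptom_of``)."""
    for inst in model.instances_of("_ANNOTATION_TYPE"):
        if inst.first("name") == name:
            raise AnnotationError(f"annotation type {name!r} already defined")
    inst = InstanceRecord(
        id=model.fresh_id("_ANNOTATION_TYPE"),
        category="_ANNOTATION_TYPE",
        slot_values={"name": [name]},
    )
    model.instances[inst.id] = inst
    return inst.id


def annotation_type_by_name(model: OntologyModel, name: str) -> Optional[str]:
    for inst in model.instances_of("_ANNOTATION_TYPE"):
        if inst.first("name") == name:
            return inst.id
    return None


def codelist_values(model: OntologyModel, element: str) -> Optional[list[str]]:
    """Codes of the element's codelist, or None when it has none."""
    inst = model.instance(element)
    codelist_id = inst.first(CODELIST_SLOT)
    if codelist_id is None:
        return None
    return list(model.instance(codelist_id).slot_values.get(CODES_SLOT, []))


def _check_condition(model: OntologyModel, cond: ElementCondition) -> None:
    inst = model.instance(cond.element)
    if not model.descends_from(inst.category, "_ELEMENT"):
        raise AnnotationError(f"{cond.element!r} is not a study element")
    codes = codelist_values(model, cond.element)
    if cond.code is not None:
        if codes is None:
            raise AnnotationError(
                f"element {cond.element!r} has no codelist to take code {cond.code!r} from"
            )
        if cond.code not in codes:
            raise AnnotationError(
                f"code {cond.code!r} is not a member of the codelist of {cond.element!r} "
                f"(members: {codes})"
            )
    if cond.range is not None and codes is not None:
        raise AnnotationError(
            f"element {cond.element!r} has a codelist; ranges may only be annotated "
            "on codelist-free items"
        )


def create_annotation(
    model: OntologyModel,
    conditions: list[ElementCondition],
    annotation_type: str,
    concepts: list[str],
) -> Annotation:
    """Store an annotation and update the concept → annotation inverse index.

    ``annotation_type`` may be an ``_ANNOTATION_TYPE`` instance id or its name.
    """
    if not conditions:
        raise AnnotationError("an annotation needs at least one condition")
    if not concepts:
        raise AnnotationError("an annotation needs at least one concept")
    type_id = annotation_type
    if type_id not in model.instances:
        resolved = annotation_type_by_name(model, annotation_type)
        if resolved is None:
            raise UnknownEntityError(f"unknown annotation type {annotation_type!r}")
        type_id = resolved
    for concept in concepts:
        if concept not in model.concepts:
            raise UnknownEntityError(f"unknown concept {concept!r}")
    for cond in conditions:
        _check_condition(model, cond)
    ann = Annotation(
        id=model.fresh_id("_ANNOTATION"),
        conditions=list(conditions),
        annotation_type=type_id,
        concepts=list(concepts),
    )
    model.annotations[ann.id] = ann
    for concept in ann.concepts:
        model.concept_annotations.setdefault(concept, []).append(ann.id)
    return ann


def delete_annotation(model: OntologyModel, annotation_id: str) -> None:
    ann = model.annotations.pop(annotation_id, None)
    if ann is None:
        raise UnknownEntityError(f"unknown annotation {annotation_id!r}")
    for concept in ann.concepts:
        ids = model.concept_annotations.get(concept, [])
        if annotation_id in ids:
            ids.remove(annotation_id)
        if not ids:
            model.concept_annotations.pop(concept, None)


def evaluate_annotation(annotation: Annotation, record: dict[str, Any]) -> bool:
    """True iff every condition holds against the data record.

    A condition requires the element to have a value; a code restricts it to
    string equality with the answer option; a range requires a numeric value
    within the inclusive bounds (a non-numeric value makes the condition
    false, it does not raise).
    """
    for cond in annotation.conditions:
        if cond.element not in record or record[cond.element] is None:
            return False
        value = record[cond.element]
        if cond.code is not None:
            if str(value) != cond.code:
                return False
        elif cond.range is not None:
            try:
                numeric = float(value)
            except (TypeError, ValueError):
                logger.warning(
                    "non-numeric value %r for range condition on %s",
                    value,
                    cond.element,
                )
                return False
            if not cond.range.contains(numeric):
                return False
    return True


def annotations_of_concept(
    model: OntologyModel, concept_id: str, include_subclasses: bool = False
) -> list[Annotation]:
    """Annotations targeting *concept_id* (and its is_a descendants when
    ``include_subclasses``), in annotation-id order."""
    if concept_id not in model.concepts:
        raise UnknownEntityError(f"unknown concept {concept_id!r}")
    targets = [concept_id]
    if include_subclasses:
        targets.extend(concept_descendants(model, concept_id))
    ids: set[str] = set()
    for target in targets:
        ids.update(model.concept_annotations.get(target, []))
    return [model.annotations[i] for i in sorted(ids)]
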
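"""Project persistence: one JSON document for the whole model.

The document carries categories, the slot registry, instances, containment
edges, hierarchy rules, mappings, concepts and annotations under a
top-level ``format_version``.  Loading validates the schema with JSON-path
diagnostics; a document written by a newer format version is refused
outright (no partial load); unknown top-level fields are preserved and
re-emitted on save, so older library versions do not destroy data written
by newer ones.
"""

from __future__ import annotations

import json
import os
from typing import Union

from .annotation import Annotation, Concept
from .errors import SchemaError, VersionError
from .frames import CategoryDef, InstanceRecord, OntologyModel, SlotDefinition
from .hierarchy import ContainsEdge, HierarchyRule
from .mapping import FormatMapping

def load_domain_ontology(model: OntologyModel, source) -> list[str]:
    """Embed a domain ontology described by a JSON/YAML config into *model*.

    ``source`` is a dict, a path, or YAML/JSON text with the shape::

        categories:
          - name: Item
            parent: _OBJECT
            slots:
              - {name: name, value_kind: string}
        rules:
          - {upper: Page, lower: Module}

    Categories are created in document order (parents first), so a config
    can build multi-level domain ontologies.  Returns the category names
    created.
    """
    import yaml

    from .frames import define_category
    from .hierarchy import add_rule

    if isinstance(source, dict):
        data = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        elif os.path.exists(source):
            with open(source, encoding="utf-8") as handle:
                text = handle.read()
        else:
            text = source
        data = yaml.safe_load(text)
    if not isinstance(data, dict) or "categories" not in data:
        raise SchemaError("$", "domain-ontology config must declare 'categories'")
    created = []
    for i, entry in enumerate(data["categories"]):
        path = f"$.categories[{i}]"
        if not isinstance(entry, dict) or "name" not in entry or "parent" not in entry:
            raise SchemaError(path, "category needs 'name' and 'parent'")
        try:
            slots = [SlotDefinition.from_dict(s) for s in entry.get("slots", [])]
            define_category(model, entry["name"], entry["parent"], slots)
        except (TypeError, KeyError) as exc:
            raise SchemaError(path, f"malformed entry: {exc}") from exc
        created.append(entry["name"])
    for i, entry in enumerate(data.get("rules", [])):
        if not isinstance(entry, dict) or set(entry) != {"upper", "lower"}:
            raise SchemaError(f"$.rules[{i}]", "rule needs exactly 'upper' and 'lower'")
        add_rule(model, entry["upper"], entry["lower"])
    return created


KNOWN_FIELDS = {
    "format_version",
    "next_id",
    "slots",
    "categories",
    "instances",
    "contains_edges",
    "hierarchy_rules",
    "mappings",
    "concepts",
    "annotations",
    "concept_annotations",
}


def model_to_dict(model: OntologyModel) -> dict:
    out = {
        "format_version": OntologyModel.FORMAT_VERSION,
        "next_id": model._next_id,
        "slots": [s.to_dict() for s in model.slots.values()],
        "categories": [c.to_dict() for c in model.categories.values()],
        "instances": [i.to_dict() for i in model.instances.values()],
        "contains_edges": [e.to_dict() for e in model.contains_edges],
        "hierarchy_rules": [r.to_dict() for r in model.hierarchy_rules],
        "mappings": [m.to_dict() for m in model.mappings.values()],
        "concepts": [c.to_dict() for c in model.concepts.values()],
        "annotations": [a.to_dict() for a in model.annotations.values()],
    }
    out.update(model.extras)
    return out


def _require(data, key, kind, path):
    if key not in data:
        raise SchemaError(f"{path}.{key}", "missing required field")
    value = data[key]
    if not isinstance(value, kind):
        raise SchemaError(f"{path}.{key}", f"expected {kind.__name__}, got {type(value).__name__}")
    return value


def model_from_dict(data: dict) -> OntologyModel:
    if not isinstance(data, dict):
        raise SchemaError("$", "project document must be a JSON object")
    version = _require(data, "format_version", str, "$")
    if version != OntologyModel.FORMAT_VERSION:
        raise VersionError(
            f"project format_version {version!r} is not supported by this library "
            f"(supported: {OntologyModel.FORMAT_VERSION!r})"
        )
    model = OntologyModel()

    def load_list(key, loader, target):
        items = data.get(key, [])
        if not isinstance(items, list):
            raise SchemaError(f"$.{key}", "expected a list")
        for i, item in enumerate(items):
            path = f"$.{key}[{i}]"
            if not isinstance(item, dict):
                raise SchemaError(path, "expected an object")
            try:
                loaded = loader(item)
            except (TypeError, KeyError, ValueError) as exc:
                raise SchemaError(path, f"malformed entry: {exc}") from exc
            target(loaded)

    load_list("slots", SlotDefinition.from_dict, lambda s: model.slots.__setitem__(s.name, s))
    load_list(
        "categories", CategoryDef.from_dict, lambda c: model.categories.__setitem__(c.name, c)
    )
    load_list(
        "instances", InstanceRecord.from_dict, lambda i: model.instances.__setitem__(i.id, i)
    )
    load_list("contains_edges", ContainsEdge.from_dict, model.contains_edges.append)
    load_list("hierarchy_rules", HierarchyRule.from_dict, model.hierarchy_rules.append)
    load_list(
        "mappings", FormatMapping.from_dict, lambda m: model.mappings.__setitem__(m.name, m)
    )
    load_list("concepts", Concept.from_dict, lambda c: model.concepts.__setitem__(c.id, c))
    load_list(
        "annotations", Annotation.from_dict, lambda a: model.annotations.__setitem__(a.id, a)
    )
    for ann in model.annotations.values():
        for concept in ann.concepts:
            model.concept_annotations.setdefault(concept, []).append(ann.id)
    model._next_id = data.get("next_id", 1)
    # referential spot-checks with path diagnostics
    for i, cat in enumerate(model.categories.values()):
        if cat.parent is not None and cat.parent not in model.categories:
            raise SchemaError(f"$.categories[{i}].parent", f"unknown category {cat.parent!r}")
    for i, inst in enumerate(model.instances.values()):
        if inst.category not in model.categories:
            raise SchemaError(f"$.instances[{i}].category", f"unknown category {inst.category!r}")
    for i, edge in enumerate(model.contains_edges):
        for side in ("parent", "child"):
            if getattr(edge, side) not in model.instances:
                raise SchemaError(
                    f"$.contains_edges[{i}].{side}", f"unknown instance {getattr(edge, side)!r}"
                )
    model.extras = {k: v for k, v in data.items() if k not in KNOWN_FIELDS}
    return model


def save_project(model: OntologyModel, path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(model_to_dict(model), handle, indent=2, ensure_ascii=False)
        handle.write("\n")


def load_project(path: Union[str, "object"]) -> OntologyModel:
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, encoding="utf-8") as handle:
            text = handle.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"$ (line {exc.lineno}, column {exc.colno})", exc.msg) from exc
    return model_from_dict(data)


def models_equal(a: OntologyModel, b: OntologyModel) -> bool:
    """Structural equality via the serialized form."""
    return model_to_dict(a) == model_to_dict(b)


def structural_signature(model: OntologyModel, slots: tuple = ()) -> tuple:
    """Id-free canonical form of the study content, for isomorphism checks.

    Instances are keyed by category plus their slot values with instance
    references replaced by the referenced instance's (category, name) pair;
    containment appears as nested structure in sibling order.  Two models
    produced by export → import are isomorphic iff their signatures match.
    """
    from . import hierarchy

    def name_of(inst_id):
        inst = model.instances.get(inst_id)
        if inst is None:
            return ("?", inst_id)
        return (inst.category, inst.first("name") or inst.first(":NAME") or "")

    def inst_sig(inst_id):
        inst = model.instance(inst_id)
        values = []
        for slot_name in sorted(inst.slot_values):
            if slots and slot_name not in slots:
                continue
            slot = model.slots.get(slot_name)
            row = list(inst.slot_values[slot_name])
            if slot is not None and slot.value_kind == "instance_ref":
                row = [name_of(v) for v in row]
            values.append((slot_name, tuple(row)))
        children = tuple(
            inst_sig(e.child) for e in hierarchy.children_of(model, inst.id)
        )
        return (inst.category, tuple(values), children)

    parented = {e.child for e in model.contains_edges}
    top = sorted(
        inst_sig(i.id)
        for i in model.instances.values()
        if i.id not in parented and model.descends_from(i.category, "_ELEMENT")
    )
    return tuple(top)
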
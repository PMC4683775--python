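"""Declarative mapping between external formats and the domain ontology.

An import/export engine is written once per *format type* (XML, delimited
table) and configured — never re-coded — per concrete format by a mapping
document.  For XML the document declares a tag tree: the root tag, and for
every tag its sub-tags, which category it maps to (or none: a structural
tag passed through transparently), and which attributes/text map to which
slots.  XML nesting between two category-mapped tags becomes a ``_contains``
edge preserving document order.

Beyond plain tags the engine supports three declarative refinements needed
by real metadata dialects:

* *reference tags* (``ItemRef``/``CodeListRef`` style): an element whose
  attribute holds the key of another instance; resolved after the pass
  either to a ``_contains`` edge or to a slot value;
* *value tags* (``CodeListItem`` style): a structural tag whose attribute
  appends a value to a multi-valued slot of the nearest mapped ancestor;
* *collected categories*: instances serialized under a fixed position in
  the tree regardless of containment (codelists live beside, not inside,
  the study hierarchy).

Table mappings are simpler: one target category, one column per slot.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from . import hierarchy
from .errors import MappingError
from .frames import InstanceRecord, OntologyModel, create_instance

logger = logging.getLogger(__name__)


@dataclass
class TagSpec:
    """Mapping of one XML element name.

    A spec with ``category`` set creates/serializes one instance per
    element; otherwise the tag is structural.  ``value_attributes`` maps
    attributes to (multi-valued) slots of the nearest mapped *ancestor*
    instance.  ``ref`` declares a reference tag:
    ``{"attribute": ..., "target_category": ..., "key_slot": ...,
    "role": "contains"|"slot", "slot": ...}``.
    """

    tag: str
    category: Optional[str] = None
    text_slot: Optional[str] = None
    attributes: dict[str, str] = field(default_factory=dict)
    subtags: list[str] = field(default_factory=list)
    is_root: bool = False
    collect: bool = False
    value_attributes: dict[str, str] = field(default_factory=dict)
    ref: Optional[dict] = None

    def to_dict(self) -> dict:
        out: dict = {"tag": self.tag}
        for key in ("category", "text_slot"):
            if getattr(self, key) is not None:
                out[key] = getattr(self, key)
        if self.attributes:
            out["attributes"] = dict(self.attributes)
        if self.subtags:
            out["subtags"] = list(self.subtags)
        if self.is_root:
            out["is_root"] = True
        if self.collect:
            out["collect"] = True
        if self.value_attributes:
            out["value_attributes"] = dict(self.value_attributes)
        if self.ref is not None:
            out["ref"] = dict(self.ref)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "TagSpec":
        return cls(**data)


@dataclass
class FormatMapping:
    """One configured format: XML tag tree or table column map."""

    name: str
    format_type: str  # "xml" | "table"
    tag_specs: list[TagSpec] = field(default_factory=list)
    namespace: Optional[str] = None
    target_category: Optional[str] = None
    column_mappings: dict[str, str] = field(default_factory=dict)  # header -> slot
    strict: bool = True

    def __post_init__(self):
        if self.format_type not in ("xml", "table"):
            raise MappingError(f"unknown format type {self.format_type!r}")
        if self.format_type == "xml":
            roots = [t for t in self.tag_specs if t.is_root]
            if len(roots) != 1:
                raise MappingError(
                    f"mapping {self.name!r} must declare exactly one root tag, "
                    f"found {len(roots)}"
                )
            names = set()
            for spec in self.tag_specs:
                if spec.tag in names:
                    raise MappingError(f"duplicate tag spec {spec.tag!r}")
                names.add(spec.tag)
            for spec in self.tag_specs:
                for sub in spec.subtags:
                    if sub not in names:
                        raise MappingError(
                            f"tag {spec.tag!r} declares undeclared subtag {sub!r}"
                        )
        elif not self.column_mappings:
            raise MappingError(f"table mapping {self.name!r} declares no columns")

    # navigation helpers
    def root(self) -> TagSpec:
        return next(t for t in self.tag_specs if t.is_root)

    def by_tag(self, tag: str) -> Optional[TagSpec]:
        for spec in self.tag_specs:
            if spec.tag == tag:
                return spec
        return None

    def for_category(self, category: str) -> Optional[TagSpec]:
        for spec in self.tag_specs:
            if spec.category == category:
                return spec
        return None

    def tag_parent(self, tag: str) -> Optional[TagSpec]:
        for spec in self.tag_specs:
            if tag in spec.subtags:
                return spec
        return None

    def validate_against(self, model: OntologyModel) -> None:
        """Check that every referenced category and slot exists in the model."""
        if self.format_type == "table":
            model.category(self.target_category)
            slot_map = model.effective_slot_map(self.target_category)
            for header, slot in self.column_mappings.items():
                if slot not in slot_map:
                    raise MappingError(
                        f"column {header!r} maps to unknown slot {slot!r} "
                        f"of {self.target_category!r}"
                    )
            return
        for spec in self.tag_specs:
            if spec.category is not None:
                slot_map = model.effective_slot_map(spec.category)
                for attr, slot in spec.attributes.items():
                    if slot not in slot_map:
                        raise MappingError(
                            f"tag {spec.tag!r}: attribute {attr!r} maps to unknown "
                            f"slot {slot!r} of category {spec.category!r}"
                        )
                if spec.text_slot is not None and spec.text_slot not in slot_map:
                    raise MappingError(
                        f"tag {spec.tag!r}: text maps to unknown slot {spec.text_slot!r}"
                    )

    def to_dict(self) -> dict:
        out: dict = {"name": self.name, "format_type": self.format_type}
        if self.format_type == "xml":
            out["tags"] = [t.to_dict() for t in self.tag_specs]
            if self.namespace:
                out["namespace"] = self.namespace
        else:
            out["target_category"] = self.target_category
            out["columns"] = dict(self.column_mappings)
        if not self.strict:
            out["strict"] = False
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "FormatMapping":
        return cls(
            name=data["name"],
            format_type=data["format_type"],
            tag_specs=[TagSpec.from_dict(t) for t in data.get("tags", [])],
            namespace=data.get("namespace"),
            target_category=data.get("target_category"),
            column_mappings=dict(data.get("columns", {})),
            strict=data.get("strict", True),
        )


def _localname(element) -> str:
    return etree.QName(element).localname


def _namespace(element) -> Optional[str]:
    return etree.QName(element).namespace


# ---------------------------------------------------------------------------
# XML import
# ---------------------------------------------------------------------------


def import_xml(model: OntologyModel, mapping: FormatMapping, document) -> list[str]:
    """Import an XML document through the mapping; returns created instance ids.

    ``document`` is an lxml element/tree, XML text, or a path.  Elements
    matching category-mapped tag specs become instances; nesting between two
    mapped tags becomes containment in document order; structural tags are
    traversed transparently.  Unmapped elements raise in strict mode and are
    skipped (with a log line) otherwise.
    """
    root = _as_element(document)
    root_spec = mapping.root()
    if _localname(root) != root_spec.tag or (
        mapping.namespace is not None and _namespace(root) != mapping.namespace
    ):
        raise MappingError(
            f"document root <{_localname(root)}> does not match the mapping root "
            f"<{root_spec.tag}>"
        )
    created: list[str] = []
    pending_refs: list[tuple] = []  # (parent instance id, ref dict, key value)

    def walk(element, spec: TagSpec, ancestor_instance: Optional[str]):
        context = ancestor_instance
        if spec.ref is not None:
            key = element.get(spec.ref["attribute"])
            if key is None:
                raise MappingError(
                    f"reference tag <{spec.tag}> lacks attribute {spec.ref['attribute']!r}"
                )
            pending_refs.append((ancestor_instance, spec.ref, key))
            return
        if spec.value_attributes and ancestor_instance is not None:
            inst = model.instance(ancestor_instance)
            for attr, slot in spec.value_attributes.items():
                value = element.get(attr)
                if value is not None:
                    inst.slot_values.setdefault(slot, []).append(value)
        if (
            spec.category is None
            and spec.text_slot is not None
            and ancestor_instance is not None
            and element.text
            and element.text.strip()
        ):
            # structural tag whose text fills a slot of the enclosing instance
            inst = model.instance(ancestor_instance)
            inst.slot_values.setdefault(spec.text_slot, []).append(element.text.strip())
        if spec.category is not None:
            values: dict[str, list] = {}
            for attr, slot in spec.attributes.items():
                value = element.get(attr)
                if value is not None:
                    values[slot] = [value]
            if spec.text_slot is not None and element.text and element.text.strip():
                values[spec.text_slot] = [element.text.strip()]
            inst = create_instance(model, spec.category, values)
            created.append(inst.id)
            if ancestor_instance is not None and not spec.collect:
                _attach(model, ancestor_instance, inst.id)
            context = inst.id
        for child in element:
            if not isinstance(child.tag, str):
                continue  # comments, processing instructions
            child_spec = mapping.by_tag(_localname(child))
            if child_spec is None or child_spec.tag not in spec.subtags:
                if mapping.strict:
                    raise MappingError(
                        f"element <{_localname(child)}> under <{spec.tag}> is not "
                        "declared in the mapping"
                    )
                logger.info("skipping unmapped element <%s>", _localname(child))
                continue
            walk(child, child_spec, context)

    walk(root, root_spec, None)

    for parent_id, ref, key in pending_refs:
        target = model.find_by_slot(ref["target_category"], ref["key_slot"], key)
        if target is None:
            raise MappingError(
                f"reference to {ref['target_category']!r} with "
                f"{ref['key_slot']!r}={key!r} does not resolve"
            )
        if ref.get("role", "slot") == "contains":
            _attach(model, parent_id, target.id)
        else:
            inst = model.instance(parent_id)
            inst.slot_values.setdefault(ref["slot"], []).append(target.id)
    return created


def _attach(model: OntologyModel, parent: str, child: str) -> None:
    """Append a containment edge without the group-category restriction of
    :func:`hierarchy.add_to_group` (imports may nest arbitrary mapped
    categories); forest invariants are still enforced."""
    if hierarchy.parent_of(model, child) is not None:
        raise MappingError(f"instance {child!r} would get a second parent")
    if hierarchy._would_cycle(model, parent, child):
        raise MappingError(f"edge {parent!r} -> {child!r} would create a cycle")
    position = len(hierarchy.children_of(model, parent))
    model.contains_edges.append(
        hierarchy.ContainsEdge(parent=parent, child=child, position=position)
    )


def _as_element(document):
    if isinstance(document, (str, bytes)):
        text = document
        if isinstance(text, str):
            stripped = text.lstrip()
            if not stripped.startswith("<"):
                return etree.parse(text).getroot()
            text = text.encode("utf-8")
        return etree.fromstring(text)
    if hasattr(document, "getroot"):
        return document.getroot()
    return document


# ---------------------------------------------------------------------------
# XML export
# ---------------------------------------------------------------------------


def export_xml(
    model: OntologyModel, mapping: FormatMapping, root_instances: list[str]
) -> etree._Element:
    """Serialize instances through the mapping; the inverse of import.

    Containment edges become nesting in sibling-ordinal order; structural
    wrapper tags declared between two mapped tags are re-created (once per
    parent element); empty optional attributes are omitted.  Instances of
    *collected* categories are emitted for the whole model, sorted by id.
    """
    root_spec = mapping.root()
    namespace = mapping.namespace
    if namespace:
        root_el = etree.Element(f"{{{namespace}}}{root_spec.tag}", nsmap={None: namespace})
    else:
        root_el = etree.Element(root_spec.tag)

    def qname(tag: str) -> str:
        return f"{{{namespace}}}{tag}" if namespace else tag

    def wrapper_path(spec: TagSpec, context_spec: TagSpec) -> list[str]:
        path: list[str] = []
        cur = mapping.tag_parent(spec.tag)
        while cur is not None and cur.tag != context_spec.tag:
            if cur.category is not None:
                raise MappingError(
                    f"category tag <{spec.tag}> is not reachable from <{context_spec.tag}> "
                    "through structural tags only"
                )
            path.append(cur.tag)
            cur = mapping.tag_parent(cur.tag)
        if cur is None:
            raise MappingError(
                f"tag <{spec.tag}> is not reachable from <{context_spec.tag}>"
            )
        return list(reversed(path))

    def ensure_wrappers(context_el, path: list[str]):
        # one structural wrapper of each tag per parent element, reused
        current = context_el
        for tag in path:
            existing = current.find(qname(tag))
            current = existing if existing is not None else etree.SubElement(current, qname(tag))
        return current

    def emit(inst: InstanceRecord, context_el, context_spec: TagSpec):
        spec = mapping.for_category(inst.category)
        if spec is None:
            raise MappingError(
                f"category {inst.category!r} of instance {inst.id!r} is not mapped"
            )
        parent_el = ensure_wrappers(context_el, wrapper_path(spec, context_spec))
        el = etree.SubElement(parent_el, qname(spec.tag))
        for attr, slot in spec.attributes.items():
            value = inst.first(slot)
            if value is not None and value != "":
                el.set(attr, _text(value))
        if spec.text_slot is not None:
            value = inst.first(spec.text_slot)
            if value is not None:
                el.text = _text(value)
        for sub_name in spec.subtags:
            sub = mapping.by_tag(sub_name)
            if sub is None:
                continue
            if sub.ref is not None:
                _emit_refs(model, inst, sub, el)
            elif sub.value_attributes:
                _emit_values(inst, sub, el)
            elif sub.category is None and not sub.collect:
                _emit_text_subtree(inst, sub, el)
        for edge in hierarchy.children_of(model, inst.id):
            emit(model.instance(edge.child), el, spec)
        return el

    def _emit_refs(model, inst, sub: TagSpec, el):
        ref = sub.ref
        if ref.get("role", "slot") == "contains":
            return  # containment refs are emitted by the nesting walk
        for target_id in inst.slot_values.get(ref["slot"], []):
            target = model.instance(target_id)
            key = target.first(ref["key_slot"])
            if key is None:
                raise MappingError(
                    f"reference target {target_id!r} lacks key slot {ref['key_slot']!r}"
                )
            etree.SubElement(el, qname(sub.tag)).set(ref["attribute"], _text(key))

    def _emit_text_subtree(inst, sub: TagSpec, el) -> bool:
        """Emit structural tags whose text carries slot values of *inst*;
        wrappers appear only when a descendant actually emits a value."""
        if sub.text_slot is not None:
            values = inst.slot_values.get(sub.text_slot, [])
            for value in values:
                etree.SubElement(el, qname(sub.tag)).text = _text(value)
            return bool(values)
        children = [
            mapping.by_tag(s)
            for s in sub.subtags
            if mapping.by_tag(s) is not None
        ]
        text_children = [
            c for c in children if c.category is None and not c.collect and c.ref is None
        ]
        if not text_children:
            return False
        wrapper = etree.SubElement(el, qname(sub.tag))
        emitted = any([_emit_text_subtree(inst, c, wrapper) for c in text_children])
        if not emitted:
            el.remove(wrapper)
        return emitted

    def _emit_values(inst, sub: TagSpec, el):
        attr_slots = list(sub.value_attributes.items())
        first_slot = attr_slots[0][1]
        for i in range(len(inst.slot_values.get(first_slot, []))):
            child = etree.SubElement(el, qname(sub.tag))
            for attr, slot in attr_slots:
                values = inst.slot_values.get(slot, [])
                if i < len(values):
                    child.set(attr, _text(values[i]))

    for inst_id in root_instances:
        emit(model.instance(inst_id), root_el, root_spec)

    parented = {e.child for e in model.contains_edges}
    for spec in mapping.tag_specs:
        if spec.collect and spec.category is not None:
            context_el, context_spec = root_el, root_spec
            # place collected instances under the first emitted ancestor element
            anchor = mapping.tag_parent(spec.tag)
            while anchor is not None and anchor.category is None:
                anchor = mapping.tag_parent(anchor.tag)
            if anchor is not None:
                anchor_els = root_el.findall(f".//{qname(anchor.tag)}")
                if not anchor_els:
                    continue  # anchor never emitted (e.g. empty export)
                context_el, context_spec = anchor_els[0], anchor
            for inst in sorted(
                model.instances_of(spec.category), key=lambda i: i.id
            ):
                if inst.id in parented or inst.id in root_instances:
                    continue
                parent_el = ensure_wrappers(
                    context_el, wrapper_path(spec, context_spec)
                )
                emit_el = etree.SubElement(parent_el, qname(spec.tag))
                for attr, slot in spec.attributes.items():
                    value = inst.first(slot)
                    if value is not None and value != "":
                        emit_el.set(attr, _text(value))
                for sub_name in spec.subtags:
                    sub = mapping.by_tag(sub_name)
                    if sub is not None and sub.value_attributes:
                        _emit_values(inst, sub, emit_el)
    return root_el


def _text(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def xml_to_string(element) -> str:
    return etree.tostring(element, pretty_print=True, encoding="unicode")


def canonical_xml(element) -> tuple:
    """Attribute-order-insensitive, whitespace-normalized structural form,
    for round-trip comparison."""
    element = _as_element(element)
    text = (element.text or "").strip()
    return (
        _localname(element),
        tuple(sorted(element.attrib.items())),
        text,
        tuple(canonical_xml(c) for c in element if isinstance(c.tag, str)),
    )


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------


def import_table(model: OntologyModel, mapping: FormatMapping, rows) -> list[str]:
    """Import a delimited table (CSV text, stream, or row iterable); one
    instance of the target category per data row.  Empty cells are omitted."""
    if mapping.format_type != "table":
        raise MappingError(f"mapping {mapping.name!r} is not a table mapping")
    if isinstance(rows, str):
        rows = list(csv.reader(io.StringIO(rows)))
    elif hasattr(rows, "read"):
        rows = list(csv.reader(rows))
    else:
        rows = [list(r) for r in rows]
    if not rows:
        raise MappingError("table has no header row")
    header = rows[0]
    if len(set(header)) != len(header):
        raise MappingError(f"duplicate column header in {header}")
    positions = {}
    for column in mapping.column_mappings:
        if column not in header:
            raise MappingError(f"mapped column {column!r} missing from header {header}")
        positions[column] = header.index(column)
    created = []
    for row in rows[1:]:
        values = {}
        for column, slot in mapping.column_mappings.items():
            idx = positions[column]
            if idx < len(row) and row[idx] != "":
                values[slot] = [row[idx]]
        inst = create_instance(model, mapping.target_category, values)
        created.append(inst.id)
    return created


def export_table(
    model: OntologyModel, mapping: FormatMapping, instances: list[str]
) -> str:
    """Export instances as CSV text; columns in mapping order, one row each."""
    if mapping.format_type != "table":
        raise MappingError(f"mapping {mapping.name!r} is not a table mapping")
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\r\n")
    writer.writerow(list(mapping.column_mappings))
    for inst_id in instances:
        inst = model.instance(inst_id)
        writer.writerow(
            [
                _text(inst.first(slot, "")) if inst.first(slot) is not None else ""
                for slot in mapping.column_mappings.values()
            ]
        )
    return out.getvalue()


# ---------------------------------------------------------------------------
# CRF preview
# ---------------------------------------------------------------------------


def render_crf_preview(model: OntologyModel, root: str) -> str:
    """Render a group and its contents as a markdown case-report-form outline.

    Groups become headings by depth; items become labelled fields with their
    codelist options, units and ranges.  Deterministic given the model.
    """
    root_inst = model.instance(root)
    if not model.descends_from(root_inst.category, "_GROUP"):
        raise MappingError(f"CRF preview root {root!r} is not a group")
    lines: list[str] = []

    def title(inst: InstanceRecord) -> str:
        return inst.first("name") or inst.first(":NAME") or inst.id

    def walk(inst: InstanceRecord, depth: int):
        if model.descends_from(inst.category, "_GROUP"):
            lines.append(f"{'#' * min(depth + 1, 6)} {title(inst)}")
            lines.append("")
            for edge in hierarchy.children_of(model, inst.id):
                walk(model.instance(edge.child), depth + 1)
        else:
            parts = [f"- **{title(inst)}**"]
            description = inst.first("description")
            if description:
                parts.append(f"— {description}")
            unit_id = inst.first("unit_of_measure")
            if unit_id and unit_id in model.instances:
                parts.append(f"({model.instance(unit_id).first('name', unit_id)})")
            rng = inst.first("range")
            if rng:
                parts.append(f"range {rng}")
            codes = None
            try:
                from .annotation import codelist_values

                codes = codelist_values(model, inst.id)
            except Exception:  # items without the codelist convention
                codes = None
            if codes:
                parts.append("options: " + " | ".join(codes))
            lines.append(" ".join(parts))

    walk(root_inst, 0)
    while lines and lines[-1] == "":
        lines.pop()
    return "\n".join(lines) + "\n"
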
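"""Study structure as an ordered containment forest, plus rule validation.

Study elements (instances of ``_ELEMENT`` subcategories) are connected by
the ``_contains`` relation: a Study contains Pages, a Page contains Modules,
a Module contains Items.  The structure is a forest — a child has at most
one parent — and sibling order is significant (it is the order on the case
report form).

Which category may contain which is declared by *hierarchy rules*.  A rule
``upper ⊑ lower`` is read, in its strict (universal) form, as: every child
of every instance of ``upper`` instantiates ``lower``:

    for all x, y:  x :: upper  and  _contains(x, y)  implies  y :: lower

Instantiation counts subcategories ("x :: C" is true for instances of C's
subcategories too).  Real forms mix child types under one group, so a
second, per-edge reading is also provided: an edge is valid when at least
one declared rule licenses it (``any_of`` mode, the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import HierarchyError, UnknownEntityError
from .frames import OntologyModel, Violation


@dataclass
class ContainsEdge:
    """One ``_contains`` link; ``position`` is the 0-based sibling ordinal."""

    parent: str
    child: str
    position: int

    def to_dict(self) -> dict:
        return {"parent": self.parent, "child": self.child, "position": self.position}

    @classmethod
    def from_dict(cls, data: dict) -> "ContainsEdge":
        return cls(**data)


@dataclass
class HierarchyRule:
    """Class-level containment licence: instances of ``upper`` may (strict:
    may only) contain instances of ``lower``."""

    upper: str
    lower: str

    def to_dict(self) -> dict:
        return {"upper": self.upper, "lower": self.lower}

    @classmethod
    def from_dict(cls, data: dict) -> "HierarchyRule":
        return cls(**data)


# -- navigation -----------------------------------------------------------------


def children_of(model: OntologyModel, parent: str) -> list[ContainsEdge]:
    edges = [e for e in model.contains_edges if e.parent == parent]
    edges.sort(key=lambda e: e.position)
    return edges


def parent_of(model: OntologyModel, child: str) -> Optional[str]:
    for e in model.contains_edges:
        if e.child == child:
            return e.parent
    return None


def roots(model: OntologyModel) -> list[str]:
    """Study-element instances with no parent, in creation order."""
    with_parent = {e.child for e in model.contains_edges}
    return [
        i.id
        for i in model.instances.values()
        if i.id not in with_parent and model.descends_from(i.category, "_ELEMENT")
    ]


def descendants(model: OntologyModel, instance: str) -> list[str]:
    """Depth-first pre-order closure of ``_contains``; excludes the start node."""
    model.instance(instance)  # raises on unknown id
    out: list[str] = []
    stack = [e.child for e in reversed(children_of(model, instance))]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(e.child for e in reversed(children_of(model, node)))
    return out


def _renumber(model: OntologyModel, parent: str) -> None:
    for i, e in enumerate(children_of(model, parent)):
        e.position = i


def _would_cycle(model: OntologyModel, group: str, element: str) -> bool:
    node: Optional[str] = group
    while node is not None:
        if node == element:
            return True
        node = parent_of(model, node)
    return False


# -- structure edits ------------------------------------------------------------


def add_to_group(
    model: OntologyModel,
    group: str,
    element: str,
    position: Optional[int] = None,
) -> ContainsEdge:
    """Insert *element* among *group*'s children at *position* (default append).

    Existing siblings at and after the position shift right; ordinals stay
    contiguous.  The parent must be a ``_GROUP`` instance and the edge must
    not create a cycle or give the element a second parent.
    """
    group_inst = model.instance(group)
    model.instance(element)
    if not model.descends_from(group_inst.category, "_GROUP"):
        raise HierarchyError(
            f"instance {group!r} of category {group_inst.category!r} is not a group"
        )
    if not model.descends_from(model.instance(element).category, "_ELEMENT"):
        raise HierarchyError(f"instance {element!r} is not a study element")
    if parent_of(model, element) is not None:
        raise HierarchyError(f"instance {element!r} already has a parent")
    if _would_cycle(model, group, element):
        raise HierarchyError(
            f"adding {element!r} under {group!r} would create a containment cycle"
        )
    siblings = children_of(model, group)
    if position is None or position > len(siblings):
        position = len(siblings)
    for e in siblings:
        if e.position >= position:
            e.position += 1
    edge = ContainsEdge(parent=group, child=element, position=position)
    model.contains_edges.append(edge)
    return edge


def remove_from_group(model: OntologyModel, group: str, element: str) -> None:
    """Remove the edge *group* → *element*; remaining siblings are renumbered."""
    for e in model.contains_edges:
        if e.parent == group and e.child == element:
            model.contains_edges.remove(e)
            _renumber(model, group)
            return
    raise HierarchyError(f"instance {element!r} is not a child of {group!r}")


def move_element(
    model: OntologyModel,
    element: str,
    new_group: str,
    position: Optional[int] = None,
) -> ContainsEdge:
    """Atomically re-parent *element*: the model is unchanged on failure."""
    old_parent = parent_of(model, element)
    if old_parent is None:
        raise HierarchyError(f"instance {element!r} has no parent to move from")
    group_inst = model.instance(new_group)
    if not model.descends_from(group_inst.category, "_GROUP"):
        raise HierarchyError(f"move target {new_group!r} is not a group")
    if _would_cycle(model, new_group, element):
        raise HierarchyError(
            f"moving {element!r} under {new_group!r} would create a containment cycle"
        )
    remove_from_group(model, old_parent, element)
    return add_to_group(model, new_group, element, position)


# -- rule checking --------------------------------------------------------------


def check_hierarchy_rule(model: OntologyModel, rule: HierarchyRule) -> bool:
    """Evaluate the universal containment rule over all edges.

    True iff every child of every instance of (a subcategory of)
    ``rule.upper`` instantiates ``rule.lower``; vacuously true when no such
    parent has children.
    """
    model.category(rule.upper)
    model.category(rule.lower)
    for edge in model.contains_edges:
        x = model.instance(edge.parent)
        if model.instance_of(x, rule.upper):
            y = model.instance(edge.child)
            if not model.instance_of(y, rule.lower):
                return False
    return True


def validate_structure(model: OntologyModel, rule_mode: str = "any_of") -> list[Violation]:
    """Validate every containment edge against the declared hierarchy rules.

    ``strict``: each rule must hold as a universal; every counterexample edge
    is reported.  ``any_of``: each edge must be licensed by at least one rule
    covering both endpoints.  A model declaring no rules is trivially valid.
    """
    if rule_mode not in ("strict", "any_of"):
        raise ValueError(f"unknown rule mode {rule_mode!r}")
    violations: list[Violation] = []
    if not model.hierarchy_rules:
        return violations
    for edge in model.contains_edges:
        x = model.instance(edge.parent)
        y = model.instance(edge.child)
        if rule_mode == "strict":
            for rule in model.hierarchy_rules:
                if model.instance_of(x, rule.upper) and not model.instance_of(y, rule.lower):
                    violations.append(
                        Violation(
                            "hierarchy",
                            f"rule ({rule.upper} contains {rule.lower}) broken: "
                            f"{edge.parent} contains {edge.child} ({y.category})",
                            edge=(edge.parent, edge.child),
                        )
                    )
        else:
            licensed = any(
                model.instance_of(x, rule.upper) and model.instance_of(y, rule.lower)
                for rule in model.hierarchy_rules
            )
            if not licensed:
                violations.append(
                    Violation(
                        "unlicensed-edge",
                        f"no rule licenses {edge.parent} ({x.category}) "
                        f"containing {edge.child} ({y.category})",
                        edge=(edge.parent, edge.child),
                    )
                )
    return violations


def add_rule(model: OntologyModel, upper: str, lower: str) -> HierarchyRule:
    for name in (upper, lower):
        if not model.descends_from(name, "_ELEMENT"):
            raise UnknownEntityError(
                f"hierarchy rule category {name!r} is not a study-element category"
            )
    rule = HierarchyRule(upper=upper, lower=lower)
    model.hierarchy_rules.append(rule)
    return rule
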
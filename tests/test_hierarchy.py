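"""Containment forest edits and hierarchy-rule validation.

The rule checker is compared against a brute-force evaluation of the
universal formula (for all x, y: x :: upper and contains(x, y) implies
y :: lower) on randomly built models.
"""

import random

import pytest

from ose import (
    HierarchyRule,
    add_to_group,
    check_hierarchy_rule,
    create_instance,
    descendants,
    move_element,
    remove_from_group,
    validate_structure,
)
from ose import fixtures, hierarchy
from ose.errors import HierarchyError, UnknownEntityError

from conftest import by_name


def brute_force_rule(model, rule):
    """Independent evaluation of the quantified containment formula."""
    holds = True
    for x in model.instances.values():
        for y in model.instances.values():
            contains = any(
                e.parent == x.id and e.child == y.id for e in model.contains_edges
            )
            if contains and model.instance_of(x, rule.upper):
                if not model.instance_of(y, rule.lower):
                    holds = False
    return holds


class TestEdits:
    def test_page_contains_module(self, example):
        page = by_name(example, "B1")
        module = by_name(example, "Socio-demographic data")
        assert hierarchy.parent_of(example, module.id) == page.id
        edge = next(e for e in example.contains_edges if e.child == module.id)
        assert edge.position == 0

    def test_insert_at_front_shifts_siblings(self, example):
        module = by_name(example, "Socio-demographic data")
        extra = create_instance(example, "Item", {"name": "AGE"})
        add_to_group(example, module.id, extra.id, position=0)
        order = [e.child for e in hierarchy.children_of(example, module.id)]
        assert order[0] == extra.id
        positions = [e.position for e in hierarchy.children_of(example, module.id)]
        assert positions == list(range(len(positions)))

    def test_cycle_rejected(self, example):
        # putting the study under its own page would close a loop
        study = by_name(example, "Heart failure study")
        page = by_name(example, "B1")
        with pytest.raises(HierarchyError):
            add_to_group(example, page.id, study.id)

    def test_second_parent_rejected(self, example):
        other_page = create_instance(example, "Page", {"name": "B2"})
        module = by_name(example, "Socio-demographic data")
        with pytest.raises(HierarchyError):
            add_to_group(example, other_page.id, module.id)

    def test_non_group_parent_rejected(self, example):
        item = by_name(example, "DYSPNEA_AT_REST")
        other = by_name(example, "SYSTOLIC_BLOOD_PRESURE")
        with pytest.raises(HierarchyError):
            add_to_group(example, item.id, other.id)

    def test_remove_only_child(self, example):
        page = by_name(example, "B1")
        module = by_name(example, "Socio-demographic data")
        remove_from_group(example, page.id, module.id)
        assert hierarchy.children_of(example, page.id) == []

    def test_move_between_pages(self, example):
        module = by_name(example, "Socio-demographic data")
        b2 = create_instance(example, "Page", {"name": "B2"})
        study = by_name(example, "Heart failure study")
        add_to_group(example, study.id, b2.id)
        move_element(example, module.id, b2.id, position=0)
        b1 = by_name(example, "B1")
        assert hierarchy.children_of(example, b1.id) == []
        assert hierarchy.parent_of(example, module.id) == b2.id

    def test_failed_move_leaves_model_unchanged(self, example):
        from ose.project import model_to_dict

        page = by_name(example, "B1")
        study = by_name(example, "Heart failure study")
        before = model_to_dict(example)
        with pytest.raises(HierarchyError):
            move_element(example, study.id, page.id)  # no parent to move from
        assert model_to_dict(example) == before


class TestDescendants:
    def test_preorder(self, example):
        page = by_name(example, "B1")
        module = by_name(example, "Socio-demographic data")
        dyspnea = by_name(example, "DYSPNEA_AT_REST")
        sbp = by_name(example, "SYSTOLIC_BLOOD_PRESURE")
        assert descendants(example, page.id) == [module.id, dyspnea.id, sbp.id]

    def test_leaf_has_no_descendants(self, example):
        item = by_name(example, "DYSPNEA_AT_REST")
        assert descendants(example, item.id) == []

    def test_unknown_instance(self, example):
        with pytest.raises(UnknownEntityError):
            descendants(example, "ghost-1")

    def test_never_contains_self(self, example):
        for inst_id in example.instances:
            assert inst_id not in descendants(example, inst_id)


class TestRules:
    def test_rule_holds_on_example(self, example):
        assert check_hierarchy_rule(example, HierarchyRule("Page", "Module"))

    def test_rule_broken_by_stray_item(self, example):
        page = by_name(example, "B1")
        stray = create_instance(example, "Item", {"name": "STRAY"})
        add_to_group(example, page.id, stray.id)
        assert not check_hierarchy_rule(example, HierarchyRule("Page", "Module"))

    def test_vacuously_true_on_empty_model(self, empty_model):
        from ose import define_category

        define_category(empty_model, "Page", "_GROUP", [])
        define_category(empty_model, "Module", "_GROUP", [])
        assert check_hierarchy_rule(empty_model, HierarchyRule("Page", "Module"))

    def test_agrees_with_brute_force_on_random_models(self):
        rng = random.Random(20240917)
        categories = ["Study", "Page", "Module", "Item"]
        for _ in range(30):
            model = fixtures.generate_random_project(rng.randint(0, 20), rng.randint(0, 9999))
            # perturb: drop declared rules, add random edges between random groups
            for _ in range(rng.randint(0, 4)):
                groups = model.instances_of("_GROUP")
                elements = model.instances_of("_ELEMENT")
                if not groups or not elements:
                    continue
                g = rng.choice(groups)
                e = rng.choice(elements)
                try:
                    add_to_group(model, g.id, e.id)
                except HierarchyError:
                    pass
            assert len(model.instances) <= 60
            for upper in categories:
                for lower in categories:
                    rule = HierarchyRule(upper, lower)
                    assert check_hierarchy_rule(model, rule) == brute_force_rule(
                        model, rule
                    )


class TestValidateStructure:
    def test_example_is_valid_in_both_modes(self, example):
        assert validate_structure(example, "strict") == []
        assert validate_structure(example, "any_of") == []

    def test_any_of_licenses_mixed_children(self, example):
        page = by_name(example, "B1")
        stray = create_instance(example, "Item", {"name": "STRAY"})
        add_to_group(example, page.id, stray.id)
        # strict: the literal universal formula now fails for (Page, Module)
        assert validate_structure(example, "strict") != []
        # any_of with an extra licence accepts the mix
        hierarchy.add_rule(example, "Page", "Item")
        assert validate_structure(example, "any_of") == []

    def test_any_of_reports_unlicensed_edge(self, example):
        study = by_name(example, "Heart failure study")
        stray = create_instance(example, "Item", {"name": "STRAY"})
        add_to_group(example, study.id, stray.id)
        offenders = validate_structure(example, "any_of")
        assert [v.edge for v in offenders] == [(study.id, stray.id)]

    def test_any_of_matches_per_edge_licensing_oracle(self, example):
        page = by_name(example, "B1")
        stray = create_instance(example, "Item", {"name": "STRAY"})
        add_to_group(example, page.id, stray.id)
        hierarchy.add_rule(example, "Page", "Item")
        for edge in example.contains_edges:
            x = example.instance(edge.parent)
            y = example.instance(edge.child)
            licensed = any(
                example.instance_of(x, r.upper) and example.instance_of(y, r.lower)
                for r in example.hierarchy_rules
            )
            assert licensed, f"edge {edge} should be licensed"
        assert validate_structure(example, "any_of") == []


def test_forest_invariants_after_random_operation_sequences():
    """Acyclicity, single-parenthood and contiguous ordinals survive any
    sequence of add/remove/move attempts."""
    rng = random.Random(7)
    model = fixtures.generate_random_project(12, 1)
    ids = [
        i.id for i in model.instances.values() if model.descends_from(i.category, "_ELEMENT")
    ]
    groups = [i.id for i in model.instances_of("_GROUP")]
    for _ in range(300):
        op = rng.choice(["add", "remove", "move"])
        try:
            if op == "add":
                add_to_group(model, rng.choice(groups), rng.choice(ids))
            elif op == "remove" and model.contains_edges:
                edge = rng.choice(model.contains_edges)
                remove_from_group(model, edge.parent, edge.child)
            else:
                move_element(
                    model, rng.choice(ids), rng.choice(groups), rng.randint(0, 5)
                )
        except HierarchyError:
            pass
        # invariants
        children = {}
        for e in model.contains_edges:
            children.setdefault(e.parent, []).append(e)
        parents = [e.child for e in model.contains_edges]
        assert len(parents) == len(set(parents)), "second parent"
        for parent, edges in children.items():
            assert sorted(e.position for e in edges) == list(range(len(edges)))
        for inst_id in ids:
            assert inst_id not in descendants(model, inst_id), "cycle"
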
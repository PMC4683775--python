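"""Ready-made example and generated projects.

``build_example_project`` constructs, in code, a small but complete study:
a domain ontology (Study, Page, Module under ``_GROUP``; Item,
Unit_of_Measure, Codelist under ``_OBJECT``), a study hierarchy
(Study → Page "B1" → Module "Socio-demographic data" → two items), a
dyspnea item with a YES/NO codelist, a systolic-blood-pressure item with a
mmHg unit, a mini phenotype concept hierarchy, two typed annotations
(dyspnea=YES is a symptom of congestive heart failure; systolic pressure
in [121;] indicates elevated systolic blood pressure), hierarchy rules and
one edit-check rule expression.  It is deterministic and needs no network.

``generate_random_project`` produces seed-reproducible projects of a given
size with the same shape, for property tests; ``generate_odm_document``
serializes a project through the shipped ODM-style mapping.
"""

from __future__ import annotations

import random

from . import annotation, expressions, hierarchy, mapping
from .annotation import ElementCondition, create_annotation, define_annotation_type, load_obo
from .frames import (
    OntologyModel,
    SlotDefinition,
    bootstrap_task_ontology,
    create_instance,
    define_category,
)

ODM_NAMESPACE = "http://www.cdisc.org/ns/odm/v1.3"

#: synthetic mini phenotype ontology (HPO-style ids and labels), OBO 1.2
MINI_PHENOTYPE_OBO = """\
format-version: 1.2
ontology: mini-hp

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0001626
name: Abnormality of the cardiovascular system
is_a: HP:0000001 ! All

[Term]
id: HP:0001635
name: Congestive heart failure
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0004421
name: Elevated systolic blood pressure
is_a: HP:0001626 ! Abnormality of the cardiovascular system
"""


def odm_example_mapping() -> mapping.FormatMapping:
    """The shipped ODM 1.3-style mapping (nested dialect).

    FormDef plays the role of a Page, ItemGroupDef of a Module, ItemDef of
    an Item; CodeLists are collected under MetaDataVersion and referenced
    from items by ``CodeListRef``.
    """
    T = mapping.TagSpec
    return mapping.FormatMapping(
        name="odm-example",
        format_type="xml",
        namespace=ODM_NAMESPACE,
        tag_specs=[
            T("ODM", is_root=True, subtags=["Study"]),
            T(
                "Study",
                category="Study",
                attributes={"OID": ":NAME"},
                subtags=["GlobalVariables", "BasicDefinitions", "MetaDataVersion"],
            ),
            T("GlobalVariables", subtags=["StudyName"]),
            T("StudyName", text_slot="name"),
            T("BasicDefinitions"),
            T("MetaDataVersion", subtags=["FormDef", "CodeList"]),
            T(
                "FormDef",
                category="Page",
                attributes={"OID": ":NAME", "Name": "name"},
                subtags=["ItemGroupDef"],
            ),
            T(
                "ItemGroupDef",
                category="Module",
                attributes={"OID": ":NAME", "Name": "name"},
                subtags=["ItemDef"],
            ),
            T(
                "ItemDef",
                category="Item",
                attributes={
                    "OID": ":NAME",
                    "Name": "name",
                    "Comment": "description",
                    "RangeCheck": "range",
                },
                subtags=["CodeListRef"],
            ),
            T(
                "CodeListRef",
                ref={
                    "attribute": "CodeListOID",
                    "target_category": "Codelist",
                    "key_slot": ":NAME",
                    "role": "slot",
                    "slot": "codelist",
                },
            ),
            T(
                "CodeList",
                category="Codelist",
                collect=True,
                attributes={"OID": ":NAME", "Name": "name"},
                subtags=["CodeListItem"],
            ),
            T("CodeListItem", value_attributes={"CodedValue": "codes"}),
        ],
    )


def items_table_mapping() -> mapping.FormatMapping:
    """CSV mapping for bulk item import/export (name, description, range)."""
    return mapping.FormatMapping(
        name="items-csv",
        format_type="table",
        target_category="Item",
        column_mappings={"name": "name", "description": "description", "range": "range"},
    )


def _define_domain_ontology(model: OntologyModel) -> None:
    oid = SlotDefinition(":NAME", "string", cardinality_max=1)
    name = SlotDefinition("name", "string", cardinality_max=1)
    define_category(model, "Study", "_GROUP", [oid, name])
    define_category(model, "Page", "_GROUP", [oid, name])
    define_category(model, "Module", "_GROUP", [oid, name])
    define_category(
        model,
        "Item",
        "_OBJECT",
        [
            oid,
            name,
            SlotDefinition("description", "string", cardinality_max=1),
            SlotDefinition("unit_of_measure", "instance_ref", cardinality_max=1),
            SlotDefinition("range", "string", cardinality_max=1),
            SlotDefinition("codelist", "instance_ref", cardinality_max=1),
            SlotDefinition("rules", "expression_ref", cardinality_max=None),
        ],
    )
    define_category(model, "Unit_of_Measure", "_OBJECT", [oid, name])
    define_category(
        model,
        "Codelist",
        "_OBJECT",
        [oid, name, SlotDefinition("codes", "string", cardinality_max=None)],
    )
    define_category(
        model,
        "Constant",
        "_CONSTANT",
        [name, SlotDefinition("value", "number", cardinality_max=1)],
    )
    for upper, lower in [("Study", "Page"), ("Page", "Module"), ("Module", "Item")]:
        hierarchy.add_rule(model, upper, lower)
    model.mappings["odm-example"] = odm_example_mapping()
    model.mappings["items-csv"] = items_table_mapping()


def build_example_project() -> OntologyModel:
    """The worked example project; deterministic, seed-independent."""
    model = bootstrap_task_ontology()
    _define_domain_ontology(model)

    study = create_instance(model, "Study", {":NAME": "S1", "name": "Heart failure study"})
    page = create_instance(model, "Page", {":NAME": "F.B1", "name": "B1"})
    module = create_instance(
        model, "Module", {":NAME": "IG.SOCIO", "name": "Socio-demographic data"}
    )
    yes_no = create_instance(
        model, "Codelist", {":NAME": "CL.YN", "name": "YesNo", "codes": ["YES", "NO"]}
    )
    mmhg = create_instance(model, "Unit_of_Measure", {":NAME": "U.MMHG", "name": "mmHg"})
    dyspnea = create_instance(
        model,
        "Item",
        {
            ":NAME": "IT.DYSPNEA",
            "name": "DYSPNEA_AT_REST",
            "description": "Does the patient have dyspnea at rest?",
            "codelist": yes_no.id,
        },
    )
    sbp = create_instance(
        model,
        "Item",
        {
            ":NAME": "IT.SBP",
            "name": "SYSTOLIC_BLOOD_PRESURE",
            "description": "Systolic blood pressure",
            "unit_of_measure": mmhg.id,
            "range": "[0;300]",
            "rules": [
                "(AND (>= item:SYSTOLIC_BLOOD_PRESURE 0) (<= item:SYSTOLIC_BLOOD_PRESURE 300))"
            ],
        },
    )
    hierarchy.add_to_group(model, study.id, page.id)
    hierarchy.add_to_group(model, page.id, module.id)
    hierarchy.add_to_group(model, module.id, dyspnea.id)
    hierarchy.add_to_group(model, module.id, sbp.id)

    load_obo(model, MINI_PHENOTYPE_OBO, name="mini-hp")
    define_annotation_type(model, "annotated_with")
    define_annotation_type(model, "risk_factor_of")
    symptom_of = define_annotation_type(model, "symptom_of")
    create_annotation(
        model,
        [ElementCondition(element=dyspnea.id, code="YES")],
        symptom_of,
        ["HP:0001635"],
    )
    create_annotation(
        model,
        [ElementCondition(element=sbp.id, range=annotation.parse_range_literal("[121;]"))],
        symptom_of,
        ["HP:0004421"],
    )
    # validate the stored edit-check rule once so a broken fixture fails fast
    expressions.parse_expression(sbp.first("rules"), model)
    return model


def generate_random_project(n_items: int, seed: int) -> OntologyModel:
    """Seed-reproducible project with *n_items* items spread over pages and
    modules; always satisfies the frame and hierarchy invariants."""
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    rng = random.Random(seed)
    model = bootstrap_task_ontology()
    _define_domain_ontology(model)
    study = create_instance(
        model, "Study", {":NAME": f"S{rng.randint(1, 999)}", "name": "Generated study"}
    )
    codelists = []
    for i in range(max(1, n_items // 4) if n_items else 0):
        n_codes = rng.randint(2, 5)
        codelists.append(
            create_instance(
                model,
                "Codelist",
                {
                    ":NAME": f"CL.{i:03d}",
                    "name": f"Codelist {i}",
                    "codes": [f"{c:02d}" for c in range(1, n_codes + 1)],
                },
            )
        )
    # partition items into modules of 1-6, modules into pages of 1-3
    module_sizes: list[int] = []
    remaining = n_items
    while remaining > 0:
        size = min(remaining, rng.randint(1, 6))
        module_sizes.append(size)
        remaining -= size
    item_index = 0
    page_index = 0
    module_index = 0
    while module_index < len(module_sizes):
        page = create_instance(
            model, "Page", {":NAME": f"F.{page_index:03d}", "name": f"Page {page_index}"}
        )
        hierarchy.add_to_group(model, study.id, page.id)
        for _ in range(rng.randint(1, 3)):
            if module_index >= len(module_sizes):
                break
            module = create_instance(
                model,
                "Module",
                {":NAME": f"IG.{module_index:03d}", "name": f"Module {module_index}"},
            )
            hierarchy.add_to_group(model, page.id, module.id)
            for _ in range(module_sizes[module_index]):
                values = {
                    ":NAME": f"IT.{item_index:04d}",
                    "name": f"ITEM_{item_index:04d}",
                }
                if rng.random() < 0.5:
                    values["description"] = f"Question {item_index}"
                if rng.random() < 0.4 and codelists:
                    values["codelist"] = rng.choice(codelists).id
                elif rng.random() < 0.3:
                    lower = rng.randint(0, 50)
                    values["range"] = f"[{lower};{lower + rng.randint(1, 100)}]"
                item = create_instance(model, "Item", values)
                hierarchy.add_to_group(model, module.id, item.id)
                item_index += 1
            module_index += 1
        page_index += 1
    return model


def generate_odm_document(
    project: OntologyModel, format_mapping: mapping.FormatMapping = None
):
    """Serialize a project's studies through the ODM-style mapping."""
    format_mapping = format_mapping or project.mappings.get(
        "odm-example", odm_example_mapping()
    )
    study_roots = [
        i.id
        for i in project.instances.values()
        if i.category == "Study" and hierarchy.parent_of(project, i.id) is None
    ]
    return mapping.export_xml(project, format_mapping, study_roots)
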
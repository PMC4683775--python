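# ose — ontology-based study metadata, headless

`ose` is a Python library and CLI for specifying and managing the *metadata*
of clinical and epidemiological studies: the items captured on case report
forms (questions, measurements, their codelists, units and ranges), the
grouping of those items into modules, pages and whole studies, and the
semantic meaning of item/answer combinations. It is aimed at data managers,
biometricians and medical-informatics engineers who need one semantically
uniform representation of study metadata that can be imported from and
exported to the formats their study software actually speaks.

## The model

Everything is built on a **frame model**: categories (classes) carry
template **slots**, slots are constrained by **facets** (cardinality,
minimum/maximum, defaults, allowed values), and **instances** carry slot
values. Three ontological layers interact:

* a built-in **task ontology** (TO) — the application-generic categories
  every project starts from. Its top level is `_CONFIG` (hidden
  configuration: format mappings, annotation types), `_ELEMENT` (visible
  study elements, with subclasses `_CONSTANT`, `_OBJECT`, `_GROUP`,
  `_ANNOTATION`, `_EXPORT`) and `_ANNOTATING_ONTOLOGY_ROOT`;
* a **domain ontology** (DO) — the organization-specific categories
  (`Study`, `Page`, `Module`, `Item`, `Codelist`, …) embedded as
  subcategories of the TO, with freely definable slots;
* layer tags recording the top-level-ontology grounding of each category.

On top of the frames sit four mechanisms:

* **study hierarchy** — an ordered containment forest over element
  instances (`_contains`), validated against class-level rules
  `upper ⊑ lower`, read either strictly (∀x,y: x :: upper ∧ contains(x,y) →
  y :: lower) or per-edge ("each edge licensed by ≥ 1 rule");
* **format mappings** — declarative tag-tree ↔ category/slot mappings that
  configure, rather than re-code, the XML (CDISC-ODM-style) and delimited-
  table engines, plus a markdown CRF preview;
* **semantic annotation** — concepts from OBO ontologies (HPO-style) linked
  to AND-connected element conditions (item, item + codelist answer,
  item + inclusive numeric range) via typed relations such as `symptom_of`,
  with a maintained inverse index for concept → annotation queries;
* a **rule-expression language** — typed s-expression trees of logical,
  comparison and arithmetic relators over numbers, constants and item
  references, for edit checks like
  `(AND (>= item:SBP 0) (<= item:SBP 300))`.

## Worked example

The built-in example project contains a heart-failure study: page "B1" with
the module "Socio-demographic data", a dyspnea item with a YES/NO codelist
and a systolic-blood-pressure item (mmHg, range `[0;300]`), annotated
against a mini phenotype ontology.

```python
from ose import fixtures, evaluate_annotation
from ose.annotation import annotations_of_concept

model = fixtures.build_example_project()
dyspnea = model.find_by_slot("_ELEMENT", "name", "DYSPNEA_AT_REST")
sbp = model.find_by_slot("_ELEMENT", "name", "SYSTOLIC_BLOOD_PRESURE")

(chf,) = annotations_of_concept(model, "HP:0001635")   # Congestive heart failure
(esbp,) = annotations_of_concept(model, "HP:0004421")  # Elevated systolic blood pressure

record = {dyspnea.id: "YES", sbp.id: 135}
print("congestive heart failure indicated:", evaluate_annotation(chf, record))
print("elevated systolic blood pressure:", evaluate_annotation(esbp, record))
```

prints

```
congestive heart failure indicated: True
elevated systolic blood pressure: True
```

`True` for the first line means *both* AND-connected conditions hold: the
dyspnea question was answered, and the answer is YES. The second line is
true because 135 lies in the annotated range `[121;]` (inclusive — 121
itself would also qualify, 120 would not). The same project renders as a
case-report-form preview:

```
# B1

## Socio-demographic data

- **DYSPNEA_AT_REST** — Does the patient have dyspnea at rest? options: YES | NO
- **SYSTOLIC_BLOOD_PRESURE** — Systolic blood pressure (mmHg) range [0;300]
```

From the shell, the same surface is available as `ose init-example`,
`ose import` / `ose export` (ODM-style XML or CSV through a mapping
document), `ose preview`, `ose validate --rules strict|any_of`,
`ose annotate`, `ose query-concept` and `ose eval` — all thin wrappers over
the library, exiting non-zero on violations.

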
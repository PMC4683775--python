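# Methods

## Frame model and ontological layering

The core is a frame system: categories with template slots, slots with
facets, and instances with ordered slot-value lists. Categories carry a
layer tag (`TLO`, `TO`, `DO`). The top-level-ontology grounding is recorded
*only* as this tag: no higher-order logic is executed, because the layering
serves as documentation of meaning, not as computation. Task-ontology
category names begin with an underscore; `_CONFIG` and all its descendants
are flagged hidden, and hiddenness is closed downward (a category defined
under a hidden parent is hidden). `define_category` refuses to place a
study-element category under a hidden parent so user-visible content cannot
leak into the configuration subtree.

Slots live in a model-wide registry (as in classic frame systems, where
slots are first-class frames): categories reference them by name and
inherit them down the parent chain. Re-declaring a slot with an identical
definition is a no-op; a conflicting re-declaration is an error rather than
a silent semantic change. Values are never coerced across kinds — a string
`"01"` stays a string even though it parses as a number — because codelist
codes must survive round trips byte-identically. `validate_instance`
returns violations as data (one per breached cardinality bound, facet or
dangling reference) and never mutates the model, so it can run as a
pre-save check or interactively.

Domain ontologies are embedded either programmatically
(`define_category`) or from a JSON/YAML config that declares categories,
their parents, slots and hierarchy rules in document order
(`load_domain_ontology`), so an organization can swap its DO without
touching code. The CLI accepts an analogous config file supplying default
mapping and rule-mode choices, with explicit flags taking precedence.

Instance ids are generated from a per-model counter
(`<category>-<counter>`), persisted with the project; ids are therefore
deterministic for any fixed construction sequence and never embed
timestamps. This makes imports reproducible and lets tests compare whole
serialized models.

## Study hierarchy

Containment is a forest: each element has at most one parent, sibling
positions are contiguous 0-based ordinals, and cycle/second-parent attempts
fail atomically (a failed `move_element` leaves the model untouched). A
hierarchy rule `upper ⊑ lower` has two readings:

* **strict** — the universal formula: every child of every instance of
  `upper` (subcategory closure included) instantiates `lower`. This is the
  formally clean reading, but it forbids mixed child types under one
  category: a Page containing both Modules and free Items breaks *every*
  rule whose upper side covers Page.
* **any_of** (default) — per-edge licensing: an edge is valid when at least
  one declared rule covers both endpoints. This is the reading real case
  report forms need.

Both are exposed and selectable per validation run. A model that declares
no rules validates trivially in both modes; requiring licences from an
empty rule set would make every unconfigured project invalid, which is not
useful behaviour for an editor. Instantiation closure ("x :: C counts
subcategories of C") is applied in both readings.

## Format mappings

One engine exists per format *type* (XML, delimited table); a concrete
format is a mapping document, not code. The XML engine walks the declared
tag tree: category-mapped tags become instances, attributes and text fill
slots, nesting between two mapped tags becomes containment in document
order, and structural tags are passed through transparently (on export they
are re-created lazily, one wrapper per parent element, so empty wrappers
never appear). Three refinements cover real metadata dialects:

* *reference tags* (`ItemRef`/`CodeListRef` style) hold a key attribute and
  resolve, after the pass, to a containment edge or a slot value;
* *value tags* (`CodeListItem` style) append an attribute value to a
  multi-valued slot of the nearest mapped ancestor;
* *collected categories* (codelists) serialize under a fixed tree position
  for all instances of the category, independent of containment, since
  codelists live beside — not inside — the study hierarchy.

The shipped example mapping is an ODM-1.3-style dialect (ODM / Study /
GlobalVariables / MetaDataVersion / FormDef / ItemGroupDef / ItemDef /
CodeList / CodeListItem / CodeListRef) in nested form. The engine is
dialect-agnostic; no ODM version is privileged, and clinical *data*
elements (ClinicalData/ItemData) are out of scope — this is a metadata
tool. Round-trip comparisons canonicalize XML as (localname, sorted
attributes, stripped text, children), i.e. attribute-order-insensitive and
whitespace-normalized; model-level isomorphism is checked on an id-free
signature in which instance references are replaced by the referenced
instance's (category, name) pair. Everything is UTF-8; namespaces are
matched by URI, never by prefix. The table engine covers the spreadsheet
role via RFC-4180 CSV with a mandatory header row.

## Annotation

Annotating ontologies are read from OBO 1.2 flat files with `obonet`; only
`id`, `name` and `is_a` are honoured, obsolete terms are skipped, a term
without a name gets its id as label, and duplicate ids (which a plain
parse would silently merge) plus `is_a` cycles are hard errors. Each
loaded ontology gets its own category under `_ANNOTATING_ONTOLOGY_ROOT`,
so several ontologies can coexist; concept identity is the term id, not
the label.

An annotation joins ≥ 1 AND-connected element conditions to ≥ 1 concepts
through a typed relation. A condition is presence-only, presence + codelist
code (the code must be a member of the element's codelist), or presence +
inclusive numeric range — ranges are legal only on codelist-free items.
Range literals use the `[lower;upper]` grammar with either bound omissible;
`[121;]` means ≥ 121, and inclusivity is applied symmetrically to upper
bounds. During evaluation a non-numeric value against a range makes the
condition false (logged), rather than raising: evaluation runs over messy
records. The concept → annotation direction is a maintained index rather
than a metaclass-carried inverse slot; every mutation path updates it, and
its equivalence with a brute-force scan is a standing test property.

## Expressions

Edit-check rules are typed s-expression trees. The operator floor is
`AND`, `OR` (variadic ≥ 2), `NOT`, the six comparisons (binary; `=` also
accepts strings), and `+ - * /` (`+`/`*` variadic); the table is
user-extensible. Arity and operand types are checked at parse time, and
references are resolved against the model when one is supplied, so a
well-typed tree cannot raise a type error during evaluation — the only
runtime errors are unbound references and division by zero. Missing
bindings raise by default (silent nulls would hide data-entry defects);
`partial=True` switches to a three-valued screening mode where unknown
operands propagate unless a known operand is decisive (`OR` with a known
true, `AND` with a known false). Numbers are integers and decimals;
integer division returns an integer when exact. Serialization is
canonical, and `parse ∘ serialize` is the identity on valid trees.

## Synthetic fixtures and what they show

`build_example_project` constructs the worked example deterministically in
code: the heart-failure study (Study → Page "B1" → Module
"Socio-demographic data" → dyspnea and systolic-blood-pressure items), the
YES/NO codelist, the mmHg unit, a synthetic four-term phenotype
mini-ontology (HPO-style ids), three annotation types, the two worked
annotations and one edit-check rule. `generate_random_project(n, seed)`
emits seed-reproducible projects with the same shape — items partitioned
into modules of 1–6, modules into pages of 1–3, roughly a quarter of items
carrying codelists with zero-padded codes, some carrying ranges.

The generators emulate the *structure* of study metadata, not its content
statistics: names are synthetic, slot values are short ASCII strings, and
only the slots the shipped mapping carries are populated. Passing round
trips therefore demonstrate the engines' structural correctness, not
coverage of every vendor's ODM extension attributes, multilingual
`TranslatedText`, or measurement-unit references, which the shipped
mapping simply does not declare.

## Problem sizes and numerical choices

The acceptance script runs 100 generated projects of up to 25 items for
the round-trip suite, 20 models of ≤ 50 instances × 16 rules for the
hierarchy-rule equivalence, 200 create/delete mutations for the inverse
index, and 300 random trees of depth ≤ 5 for the expression suite — sizes
chosen so the brute-force oracles (quadratic instance × edge loops, full
rescans) stay exact and cheap while still exercising every code path the
larger-scale behaviour depends on.
Float comparisons in the expression cross-check use an absolute 1e-9
tolerance; everything else is exact. Sibling ordinals break ties in all
traversals, so every export, preview and descendant listing is
deterministic given a project.

## Known limitations

* No OWL input and no reasoning beyond `is_a` transitive closure.
* The strict hierarchy reading and the any_of reading can disagree by
  design; there is no attempt to infer which a given project "meant".
* Table import creates instances but no containment; hierarchy must come
  from XML import or explicit edits.
* No undo/versioning of structure edits, no GUI, no database backend;
  project persistence is a single JSON document with a hard version gate
  (a newer `format_version` is refused outright, unknown sibling fields
  are preserved on resave).
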
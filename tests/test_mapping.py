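"""Declarative XML/table mappings: import, export, round trips, CRF preview."""

import pytest

from ose import fixtures, hierarchy, mapping, project
from ose.errors import MappingError
from ose.fixtures import ODM_NAMESPACE, odm_example_mapping
from ose.frames import bootstrap_task_ontology
from ose.mapping import canonical_xml, export_xml, import_table, import_xml, export_table

from conftest import by_name


def fresh_domain_model():
    model = bootstrap_task_ontology()
    fixtures._define_domain_ontology(model)
    return model


MINIMAL_ODM = f"""\
<ODM xmlns="{ODM_NAMESPACE}">
  <Study OID="S1">
    <GlobalVariables><StudyName>Pilot</StudyName></GlobalVariables>
    <MetaDataVersion>
      <FormDef OID="F1" Name="Baseline">
        <ItemGroupDef OID="G1" Name="Vitals">
          <ItemDef OID="I1" Name="HEIGHT" Comment="Body height"/>
          <ItemDef OID="I2" Name="SMOKER">
            <CodeListRef CodeListOID="CL1"/>
          </ItemDef>
        </ItemGroupDef>
      </FormDef>
      <CodeList OID="CL1" Name="YesNo">
        <CodeListItem CodedValue="Y"/>
        <CodeListItem CodedValue="N"/>
      </CodeList>
    </MetaDataVersion>
  </Study>
</ODM>
"""


class TestImportXml:
    def test_study_tag_maps_to_study_instance(self):
        model = fresh_domain_model()
        created = import_xml(model, odm_example_mapping(), MINIMAL_ODM)
        studies = model.instances_of("Study")
        assert len(studies) == 1
        assert studies[0].first(":NAME") == "S1"
        assert studies[0].first("name") == "Pilot"
        assert len(created) == 6  # study, form, group, 2 items, codelist

    def test_nesting_becomes_containment_in_document_order(self):
        model = fresh_domain_model()
        import_xml(model, odm_example_mapping(), MINIMAL_ODM)
        study = model.instances_of("Study")[0]
        (page,) = [model.instance(e.child) for e in hierarchy.children_of(model, study.id)]
        (module,) = [model.instance(e.child) for e in hierarchy.children_of(model, page.id)]
        items = [model.instance(e.child) for e in hierarchy.children_of(model, module.id)]
        assert [i.first("name") for i in items] == ["HEIGHT", "SMOKER"]

    def test_codelist_reference_resolved_to_slot(self):
        model = fresh_domain_model()
        import_xml(model, odm_example_mapping(), MINIMAL_ODM)
        smoker = by_name(model, "SMOKER")
        codelist = model.instance(smoker.first("codelist"))
        assert codelist.slot_values["codes"] == ["Y", "N"]
        # the codelist is configuration-side: not in the study hierarchy
        assert hierarchy.parent_of(model, codelist.id) is None

    def test_root_mismatch_rejected(self):
        model = fresh_domain_model()
        with pytest.raises(MappingError):
            import_xml(model, odm_example_mapping(), "<NotODM/>")

    def test_unmapped_element_strict_vs_lenient(self):
        doc = MINIMAL_ODM.replace(
            "<GlobalVariables>", "<Mystery/><GlobalVariables>"
        )
        strict = odm_example_mapping()
        with pytest.raises(MappingError):
            import_xml(fresh_domain_model(), strict, doc)
        lenient = odm_example_mapping()
        lenient.strict = False
        model = fresh_domain_model()
        import_xml(model, lenient, doc)
        assert len(model.instances_of("Study")) == 1

    def test_ref_to_contains_edge(self):
        """ItemRef-style reference tags become containment edges."""
        T = mapping.TagSpec
        ref_mapping = mapping.FormatMapping(
            name="ref-dialect",
            format_type="xml",
            tag_specs=[
                T("Root", is_root=True, subtags=["Group", "Item"]),
                T(
                    "Group",
                    category="Module",
                    attributes={"OID": ":NAME"},
                    subtags=["ItemRef"],
                ),
                T(
                    "ItemRef",
                    ref={
                        "attribute": "ItemOID",
                        "target_category": "Item",
                        "key_slot": ":NAME",
                        "role": "contains",
                    },
                ),
                T("Item", category="Item", collect=True, attributes={"OID": ":NAME"}),
            ],
        )
        doc = (
            "<Root>"
            '<Group OID="G1"><ItemRef ItemOID="I1"/><ItemRef ItemOID="I2"/></Group>'
            '<Item OID="I1"/><Item OID="I2"/>'
            "</Root>"
        )
        model = fresh_domain_model()
        import_xml(model, ref_mapping, doc)
        group = model.instances_of("Module")[0]
        children = [
            model.instance(e.child).first(":NAME")
            for e in hierarchy.children_of(model, group.id)
        ]
        assert children == ["I1", "I2"]


class TestExportXml:
    def test_study_attribute_export(self, example):
        doc = export_xml(example, odm_example_mapping(), [by_name(example, "Heart failure study").id])
        study_el = doc.find(f"{{{ODM_NAMESPACE}}}Study")
        assert study_el.get("OID") == "S1"

    def test_empty_instance_list_gives_root_only(self, example):
        doc = export_xml(example, odm_example_mapping(), [])
        # collected codelists still appear nowhere without an anchor study
        assert [c for c in doc] == []

    def test_unmapped_category_rejected(self, example):
        mmhg = example.find_by_slot("Unit_of_Measure", "name", "mmHg")
        with pytest.raises(MappingError):
            export_xml(example, odm_example_mapping(), [mmhg.id])

    def test_export_import_canonical_round_trip(self):
        original = fixtures.generate_random_project(18, 5)
        doc = fixtures.generate_odm_document(original)
        reimported = fresh_domain_model()
        import_xml(reimported, odm_example_mapping(), doc)
        doc2 = fixtures.generate_odm_document(reimported)
        assert canonical_xml(doc) == canonical_xml(doc2)

    def test_export_is_byte_stable(self):
        p1 = fixtures.generate_random_project(10, 2)
        p2 = fixtures.generate_random_project(10, 2)
        text1 = mapping.xml_to_string(fixtures.generate_odm_document(p1))
        text2 = mapping.xml_to_string(fixtures.generate_odm_document(p2))
        assert text1 == text2

    def test_import_does_not_mutate_mapping(self):
        fmt = odm_example_mapping()
        before = fmt.to_dict()
        import_xml(fresh_domain_model(), fmt, MINIMAL_ODM)
        assert fmt.to_dict() == before


class TestProjectRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_import_of_export_is_isomorphic(self, seed):
        original = fixtures.generate_random_project(12 + seed, seed)
        doc = fixtures.generate_odm_document(original)
        reimported = fresh_domain_model()
        import_xml(reimported, odm_example_mapping(), doc)
        assert project.structural_signature(original) == project.structural_signature(
            reimported
        )


class TestTables:
    def test_import_two_rows(self):
        model = fresh_domain_model()
        created = import_table(
            model,
            fixtures.items_table_mapping(),
            "name,description,range\r\nAGE,Age in years,[0;120]\r\nSEX,Biological sex,\r\n",
        )
        assert len(created) == 2
        age = by_name(model, "AGE")
        assert age.first("range") == "[0;120]"
        assert by_name(model, "SEX").first("range") is None

    def test_export_zero_instances_is_header_only(self):
        model = fresh_domain_model()
        assert export_table(model, fixtures.items_table_mapping(), []) == (
            "name,description,range\r\n"
        )

    def test_round_trip_preserves_cell_values(self):
        model = fresh_domain_model()
        text = "name,description,range\r\nAGE,Age in years,[0;120]\r\nBMI,,[10;80]\r\n"
        created = import_table(model, fixtures.items_table_mapping(), text)
        assert export_table(model, fixtures.items_table_mapping(), created) == text

    def test_missing_mapped_column_rejected(self):
        model = fresh_domain_model()
        with pytest.raises(MappingError):
            import_table(model, fixtures.items_table_mapping(), "name,comment\r\nX,Y\r\n")

    def test_duplicate_header_rejected(self):
        model = fresh_domain_model()
        with pytest.raises(MappingError):
            import_table(model, fixtures.items_table_mapping(), "name,name,range\r\nX,Y,\r\n")

    def test_table_and_xml_paths_agree_on_slot_values(self):
        """Equivalent content through the CSV and XML engines yields
        slot-value-identical item instances."""
        via_table = fresh_domain_model()
        import_table(
            via_table,
            fixtures.items_table_mapping(),
            "name,description,range\r\nHEIGHT,Body height,\r\n",
        )
        via_xml = fresh_domain_model()
        import_xml(via_xml, odm_example_mapping(), MINIMAL_ODM)
        t_item = by_name(via_table, "HEIGHT")
        x_item = by_name(via_xml, "HEIGHT")
        keys = ("name", "description", "range")
        assert {k: t_item.first(k) for k in keys} == {k: x_item.first(k) for k in keys}


class TestCrfPreview:
    def test_headings_and_items(self, example):
        page = by_name(example, "B1")
        text = mapping.render_crf_preview(example, page.id)
        assert text.splitlines()[0] == "# B1"
        assert "## Socio-demographic data" in text
        assert "**DYSPNEA_AT_REST**" in text

    def test_codelist_options_listed(self, example):
        page = by_name(example, "B1")
        text = mapping.render_crf_preview(example, page.id)
        assert "options: YES | NO" in text
        assert "(mmHg)" in text and "range [0;300]" in text

    def test_empty_group_is_heading_only(self, example):
        from ose import create_instance

        lonely = create_instance(example, "Page", {"name": "Empty page"})
        assert mapping.render_crf_preview(example, lonely.id) == "# Empty page\n"

    def test_non_group_root_rejected(self, example):
        item = by_name(example, "DYSPNEA_AT_REST")
        with pytest.raises(MappingError):
            mapping.render_crf_preview(example, item.id)

    def test_deterministic(self, example):
        page = by_name(example, "B1")
        assert mapping.render_crf_preview(example, page.id) == mapping.render_crf_preview(
            example, page.id
        )
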
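"""Bead assignment: partition property, typing rules, manual-file dialect."""

import io

import pytest

import sugarcg as sc
from sugarcg.cg_mapping import (
    MappingError,
    MappingRules,
    assign_beads,
    bead_type_of,
    read_mapping_file,
    validate_mapping,
    write_mapping_file,
)
from sugarcg.chem_model import Sugar, build_atom_graph


def _names(all_40_specs):
    return [s.name for s in all_40_specs]


class TestAssignBeads:
    def test_maltose_bead_and_vs_counts(self, maltose_graph):
        mapping = assign_beads(maltose_graph)
        assert len(mapping.real_beads) == 6
        assert sum(b.is_virtual for b in mapping.beads) == 2
        assert len(mapping.virtual_sites) == 2

    def test_partition_property_all_specs(self, all_40_specs):
        for spec in all_40_specs:
            graph = build_atom_graph(spec)
            mapping = assign_beads(graph)
            assigned = [ref for b in mapping.real_beads for ref in b.atoms]
            assert sorted(assigned) == sorted(graph.atom_order), spec.name

    def test_heavy_counts_and_hydrogen_colocation(self, all_40_specs):
        for spec in all_40_specs:
            graph = build_atom_graph(spec)
            g = graph.graph
            mapping = assign_beads(graph)
            atom_to_bead = mapping.atom_to_bead()
            for bead in mapping.real_beads:
                heavy = [r for r in bead.atoms if g.nodes[r]["heavy"]]
                assert 3 <= len(heavy) <= 5, (spec.name, bead.bead_name)
            for ref in graph.atom_order:
                if not g.nodes[ref]["heavy"]:
                    heavy_nb = next(n for n in g.neighbors(ref) if g.nodes[n]["heavy"])
                    assert atom_to_bead[ref] == atom_to_bead[heavy_nb]

    def test_exactly_one_bead_holds_glycosidic_oxygen(self, all_40_specs):
        for spec in all_40_specs:
            graph = build_atom_graph(spec)
            mapping = assign_beads(graph)
            holders = [b.bead_name for b in mapping.real_beads
                       if graph.glycosidic_oxygen in b.atoms]
            assert len(holders) == 1, spec.name

    def test_deterministic_byte_identical(self, maltose_graph):
        a = write_mapping_file(assign_beads(maltose_graph))
        b = write_mapping_file(assign_beads(maltose_graph))
        assert a == b

    def test_trehalose_symmetry_except_glycosidic_bead(self, trehalose_graph):
        mapping = assign_beads(trehalose_graph)
        by_name = {b.bead_name: b for b in mapping.real_beads}
        # swap residues on the acceptor partition: A2/A3 mirror B2/B3 exactly
        for a_name, b_name in (("A2", "B2"), ("A3", "B3")):
            swapped = {(3 - r, n) for r, n in by_name[a_name].atoms}
            assert swapped == set(by_name[b_name].atoms)
        # the glycosidic bead differs from its mirror by exactly the bridging O
        a1 = {(3 - r, n) for r, n in by_name["A1"].atoms if n != "O1"}
        b1 = {(r, n) for r, n in by_name["B1"].atoms if (r, n) != (1, "O1")}
        assert a1 == b1

    def test_broken_rules_raise_mapping_error_naming_atoms(self, maltose_graph):
        rules = MappingRules(
            donor_slots={
                "124": (("C1", "C2", "O2"), ("C3", "C4", "O4"), ("C5", "O5", "C6", "O6")),
                "6": MappingRules().donor_slots["6"],
            }
        )
        with pytest.raises(MappingError, match="O3"):
            assign_beads(maltose_graph, rules)

    def test_split_bead_detected(self, maltose_graph):
        mapping = assign_beads(maltose_graph)
        # move a non-adjacent atom pair into one bead: swap C1 and C5 heavy groups
        import dataclasses

        beads = list(mapping.beads)
        a1, a3 = beads[0], beads[2]
        moved = tuple(r for r in a1.atoms if r[1] != "C1") + ((1, "C5"),)
        back = tuple(r for r in a3.atoms if r[1] != "C5") + ((1, "C1"),)
        beads[0] = dataclasses.replace(a1, atoms=moved)
        beads[2] = dataclasses.replace(a3, atoms=back)
        broken = dataclasses.replace(mapping, beads=tuple(beads))
        with pytest.raises(MappingError, match="split|span"):
            validate_mapping(broken, maltose_graph)


class TestBeadTypes:
    def test_glc_1_3_types_within_published_alphabet(self):
        graph = build_atom_graph(sc.parse_glycam_name("3GB_0GB"))
        mapping = assign_beads(graph)
        types = {b.bead_type for b in mapping.real_beads}
        assert types <= {"SP4r", "SP1r", "SN6"}

    def test_man_1_6_junction_uses_sn6r(self):
        graph = sc.build_atom_graph(sc.parse_glycam_name("6MB_0MA"))
        mapping = assign_beads(graph)
        types = {b.bead_type for b in mapping.real_beads}
        assert "SN6r" in types
        glc6 = assign_beads(sc.build_atom_graph(sc.parse_glycam_name("6GB_0GB")))
        assert "SN6r" not in {b.bead_type for b in glc6.real_beads}

    def test_unknown_key_raises(self):
        with pytest.raises(KeyError):
            bead_type_of(MappingRules(), "donor", 7, 4, Sugar.GLC)
        with pytest.raises(KeyError):
            bead_type_of(MappingRules(), "linker", 0, 4, Sugar.GLC)

    def test_virtual_sites_use_configured_label(self, maltose_graph):
        rules = MappingRules(vs_type="TX1")
        mapping = assign_beads(maltose_graph, rules)
        assert {b.bead_type for b in mapping.beads if b.is_virtual} == {"TX1"}


class TestMappingFiles:
    def test_round_trip_is_canonical_identity(self, maltose_graph):
        text = write_mapping_file(assign_beads(maltose_graph))
        again = write_mapping_file(read_mapping_file(io.StringIO(text)))
        assert again == text

    def test_duplicate_atom_reports_line_number(self):
        bad = (
            "1 A1 SP4r C1 H1 O1 HO1\n"
            "1 A2 SP1r C3 H3 C1\n"
        )
        with pytest.raises(MappingError, match=r":2:"):
            read_mapping_file(io.StringIO(bad))

    def test_unknown_atom_token_rejected(self):
        with pytest.raises(MappingError, match="unknown atom token"):
            read_mapping_file(io.StringIO("1 A1 SP4r c-1\n"))

    def test_missing_residue_rejected(self):
        bad = "1 A1 SP4r C1 C2 O2\nVS 2 A1 A1 A1\n"
        with pytest.raises(MappingError, match="residue"):
            read_mapping_file(io.StringIO(bad))

    def test_manual_maltose_file_reproduces_automated_mapping(self, maltose_graph):
        # hand-written beta-maltose mapping in the documented dialect
        manual = """\
# beta-maltose (4GB_0GA): reducing 4GB = residue 1, terminal 0GA = residue 2
1 A1 SP4r C1 H1 O1 HO1 C2 H2 O2 HO2
1 A2 SP1r C3 H3 O3 HO3 C4 H4
1 A3 SP4r C5 H5 O5 C6 H61 H62 O6 HO6
2 B1 SN6  C1 H1 C2 H2 O2 HO2 1:O4
2 B2 SP1r C3 H3 O3 HO3 C4 H4 O4 HO4
2 B3 SP4r C5 H5 O5 C6 H61 H62 O6 HO6
VS 1 A1 A2 A3
VS 2 B1 B2 B3
"""
        mapping = read_mapping_file(io.StringIO(manual))
        validate_mapping(mapping, maltose_graph)
        auto = assign_beads(maltose_graph)
        for got, want in zip(mapping.real_beads, auto.real_beads):
            assert got.bead_name == want.bead_name
            assert set(got.atoms) == set(want.atoms)
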
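"""Analysis granularities: individual, component, interface, complex."""

import numpy as np
import pytest

from fodm import (
    AnalysisParams,
    UnitSelection,
    analyze_complex,
    analyze_component,
    analyze_individual,
    analyze_with_interface,
    interface_residues,
    make_inverted,
    make_micelle,
    parse_structure,
    records_to_tsv,
)
from fodm.errors import SelectionError
from fodm.units import profile_table

from conftest import atom_line, make_pdb_text


def ca_chain_pdb(tmp_path, name, coords_by_chain):
    """CA-only PDB with several chains: {chain: [(resseq, x, y, z), ...]}."""
    lines = []
    serial = 1
    for chain, coords in coords_by_chain.items():
        for resseq, x, y, z in coords:
            lines.append(atom_line(serial, "CA", "LEU", chain, resseq, x, y, z))
            serial += 1
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\nEND\n")
    return parse_structure(p)


@pytest.fixture
def two_chain_structure(tmp_path, rng):
    """Two compact 20-residue chains ~12 A apart (interface in the middle)."""
    a = rng.normal(scale=3.0, size=(20, 3))
    b = rng.normal(scale=3.0, size=(20, 3)) + np.array([12.0, 0.0, 0.0])
    return ca_chain_pdb(tmp_path, "dimer.pdb", {
        "A": [(i + 1, *a[i]) for i in range(20)],
        "B": [(i + 1, *b[i]) for i in range(20)],
    })


class TestIndividualAndComponent:
    def test_component_of_full_parent_equals_individual(self, two_chain_structure):
        parent = UnitSelection(label="A", chain_ids=("A",))
        rec_ind = analyze_individual(two_chain_structure, parent)
        rec_comp = analyze_component(two_chain_structure, parent, parent)
        assert rec_comp.rd == pytest.approx(rec_ind.rd, abs=1e-12)
        assert rec_comp.k == rec_ind.k
        assert rec_comp.n_residues == rec_ind.n_residues

    def test_disjoint_components_conserve_parent_o(self, two_chain_structure):
        # unnormalized restricted O values of a partition reassemble the parent
        from fodm.field_profiles import o_profile, orient_unit
        from fodm.units import _unit_arrays

        params = AnalysisParams()
        parent = UnitSelection(label="A", chain_ids=("A",))
        pts, hv, labels = _unit_arrays(two_chain_structure, parent, params)
        unit = orient_unit(pts, hv, labels)
        o = o_profile(unit, cutoff_c=params.cutoff)
        half1, half2 = o.values[:10], o.values[10:]
        assert half1.sum() + half2.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.concatenate([half1, half2]), o.values)

    def test_sub_outside_parent_rejected(self, two_chain_structure):
        parent = UnitSelection(label="A", chain_ids=("A",))
        alien = UnitSelection(label="B-range", residue_ranges=(("B", 1, 10),))
        with pytest.raises(SelectionError):
            analyze_component(two_chain_structure, parent, alien)

    def test_too_small_selection_rejected(self, two_chain_structure):
        tiny = UnitSelection(label="tiny", residue_ranges=(("A", 1, 2),))
        with pytest.raises(SelectionError):
            analyze_individual(two_chain_structure, tiny)

    def test_records_are_deterministic(self, two_chain_structure):
        sel = UnitSelection(label="A", chain_ids=("A",))
        r1 = analyze_individual(two_chain_structure, sel)
        r2 = analyze_individual(two_chain_structure, sel)
        assert r1.rd == r2.rd and r1.k == r2.k
        assert r1.result.d_ot == r2.result.d_ot

    def test_provenance_stamped(self, two_chain_structure):
        rec = analyze_individual(
            two_chain_structure, UnitSelection(label="A", chain_ids=("A",)))
        assert rec.provenance["scale"] == "kyte_doolittle"
        assert rec.provenance["cutoff_A"] == 9.0
        assert rec.provenance["k_grid"] == [0.0, 10.0, 0.01]


class TestInterface:
    def test_distant_partner_gives_empty_pp(self, tmp_path, rng):
        a = rng.normal(scale=3.0, size=(10, 3))
        st = ca_chain_pdb(tmp_path, "far.pdb", {
            "A": [(i + 1, *a[i]) for i in range(10)],
            "B": [(i + 1, a[i, 0] + 100.0, a[i, 1], a[i, 2]) for i in range(10)],
        })
        pp, nopp = interface_residues(
            st, UnitSelection(label="A", chain_ids=("A",)),
            UnitSelection(label="B", chain_ids=("B",)))
        assert not pp.any() and nopp.all()

    def test_exact_threshold_is_contact(self, tmp_path):
        st = ca_chain_pdb(tmp_path, "edge.pdb", {
            "A": [(1, 0.0, 0.0, 0.0)],
            "B": [(1, 9.0, 0.0, 0.0)],
        })
        pp, _ = interface_residues(
            st, UnitSelection(label="A", chain_ids=("A",)),
            UnitSelection(label="B", chain_ids=("B",)), threshold=9.0)
        assert pp.tolist() == [True]

    def test_single_contact_identified(self, tmp_path):
        # five collinear target residues; one partner residue 5 A from residue 3
        st = ca_chain_pdb(tmp_path, "contact.pdb", {
            "A": [(i + 1, 20.0 * i, 0.0, 0.0) for i in range(5)],
            "B": [(1, 40.0, 5.0, 0.0)],
        })
        pp, nopp = interface_residues(
            st, UnitSelection(label="A", chain_ids=("A",)),
            UnitSelection(label="B", chain_ids=("B",)))
        assert pp.tolist() == [False, False, True, False, False]
        assert (pp ^ nopp).all()  # exhaustive and disjoint

    def test_partition_exhaustive_disjoint(self, two_chain_structure):
        pp, nopp = interface_residues(
            two_chain_structure, UnitSelection(label="A", chain_ids=("A",)),
            UnitSelection(label="B", chain_ids=("B",)))
        assert pp.sum() + nopp.sum() == 20
        assert not (pp & nopp).any()

    def test_interface_record_has_both_classes(self, two_chain_structure):
        rec = analyze_with_interface(
            two_chain_structure,
            UnitSelection(label="A", chain_ids=("A",)),
            UnitSelection(label="B", chain_ids=("B",)))
        assert rec.rd_pp is not None and rec.rd_nopp is not None
        assert 0 <= rec.rd_pp <= 1 and 0 <= rec.rd_nopp <= 1
        assert 0 < rec.n_pp < 20

    def test_no_partners_gives_rd_only(self, two_chain_structure):
        rec = analyze_with_interface(
            two_chain_structure, UnitSelection(label="A", chain_ids=("A",)), None)
        assert rec.rd_pp is None and rec.rd_nopp is None

    def test_all_contact_duplicates_rd_and_omits_nopp(self, tmp_path, rng):
        # interlocked chains: every A residue within 9 A of a B residue
        a = rng.normal(scale=2.0, size=(10, 3))
        st = ca_chain_pdb(tmp_path, "mixed.pdb", {
            "A": [(i + 1, *a[i]) for i in range(10)],
            "B": [(i + 1, a[i, 0] + 1.0, a[i, 1], a[i, 2]) for i in range(10)],
        })
        rec = analyze_with_interface(
            st, UnitSelection(label="A", chain_ids=("A",)),
            UnitSelection(label="B", chain_ids=("B",)))
        assert rec.rd_pp == pytest.approx(rec.rd)
        assert rec.rd_nopp is None


class TestComplex:
    def test_complex_report_shape(self, two_chain_structure):
        parts = [UnitSelection(label="first half of A",
                               residue_ranges=(("A", 1, 10),))]
        records = analyze_complex(two_chain_structure, parts)
        # 1 complex + per chain (component + individual) * 2 + 1 partition
        assert len(records) == 1 + 2 * 2 + 1
        labels = [r.label for r in records]
        assert labels[0].endswith("complex")
        assert any("in complex" in l for l in labels)

    def test_single_chain_complex_equals_chain(self, tmp_path, rng):
        a = rng.normal(scale=3.0, size=(15, 3))
        st = ca_chain_pdb(tmp_path, "mono.pdb", {
            "A": [(i + 1, *a[i]) for i in range(15)]})
        records = analyze_complex(st)
        complex_rec, _, individual_rec = records
        assert complex_rec.rd == pytest.approx(individual_rec.rd, abs=1e-12)

    def test_full_partition_component_equals_complex(self, two_chain_structure):
        part = UnitSelection(label="everything", chain_ids=("A", "B"))
        records = analyze_complex(two_chain_structure, [part])
        assert records[-1].rd == pytest.approx(records[0].rd, abs=1e-12)


class TestSyntheticClassification:
    @pytest.mark.parametrize("seed", range(10))
    def test_micelle_units_show_core(self, seed):
        assert analyze_individual(make_micelle(100, seed=seed)).rd < 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_inverted_units_lack_core(self, seed):
        rec = analyze_individual(make_inverted(100, seed=seed))
        assert rec.rd > 0.5
        assert rec.k > 0.5  # strong field modification


class TestReporting:
    def test_tsv_columns_and_dash_convention(self, two_chain_structure, tmp_path):
        recs = [
            analyze_with_interface(
                two_chain_structure, UnitSelection(label="A", chain_ids=("A",)),
                UnitSelection(label="B", chain_ids=("B",))),
            analyze_individual(two_chain_structure,
                               UnitSelection(label="B", chain_ids=("B",))),
        ]
        out = tmp_path / "report.tsv"
        df = records_to_tsv(recs, out)
        assert list(df.columns) == ["label", "fragment", "mode", "n_residues",
                                    "RD", "RD_PP", "RD_noPP", "K"]
        text = out.read_text()
        assert "−" in text  # absent interface values rendered as a dash

    def test_profile_table_shape(self, two_chain_structure):
        df = profile_table(two_chain_structure,
                           UnitSelection(label="A", chain_ids=("A",)))
        assert len(df) == 20
        assert {"T", "O", "R", "M"} <= set(df.columns)
        for col in ("T", "O", "R", "M"):
            assert df[col].sum() == pytest.approx(1.0, abs=1e-9)
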
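import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetra import synthdata
from tetra.structio import RigidTransform, fxiii_a_domains, uniform_domain_map
from tetra.xlinks import (
    CrossLink,
    CrossLinkError,
    DistanceRestraint,
    Selector,
    build_restraints,
    domain_contact_matrix,
    evaluate_restraints,
    export_restraints,
    load_crosslinks,
    restraint_distance,
    write_crosslinks,
)

CSV_HEADER = "protein_1,residue_1,protein_2,residue_2,linker\n"


class TestLoad:
    def test_three_rows(self, tmp_path):
        p = tmp_path / "links.csv"
        p.write_text(CSV_HEADER + "A,10,B,20,DSS\nA,11,B,22,DSS\nA,5,A,9,DSS\n")
        table = load_crosslinks(str(p))
        assert len(table) == 3
        assert table[0].kind == "inter" and table[2].kind == "intra"

    def test_bad_row_collected(self, tmp_path):
        p = tmp_path / "links.csv"
        p.write_text(CSV_HEADER + "A,0,B,20,DSS\nA,11,B,22,DSS\n")
        table = load_crosslinks(str(p))
        assert len(table) == 1 and len(table.errors) == 1

    def test_no_parseable_rows_raise(self, tmp_path):
        p = tmp_path / "links.csv"
        p.write_text(CSV_HEADER + "A,zero,B,x,DSS\n")
        with pytest.raises(CrossLinkError):
            load_crosslinks(str(p))

    def test_generator_file_round_trip(self, toy2, tmp_path):
        links, _ = synthdata.sample_crosslinks(toy2, n=12, satisfied_fraction=0.5, seed=1)
        p = tmp_path / "gen.csv"
        write_crosslinks(links, str(p))
        assert list(load_crosslinks(str(p))) == links


class TestBuild:
    def test_default_dss_bounds(self):
        (r,) = build_restraints([CrossLink("A", 10, "B", 20)], {"A": ["A"], "B": ["B"]})
        assert (r.lower_bound, r.upper_bound) == (3.0, 24.0)

    def test_empty_input(self):
        assert build_restraints([], {"A": ["A"]}) == []

    def test_homodimer_ambiguity_expands_to_chain_product(self):
        restraints = build_restraints(
            [CrossLink("X", 1, "Y", 2)], {"X": ["A", "B"], "Y": ["C", "D"]}
        )
        # enumeration: 2 chains x 2 chains = 4 alternatives in one OR-group
        assert len(restraints) == 4
        assert {r.group for r in restraints} == {0}
        pairs = {(r.selector_1.chain_id, r.selector_2.chain_id) for r in restraints}
        assert pairs == {("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")}

    def test_unmapped_protein_errors(self):
        with pytest.raises(CrossLinkError):
            build_restraints([CrossLink("A", 1, "Q", 2)], {"A": ["A"]})

    def test_invalid_bounds_rejected(self):
        with pytest.raises(CrossLinkError):
            DistanceRestraint(Selector("A", 1), Selector("B", 2), 24.0, 3.0)


class TestEvaluate:
    def test_in_and_out_of_band(self, toy2):
        links, labels = synthdata.sample_crosslinks(toy2, n=20, satisfied_fraction=0.5, seed=2)
        restraints = build_restraints(links, {c: [c] for c in toy2.chains()})
        report = evaluate_restraints(toy2, restraints)
        by_group = dict(zip(report.details["group"], report.details["status"]))
        for g, label in enumerate(labels):
            assert by_group[g] == ("satisfied" if label else "violated")

    def test_planted_fraction_recovered_exactly(self, toy2):
        links, _ = synthdata.sample_crosslinks(toy2, n=40, satisfied_fraction=0.75, seed=0)
        restraints = build_restraints(links, {c: [c] for c in toy2.chains()})
        report = evaluate_restraints(toy2, restraints)
        assert report.satisfaction_fraction == 0.75

    def test_agrees_with_brute_force_distances(self, toy2):
        assert toy2.n_atoms <= 500
        links, _ = synthdata.sample_crosslinks(toy2, n=30, satisfied_fraction=0.6, seed=5)
        restraints = build_restraints(links, {c: [c] for c in toy2.chains()})
        # oracle: all-pairs scan over raw atom records
        atoms = {(a.chain_id, a.residue_index, a.atom_name): a.position for a in toy2.atoms()}
        for r in restraints:
            def anchor(sel):
                cb = atoms.get((sel.chain_id, sel.residue_index, "CB"))
                return cb if cb is not None else atoms[(sel.chain_id, sel.residue_index, "CA")]
            expected = float(np.linalg.norm(anchor(r.selector_1) - anchor(r.selector_2)))
            assert restraint_distance(toy2, r) == pytest.approx(expected, abs=1e-12)

    def test_selector_swap_keeps_status(self, toy2):
        links, _ = synthdata.sample_crosslinks(toy2, n=10, satisfied_fraction=0.5, seed=3)
        fwd = build_restraints(links, {c: [c] for c in toy2.chains()})
        swapped = [
            DistanceRestraint(r.selector_2, r.selector_1, r.lower_bound, r.upper_bound, r.group)
            for r in fwd
        ]
        a = evaluate_restraints(toy2, fwd).details["status"]
        b = evaluate_restraints(toy2, swapped).details["status"]
        assert list(a) == list(b)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-180, 180),
        tx=st.floats(-30, 30),
        tz=st.floats(-10, 10),
    )
    def test_fraction_invariant_under_rigid_transform(self, toy2, angle, tx, tz):
        links, _ = synthdata.sample_crosslinks(toy2, n=16, satisfied_fraction=0.5, seed=4)
        restraints = build_restraints(links, {c: [c] for c in toy2.chains()})
        base = evaluate_restraints(toy2, restraints).satisfaction_fraction
        moved = toy2.transformed(RigidTransform.about_z(angle, (tx, 0.0, tz)))
        assert evaluate_restraints(moved, restraints).satisfaction_fraction == base

    def test_unresolvable_residue_counted_separately(self, toy2):
        r_ok = DistanceRestraint(Selector("A", 1), Selector("A", 5), group=0)
        r_bad = DistanceRestraint(Selector("A", 999), Selector("A", 5), group=1)
        report = evaluate_restraints(toy2, [r_ok, r_bad])
        assert report.n_unmappable == 1
        assert report.n_total == 2
        # unmappable groups do not dilute the satisfaction fraction
        assert report.satisfaction_fraction in (0.0, 1.0)


class TestContactMatrix:
    def test_barrel_to_sushi_cell(self):
        domains = {
            "FXIIIA": fxiii_a_domains(("A",)),
            "FXIIIB": uniform_domain_map(("B",), 10, 60),
        }
        mat = domain_contact_matrix([CrossLink("FXIIIA", 600, "FXIIIB", 30)], domains)
        assert mat.loc["FXIIIA:beta-barrel-1", "FXIIIB:S1"] == 1
        assert mat.to_numpy().sum() == 1

    def test_empty_input_all_zero(self):
        mat = domain_contact_matrix([], {})
        assert mat.size == 0

    def test_34_interface_links_sum_to_34(self, toy2):
        links, _ = synthdata.sample_crosslinks(toy2, n=34, satisfied_fraction=1.0, seed=6)
        domains = {c: uniform_domain_map((c,), 4, 5) for c in toy2.chains()}
        mat = domain_contact_matrix(links, domains)
        assert mat.to_numpy().sum() == 34


class TestExport:
    def _restraints(self, n=4):
        links = [CrossLink("A", 10 + i, "B", 40 + i) for i in range(n)]
        return build_restraints(links, {"A": ["A"], "B": ["B"]})

    def test_tbl_renders_bounds(self):
        text = export_restraints(self._restraints(1), "haddock_tbl")
        assert "24.0 21.0 0.0" in text  # distance / minus encodes the 3-24 A window
        assert text.count("assign") == 1

    def test_deterministic_bytes(self):
        r = self._restraints()
        assert export_restraints(r, "haddock_tbl") == export_restraints(r, "haddock_tbl")
        assert export_restraints(r, "csv") == export_restraints(r, "csv")

    def test_64_groups_yield_64_blocks(self, toy2):
        links, _ = synthdata.sample_crosslinks(toy2, n=64, satisfied_fraction=0.5, seed=9)
        restraints = build_restraints(links, {c: [c] for c in toy2.chains()})
        text = export_restraints(restraints, "haddock_tbl")
        assert text.count("assign") == 64

    def test_ambiguous_group_renders_or_block(self):
        restraints = build_restraints(
            [CrossLink("X", 1, "Y", 2)], {"X": ["A", "B"], "Y": ["C"]}
        )
        text = export_restraints(restraints, "haddock_tbl")
        assert text.count("assign") == 1 and " or " in text

    def test_unknown_dialect(self):
        with pytest.raises(CrossLinkError):
            export_restraints(self._restraints(1), "xml")

    def test_empty_errors(self):
        with pytest.raises(CrossLinkError):
            export_restraints([], "csv")
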
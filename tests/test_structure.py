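"""Structure parsing, contacts, burial, annotation and superposition."""

import math

import numpy as np
import pytest
from Bio.SVDSuperimposer import SVDSuperimposer

from suppscan.records import RegionSpec, SubstitutionRecord
from suppscan.structure import (
    ChainMap,
    ContactThresholds,
    CoreParams,
    Selection,
    StructureModel,
    annotate_sites,
    annotation_summary,
    hydrophobic_core_residues,
    inter_chain_contacts,
    kabsch,
    read_structure,
    segment_rotation_angle,
    superpose,
)
from suppscan.synthstruct import (
    make_ca_line,
    make_helix,
    make_hinge_pair,
    make_packed_cluster,
    make_residue,
    merge_models,
    rotation_about_axis,
    transform_model,
    write_model,
)


def pdb_atom_line(serial, name, resname, chain, resseq, xyz, occ=1.0, altloc=" ", element="C"):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


class TestReadStructure:
    def test_two_residue_synthetic_pdb(self, tmp_path):
        model = make_ca_line("GA", "A")
        path = tmp_path / "two.pdb"
        write_model(model, path)
        loaded = read_structure(path)
        assert list(loaded.chains) == ["A"]
        assert [r.number for r in loaded.chain("A")] == [1, 2]

    def test_pdb_and_mmcif_give_identical_models(self, tmp_path):
        model = make_helix("LIVFMWYA", "B", start=5)
        p1, p2 = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_model(model, p1)
        write_model(model, p2)
        a, b = read_structure(p1, "pdb"), read_structure(p2, "mmcif")
        ra, rb = a.chain("B"), b.chain("B")
        assert [(r.number, r.name) for r in ra] == [(r.number, r.name) for r in rb]
        assert np.allclose(
            [r.atoms[0].xyz for r in ra], [r.atoms[0].xyz for r in rb], atol=1e-3
        )

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, (0, 0, 0), occ=0.6, altloc="A"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, (5, 0, 0), occ=0.4, altloc="B"),
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        (res,) = model.chain("A")
        assert len(res.atoms) == 1
        assert np.allclose(res.atom("CA").xyz, (0, 0, 0))

    def test_hydrogens_dropped(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, (0, 0, 0)),
            pdb_atom_line(2, "HA", "ALA", "A", 1, (0.5, 0, 0), element="H"),
            "END",
        ]
        path = tmp_path / "h.pdb"
        path.write_text("\n".join(lines) + "\n")
        (res,) = read_structure(path).chain("A")
        assert [a.name for a in res.atoms] == ["CA"]

    def test_missing_chain_names_available(self):
        model = make_ca_line("GA", "A")
        with pytest.raises(KeyError, match="available chains"):
            model.chain("Z")


class TestContacts:
    def test_close_glycines_are_vdw_contact(self):
        m = merge_models(
            make_ca_line("G", "A"), make_ca_line("G", "B", origin=(3.5, 0, 0))
        )
        contacts = inter_chain_contacts(m, "A", "B")
        assert len(contacts) == 1
        assert contacts[0].category == "vdw"
        assert contacts[0].min_distance == pytest.approx(3.5)

    def test_distant_pair_no_contact(self):
        m = merge_models(
            make_ca_line("G", "A"), make_ca_line("G", "B", origin=(10, 0, 0))
        )
        assert inter_chain_contacts(m, "A", "B") == []

    def test_glu_arg_salt_bridge(self):
        glu = make_residue("GLU", 1, (0, 0, 0), [("OE1", "O", (2, 0, 0))])
        arg = make_residue("ARG", 1, (7, 0, 0), [("NH1", "N", (5, 0, 0))])
        m = StructureModel({"A": [glu], "B": [arg]})
        (contact,) = inter_chain_contacts(m, "A", "B")
        assert contact.category == "salt_bridge"
        assert contact.min_distance == pytest.approx(3.0)

    def test_backbone_no_pair_is_hbond(self):
        a = make_residue("GLY", 1, (0, 0, 0), [("O", "O", (1, 0, 0))])
        b = make_residue("GLY", 1, (6, 0, 0), [("N", "N", (4, 0, 0))])
        m = StructureModel({"A": [a], "B": [b]})
        (contact,) = inter_chain_contacts(m, "A", "B")
        assert contact.category == "hbond"

    def test_symmetry_in_chain_order(self):
        rng = np.random.default_rng(4)
        a = [
            make_residue("GLY", i + 1, rng.uniform(0, 12, 3)) for i in range(15)
        ]
        b = [
            make_residue("SER", i + 1, rng.uniform(0, 12, 3)) for i in range(15)
        ]
        m = StructureModel({"A": a, "B": b})
        ab = {
            (c.number_a, c.number_b, round(c.min_distance, 6), c.category)
            for c in inter_chain_contacts(m, "A", "B")
        }
        ba = {
            (c.number_b, c.number_a, round(c.min_distance, 6), c.category)
            for c in inter_chain_contacts(m, "B", "A")
        }
        assert ab == ba and len(ab) > 0

    def test_random_coordinates_match_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        thresholds = ContactThresholds()
        chain_a = [
            make_residue(
                "GLU", i + 1, rng.uniform(0, 15, 3),
                [("OE1", "O", rng.uniform(0, 15, 3))],
            )
            for i in range(20)
        ]
        chain_b = [
            make_residue(
                "ARG", i + 1, rng.uniform(0, 15, 3),
                [("NH1", "N", rng.uniform(0, 15, 3))],
            )
            for i in range(20)
        ]
        m = StructureModel({"A": chain_a, "B": chain_b})
        got = {
            (c.number_a, c.number_b): (round(c.min_distance, 9), c.category)
            for c in inter_chain_contacts(m, "A", "B", thresholds)
        }
        # independent O(n^2) re-derivation of the same classification rules
        expected = {}
        for ra in chain_a:
            for rb in chain_b:
                dmin, dsalt, dno = math.inf, math.inf, math.inf
                for aa in ra.atoms:
                    for ab in rb.atoms:
                        d = float(np.linalg.norm(aa.xyz - ab.xyz))
                        dmin = min(dmin, d)
                        if aa.element in "NO" and ab.element in "NO":
                            dno = min(dno, d)
                        if aa.name == "OE1" and ab.name == "NH1":
                            dsalt = min(dsalt, d)
                if dmin <= thresholds.vdw:
                    if dsalt <= thresholds.salt_bridge:
                        cat = "salt_bridge"
                    elif dno <= thresholds.hbond:
                        cat = "hbond"
                    else:
                        cat = "vdw"
                    expected[(ra.number, rb.number)] = (round(dmin, 9), cat)
        assert got == expected


class TestHydrophobicCore:
    def test_packed_leucines_all_in_core(self):
        m = make_packed_cluster(n=6)
        core = hydrophobic_core_residues(m, "A", CoreParams(radius=5.0, burial_min=10))
        assert set(core) == {1, 2, 3, 4, 5, 6}

    def test_isolated_serine_excluded(self):
        cluster = make_packed_cluster(n=6)
        ser = make_residue("SER", 50, (2, 2, 2), [("OG", "O", (2.5, 2, 2))])
        m = StructureModel({"A": cluster.chain("A") + [ser]})
        core = hydrophobic_core_residues(m, "A", CoreParams(radius=5.0, burial_min=5))
        assert 50 not in core

    def test_short_chain_rejected(self):
        m = make_ca_line("LL", "A")
        with pytest.raises(ValueError, match="fewer than 3"):
            hydrophobic_core_residues(m, "A")

    def test_burial_scores_match_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        residues = []
        for i in range(40):
            ca = rng.uniform(0, 20, 3)
            residues.append(
                make_residue("LEU", i + 1, ca, [("CB", "C", ca + rng.normal(0, 1, 3))])
            )
        m = StructureModel({"A": residues})
        params = CoreParams(radius=7.5, burial_min=0)
        got = hydrophobic_core_residues(m, "A", params)
        for res in residues:
            centroid = res.atom("CB").xyz  # only side-chain atom
            count = 0
            for other in residues:
                if other.number == res.number:
                    continue
                for atom in other.atoms:
                    if np.linalg.norm(atom.xyz - centroid) <= params.radius:
                        count += 1
            assert got[res.number] == count


class TestAnnotation:
    def test_core_and_interface_labels(self):
        region = RegionSpec("toy", 1, 12, "LSEKVADTNQIG")
        records = [
            SubstitutionRecord(pos, region.wt_at(pos), "R", 1)
            for pos in region.positions
        ][:10]
        core_positions = {r.position for r in records[:4]}
        core_set = {p: 40 for p in core_positions}
        annotations = annotate_sites(records, [], core_set, ChainMap("A", 0))
        assert len(annotations) == len(records)
        for ann, rec in zip(annotations, records):
            if rec.position in core_positions:
                assert ann.categories == {"hydrophobic_core"}
            else:
                assert ann.categories == {"other"}
        summary = annotation_summary(annotations)
        assert summary["fraction_hydrophobic_core"] == pytest.approx(0.4)

    def test_interface_requires_supporting_contact(self):
        m = merge_models(
            make_ca_line("L", "A", start=10), make_ca_line("G", "B", origin=(3.5, 0, 0), start=1)
        )
        contacts = inter_chain_contacts(m, "A", "B")
        region = RegionSpec("toy", 10, 10, "L")
        records = [SubstitutionRecord(10, "L", "R", 1)]
        (ann,) = annotate_sites(records, contacts, {}, ChainMap("A", 0), m)
        assert "interface" in ann.categories
        assert len(ann.supporting_contacts) >= 1

    def test_unresolved_positions_excluded_from_fractions(self):
        m = make_ca_line("LLL", "A", start=1)
        region = RegionSpec("toy", 1, 5, "LLLLL")
        records = [
            SubstitutionRecord(p, "L", "R", 1) for p in range(1, 6)
        ]
        annotations = annotate_sites(records, [], {}, ChainMap("A", 0), m)
        cats = [a.categories for a in annotations]
        assert cats[3] == {"unresolved"} and cats[4] == {"unresolved"}
        summary = annotation_summary(annotations)
        assert summary["n_resolved"] == 3
        assert summary["n_unresolved"] == 2


class TestSuperposition:
    def test_identical_models_identity_transform(self):
        m = make_helix("LIVFMWYAGS", "A")
        res = superpose(m, m, "A:1-10")
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_constructed_rotation_recovered_to_1e6(self):
        m = make_helix("LIVFMWYAGSLIVF", "A")
        R = rotation_about_axis((0, 0, 1), 30.0)
        rotated = transform_model(m, R, (1.0, -2.0, 3.0))
        res = superpose(m, rotated, "A:1-14")
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert res.rotation_angle_deg == pytest.approx(30.0, abs=1e-6)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_rmsd_matches_svd_superimposer_oracle(self):
        rng = np.random.default_rng(12)
        fixed = rng.uniform(0, 20, (12, 3))
        moving = fixed @ rotation_about_axis((1, 1, 0), 40.0).T + rng.normal(0, 0.3, (12, 3))
        _, _, rmsd = kabsch(moving, fixed)
        sup = SVDSuperimposer()
        sup.set(fixed, moving)
        sup.run()
        assert rmsd == pytest.approx(sup.get_rms(), abs=1e-9)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        m = make_helix("LIVFMWYAGS", "A")
        noisy = StructureModel(
            {
                "A": [
                    make_residue(r.name, r.number, r.atoms[0].xyz + np.random.default_rng(r.number).normal(0, 0.2, 3))
                    for r in m.chain("A")
                ]
            }
        )
        base = superpose(m, noisy, "A:1-10").rmsd
        pre = transform_model(noisy, rotation_about_axis((1, 2, 3), 77.0), (4, 5, 6))
        assert superpose(m, pre, "A:1-10").rmsd == pytest.approx(base, abs=1e-9)

    def test_noise_rmsd_scale(self):
        # isotropic noise sigma on both=only moving copy: RMSD ~ sigma*sqrt(3) ballpark
        rng = np.random.default_rng(2)
        m = make_helix("LIVFMWYAGS" * 3, "A")
        sigma = 0.1
        noisy = StructureModel(
            {
                "A": [
                    make_residue(r.name, r.number, r.atoms[0].xyz + rng.normal(0, sigma, 3))
                    for r in m.chain("A")
                ]
            }
        )
        res = superpose(m, noisy, "A:1-30")
        assert 0.3 * sigma < res.rmsd < 3.0 * sigma
        assert res.rotation_angle_deg < 5.0

    def test_too_few_atoms_error(self):
        m = make_ca_line("GA", "A")
        with pytest.raises(ValueError, match="3"):
            superpose(m, m, "A:1-2")

    def test_selection_parsing(self):
        sel = Selection.parse("A:1-149,1150-1220")
        assert sel.chain_id == "A"
        assert sel.ranges == ((1, 149), (1150, 1220))
        with pytest.raises(ValueError):
            Selection.parse("A")


class TestSegmentRotation:
    def test_identical_models_zero_angle(self):
        a, b, align, seg = make_hinge_pair(20.0)
        assert segment_rotation_angle(a, a, align, seg) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_hinge_angle_recovered(self):
        for angle in (5.0, 20.0, 90.0):
            a, b, align, seg = make_hinge_pair(angle)
            got = segment_rotation_angle(a, b, align, seg)
            assert got == pytest.approx(angle, abs=0.5)

    def test_symmetric_in_model_order(self):
        a, b, align, seg = make_hinge_pair(20.0)
        ab = segment_rotation_angle(a, b, align, seg)
        ba = segment_rotation_angle(b, a, align, seg)
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_short_segment_rejected(self):
        a, b, align, _ = make_hinge_pair(20.0)
        with pytest.raises(ValueError, match="4"):
            segment_rotation_angle(a, b, align, "A:21-23")
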
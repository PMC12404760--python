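"""Interface contact detection, the interface diff and geometric invariants."""

import itertools

import gemmi
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import coevmi as cv
from coevmi.structure_contacts import (
    HYDROPHOBIC_CARBONS,
    SALT_ACIDIC,
    SALT_BASIC,
    SYNTHETIC_CHAIN_CORRESPONDENCE,
    SYNTHETIC_CHAIN_MAP_CANONICAL,
    SYNTHETIC_RESIDUE_CORRESPONDENCE,
    ChainMappingError,
    build_synthetic_interface_pair,
)


def _write_pdb(tmp_path, text, name="m.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_load_structure_chains_and_residues(interface_models):
    canonical, _ = interface_models
    assert canonical.chain_ids == ["S", "B", "G", "D"]
    assert canonical.protein_of("S") == "SSPN"
    assert canonical.residues["S"] == [(57, "ARG"), (145, "LEU")]
    assert canonical.residues["G"] == [(88, "PHE")]


def test_missing_chain_in_map_raises(tmp_path):
    can, _ = build_synthetic_interface_pair()
    p = _write_pdb(tmp_path, can)
    with pytest.raises(ChainMappingError):
        cv.load_structure(p, chain_map={"S": "SSPN"})


def test_mmcif_round_trip_matches_pdb(tmp_path, interface_models):
    canonical, _ = interface_models
    can, _ = build_synthetic_interface_pair()
    pdb = _write_pdb(tmp_path, can)
    st = gemmi.read_structure(str(pdb))
    st.setup_entities()
    cif = tmp_path / "m.cif"
    st.make_mmcif_document().write_file(str(cif))
    from_cif = cv.load_structure(cif, format="mmcif", chain_map=SYNTHETIC_CHAIN_MAP_CANONICAL)
    assert from_cif.chains == canonical.chains
    assert from_cif.residues == canonical.residues
    np.testing.assert_allclose(from_cif.coords, canonical.coords, atol=1e-3)


def test_altloc_resolves_to_highest_occupancy(tmp_path):
    text = (
        "ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.40  0.00           N\n"
        "ATOM      2  N  BGLY A   1       9.000   9.000   9.000  0.60  0.00           N\n"
        "END\n"
    )
    model = cv.load_structure(_write_pdb(tmp_path, text), chain_map={"A": "P"})
    names, pts = model.atom_coords("A", 1)
    assert names == ["N"]
    np.testing.assert_allclose(pts[0], [9.0, 9.0, 9.0])


def test_salt_bridge_within_cutoff(interface_models):
    canonical, _ = interface_models
    bridges = cv.detect_salt_bridges(canonical, ("S", "D"))
    assert len(bridges) == 1
    (b,) = bridges
    assert b.res_a == ("S", 57, "ARG") and b.res_b == ("D", 64, "ASP")
    assert b.min_distance == pytest.approx(2.9, abs=1e-6)
    assert (b.atom_a, b.atom_b) == ("NH1", "OD1")


def test_salt_bridge_beyond_cutoff(interface_models):
    canonical, _ = interface_models
    assert cv.detect_salt_bridges(canonical, ("S", "D"), cutoff=2.5) == []


def test_hydrophobic_pocket_two_contacts(interface_models):
    canonical, _ = interface_models
    pocket = cv.detect_hydrophobic_contacts(
        canonical, ("S", "G")
    ) + cv.detect_hydrophobic_contacts(canonical, ("S", "B"))
    assert {(c.res_a, c.res_b) for c in pocket} == {
        (("S", 145, "LEU"), ("G", 88, "PHE")),
        (("S", 145, "LEU"), ("B", 125, "TYR")),
    }


def test_polar_residues_excluded_from_hydrophobic(interface_models):
    canonical, _ = interface_models
    # Arg57 and Asp64 sit 2.9 A apart but neither is apolar
    assert cv.detect_hydrophobic_contacts(canonical, ("S", "D")) == []


def test_exact_fixture_contact_inventory(interface_models):
    canonical, _ = interface_models
    contacts = cv.detect_all_contacts(canonical)
    assert sum(c.type == "salt_bridge" for c in contacts) == 1
    assert sum(c.type == "hydrophobic" for c in contacts) == 2


def test_min_distance_matches_brute_force(interface_models):
    canonical, _ = interface_models
    for c in cv.detect_all_contacts(canonical):
        sets = (
            HYDROPHOBIC_CARBONS
            if c.type == "hydrophobic"
            else {**SALT_BASIC, **SALT_ACIDIC}
        )
        _, pa = canonical.atom_coords(c.res_a[0], c.res_a[1], sets[c.res_a[2]])
        _, pb = canonical.atom_coords(c.res_b[0], c.res_b[1], sets[c.res_b[2]])
        brute = min(
            float(np.linalg.norm(x - y)) for x, y in itertools.product(pa, pb)
        )
        assert c.min_distance == pytest.approx(brute, abs=1e-6)


def test_rigid_body_invariance(interface_models):
    canonical, _ = interface_models
    rot = Rotation.from_euler("xyz", [0.4, -1.2, 2.2]).as_matrix()
    moved = canonical.transformed(rot, np.array([11.0, -6.0, 3.5]))
    before = cv.detect_all_contacts(canonical)
    after = cv.detect_all_contacts(moved)
    assert [(c.type, c.res_a, c.res_b) for c in before] == [
        (c.type, c.res_a, c.res_b) for c in after
    ]
    np.testing.assert_allclose(
        [c.min_distance for c in before], [c.min_distance for c in after], atol=1e-9
    )


def test_salt_and_hydrophobic_sets_disjoint(interface_models):
    canonical, _ = interface_models
    contacts = cv.detect_all_contacts(canonical)
    by_type = {}
    for c in contacts:
        by_type.setdefault(c.type, set()).add((c.res_a, c.res_b))
    assert by_type["salt_bridge"].isdisjoint(by_type["hydrophobic"])


def test_diff_identical_models_all_conserved(interface_models):
    canonical, _ = interface_models
    diff = cv.diff_interfaces(
        canonical, canonical, {c: c for c in canonical.chain_ids}
    )
    assert len(diff.conserved) == 3
    assert not diff.substituted_partner and not diff.lost and not diff.gained


def test_diff_reports_substituted_partner(interface_models):
    canonical, compensatory = interface_models
    diff = cv.diff_interfaces(
        canonical,
        compensatory,
        SYNTHETIC_CHAIN_CORRESPONDENCE,
        SYNTHETIC_RESIDUE_CORRESPONDENCE,
    )
    assert len(diff.conserved) == 2  # salt bridge + Tyr side of the pocket
    assert len(diff.substituted_partner) == 1
    old, new = diff.substituted_partner[0]
    assert old.res_b == ("G", 88, "PHE") and new.res_b == ("Z", 101, "LEU")
    assert not diff.lost and not diff.gained


def test_diff_detects_lost_contact(interface_models):
    canonical, _ = interface_models
    pushed = canonical.transformed(np.eye(3), np.zeros(3))
    mask = [ch == "D" for ch in pushed.atom_chain]
    pushed.coords[mask] += 50.0  # move the Asp chain out of range
    diff = cv.diff_interfaces(
        canonical, pushed, {c: c for c in canonical.chain_ids}
    )
    assert len(diff.lost) == 1
    assert diff.lost[0].type == "salt_bridge"


def test_diff_unmapped_chain_raises(interface_models):
    canonical, compensatory = interface_models
    with pytest.raises(ChainMappingError):
        cv.diff_interfaces(canonical, compensatory, {"S": "S"})
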
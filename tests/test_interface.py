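"""Contact extraction, typing, class/region partition, conservation."""

import numpy as np
import pytest

from rbdcompare.interface import (
    Contact,
    ContactCutoffs,
    RanRegionScheme,
    classify_class,
    classify_contacts,
    contact_surface,
    cutoff_sensitivity,
    find_contacts,
    map_conservation,
)
from rbdcompare.structure_io import (
    Atom,
    Chain,
    Residue,
    ResidueSelection,
    Structure,
    apply_transform,
)
from rbdcompare.superposition import AlignmentMap
from rbdcompare.synthetic_data import plant_interface, two_domain_complex

A_SIDE = ResidueSelection("A")
B_SIDE = ResidueSelection("B")


def pair_structure(res_a: Residue, res_b: Residue) -> Structure:
    return Structure("PAIR", [[Chain("A", [res_a]), Chain("B", [res_b])]])


def carbon_pair(distance: float) -> Structure:
    ra = Residue("A", 1, "", "ALA", [Atom("CB", "C", np.zeros(3)),
                                     Atom("CA", "C", np.array([0.0, 0.0, 8.0]))])
    rb = Residue("B", 1, "", "ALA", [Atom("CB", "C", np.array([0.0, 0.0, -distance])),
                                     Atom("CA", "C", np.array([0.0, 0.0, -distance - 8.0]))])
    return pair_structure(ra, rb)


def test_vdw_cutoff_boundary():
    assert len(find_contacts(carbon_pair(3.9), A_SIDE, B_SIDE)) == 1
    assert find_contacts(carbon_pair(3.9), A_SIDE, B_SIDE)[0].ctype == "vdw"
    assert len(find_contacts(carbon_pair(4.1), A_SIDE, B_SIDE)) == 0


def test_backbone_hbond_typing():
    st = plant_interface([("hbond_backbone", 2.9)])
    (c,) = find_contacts(st, A_SIDE, B_SIDE)
    assert c.ctype == "hbond_backbone"
    assert c.distance == pytest.approx(2.9)


def test_sidechain_hbond_typing():
    st = plant_interface([("hbond_sidechain", 3.2)])
    (c,) = find_contacts(st, A_SIDE, B_SIDE)
    assert c.ctype == "hbond_sidechain"


def test_salt_bridge_typing():
    st = plant_interface([("salt_bridge", 3.2)])
    (c,) = find_contacts(st, A_SIDE, B_SIDE)
    assert c.ctype == "salt_bridge"


def test_planted_inventory_recovered_exactly():
    spec = [("vdw", 3.9), ("vdw", 3.5), ("vdw", 2.0),
            ("hbond_backbone", 2.9), ("hbond_backbone", 3.4),
            ("salt_bridge", 3.8)]
    st = plant_interface(spec)
    contacts = find_contacts(st, A_SIDE, B_SIDE)
    got = sorted(c.ctype for c in contacts)
    assert got == sorted(t for t, _ in spec)


def test_contacts_symmetric_and_rigid_invariant():
    st = plant_interface([("vdw", 3.9), ("salt_bridge", 3.2)])
    fwd = find_contacts(st, A_SIDE, B_SIDE)
    rev = find_contacts(st, B_SIDE, A_SIDE)
    assert len(fwd) == len(rev)
    assert {(c.rbd_res.key, c.ran_res.key) for c in fwd} == {
        (c.ran_res.key, c.rbd_res.key) for c in rev
    }
    rng = np.random.default_rng(11)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    moved = apply_transform(st, q, rng.normal(size=3) * 20)
    moved_contacts = find_contacts(moved, A_SIDE, B_SIDE)
    assert [c.ctype for c in moved_contacts] == [c.ctype for c in fwd]
    assert np.allclose([c.distance for c in moved_contacts],
                       [c.distance for c in fwd], atol=1e-9)


def test_grid_search_equals_brute_force():
    """k-d tree neighbour search finds exactly the all-pairs inventory."""
    st = two_domain_complex(seed=9, n_res=30, separation=2.0)
    contacts = find_contacts(st, A_SIDE, B_SIDE)
    from rbdcompare.structure_io import select_heavy_atoms

    atoms_a = select_heavy_atoms(st, A_SIDE)
    atoms_b = select_heavy_atoms(st, B_SIDE)
    brute = {
        ((ra.key, aa.name), (rb.key, ab.name))
        for ra, aa in atoms_a
        for rb, ab in atoms_b
        if np.linalg.norm(aa.position - ab.position) <= 4.0
    }
    got = {((c.rbd_res.key, c.rbd_atom.name), (c.ran_res.key, c.ran_atom.name))
           for c in contacts}
    assert got == brute


def test_inconsistent_cutoffs_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        ContactCutoffs(vdw=3.0, hbond=3.5, salt_bridge=3.0)


def make_contact(rbd_num: int, ran_num: int) -> Contact:
    ra = Residue("R", rbd_num, "", "ALA", [Atom("CB", "C", np.zeros(3))])
    rb = Residue("G", ran_num, "", "ALA", [Atom("CB", "C", np.zeros(3))])
    return Contact(ra, ra.atoms[0], rb, rb.atoms[0], 3.5, "vdw")


@pytest.mark.parametrize("rbd_num,ran_num,expected", [
    (5, 80, 1),      # extension vs G-domain
    (50, 213, 2),    # globular RBD vs DEDDDL
    (50, 35, 3),     # globular RBD vs effector loop (globular Ran)
    (50, 80, 3),     # globular vs globular
    (5, 213, None),  # extension vs tail: unclassifiable
])
def test_class_decision_rule(rbd_num, ran_num, expected):
    scheme = RanRegionScheme()
    extension = ResidueSelection("R", [(1, 10)])
    assert classify_class(make_contact(rbd_num, ran_num), extension, scheme) == expected


def test_classify_contacts_partitions_and_surfaces_unclassified():
    contacts = [make_contact(5, 80), make_contact(50, 213), make_contact(5, 213)]
    report = classify_contacts(contacts, ResidueSelection("R", [(1, 10)]))
    assert len(report.contacts) == 2
    assert len(report.unclassified) == 1
    assert report.counts_by_class() == {1: 1, 2: 1}
    assert report.counts_by_region() == {"g_domain": 1, "deddd_motif": 1}
    assert sum(report.rollup_rbd().values()) == len(report.contacts)


def test_ran_region_scheme_defaults_and_validation():
    scheme = RanRegionScheme()
    assert scheme.deddd_motif == (211, 216)
    assert scheme.region_of(213) == "deddd_motif"
    assert scheme.region_of(35) == "effector_loop"
    assert scheme.region_of(100) == "g_domain"
    assert scheme.in_tail(190) and not scheme.in_tail(100)
    with pytest.raises(ValueError, match="disjoint"):
        RanRegionScheme(linker=(180, 215))


def test_contact_surface_counts():
    st = plant_interface([("vdw", 3.9)])
    assert len(contact_surface(st, A_SIDE, B_SIDE)) == 1
    empty = plant_interface([])
    assert contact_surface(empty, A_SIDE, B_SIDE) == set()


def test_contact_surface_cutoff_sensitivity_report():
    st = plant_interface([("vdw", 3.9), ("vdw", 3.0), ("vdw", 2.0)])
    sens = cutoff_sensitivity(st, A_SIDE, B_SIDE, cutoff=4.0, delta=0.25)
    assert sens == {"3.75": 2, "4.00": 3, "4.25": 3}


def conservation_fixture(query_seq: str):
    """Interface whose A-side residues are the EWKER motif, with a query map."""
    motif = ["GLU", "TRP", "LYS", "ARG", "GLU"]  # E W K R E
    one_to_three = {"S": "SER", "W": "TRP", "V": "VAL", "E": "GLU", "R": "ARG",
                    "K": "LYS"}
    res_a, res_b, contacts = [], [], []
    for i, rn in enumerate(motif):
        x = 25.0 * i
        ra = Residue("A", i + 1, "", rn, [Atom("CB", "C", np.array([x, 0, 0.0]))])
        rb = Residue("B", i + 1, "", "ALA", [Atom("CB", "C", np.array([x, 0, -3.5]))])
        res_a.append(ra)
        res_b.append(rb)
        contacts.append(Contact(ra, ra.atoms[0], rb, rb.atoms[0], 3.5, "vdw"))
    report = classify_contacts(contacts, ResidueSelection("A", [(10 ** 9, 10 ** 9)]))
    query = [
        Residue("Q", i + 1, "", one_to_three[q], [Atom("CB", "C", np.zeros(3))])
        for i, q in enumerate(query_seq)
    ]
    amap = AlignmentMap(list(zip(res_a, query)), np.zeros(len(query)))
    return report, amap


def test_map_conservation_all_identical():
    report, amap = conservation_fixture("EWKRE")
    marked = map_conservation(report, amap)
    assert all(c.conserved for c in marked.contacts)


def test_map_conservation_motif_substitutions():
    """E->S and K->V substitutions flagged; W, R and the other E conserved."""
    report, amap = conservation_fixture("SWVRE")
    marked = map_conservation(report, amap)
    flags = {c.rbd_res.res_name + str(c.rbd_res.seq_number): c.conserved
             for c in marked.contacts}
    assert flags == {"GLU1": False, "TRP2": True, "LYS3": False,
                     "ARG4": True, "GLU5": True}


def test_map_conservation_unaligned_is_unknown():
    report, amap = conservation_fixture("EWKRE")
    amap.pairs.pop()  # drop the last pair: residue 5 unaligned
    marked = map_conservation(report, amap)
    assert marked.contacts[-1].conserved is None
    assert sum(c.conserved is True for c in marked.contacts) == 4


def test_map_conservation_requires_matching_chain():
    report, _ = conservation_fixture("EWKRE")
    stray = Residue("Z", 999, "", "ALA", [Atom("CB", "C", np.zeros(3))])
    bad_map = AlignmentMap([(stray, stray)], np.zeros(1))
    with pytest.raises(ValueError, match="does not cover"):
        map_conservation(report, bad_map)
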
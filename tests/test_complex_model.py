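"""Grafting, complex alignment, clash detection, compromised contacts."""

import numpy as np
import pytest

from rbdcompare.complex_model import (
    align_complexes,
    compromised_contacts,
    detect_clashes,
    graft,
)
from rbdcompare.interface import classify_contacts, find_contacts
from rbdcompare.structure_io import (
    ResidueSelection,
    Structure,
    apply_transform,
    select_ca,
    select_heavy_atoms,
)
from rbdcompare.superposition import AlignmentMap, equivalence, kabsch
from rbdcompare.synthetic_data import (
    make_clash_pair,
    make_helix,
    perturb_to_rmsd,
    two_domain_complex,
)

A_SIDE = ResidueSelection("A")
B_SIDE = ResidueSelection("B")


def domain_b_as_query(complex_structure: Structure, query_id="QUERY") -> Structure:
    """Extract chain B of a complex as a standalone query structure."""
    chain = complex_structure.copy().chain("B")
    return Structure(query_id, [[chain]])


def test_identity_graft_reproduces_template(binary_complex):
    query = domain_b_as_query(binary_complex)
    amap = equivalence(binary_complex, B_SIDE, query, B_SIDE)
    model = graft(query, B_SIDE, binary_complex, B_SIDE, amap)
    assert model.transform.rmsd < 1e-9
    assert np.allclose(model.transform.rotation, np.eye(3), atol=1e-9)
    # grafted chain coordinates equal the template domain's
    orig = select_ca(binary_complex, B_SIDE).coords
    new = select_ca(model.complex, ResidueSelection(model.query_chain_id)).coords
    assert np.allclose(orig, new, atol=1e-9)


def test_graft_never_moves_partner_atoms(binary_complex):
    query = perturb_to_rmsd(domain_b_as_query(binary_complex), 1.5, seed=2)
    amap = equivalence(binary_complex, B_SIDE, query, B_SIDE)
    model = graft(query, B_SIDE, binary_complex, B_SIDE, amap)
    before = [a.position.copy() for _, a in select_heavy_atoms(binary_complex, A_SIDE)]
    after = [a.position for _, a in
             select_heavy_atoms(model.complex, A_SIDE)]
    assert len(before) == len(after)
    for b, a in zip(before, after):
        assert np.array_equal(b, a)  # bitwise: partners are untouched


def test_graft_transform_rmsd_equals_planted_perturbation(binary_complex):
    planted = 1.5
    query = perturb_to_rmsd(domain_b_as_query(binary_complex), planted, seed=2)
    pairs = list(zip(select_ca(binary_complex, B_SIDE).residues,
                     select_ca(query, B_SIDE).residues))
    amap = AlignmentMap(pairs, np.zeros(len(pairs)))
    model = graft(query, B_SIDE, binary_complex, B_SIDE, amap)
    assert model.transform.rmsd == pytest.approx(planted, rel=0.02)


def test_graft_requires_enough_pairs(binary_complex):
    query = domain_b_as_query(binary_complex)
    tiny = AlignmentMap([], np.zeros(0))
    with pytest.raises(ValueError, match="3 residue pairs"):
        graft(query, B_SIDE, binary_complex, B_SIDE, tiny)


def test_align_complexes_identity_and_roundtrip(binary_complex):
    moved, sup = align_complexes(binary_complex, binary_complex, A_SIDE, A_SIDE)
    assert sup.rmsd < 1e-9
    rng = np.random.default_rng(8)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    t = rng.normal(size=3) * 30
    displaced = apply_transform(binary_complex, q, t)
    recovered, sup2 = align_complexes(displaced, binary_complex, A_SIDE, A_SIDE)
    assert sup2.rmsd < 1e-9
    # the whole complex (chain B too) is brought back
    assert np.allclose(
        select_ca(recovered, B_SIDE).coords,
        select_ca(binary_complex, B_SIDE).coords,
        atol=1e-8,
    )


def test_detect_clashes_counts():
    far = make_clash_pair(0)
    assert detect_clashes(far, A_SIDE, B_SIDE).severity == 0
    seven = make_clash_pair(7)
    report = detect_clashes(seven, A_SIDE, B_SIDE)
    assert report.severity == 7
    one = make_clash_pair(1, min_distance=1.0)
    (pair,) = detect_clashes(one, A_SIDE, B_SIDE).pairs
    assert pair[4] == pytest.approx(1.0, abs=1e-6)


def test_detect_clashes_equals_brute_force_and_monotone():
    st = two_domain_complex(seed=5, n_res=25, separation=-1.0)
    for cutoff in (1.5, 2.5, 3.5):
        report = detect_clashes(st, A_SIDE, B_SIDE, cutoff)
        atoms_a = select_heavy_atoms(st, A_SIDE)
        atoms_b = select_heavy_atoms(st, B_SIDE)
        brute = sum(
            1
            for _, aa in atoms_a
            for _, ab in atoms_b
            if np.linalg.norm(aa.position - ab.position) < cutoff
        )
        assert report.severity == brute
    sev = [detect_clashes(st, A_SIDE, B_SIDE, c).severity for c in (3.5, 2.5, 1.5)]
    assert sev[0] >= sev[1] >= sev[2]


def test_align_then_clash_invariant_to_joint_pretransform(binary_complex):
    clashy = two_domain_complex(seed=5, n_res=25, separation=-1.0)
    ref = clashy
    base_moved, _ = align_complexes(clashy, ref, A_SIDE, A_SIDE)
    base = detect_clashes(base_moved, A_SIDE, B_SIDE).severity
    rng = np.random.default_rng(13)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    jolted = apply_transform(clashy, q, rng.normal(size=3) * 50)
    moved, _ = align_complexes(jolted, ref, A_SIDE, A_SIDE)
    assert detect_clashes(moved, A_SIDE, B_SIDE).severity == base


def test_identity_graft_retains_all_contacts(binary_complex):
    close = two_domain_complex(seed=21, n_res=25, separation=0.5)
    contacts = find_contacts(close, B_SIDE, A_SIDE)
    assert contacts, "fixture must have an interface"
    report = classify_contacts(contacts, ResidueSelection("B", [(10 ** 9, 10 ** 9)]))
    query = domain_b_as_query(close)
    amap = equivalence(close, B_SIDE, query, B_SIDE)
    model = graft(query, B_SIDE, close, B_SIDE, amap)
    comp = compromised_contacts(report, model)
    assert comp.counts == {"retained": len(report.contacts)}
    assert comp.fraction_compromised == 0.0


def test_planted_substitution_flagged(binary_complex):
    close = two_domain_complex(seed=21, n_res=25, separation=0.5)
    contacts = find_contacts(close, B_SIDE, A_SIDE)
    report = classify_contacts(contacts, ResidueSelection("B", [(10 ** 9, 10 ** 9)]))
    contact_resnum = report.contacts[0].rbd_res.seq_number
    query = domain_b_as_query(close)
    for res in query.chain("B"):
        if res.seq_number == contact_resnum:
            res.res_name = "TRP"  # planted substitution at a contact residue
    amap = equivalence(close, B_SIDE, query, B_SIDE)
    model = graft(query, B_SIDE, close, B_SIDE, amap)
    comp = compromised_contacts(report, model)
    n_at_res = sum(1 for c in report.contacts if c.rbd_res.seq_number == contact_resnum)
    assert comp.counts["substituted_residue"] == n_at_res
    statuses = {c.rbd_res.seq_number: s for c, s in comp.statuses}
    assert statuses[contact_resnum] == "substituted_residue"


def test_missing_epitope_flagged(binary_complex):
    close = two_domain_complex(seed=21, n_res=25, separation=0.5)
    contacts = find_contacts(close, B_SIDE, A_SIDE)
    report = classify_contacts(contacts, ResidueSelection("B", [(10 ** 9, 10 ** 9)]))
    contact_resnum = report.contacts[0].rbd_res.seq_number
    query = domain_b_as_query(close)
    chain = query.chain("B")
    chain.residues = [r for r in chain.residues if r.seq_number != contact_resnum]
    amap = equivalence(close, B_SIDE, query, B_SIDE)
    model = graft(query, B_SIDE, close, B_SIDE, amap)
    comp = compromised_contacts(report, model)
    assert comp.counts["absent_epitope"] >= 1
    statuses = {c.rbd_res.seq_number: s for c, s in comp.statuses}
    assert statuses[contact_resnum] == "absent_epitope"


def test_compromised_contacts_template_mismatch(binary_complex):
    other = make_helix(10, chain_id="Z", structure_id="ZED")
    contacts_elsewhere = classify_contacts([], ResidueSelection("Z"))
    query = domain_b_as_query(binary_complex)
    amap = equivalence(binary_complex, B_SIDE, query, B_SIDE)
    model = graft(query, B_SIDE, binary_complex, B_SIDE, amap)
    # an empty report trivially matches; a report on the wrong chain must not
    close = two_domain_complex(seed=21, n_res=25, separation=0.5)
    wrong = classify_contacts(
        find_contacts(close, A_SIDE, B_SIDE),  # RBD side = chain A, not the domain
        ResidueSelection("A", [(10 ** 9, 10 ** 9)]),
    )
    with pytest.raises(ValueError, match="template domain chain"):
        compromised_contacts(wrong, model)
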
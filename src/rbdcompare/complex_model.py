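"""Superposition-based complex modelling and steric-clash analysis.

A query domain (e.g. an unliganded RBD) is modelled into a template complex
by rigid-body grafting: the query is superposed onto the template's
corresponding domain through a core Cα map and replaces it, while the other
partners keep their template coordinates bit-for-bit.  No rotamer building is
attempted — the model carries the query's own side chains where it has them
and a name-only "threading" (template position -> query residue type)
elsewhere, so clash analysis of threaded regions is restricted to backbone +
Cβ to avoid overstating overlaps from unmodelled side chains.

The same machinery aligns whole complexes through a shared component (e.g.
two export complexes through CRM1 HEAT-repeat helices, or through Ran) and
inventories which template interface contacts survive the threading.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .interface import InterfaceReport
from .structure_io import (
    Atom,
    Chain,
    Residue,
    ResidueSelection,
    Structure,
    apply_transform,
    select_ca,
    select_heavy_atoms,
)
from .superposition import AlignmentMap, SuperpositionResult, kabsch

__all__ = [
    "GraftModel",
    "ClashReport",
    "CompromisedContactReport",
    "graft",
    "align_complexes",
    "detect_clashes",
    "compromised_contacts",
]

DEFAULT_CLASH_CUTOFF = 2.5  # Å; heavy-atom pairs this close are severe overlaps


@dataclass
class GraftModel:
    """A template complex with one domain replaced by a superposed query."""

    template_id: str
    query_id: str
    query_chain_id: str
    template_domain: ResidueSelection
    transform: SuperpositionResult
    complex: Structure
    threading: dict[tuple[str, int, str], Residue]  # template residue -> query residue

    def threaded_resname(self, template_key: tuple[str, int, str]) -> str | None:
        res = self.threading.get(template_key)
        return res.res_name if res is not None else None


@dataclass
class ClashReport:
    """Atom pairs closer than the clash cutoff, with per-residue rollups."""

    cutoff: float
    pairs: list[tuple[Residue, Atom, Residue, Atom, float]] = field(default_factory=list)

    @property
    def severity(self) -> int:
        return len(self.pairs)

    def rollup(self, side: str = "a") -> list[tuple[tuple[str, int, str], int]]:
        idx = 0 if side == "a" else 2
        counts = Counter(p[idx].key for p in self.pairs)
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def residues(self, side: str = "a") -> set[tuple[str, int, str]]:
        idx = 0 if side == "a" else 2
        return {p[idx].key for p in self.pairs}

    def summary(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "severity": self.severity,
            "residues_a": [f"{c}:{n}{i}" for c, n, i in sorted(self.residues("a"))],
            "residues_b": [f"{c}:{n}{i}" for c, n, i in sorted(self.residues("b"))],
        }


@dataclass
class CompromisedContactReport:
    """Template contacts annotated by their fate after threading.

    retained            — the threaded residue type is unchanged,
    substituted_residue — a different residue type threads to the position,
    absent_epitope      — the query provides no equivalent residue.
    """

    statuses: list[tuple[object, str]]  # (Contact, status)

    @property
    def counts(self) -> Counter:
        return Counter(status for _, status in self.statuses)

    @property
    def fraction_compromised(self) -> float:
        if not self.statuses:
            return 0.0
        c = self.counts
        return (c["substituted_residue"] + c["absent_epitope"]) / len(self.statuses)

    def summary(self) -> dict:
        return {
            "n_contacts": len(self.statuses),
            "counts": dict(sorted(self.counts.items())),
            "fraction_compromised": round(self.fraction_compromised, 4),
        }


def graft(
    query: Structure,
    query_sel: ResidueSelection,
    template_complex: Structure,
    template_domain: ResidueSelection,
    core_map: AlignmentMap,
    extend_threading_cutoff: float = 4.0,
) -> GraftModel:
    """Rigidly place the query domain into the template complex.

    ``core_map`` pairs template-domain residues (A side) with query residues
    (B side); the transform superposes the mapped query Cα atoms onto the
    template's.  The grafted complex keeps every non-domain template chain
    untouched and appends the transformed query chain.  The threading table
    covers the core map plus any further mutual-nearest Cα pairs within
    ``extend_threading_cutoff`` after placement.
    """
    if len(core_map) < 3:
        raise ValueError("core map must contain at least 3 residue pairs")
    tmpl_ca = select_ca(template_complex, template_domain)
    query_ca = select_ca(query, query_sel)
    tmpl_by_key = {res.key: pos for res, pos in tmpl_ca}
    query_by_key = {res.key: (res, pos) for res, pos in query_ca}
    coords_t, coords_q = [], []
    for res_t, res_q in core_map.pairs:
        pos_t = tmpl_by_key.get(res_t.key)
        entry_q = query_by_key.get(res_q.key)
        if pos_t is None or entry_q is None:
            raise ValueError(
                f"core map pair ({res_t.key}, {res_q.key}) not covered by the "
                "template-domain / query selections"
            )
        coords_t.append(pos_t)
        coords_q.append(entry_q[1])
    sup = kabsch(np.array(coords_t), np.array(coords_q))
    moved_query = apply_transform(query, sup.rotation, sup.translation)

    # assemble: template chains minus the domain residues, plus the query chain
    partner_chains: list[Chain] = []
    for ch in template_complex.model(template_domain.model_index):
        if ch.chain_id == template_domain.chain_id:
            keep = [r for r in ch.residues
                    if not (r.is_amino_acid and template_domain.contains(r.seq_number))]
            if keep:
                partner_chains.append(Chain(ch.chain_id, keep))
        else:
            partner_chains.append(ch)
    query_chain_src = moved_query.chain(query_sel.chain_id, query_sel.model_index)
    used_ids = {ch.chain_id for ch in partner_chains}
    new_id = query_sel.chain_id
    if new_id in used_ids:
        for cand in "QZYXWVUTSRqz0123456789":
            if cand not in used_ids:
                new_id = cand
                break
    grafted_residues = []
    for r in query_chain_src.residues:
        if r.is_amino_acid and query_sel.contains(r.seq_number):
            grafted_residues.append(
                Residue(new_id, r.seq_number, r.insertion_code, r.res_name,
                        list(r.atoms), r.is_het)
            )
    model_structure = Structure(
        f"{template_complex.id}+{query.id}",
        [partner_chains + [Chain(new_id, grafted_residues)]],
    )

    # threading: core map, extended by mutual-nearest CA pairs after placement
    threading: dict[tuple[str, int, str], Residue] = {
        res_t.key: res_q for res_t, res_q in core_map.pairs
    }
    moved_q_ca = select_ca(moved_query, query_sel)
    q_coords = moved_q_ca.coords
    tree_q = cKDTree(q_coords)
    t_coords = tmpl_ca.coords
    tree_t = cKDTree(t_coords)
    d_tq, j_tq = tree_q.query(t_coords, k=1)
    d_qt, i_qt = tree_t.query(q_coords, k=1)
    for i, (res_t, _pos) in enumerate(tmpl_ca):
        if res_t.key in threading:
            continue
        j = int(j_tq[i])
        if d_tq[i] <= extend_threading_cutoff and int(i_qt[j]) == i:
            threading[res_t.key] = moved_q_ca.residues[j]

    return GraftModel(
        template_id=template_complex.id,
        query_id=query.id,
        query_chain_id=new_id,
        template_domain=template_domain,
        transform=sup,
        complex=model_structure,
        threading=threading,
    )


def align_complexes(
    mobile_complex: Structure,
    reference_complex: Structure,
    mobile_sel: ResidueSelection,
    reference_sel: ResidueSelection,
    pairs: list[tuple[int, int]] | None = None,
) -> tuple[Structure, SuperpositionResult]:
    """Move a whole complex by superposing a shared component only.

    The shared component's Cα atoms are paired by author seq_number (or by
    explicit index ``pairs`` into the two CA selections); the resulting
    transform is applied to every atom of the mobile complex.
    """
    ca_ref = select_ca(reference_complex, reference_sel)
    ca_mob = select_ca(mobile_complex, mobile_sel)
    if pairs is None:
        by_num = {res.seq_number: pos for res, pos in ca_mob}
        A, B = [], []
        for res, pos in ca_ref:
            other = by_num.get(res.seq_number)
            if other is not None:
                A.append(pos)
                B.append(other)
    else:
        A = [ca_ref.coords[i] for i, _ in pairs]
        B = [ca_mob.coords[j] for _, j in pairs]
    sup = kabsch(np.array(A), np.array(B))
    moved = apply_transform(mobile_complex, sup.rotation, sup.translation)
    return moved, sup


def detect_clashes(
    structure: Structure,
    side_a: ResidueSelection,
    side_b: ResidueSelection,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    backbone_cb_only_a: bool = False,
) -> ClashReport:
    """All heavy-atom pairs across the two selections closer than the cutoff.

    ``backbone_cb_only_a`` restricts side A to backbone + Cβ (for grafted
    domains whose threaded side chains are not modelled).  An empty report is
    a valid result.
    """
    atoms_a = select_heavy_atoms(structure, side_a, backbone_cb_only=backbone_cb_only_a)
    atoms_b = select_heavy_atoms(structure, side_b)
    report = ClashReport(cutoff=clash_cutoff)
    if not atoms_a or not atoms_b:
        return report
    tree_b = cKDTree(np.array([a.position for _, a in atoms_b]))
    coords_a = np.array([a.position for _, a in atoms_a])
    for i, neighbours in enumerate(tree_b.query_ball_point(coords_a, clash_cutoff)):
        res_a, atom_a = atoms_a[i]
        for j in sorted(neighbours):
            res_b, atom_b = atoms_b[j]
            d = float(np.linalg.norm(atom_a.position - atom_b.position))
            if d < clash_cutoff:
                report.pairs.append((res_a, atom_a, res_b, atom_b, d))
    report.pairs.sort(key=lambda p: p[4])
    return report


def compromised_contacts(
    template_report: InterfaceReport,
    graft_model: GraftModel,
) -> CompromisedContactReport:
    """Annotate each template interface contact by its fate in the graft.

    A contact is keyed by its template RBD residue: retained if the threaded
    query residue has the same type, substituted_residue if a different type
    threads there, absent_epitope if nothing threads there.
    """
    covered = any(
        c.rbd_res.chain_id == graft_model.template_domain.chain_id
        for c in template_report.contacts
    )
    if template_report.contacts and not covered:
        raise ValueError(
            "template report was not computed on the graft's template domain chain"
        )
    statuses = []
    for c in template_report.contacts:
        threaded = graft_model.threaded_resname(c.rbd_res.key)
        if threaded is None:
            status = "absent_epitope"
        elif threaded == c.rbd_res.res_name:
            status = "retained"
        else:
            status = "substituted_residue"
        statuses.append((c, status))
    return CompromisedContactReport(statuses)
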
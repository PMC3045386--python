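"""Intermolecular contact extraction, classification and conservation mapping.

A Ran/RBD interface is a "molecular embrace": Ran wraps its C-terminal tail
(linker, C-helix, acidic DEDDDL motif at 211-216) around the RBD, and the RBD
wraps its N-terminal extension around the Ran G-domain.  Contacts are typed
geometrically (van der Waals, side-chain or backbone hydrogen bond, salt
bridge) and partitioned into three classes:

  class 1 — RBD N-terminal extension against the Ran G-domain,
  class 2 — Ran C-terminal tail against the RBD globular domain,
  class 3 — the two globular domains against each other.

Deposited structures lack hydrogens, so hydrogen bonds use heavy-atom
donor–acceptor distance criteria with no angle term.  Conservation of the
contacting surface in a homologous RBD is mapped through a structure-based
alignment: a contact residue is conserved iff its equivalenced residue has
the same residue type.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Atom, Residue, ResidueSelection, Structure, select_heavy_atoms
from .superposition import AlignmentMap

__all__ = [
    "ContactCutoffs",
    "RanRegionScheme",
    "Contact",
    "InterfaceReport",
    "find_contacts",
    "classify_class",
    "classify_contacts",
    "contact_surface",
    "map_conservation",
    "cutoff_sensitivity",
]

CTYPES = ("vdw", "hbond_sidechain", "hbond_backbone", "salt_bridge")

# side-chain nitrogens of basic residues / side-chain oxygens of acidic ones
BASIC_SC_N = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_SC_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
HBOND_ELEMENTS_DONOR = {"N", "O", "S"}
HBOND_ELEMENTS_ACCEPTOR = {"N", "O"}


@dataclass(frozen=True)
class ContactCutoffs:
    """Heavy-atom distance cutoffs, Å.  Hydrogen-bond and salt-bridge shells
    must lie inside the van der Waals shell so type counts partition the
    contact list."""

    vdw: float = 4.0
    hbond: float = 3.5
    salt_bridge: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.hbond <= self.vdw and 0 < self.salt_bridge <= self.vdw):
            raise ValueError(
                "inconsistent cutoffs: hbond and salt_bridge must be <= vdw "
                f"(got hbond={self.hbond}, salt_bridge={self.salt_bridge}, vdw={self.vdw})"
            )


@dataclass(frozen=True)
class RanRegionScheme:
    """Named inclusive residue ranges partitioning Ran.

    The DEDDDL motif is fixed at 211-216 by sequence.  The G-domain /
    effector-loop split and the linker / C-helix boundaries on the tail are
    implementer defaults (the literature marks them graphically); override
    them per structure if needed.  Lookup precedence runs from the most
    specific element outward.
    """

    deddd_motif: tuple[int, int] = (211, 216)
    c_helix: tuple[int, int] = (188, 210)
    linker: tuple[int, int] = (177, 187)
    effector_loop: tuple[int, int] = (29, 45)
    g_domain: tuple[int, int] = (1, 176)

    TAIL_REGIONS = ("linker", "c_helix", "deddd_motif")

    def __post_init__(self) -> None:
        named = [
            ("deddd_motif", self.deddd_motif),
            ("c_helix", self.c_helix),
            ("linker", self.linker),
            ("effector_loop", self.effector_loop),
        ]
        spans = sorted(rng for _, rng in named)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("Ran region ranges must be disjoint")

    def region_of(self, seq_number: int) -> str | None:
        for name in ("deddd_motif", "c_helix", "linker", "effector_loop", "g_domain"):
            lo, hi = getattr(self, name)
            if lo <= seq_number <= hi:
                return name
        return None

    def in_tail(self, seq_number: int) -> bool:
        return self.region_of(seq_number) in self.TAIL_REGIONS


@dataclass
class Contact:
    """One classified intermolecular heavy-atom pair (RBD side first)."""

    rbd_res: Residue
    rbd_atom: Atom
    ran_res: Residue
    ran_atom: Atom
    distance: float
    ctype: str
    iface_class: int | None = None      # 1/2/3, None = unclassified
    ran_region: str | None = None
    conserved: bool | None = None       # None = unknown / unaligned


@dataclass
class InterfaceReport:
    """A contact list with rollups by residue, type, class and Ran region."""

    contacts: list[Contact]
    cutoffs: ContactCutoffs = field(default_factory=ContactCutoffs)
    unclassified: list[Contact] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contacts)

    def counts_by_ctype(self) -> Counter:
        return Counter(c.ctype for c in self.contacts)

    def counts_by_class(self) -> Counter:
        return Counter(c.iface_class for c in self.contacts if c.iface_class is not None)

    def counts_by_region(self) -> Counter:
        return Counter(c.ran_region for c in self.contacts if c.ran_region is not None)

    def rollup_rbd(self) -> Counter:
        return Counter(c.rbd_res.key for c in self.contacts)

    def rollup_ran(self) -> Counter:
        return Counter(c.ran_res.key for c in self.contacts)

    def rbd_residues(self, iface_class: int | None = None, ctype: str | None = None,
                     ran_region: str | None = None) -> set[tuple[str, int, str]]:
        """RBD residues making at least one contact matching the filters."""
        out = set()
        for c in self.contacts:
            if iface_class is not None and c.iface_class != iface_class:
                continue
            if ctype is not None and c.ctype != ctype:
                continue
            if ran_region is not None and c.ran_region != ran_region:
                continue
            out.add(c.rbd_res.key)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.contacts + self.unclassified:
            rows.append(
                {
                    "rbd_chain": c.rbd_res.chain_id,
                    "rbd_resnum": c.rbd_res.seq_number,
                    "rbd_resname": c.rbd_res.res_name,
                    "rbd_atom": c.rbd_atom.name,
                    "ran_chain": c.ran_res.chain_id,
                    "ran_resnum": c.ran_res.seq_number,
                    "ran_resname": c.ran_res.res_name,
                    "ran_atom": c.ran_atom.name,
                    "distance": round(c.distance, 3),
                    "ctype": c.ctype,
                    "iface_class": c.iface_class if c.iface_class is not None else "unclassified",
                    "ran_region": c.ran_region or "",
                    "conserved": {True: "yes", False: "no", None: "unknown"}[c.conserved],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_contacts": len(self.contacts),
            "n_unclassified": len(self.unclassified),
            "by_ctype": dict(sorted(self.counts_by_ctype().items())),
            "by_class": {str(k): v for k, v in sorted(self.counts_by_class().items())},
            "by_region": dict(sorted(self.counts_by_region().items())),
            "cutoffs": {
                "vdw": self.cutoffs.vdw,
                "hbond": self.cutoffs.hbond,
                "salt_bridge": self.cutoffs.salt_bridge,
            },
        }


def _contact_type(a: tuple[Residue, Atom], b: tuple[Residue, Atom],
                  d: float, cutoffs: ContactCutoffs) -> str:
    """Most specific type for an atom pair: salt bridge > H bond > vdW.

    Backbone vs side-chain H bonds are distinguished by the first (RBD-side)
    atom's backbone flag.
    """
    (res_a, atom_a), (res_b, atom_b) = a, b
    if d <= cutoffs.salt_bridge:
        ab = (atom_a.name in BASIC_SC_N.get(res_a.res_name, ())
              and atom_b.name in ACIDIC_SC_O.get(res_b.res_name, ()))
        ba = (atom_b.name in BASIC_SC_N.get(res_b.res_name, ())
              and atom_a.name in ACIDIC_SC_O.get(res_a.res_name, ()))
        if ab or ba:
            return "salt_bridge"
    if d <= cutoffs.hbond:
        da = (atom_a.element in HBOND_ELEMENTS_DONOR
              and atom_b.element in HBOND_ELEMENTS_ACCEPTOR)
        ad = (atom_b.element in HBOND_ELEMENTS_DONOR
              and atom_a.element in HBOND_ELEMENTS_ACCEPTOR)
        if da or ad:
            return "hbond_backbone" if atom_a.is_backbone else "hbond_sidechain"
    return "vdw"


def find_contacts(
    complex_structure: Structure,
    side_a: ResidueSelection,
    side_b: ResidueSelection,
    cutoffs: ContactCutoffs | None = None,
) -> list[Contact]:
    """All intermolecular heavy-atom pairs within the vdW cutoff, typed.

    Side A is the RBD side, side B the Ran side.  A neighbour grid (k-d tree)
    keeps the search near-linear in atom count.  An empty interface returns an
    empty list.
    """
    cutoffs = cutoffs or ContactCutoffs()
    atoms_a = select_heavy_atoms(complex_structure, side_a)
    atoms_b = select_heavy_atoms(complex_structure, side_b)
    if not atoms_a or not atoms_b:
        raise ValueError("both interface selections must be non-empty")
    keys_a = {(r.key, a.name) for r, a in atoms_a}
    if any((r.key, a.name) in keys_a for r, a in atoms_b):
        raise ValueError("interface selections overlap")
    coords_a = np.array([a.position for _, a in atoms_a])
    coords_b = np.array([a.position for _, a in atoms_b])
    tree_b = cKDTree(coords_b)
    contacts: list[Contact] = []
    for i, neighbours in enumerate(tree_b.query_ball_point(coords_a, cutoffs.vdw)):
        res_a, atom_a = atoms_a[i]
        for j in sorted(neighbours):
            res_b, atom_b = atoms_b[j]
            d = float(np.linalg.norm(atom_a.position - atom_b.position))
            ctype = _contact_type((res_a, atom_a), (res_b, atom_b), d, cutoffs)
            contacts.append(Contact(res_a, atom_a, res_b, atom_b, d, ctype))
    contacts.sort(key=lambda c: (c.rbd_res.seq_number, c.rbd_atom.name,
                                 c.ran_res.seq_number, c.ran_atom.name))
    return contacts


def classify_class(
    contact: Contact,
    rbd_extension: ResidueSelection,
    scheme: RanRegionScheme,
) -> int | None:
    """Assign the 1/2/3 interface class; None for extension-tail pairs.

    class 1: RBD extension atom against the Ran G-domain (effector loop
    included — it is part of the globular domain); class 2: Ran tail atom
    against the RBD globular domain; class 3: globular against globular.
    """
    in_ext = rbd_extension.contains(contact.rbd_res.seq_number)
    in_tail = scheme.in_tail(contact.ran_res.seq_number)
    if in_ext and not in_tail:
        return 1
    if in_tail and not in_ext:
        return 2
    if not in_ext and not in_tail:
        return 3
    return None


def classify_contacts(
    contacts: list[Contact],
    rbd_extension: ResidueSelection,
    scheme: RanRegionScheme | None = None,
    cutoffs: ContactCutoffs | None = None,
) -> InterfaceReport:
    """Annotate contacts with class and Ran region and build a report.

    Unclassifiable pairs (extension against tail) are surfaced in the
    report's ``unclassified`` list, never silently dropped.
    """
    scheme = scheme or RanRegionScheme()
    classified: list[Contact] = []
    unclassified: list[Contact] = []
    for c in contacts:
        region = scheme.region_of(c.ran_res.seq_number)
        klass = classify_class(c, rbd_extension, scheme)
        c2 = replace(c, iface_class=klass, ran_region=region)
        (classified if klass is not None else unclassified).append(c2)
    return InterfaceReport(classified, cutoffs or ContactCutoffs(), unclassified)


def contact_surface(
    complex_structure: Structure,
    query_side: ResidueSelection,
    partner_side: ResidueSelection,
    cutoff: float = 4.0,
) -> set[tuple[str, int, str]]:
    """Query-side residues with any heavy atom within ``cutoff`` of the partner."""
    atoms_q = select_heavy_atoms(complex_structure, query_side)
    atoms_p = select_heavy_atoms(complex_structure, partner_side)
    if not atoms_q or not atoms_p:
        return set()
    tree_p = cKDTree(np.array([a.position for _, a in atoms_p]))
    out: set[tuple[str, int, str]] = set()
    coords_q = np.array([a.position for _, a in atoms_q])
    dists, _ = tree_p.query(coords_q, k=1)
    for (res, _atom), d in zip(atoms_q, dists):
        if d <= cutoff:
            out.add(res.key)
    return out


def map_conservation(
    report: InterfaceReport,
    amap: AlignmentMap,
) -> InterfaceReport:
    """Mark each contact's template RBD residue as conserved in a query RBD.

    ``amap`` pairs template RBD residues (A side) with query residues (B
    side).  A contact is conserved iff its equivalenced query residue has the
    same residue type; template residues with no equivalent stay unknown.
    """
    by_key = {a.key: b for a, b in amap.pairs}
    if not any(c.rbd_res.key in by_key for c in report.contacts):
        raise ValueError("alignment map does not cover the report's RBD chain")
    marked = []
    for c in report.contacts:
        partner = by_key.get(c.rbd_res.key)
        conserved = None if partner is None else (partner.res_name == c.rbd_res.res_name)
        marked.append(replace(c, conserved=conserved))
    return InterfaceReport(marked, report.cutoffs, list(report.unclassified))


def cutoff_sensitivity(
    complex_structure: Structure,
    query_side: ResidueSelection,
    partner_side: ResidueSelection,
    cutoff: float = 4.0,
    delta: float = 0.25,
) -> dict[str, int]:
    """Contact-surface residue counts at cutoff and cutoff ± delta.

    Reported alongside headline residue counts so their stability against the
    (conventional, not physically sharp) distance threshold is visible.
    """
    return {
        f"{cutoff - delta:.2f}": len(
            contact_surface(complex_structure, query_side, partner_side, cutoff - delta)
        ),
        f"{cutoff:.2f}": len(
            contact_surface(complex_structure, query_side, partner_side, cutoff)
        ),
        f"{cutoff + delta:.2f}": len(
            contact_surface(complex_structure, query_side, partner_side, cutoff + delta)
        ),
    }
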
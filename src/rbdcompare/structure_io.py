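"""Macromolecular coordinate I/O and selection.

A thin hierarchical model (Structure -> models -> chains -> residues -> atoms)
over PDB-format files, parsed and written through :mod:`gemmi`.  Residues keep
author numbering exactly as deposited; alternate locations are retained on
read, and analysis helpers reduce each residue to its highest-occupancy
conformer.  Hydrogens and waters are excluded from analysis selections; all
geometry is heavy-atom, in Å.
"""

from __future__ import annotations

import os
import urllib.request
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueSelection",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "select_ca",
    "select_heavy_atoms",
    "apply_transform",
    "fetch_pdb",
    "primary_atoms",
]

BACKBONE_NAMES = {"N", "CA", "C", "O"}
WATER_NAMES = {"HOH", "WAT", "DOD"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine, treated as protein
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class Atom:
    """One atom record: PDB name, element, Å position, occupancy, altloc."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """A residue in author numbering: (chain_id, seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    is_het: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in STANDARD_AA

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def atom(self, name: str) -> Atom | None:
        """Highest-occupancy conformer of the named atom (tie -> lowest altloc)."""
        best = None
        for a in self.atoms:
            if a.name == name:
                if best is None or (-a.occupancy, a.altloc) < (-best.occupancy, best.altloc):
                    best = a
        return best

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A coordinate set: models (NMR order preserved) of chains of residues."""

    id: str
    models: list[list[Chain]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError(f"structure {self.id!r}: at least one model required")

    def model(self, index: int = 0) -> list[Chain]:
        return self.models[index]

    def chain(self, chain_id: str, model_index: int = 0) -> Chain:
        for ch in self.models[model_index]:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"structure {self.id!r}: no chain {chain_id!r} in model {model_index}")

    def chain_ids(self, model_index: int = 0) -> list[str]:
        return [ch.chain_id for ch in self.models[model_index]]

    def atoms(self, model_index: int = 0) -> Iterator[tuple[Residue, Atom]]:
        for ch in self.models[model_index]:
            for res in ch:
                for atom in res.atoms:
                    yield res, atom

    def n_atoms(self, model_index: int = 0) -> int:
        return sum(1 for _ in self.atoms(model_index))

    def copy(self) -> "Structure":
        models = []
        for model in self.models:
            chains = []
            for ch in model:
                residues = [
                    Residue(
                        r.chain_id, r.seq_number, r.insertion_code, r.res_name,
                        [Atom(a.name, a.element, a.position.copy(), a.occupancy, a.altloc)
                         for a in r.atoms],
                        r.is_het,
                    )
                    for r in ch.residues
                ]
                chains.append(Chain(ch.chain_id, residues))
            models.append(chains)
        return Structure(self.id, models)


@dataclass
class ResidueSelection:
    """Inclusive author-numbered ranges on one chain of one model.

    ``ranges=None`` selects the whole chain.  Ranges are normalized: sorted,
    merged when overlapping, and each must satisfy start <= end.
    """

    chain_id: str
    ranges: list[tuple[int, int]] | None = None
    model_index: int = 0

    def __post_init__(self) -> None:
        if self.ranges is not None:
            norm: list[tuple[int, int]] = []
            for start, end in sorted(self.ranges):
                if start > end:
                    raise ValueError(f"selection range {start}-{end}: start > end")
                if norm and start <= norm[-1][1] + 1:
                    norm[-1] = (norm[-1][0], max(norm[-1][1], end))
                else:
                    norm.append((start, end))
            self.ranges = norm

    def contains(self, seq_number: int) -> bool:
        if self.ranges is None:
            return True
        return any(start <= seq_number <= end for start, end in self.ranges)

    @classmethod
    def parse(cls, text: str, model_index: int = 0) -> "ResidueSelection":
        """Parse ``"A"`` or ``"A:330-343,350-363"`` into a selection."""
        chain, _, rest = text.partition(":")
        if not rest:
            return cls(chain, None, model_index)
        ranges = []
        for part in rest.split(","):
            lo, _, hi = part.partition("-")
            ranges.append((int(lo), int(hi) if hi else int(lo)))
        return cls(chain, ranges, model_index)


# ---------------------------------------------------------------------------
# Reading and writing


def _prescan_pdb(path: str) -> None:
    """Reject malformed coordinate records with the offending line number."""
    n_coords = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}:{lineno}: coordinate record too short")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}:{lineno}: unparseable coordinates"
                    ) from exc
                n_coords += 1
    if n_coords == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")


def read_structure(path: str | os.PathLike, format: str = "pdb") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    All ATOM/HETATM records are retained (altlocs included, with identifiers);
    MODEL blocks become separate models in deposition order.
    """
    path = os.fspath(path)
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    models: list[list[Chain]] = []
    for gmodel in st:
        chains: list[Chain] = []
        for gchain in gmodel:
            residues: list[Residue] = []
            for gres in gchain:
                atoms = [
                    Atom(
                        ga.name,
                        ga.element.name.upper(),
                        np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        min(max(ga.occ, 0.0), 1.0),
                        "" if ga.altloc == "\0" else ga.altloc,
                    )
                    for ga in gres
                ]
                residues.append(
                    Residue(
                        gchain.name,
                        gres.seqid.num,
                        (gres.seqid.icode or "").strip(),
                        gres.name,
                        atoms,
                        gres.het_flag == "H",
                    )
                )
            chains.append(Chain(gchain.name, residues))
        models.append(chains)
    sid = st.name or os.path.splitext(os.path.basename(path))[0]
    return Structure(sid, models)


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a :class:`Structure` as PDB text (coordinates to 3 decimals)."""
    if structure.n_atoms() == 0:
        raise ValueError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.id
    for mi, model in enumerate(structure.models):
        gmodel = gemmi.Model(mi + 1)
        for ch in model:
            gchain = gemmi.Chain(ch.chain_id)
            for res in ch:
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
                gres.het_flag = "H" if res.is_het else "A"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.position)
                    ga.occ = atom.occupancy
                    ga.altloc = atom.altloc or "\0"
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def fetch_pdb(code: str, cache_dir: str | os.PathLike, timeout: float = 30.0) -> str:
    """Download a PDB entry into ``cache_dir`` (skipped if already cached).

    Returns the local path.  All analysis code paths take local files; this is
    a convenience for populating a cache from the RCSB archive.
    """
    code = code.lower()
    if len(code) != 4 or not code.isalnum():
        raise ValueError(f"not a PDB accession: {code!r}")
    os.makedirs(cache_dir, exist_ok=True)
    dest = os.path.join(os.fspath(cache_dir), f"{code}.pdb")
    if not os.path.exists(dest):
        url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
        with open(dest, "wb") as fh:
            fh.write(data)
    return dest


# ---------------------------------------------------------------------------
# Selections and transforms


def primary_atoms(residue: Residue, heavy_only: bool = True) -> list[Atom]:
    """One conformer per atom name: highest occupancy, ties to lowest altloc."""
    best: dict[str, Atom] = {}
    for atom in residue.atoms:
        if heavy_only and atom.is_hydrogen:
            continue
        cur = best.get(atom.name)
        if cur is None or (-atom.occupancy, atom.altloc) < (-cur.occupancy, cur.altloc):
            best[atom.name] = atom
    # preserve file order of first appearance
    order: dict[str, int] = {}
    for i, a in enumerate(residue.atoms):
        order.setdefault(a.name, i)
    return sorted(best.values(), key=lambda a: order[a.name])


class CAList(list):
    """Ordered (Residue, position) pairs plus a report of skipped residues."""

    def __init__(self, pairs: Iterable[tuple[Residue, np.ndarray]], skipped: list[Residue]):
        super().__init__(pairs)
        self.skipped = skipped

    @property
    def coords(self) -> np.ndarray:
        return np.array([pos for _, pos in self], dtype=float).reshape(-1, 3)

    @property
    def residues(self) -> list[Residue]:
        return [res for res, _ in self]


def select_ca(structure: Structure, sel: ResidueSelection) -> CAList:
    """Cα positions of selected residues, in sequence order.

    Waters and non-amino-acid het groups are excluded; residues in range that
    lack a CA atom are skipped and listed in the result's ``skipped`` report.
    Raises if the selection yields no atoms (guards against silent 0-atom
    superpositions).
    """
    chain = structure.chain(sel.chain_id, sel.model_index)
    pairs: list[tuple[Residue, np.ndarray]] = []
    skipped: list[Residue] = []
    for res in chain:
        if res.is_water or not res.is_amino_acid:
            continue
        if not sel.contains(res.seq_number):
            continue
        ca = res.ca
        if ca is None:
            skipped.append(res)
        else:
            pairs.append((res, ca.position))
    if not pairs:
        raise ValueError(
            f"selection {sel.chain_id}:{sel.ranges} on {structure.id!r} yields no CA atoms"
        )
    return CAList(pairs, skipped)


def select_heavy_atoms(
    structure: Structure,
    sel: ResidueSelection,
    protein_only: bool = True,
    backbone_cb_only: bool = False,
) -> list[tuple[Residue, Atom]]:
    """Heavy atoms of selected residues, one conformer per atom name.

    ``backbone_cb_only`` restricts to N/CA/C/O/CB (used for clash analysis of
    threaded regions whose side chains are not modelled).
    """
    chain = structure.chain(sel.chain_id, sel.model_index)
    out: list[tuple[Residue, Atom]] = []
    for res in chain:
        if res.is_water:
            continue
        if protein_only and not res.is_amino_acid:
            continue
        if not sel.contains(res.seq_number):
            continue
        for atom in primary_atoms(res):
            if backbone_cb_only and atom.name not in ("N", "CA", "C", "O", "CB"):
                continue
            out.append((res, atom))
    return out


def apply_transform(
    structure: Structure, rotation: np.ndarray, translation: np.ndarray
) -> Structure:
    """Return a copy with every atom mapped x -> R.x + t.

    The rotation must be proper orthonormal (det +1, tolerance 1e-6).
    """
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float).reshape(3)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-6):
        raise ValueError("improper rotation (det != +1); reflections are not allowed")
    out = structure.copy()
    for model in out.models:
        for ch in model:
            for res in ch:
                for atom in res.atoms:
                    atom.position = rotation @ atom.position + translation
    return out
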
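"""Ground-truth fixtures for exercising the pipeline without downloads.

Generators build small, well-formed coordinate sets with planted, exactly
known properties: ideal helices for superposition, copies perturbed to a
prescribed optimal-fit rmsd, two-chain structures with planted contacts of
each geometric type, domain pairs with a known clash count, and two-domain
complexes for grafting.  Everything is seed-deterministic and writes valid
PDB (with a JSON ground-truth sidecar), so file-based code paths and the CLI
are exercised end to end.  These are geometric test articles, not physically
realistic proteins.
"""

from __future__ import annotations

import json
import math
import os
from typing import Sequence

import numpy as np

from .structure_io import (
    Atom,
    Chain,
    Residue,
    ResidueSelection,
    Structure,
    select_ca,
    write_structure,
)
from .superposition import kabsch

__all__ = [
    "make_helix",
    "perturb_to_rmsd",
    "plant_interface",
    "make_clash_pair",
    "two_domain_complex",
    "write_fixture",
]

HELIX_RISE = 1.5          # Å per residue
HELIX_TURN = 100.0        # degrees per residue
HELIX_RADIUS = 2.279      # gives consecutive CA-CA distances of 3.8 Å

_CTYPE_ATOMS = {
    # ctype -> ((resname_a, atom_a, element_a), (resname_b, atom_b, element_b), max_d)
    "vdw": (("ALA", "CB", "C"), ("ALA", "CB", "C"), 4.0),
    "hbond_backbone": (("ALA", "N", "N"), ("ALA", "O", "O"), 3.5),
    "hbond_sidechain": (("SER", "OG", "O"), ("ALA", "N", "N"), 3.5),
    "salt_bridge": (("LYS", "NZ", "N"), ("GLU", "OE1", "O"), 4.0),
}


def _helix_ca(n_res: int, start: int = 1) -> np.ndarray:
    idx = np.arange(n_res)
    theta = np.deg2rad(HELIX_TURN) * idx
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * idx]
    )


def make_helix(
    n_res: int,
    seed: int = 0,
    chain_id: str = "A",
    start_number: int = 1,
    sequence: str | None = None,
    structure_id: str = "HELIX",
) -> Structure:
    """Ideal α-helical backbone (N, CA, C, O) with poly-Ala default sequence.

    Geometry: 1.5 Å rise and 100° turn per residue, giving consecutive CA-CA
    distances of ~3.8 Å.  ``seed`` only selects the random sequence when
    ``sequence`` is None-and-requested; the coordinates are deterministic.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    if sequence is not None and len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    from .structure_io import THREE_TO_ONE

    one_to_three = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
    ca = _helix_ca(n_res)
    residues = []
    for i in range(n_res):
        res_name = "ALA" if sequence is None else one_to_three.get(sequence[i], "ALA")
        atoms = [Atom("CA", "C", ca[i])]
        if i > 0:
            n_pos = ca[i] + 0.385 * (ca[i - 1] - ca[i])
            atoms.insert(0, Atom("N", "N", n_pos))
        if i < n_res - 1:
            c_pos = ca[i] + 0.40 * (ca[i + 1] - ca[i])
            radial = np.array([c_pos[0], c_pos[1], 0.0])
            radial = radial / np.linalg.norm(radial)
            atoms.append(Atom("C", "C", c_pos))
            atoms.append(Atom("O", "O", c_pos + 1.23 * radial))
        residues.append(Residue(chain_id, start_number + i, "", res_name, atoms))
    return Structure(structure_id, [[Chain(chain_id, residues)]])


def perturb_to_rmsd(
    structure: Structure,
    target_rmsd: float,
    seed: int = 0,
    tol: float = 0.005,
) -> Structure:
    """Copy with a planted optimal-superposition Cα rmsd to the input.

    A random per-residue displacement field (all atoms of a residue move
    together) is rescaled iteratively — recomputing the best-fit rigid
    superposition each pass — until the residual rmsd is within ``tol``
    (relative) of the target.  target 0 returns an identical copy.
    """
    if target_rmsd < 0:
        raise ValueError("target rmsd must be non-negative")
    out = structure.copy()
    out.id = f"{structure.id}_perturbed"
    if target_rmsd == 0:
        return out
    rng = np.random.default_rng(seed)
    model = out.model(0)
    displacements = []
    for ch in model:
        for res in ch:
            displacements.append((res, rng.normal(size=3)))
    originals = {
        id(res): [a.position.copy() for a in res.atoms] for res, _ in displacements
    }

    def ca_coords(struct: Structure) -> np.ndarray:
        coords = []
        for ch in struct.model(0):
            coords.extend(pos for _, pos in select_ca(struct, ResidueSelection(ch.chain_id)))
        return np.array(coords)

    ref = ca_coords(structure)
    scale = target_rmsd
    for _ in range(40):
        for res, disp in displacements:
            for atom, orig in zip(res.atoms, originals[id(res)]):
                atom.position = orig + scale * disp
        cur = kabsch(ref, ca_coords(out)).rmsd
        if abs(cur - target_rmsd) <= tol * target_rmsd:
            break
        scale *= target_rmsd / cur
    return out


def plant_interface(
    spec: Sequence[tuple[str, float]],
    structure_id: str = "PLANT",
) -> Structure:
    """Two-chain structure whose interface contains exactly the planted pairs.

    Each (ctype, distance) entry plants one atom pair of that geometric type
    at that distance, isolated 25 Å from every other plant so the recovered
    contact inventory equals the request exactly.  Distances must respect the
    type's cutoff (vdw/salt bridge <= 4.0 Å, H bond <= 3.5 Å).
    """
    res_a_list, res_b_list = [], []
    for k, (ctype, d) in enumerate(spec):
        if ctype not in _CTYPE_ATOMS:
            raise ValueError(f"unknown contact type {ctype!r}")
        (rn_a, an_a, el_a), (rn_b, an_b, el_b), max_d = _CTYPE_ATOMS[ctype]
        if not 0 < d <= max_d:
            raise ValueError(
                f"distance {d} inconsistent with {ctype} cutoff {max_d} Å"
            )
        x = 25.0 * k
        res_a_list.append(
            Residue("A", k + 1, "", rn_a, [
                Atom("CA", "C", np.array([x, 0.0, 6.0])),
                Atom(an_a, el_a, np.array([x, 0.0, 0.0])),
            ])
        )
        res_b_list.append(
            Residue("B", k + 1, "", rn_b, [
                Atom("CA", "C", np.array([x, 0.0, -(d + 6.0)])),
                Atom(an_b, el_b, np.array([x, 0.0, -d])),
            ])
        )
    if not res_a_list:  # empty plant: two far-apart residues, no contacts
        res_a_list = [Residue("A", 1, "", "ALA", [Atom("CA", "C", np.zeros(3))])]
        res_b_list = [Residue("B", 1, "", "ALA", [Atom("CA", "C", np.array([0.0, 0.0, 100.0]))])]
    return Structure(structure_id, [[Chain("A", res_a_list), Chain("B", res_b_list)]])


def make_clash_pair(
    n_clashes: int,
    min_distance: float = 1.0,
    structure_id: str = "CLASH",
) -> Structure:
    """Two chains whose default-cutoff clash count is exactly ``n_clashes``.

    Each clash is an isolated CA-CA pair at ``min_distance``; one well
    separated (100 Å) non-clashing residue pair is always present so the
    structure is never empty.
    """
    if n_clashes < 0:
        raise ValueError("n_clashes must be non-negative")
    if not 0 < min_distance < 2.5:
        raise ValueError("min_distance must lie inside the default 2.5 Å clash cutoff")
    res_a, res_b = [], []
    for k in range(n_clashes):
        x = 10.0 * k
        res_a.append(Residue("A", k + 1, "", "ALA",
                             [Atom("CA", "C", np.array([x, 0.0, 0.0]))]))
        res_b.append(Residue("B", k + 1, "", "ALA",
                             [Atom("CA", "C", np.array([x, 0.0, -min_distance]))]))
    res_a.append(Residue("A", n_clashes + 1, "", "GLY",
                         [Atom("CA", "C", np.array([0.0, 100.0, 0.0]))]))
    res_b.append(Residue("B", n_clashes + 1, "", "GLY",
                         [Atom("CA", "C", np.array([0.0, 200.0, 0.0]))]))
    return Structure(structure_id, [[Chain("A", res_a), Chain("B", res_b)]])


def two_domain_complex(
    seed: int = 0,
    n_res: int = 20,
    separation: float = 12.0,
    structure_id: str = "COMPLEX",
) -> Structure:
    """A binary complex of two helical domains (chains A and B).

    Chain B is a helix rotated by a seed-determined rigid motion and placed
    ``separation`` Å away along x, leaving a loose interface suitable for
    graft and alignment tests.
    """
    rng = np.random.default_rng(seed)
    # varied sequences anchor the alignment register (a poly-Ala ideal helix
    # is self-similar under a one-residue shift)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    seq_a = "".join(rng.choice(letters, size=n_res))
    seq_b = "".join(rng.choice(letters, size=n_res))
    a = make_helix(n_res, chain_id="A", structure_id="X", sequence=seq_a)
    b = make_helix(n_res, chain_id="B", structure_id="X",
                   sequence=seq_b, start_number=101)
    # random proper rotation from a QR decomposition
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = np.array([separation + HELIX_RADIUS * 2, 0.0, 0.0])
    for res in b.chain("B"):
        for atom in res.atoms:
            atom.position = q @ atom.position + shift
    return Structure(structure_id, [[a.chain("A"), b.chain("B")]])


def write_fixture(
    kind: str,
    out_dir: str | os.PathLike,
    seed: int = 0,
    **params,
) -> tuple[str, str]:
    """Generate a fixture, write PDB + JSON ground-truth sidecar, return paths."""
    os.makedirs(out_dir, exist_ok=True)
    meta: dict = {"kind": kind, "seed": seed, "params": params}
    if kind == "helix":
        st = make_helix(params.get("n_res", 20), seed=seed)
        meta["truth"] = {"n_res": params.get("n_res", 20), "ca_ca": 3.8}
    elif kind == "perturbed_copy":
        base = make_helix(params.get("n_res", 20), seed=seed)
        st = perturb_to_rmsd(base, params["target_rmsd"], seed=seed)
        meta["truth"] = {"rmsd_to_ideal_helix": params["target_rmsd"]}
    elif kind == "contact_plant":
        st = plant_interface(params["spec"])
        meta["truth"] = {"contacts": [list(p) for p in params["spec"]]}
    elif kind == "clash_pair":
        st = make_clash_pair(params.get("n_clashes", 1), params.get("min_distance", 1.0))
        meta["truth"] = {"severity": params.get("n_clashes", 1)}
    elif kind == "two_domain_complex":
        st = two_domain_complex(seed=seed, n_res=params.get("n_res", 20))
        meta["truth"] = {"chains": ["A", "B"]}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    pdb_path = os.path.join(os.fspath(out_dir), f"{kind}_{seed}.pdb")
    json_path = os.path.join(os.fspath(out_dir), f"{kind}_{seed}.json")
    write_structure(st, pdb_path)
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return pdb_path, json_path
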
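"""Rigid-body superposition, rmsd_100 and structure-based equivalencing.

The Kabsch algorithm gives the closed-form least-squares rigid fit of one
paired Cα set onto another (proper rotations only).  Because the raw rmsd of
an alignment grows with its length, comparisons across alignments of
different size use the length-normalized score

    rmsd_100 = rmsd / (1 + ln((N / 100)^1/2))

which rescales every alignment to an effective length of 100 residues.  The
normalization diverges for very short alignments (the denominator crosses
zero near N ≈ 13.5), so a validity floor of N >= 20 is enforced.

Residue equivalencing between two domains that share low sequence identity is
structure-based: an initial pairing from a global sequence alignment is
refined by alternating superposition with mutual-nearest re-pairing of Cα
atoms inside an inclusion cutoff (default 4 Å), keeping the pairing
sequence-order preserving, until the pair set is stable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.spatial import cKDTree

from .structure_io import CAList, Residue, ResidueSelection, Structure, select_ca

__all__ = [
    "SuperpositionResult",
    "AlignmentMap",
    "ComparisonTable",
    "kabsch",
    "rmsd100",
    "equivalence",
    "percent_identity",
    "pairwise_table",
]

RMSD100_MIN_N = 20


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform of B onto A with its rmsd."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_aligned: int

    @property
    def rmsd100(self) -> float:
        return rmsd100(self.rmsd, self.n_aligned)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "SuperpositionResult":
        return SuperpositionResult(
            self.rotation.T, -self.rotation.T @ self.translation, self.rmsd, self.n_aligned
        )


@dataclass
class AlignmentMap:
    """Ordered equivalenced residue pairs (A, B) with post-fit Cα distances."""

    pairs: list[tuple[Residue, Residue]]
    distances: np.ndarray
    superposition: SuperpositionResult | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def identity_fraction(self) -> float:
        if not self.pairs:
            return 0.0
        same = sum(1 for a, b in self.pairs if a.res_name == b.res_name)
        return same / len(self.pairs)

    def lookup_b(self, res_a: Residue) -> Residue | None:
        for a, b in self.pairs:
            if a.key == res_a.key:
                return b
        return None


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation superposition of paired point sets (B onto A).

    Minimizes sum |a_i - (R b_i + t)|^2 over rotations with det(R) = +1;
    reflections are excluded by flipping the sign of the smallest singular
    vector when needed.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"paired coordinate sets required, got {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 paired points required, got {n}")
    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    A0 = A - cen_a
    B0 = B - cen_b
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: points are (near-)collinear")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_a - R @ cen_b
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(R, t, rmsd, n)


def rmsd100(rmsd: float, n: int) -> float:
    """Normalize an rmsd over N aligned Cα atoms to an effective length of 100.

    rmsd_100 = rmsd / (1 + ln((N/100)^1/2)).  Requires N >= 20: the
    denominator is non-positive for N <= ~13.5 and numerically unstable just
    above it, and the normalization is not meaningful for tiny alignments.
    """
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if n < RMSD100_MIN_N:
        raise ValueError(
            f"rmsd_100 undefined for N={n}: the normalization 1 + ln(sqrt(N/100)) "
            f"requires N >= {RMSD100_MIN_N} (denominator vanishes near N=13.5)"
        )
    return rmsd / (1.0 + math.log(math.sqrt(n / 100.0)))


# ---------------------------------------------------------------------------
# Structure-based equivalencing


def _sequence_seed(res_a: list[Residue], res_b: list[Residue]) -> list[tuple[int, int]]:
    """Initial index pairing from a global sequence alignment.

    Scoring: match +1, mismatch 0, gap -1 — deliberately simple so the seed is
    reproducible; the iterative geometric refinement does the real work.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    seq_a = "".join(r.one_letter for r in res_a)
    seq_b = "".join(r.one_letter for r in res_b)
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        pairs.extend(zip(range(a_start, a_end), range(b_start, b_end)))
    return pairs


def _ordered_mutual_pairs(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """Mutual-nearest Cα pairs within cutoff, restricted to a sequence-order
    preserving subset (longest increasing subsequence; ties broken by smaller
    distance, then lower index)."""
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    d_ab, j_ab = tree_b.query(coords_a, k=1)
    d_ba, i_ba = tree_a.query(coords_b, k=1)
    cands: list[tuple[int, int, float]] = []
    for i, (d, j) in enumerate(zip(d_ab, j_ab)):
        if d <= cutoff and i_ba[j] == i:
            cands.append((i, int(j), float(d)))
    cands.sort(key=lambda c: (c[0], c[2], c[1]))
    # longest strictly-increasing subsequence in j (i already increasing)
    if not cands:
        return []
    n = len(cands)
    best_len = [1] * n
    prev = [-1] * n
    for k in range(n):
        for m in range(k):
            if cands[m][1] < cands[k][1] and best_len[m] + 1 > best_len[k]:
                best_len[k] = best_len[m] + 1
                prev[k] = m
    end = int(np.argmax(best_len))
    out = []
    while end != -1:
        out.append((cands[end][0], cands[end][1]))
        end = prev[end]
    return out[::-1]


def equivalence(
    struct_a: Structure,
    sel_a: ResidueSelection,
    struct_b: Structure,
    sel_b: ResidueSelection,
    seed_pairs: list[tuple[int, int]] | None = None,
    cutoff: float = 4.0,
    max_iter: int = 50,
) -> AlignmentMap:
    """Topologically equivalent Cα positions between two domains.

    Deterministic for fixed inputs.  ``seed_pairs`` (index pairs into the two
    CA selections) overrides the sequence-alignment seed for hard cases.
    Raises if no pairs fall within the cutoff after the first refinement.
    """
    ca_a = select_ca(struct_a, sel_a)
    ca_b = select_ca(struct_b, sel_b)
    coords_a = ca_a.coords
    coords_b = ca_b.coords
    pairs = seed_pairs if seed_pairs is not None else _sequence_seed(
        ca_a.residues, ca_b.residues
    )
    if len(pairs) < 3:
        raise ValueError("fewer than 3 seed pairs; supply seed_pairs explicitly")
    seen: set[tuple[tuple[int, int], ...]] = set()
    sup = None
    for _ in range(max_iter):
        ia = [i for i, _ in pairs]
        ib = [j for _, j in pairs]
        sup = kabsch(coords_a[ia], coords_b[ib])
        moved_b = sup.apply(coords_b)
        new_pairs = _ordered_mutual_pairs(coords_a, moved_b, cutoff)
        if len(new_pairs) < 3:
            raise ValueError(
                "no structural correspondence: fewer than 3 mutual-nearest "
                f"CA pairs within {cutoff} Å"
            )
        key = tuple(new_pairs)
        if new_pairs == pairs or key in seen:
            pairs = new_pairs
            break
        seen.add(key)
        pairs = new_pairs
    ia = [i for i, _ in pairs]
    ib = [j for _, j in pairs]
    sup = kabsch(coords_a[ia], coords_b[ib])
    moved_b = sup.apply(coords_b[ib])
    dists = np.linalg.norm(coords_a[ia] - moved_b, axis=1)
    res_pairs = [(ca_a.residues[i], ca_b.residues[j]) for i, j in pairs]
    return AlignmentMap(res_pairs, dists, sup)


def percent_identity(amap: AlignmentMap) -> float:
    """Sequence identity over equivalenced pairs, in percent."""
    if len(amap) == 0:
        raise ValueError("empty alignment map")
    return 100.0 * amap.identity_fraction


# ---------------------------------------------------------------------------
# Pairwise comparison tables


@dataclass
class ComparisonTable:
    """Symmetric pairwise rmsd / N / rmsd_100 matrices with a summary mean."""

    labels: list[str]
    rmsd: pd.DataFrame
    n: pd.DataFrame
    rmsd100: pd.DataFrame

    @property
    def mean_rmsd100(self) -> float:
        vals = [
            self.rmsd100.iat[i, j]
            for i, j in itertools.combinations(range(len(self.labels)), 2)
        ]
        return float(np.mean(vals))

    def to_tsv(self, path: str) -> None:
        rows = []
        for i, j in itertools.combinations(range(len(self.labels)), 2):
            rows.append(
                {
                    "a": self.labels[i],
                    "b": self.labels[j],
                    "rmsd": round(self.rmsd.iat[i, j], 4),
                    "n": int(self.n.iat[i, j]),
                    "rmsd100": round(self.rmsd100.iat[i, j], 4),
                }
            )
        df = pd.DataFrame(rows)
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False)
            fh.write(f"# mean_rmsd100\t{self.mean_rmsd100:.4f}\n")


def _core_pairing(ca_a: CAList, ca_b: CAList) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair fixed-core selections by shared author seq_number."""
    by_num_b = {res.seq_number: pos for (res, pos) in ca_b}
    pa, pb = [], []
    for res, pos in ca_a:
        other = by_num_b.get(res.seq_number)
        if other is not None:
            pa.append(pos)
            pb.append(other)
    return np.array(pa), np.array(pb), len(pa)


def pairwise_table(
    entries: list[tuple[Structure, ResidueSelection]],
    mode: str = "core",
    labels: list[str] | None = None,
    cutoff: float = 4.0,
) -> ComparisonTable:
    """All-against-all superposition of the given chains.

    mode ``core``: residues are paired by author number inside each entry's
    (identical) core selection.  mode ``all_common``: residues are paired by
    structure-based equivalencing (:func:`equivalence`), so N varies by pair.
    """
    if len(entries) < 2:
        raise ValueError("at least two entries required")
    if mode not in ("core", "all_common"):
        raise ValueError(f"unknown mode {mode!r}")
    if labels is None:
        labels = [
            f"{s.id}:{sel.chain_id}" + (f"/m{sel.model_index}" if sel.model_index else "")
            for s, sel in entries
        ]
    k = len(entries)
    rmsd_m = np.zeros((k, k))
    n_m = np.zeros((k, k), dtype=int)
    r100_m = np.zeros((k, k))
    for i in range(k):
        n_m[i, i] = len(select_ca(*entries[i]))
    for i, j in itertools.combinations(range(k), 2):
        try:
            if mode == "core":
                ca_i = select_ca(*entries[i])
                ca_j = select_ca(*entries[j])
                A, B, n = _core_pairing(ca_i, ca_j)
                if n < 3:
                    raise ValueError("fewer than 3 shared core residues")
                sup = kabsch(A, B)
            else:
                amap = equivalence(*entries[i], *entries[j], cutoff=cutoff)
                sup = amap.superposition
        except ValueError as exc:
            raise ValueError(
                f"superposition failed for pair ({labels[i]}, {labels[j]}): {exc}"
            ) from exc
        rmsd_m[i, j] = rmsd_m[j, i] = sup.rmsd
        n_m[i, j] = n_m[j, i] = sup.n_aligned
        r100_m[i, j] = r100_m[j, i] = rmsd100(sup.rmsd, sup.n_aligned)
    idx = pd.Index(labels)
    return ComparisonTable(
        labels,
        pd.DataFrame(rmsd_m, index=idx, columns=idx),
        pd.DataFrame(n_m, index=idx, columns=idx),
        pd.DataFrame(r100_m, index=idx, columns=idx),
    )
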
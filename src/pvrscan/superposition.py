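"""Rigid-body superposition and pairwise structural alignment.

The aligner follows the classic iterative scheme used by TM-align-family
methods: an initial rigid superposition is found by exhaustive ungapped
window matching, then the method alternates between

1. Needleman-Wunsch dynamic programming over the per-pair score
   ``1 / (1 + (d_ij / d0)^2)`` computed on the current superposition
   (terminal gaps free, so length-variable termini stay unaligned), and
2. a Kabsch least-squares refit on the currently aligned residue pairs,

until the aligned set is stable (or an iteration cap is reached).  The
reported quantities are the TM-score (normalised by the reference chain
length by default), the RMSD over aligned CA pairs, and the structure-based
sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ResidueRef, Structure, ca_trace, trace_names

try:  # numba accelerates the DP fill; plain Python is a functional fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


class AlignmentError(ValueError):
    """Raised for invalid superposition/alignment inputs."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation 3x3, translation 3)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise AlignmentError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise AlignmentError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class PairwiseAlignment:
    """Residue-level correspondence between two structures/chains."""

    a_id: str
    b_id: str
    pairs: list[tuple[ResidueRef, ResidueRef]]
    transform: RigidTransform  # maps b coordinates onto a's frame
    rmsd: float
    tm_score: float
    seq_identity: float
    n_aligned: int
    converged: bool = True
    pair_names: list[tuple[str, str]] = field(default_factory=list)
    pair_indices: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_aligned != len(self.pairs):
            raise AlignmentError("n_aligned must equal the number of pairs")


@dataclass
class AlignParams:
    """Tunable knobs of the iterative aligner."""

    gap_penalty: float = 0.6  # cost of aligning a residue against a gap
    max_iter: int = 30
    seed_window: int = 40
    seed_stride: int = 5
    n_seeds: int = 3  # independent seed superpositions carried to convergence
    norm: str = "ref"  # TM-score normalisation: "ref" or "shorter"
    d0_min: float = 0.5  # floor on d0 used in the DP score


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of Q onto P.

    Returns the proper rigid transform minimising RMSD(R Q + t, P) and that
    minimal RMSD.  Reflections are corrected, so the result is always a
    physical rotation.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise AlignmentError(f"P and Q must both be n x 3, got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise AlignmentError("need at least 3 points for superposition")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # rank check: collinear/degenerate sets have no unique rotation
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise AlignmentError("degenerate (collinear) point set")
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    resid = Q0 @ R.T - P0
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return RigidTransform(R, t), rmsd


def tm_d0(L_norm: int) -> float:
    """Length-dependent distance scale of the TM-score."""
    if L_norm <= 15:
        raise AlignmentError("TM-score d0 is defined for normalisation length > 15")
    return 1.24 * (L_norm - 15) ** (1.0 / 3.0) - 1.8


def tm_score(d: Sequence[float], L_norm: int) -> float:
    """TM-score of a set of aligned-pair distances.

    score = (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2) with
    d0 = 1.24 (L_norm - 15)^(1/3) - 1.8.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise AlignmentError("empty distance list")
    if np.any(d < 0):
        raise AlignmentError("negative aligned-pair distance")
    d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


@njit(cache=True)
def _nw_traceback(S: np.ndarray, gap: float) -> np.ndarray:  # pragma: no cover - jit
    """Semi-global NW over score matrix S; terminal gaps are free.

    Returns an (k, 2) int64 array of aligned (i, j) index pairs.
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    T = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up(i gap), 2 left(j gap)
    for i in range(1, n + 1):
        T[i, 0] = 1
    for j in range(1, m + 1):
        T[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] - (gap if j < m else 0.0)
            left = H[i, j - 1] - (gap if i < n else 0.0)
            best = diag
            code = 0
            if up > best:
                best = up
                code = 1
            if left > best:
                best = left
                code = 2
            H[i, j] = best
            T[i, j] = code
    out = np.empty((min(n, m), 2), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        c = T[i, j]
        if c == 0 and i > 0 and j > 0:
            out[k, 0] = i - 1
            out[k, 1] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif c == 1 or j == 0:
            i -= 1
        else:
            j -= 1
    return out[:k][::-1]


def _seed_transforms(
    A: np.ndarray, B: np.ndarray, window: int, stride: int, n_seeds: int
) -> list[RigidTransform]:
    """Best ungapped-window superpositions, used to seed the iteration.

    Every (window in A) x (window in B) pair is superposed by Kabsch (done
    in closed form on batched covariance matrices) and the lowest-RMSD pairs
    provide the starting transforms.
    """
    w = min(window, len(A), len(B))
    ia = np.arange(0, len(A) - w + 1, stride)
    ib = np.arange(0, len(B) - w + 1, stride)
    WA = np.stack([A[i : i + w] for i in ia])  # (na, w, 3)
    WB = np.stack([B[j : j + w] for j in ib])  # (nb, w, 3)
    WA0 = WA - WA.mean(axis=1, keepdims=True)
    WB0 = WB - WB.mean(axis=1, keepdims=True)
    # cross-covariances for every window pair: (na, nb, 3, 3)
    H = np.einsum("awk,bwl->abkl", WA0, WB0)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U @ Vt)
    S_adj = S.copy()
    S_adj[..., 2] *= np.sign(det)
    ssq = (WA0**2).sum(axis=(1, 2))[:, None] + (WB0**2).sum(axis=(1, 2))[None, :]
    msd = np.maximum(ssq - 2.0 * S_adj.sum(axis=-1), 0.0) / w
    order = np.argsort(msd, axis=None)[:n_seeds]
    seeds = []
    for flat in order:
        i, j = np.unravel_index(flat, msd.shape)
        tr, _ = kabsch(A[ia[i] : ia[i] + w], B[ib[j] : ib[j] + w])
        seeds.append(tr)
    return seeds


def _trace_of(x, chain_id: Optional[str]):
    if isinstance(x, Structure):
        return ca_trace(x, chain_id), trace_names(x, chain_id), x.id
    # assume (trace, names, id) triple
    trace, names, sid = x
    return list(trace), list(names), sid


def align_pair(
    a,
    b,
    params: Optional[AlignParams] = None,
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
) -> PairwiseAlignment:
    """Iterative structural alignment of chain b onto chain a.

    ``a`` and ``b`` are Structures (first polymer chain unless ``chain_a`` /
    ``chain_b`` is given) or pre-extracted ``(trace, names, id)`` triples.
    """
    params = params or AlignParams()
    trace_a, names_a, id_a = _trace_of(a, chain_a)
    trace_b, names_b, id_b = _trace_of(b, chain_b)
    if len(trace_a) < 20 or len(trace_b) < 20:
        raise AlignmentError(
            f"CA traces too short for alignment ({len(trace_a)}, {len(trace_b)}; need >= 20)"
        )
    A = np.array([c for _, c in trace_a])
    B = np.array([c for _, c in trace_b])
    L_norm = len(A) if params.norm == "ref" else min(len(A), len(B))
    d0 = max(tm_d0(L_norm), params.d0_min)

    best: Optional[tuple[float, np.ndarray, RigidTransform, bool]] = None
    for seed in _seed_transforms(A, B, params.seed_window, params.seed_stride, params.n_seeds):
        tr = seed
        prev_pairs: Optional[np.ndarray] = None
        converged = False
        pairs_ij = np.empty((0, 2), dtype=np.int64)
        for _ in range(params.max_iter):
            Bt = tr.apply(B)
            D = cdist(A, Bt)
            S = 1.0 / (1.0 + (D / d0) ** 2)
            pairs_ij = _nw_traceback(S, params.gap_penalty)
            if prev_pairs is not None and pairs_ij.shape == prev_pairs.shape and np.array_equal(
                pairs_ij, prev_pairs
            ):
                converged = True
                break
            prev_pairs = pairs_ij
            if len(pairs_ij) < 3:
                break
            tr, _ = kabsch(A[pairs_ij[:, 0]], B[pairs_ij[:, 1]])
        if len(pairs_ij) == 0:
            continue
        dists = np.linalg.norm(A[pairs_ij[:, 0]] - tr.apply(B[pairs_ij[:, 1]]), axis=1)
        score = tm_score(dists, L_norm)
        if best is None or score > best[0]:
            best = (score, pairs_ij, tr, converged)

    if best is None:
        raise AlignmentError(f"no alignment found between {id_a} and {id_b}")
    score, pairs_ij, tr, converged = best
    dists = np.linalg.norm(A[pairs_ij[:, 0]] - tr.apply(B[pairs_ij[:, 1]]), axis=1)
    rmsd = float(np.sqrt(np.mean(dists**2)))
    pairs = [(trace_a[i][0], trace_b[j][0]) for i, j in pairs_ij]
    pair_names = [(names_a[i], names_b[j]) for i, j in pairs_ij]
    n_id = sum(1 for x, y in pair_names if x == y)
    return PairwiseAlignment(
        a_id=id_a,
        b_id=id_b,
        pairs=pairs,
        transform=tr,
        rmsd=rmsd,
        tm_score=score,
        seq_identity=100.0 * n_id / len(pairs),
        n_aligned=len(pairs),
        converged=converged,
        pair_names=pair_names,
        pair_indices=[(int(i), int(j)) for i, j in pairs_ij],
    )


def seq_identity(al: PairwiseAlignment) -> float:
    """Percent identical residue names among aligned pairs."""
    if al.n_aligned == 0 or not al.pair_names:
        raise AlignmentError("empty alignment")
    n_id = sum(1 for a, b in al.pair_names if a == b)
    return 100.0 * n_id / al.n_aligned


def select_subset(
    alignments: Sequence[PairwiseAlignment],
    min_aligned: int = 220,
    max_rmsd: float = 3.0,
) -> list[PairwiseAlignment]:
    """Keep alignments with more than ``min_aligned`` aligned residues OR an
    RMSD below ``max_rmsd`` (both inequalities strict)."""
    return [al for al in alignments if al.n_aligned > min_aligned or al.rmsd < max_rmsd]
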
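"""Structure of the phenotypic-equivalence set: reachability, observability,
the Kalman decomposition, minimal realizations and neutral directions.

The set N of all systems sharing a given impulse response is the neutral
set along which gene networks can drift without selection noticing.  Its
local geometry is captured by:

* the *reachable subspace* -- state directions an input can excite,
  span(B, AB, ..., A^(n-1) B);
* the *unobservable subspace* -- the largest A-invariant subspace inside
  null(C), motion in which never reaches the phenotype;
* the *Kalman decomposition* -- a change of basis splitting the kryptotype
  into reachable/unreachable x observable/unobservable blocks; only the
  reachable-and-observable block (the *minimal realization*) determines the
  phenotype;
* the *neutral tangent* -- first-order directions (ZA - AZ, ZB, -CZ)
  obtained from infinitesimal changes of basis V = I + eps Z, which leave
  the phenotype unchanged to first order in eps.  Holding B and C fixed
  restricts Z to {Z : ZB = 0, CZ = 0}, generically an (n - m)(n - l)
  dimensional space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import expm

from .systems import LinearSystem, markov_parameters, phenotypically_equivalent

__all__ = [
    "SubspaceDims",
    "KalmanDecomposition",
    "NeutralTangent",
    "reachable_subspace",
    "unobservable_subspace",
    "kalman_decomposition",
    "minimal_realization",
    "hankel_rank",
    "pad_nonminimal",
    "neutral_tangent",
    "CONSTRAINT_MODES",
]

#: Default relative rank tolerance: singular values below rank_tol times the
#: largest singular value are treated as zero.
RANK_TOL = 1e-9

CONSTRAINT_MODES = ("free", "fixed_B", "fixed_C", "fixed_BC")


def _svd_rank(s: np.ndarray, rank_tol: float) -> tuple[int, bool]:
    """Rank from singular values, plus an ambiguity flag when values straddle
    the threshold within a factor of 10."""
    if s.size == 0:
        return 0, False
    smax = s[0]
    if smax == 0:
        return 0, False
    thresh = rank_tol * smax
    rank = int(np.sum(s > thresh))
    ambiguous = bool(np.any((s > thresh / 10) & (s <= thresh * 10)))
    return rank, ambiguous


def _orth(M: np.ndarray, rank_tol: float) -> tuple[np.ndarray, bool]:
    """Orthonormal basis of the column span of M (n x 0 if M is zero/empty)."""
    n = M.shape[0]
    if M.size == 0:
        return np.zeros((n, 0)), False
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank, amb = _svd_rank(s, rank_tol)
    return U[:, :rank], amb


def _null(M: np.ndarray, dim: int, rank_tol: float) -> tuple[np.ndarray, bool]:
    """Orthonormal basis of the null space of M acting on R^dim."""
    if M.size == 0 or M.shape[0] == 0:
        return np.eye(dim), False
    _, s, Vt = np.linalg.svd(M)
    rank, amb = _svd_rank(s, rank_tol)
    return Vt[rank:].T, amb


def _complement_within(S: np.ndarray, W: np.ndarray, rank_tol: float) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of span(S) inside span(W).

    W has orthonormal columns, so the residual's singular values are sines of
    principal angles; they are compared against an absolute threshold (a pure
    noise residual must yield an empty basis, which a relative cut would not).
    """
    proj = W - S @ (S.T @ W) if S.shape[1] else W
    n = W.shape[0]
    if proj.size == 0:
        return np.zeros((n, 0))
    U, s, _ = np.linalg.svd(proj, full_matrices=False)
    rank = int(np.sum(s > np.sqrt(rank_tol)))
    return U[:, :rank]


def controllability_matrix(sys: LinearSystem) -> np.ndarray:
    """[B, AB, ..., A^(n-1) B], shape (n, n*m)."""
    blocks = []
    X = sys.B
    for _ in range(sys.n):
        blocks.append(X)
        X = sys.A @ X
    return np.hstack(blocks)


def observability_matrix(sys: LinearSystem) -> np.ndarray:
    """[C; CA; ...; CA^(n-1)], shape (n*l, n)."""
    blocks = []
    X = sys.C
    for _ in range(sys.n):
        blocks.append(X)
        X = X @ sys.A
    return np.vstack(blocks)


def reachable_subspace(sys: LinearSystem, rank_tol: float = RANK_TOL) -> np.ndarray:
    """Orthonormal basis (n x r) of the reachable subspace
    span(B, AB, ..., A^(n-1) B)."""
    basis, _ = _orth(controllability_matrix(sys), rank_tol)
    return basis


def unobservable_subspace(sys: LinearSystem, rank_tol: float = RANK_TOL) -> np.ndarray:
    """Orthonormal basis (n x q) of the unobservable subspace: the null space
    of the stacked observability matrix, equivalently the largest A-invariant
    subspace contained in null(C)."""
    basis, _ = _null(observability_matrix(sys), sys.n, rank_tol)
    return basis


class SubspaceDims(NamedTuple):
    """Dimensions of the four Kalman classes, in block order."""

    reach_unobs: int  # reachable & unobservable
    reach_obs: int  # reachable & observable (the minimal block)
    unreach_unobs: int  # unreachable & unobservable
    unreach_obs: int  # unreachable & observable


@dataclass(frozen=True)
class KalmanDecomposition:
    """Result of the Kalman decomposition of an (A, B, C) system.

    ``P`` is the change of basis; the transformed system
    (P A P^-1, P B, C P^-1) has the staircase zero-block pattern with block
    order (reachable-unobservable, reachable-observable,
    unreachable-unobservable, unreachable-observable); ``minimal`` is the
    reachable-observable subsystem, phenotypically equivalent to the input.
    """

    P: np.ndarray
    dims: SubspaceDims
    transformed: tuple[np.ndarray, np.ndarray, np.ndarray]
    minimal: LinearSystem
    warnings: tuple[str, ...] = ()

    @property
    def Pinv(self) -> np.ndarray:
        return np.linalg.inv(self.P)


def kalman_decomposition(
    sys: LinearSystem, rank_tol: float = RANK_TOL
) -> KalmanDecomposition:
    """Split the kryptotype into the four reachability/observability classes.

    The bases are assembled from the reachable subspace R and the
    unobservable subspace Q: block 1 is R ∩ Q, block 2 its orthogonal
    complement within R, block 3 its complement within Q, and block 4 the
    complement of R + Q.  With columns of P^-1 in that order, A maps each
    block into the blocks the staircase pattern allows, B lies in the
    reachable blocks and C vanishes on the unobservable ones.
    """
    n = sys.n
    warnings: list[str] = []

    R, amb_r = _orth(controllability_matrix(sys), rank_tol)
    if amb_r:
        warnings.append("reachable-subspace rank ambiguous near rank_tol")
    Q, amb_o = _null(observability_matrix(sys), n, rank_tol)
    if amb_o:
        warnings.append("unobservable-subspace rank ambiguous near rank_tol")

    # intersection R ∩ Q: vectors annihilated by both orthogonal projectors.
    # The stacked projector has O(1) scale by construction, so its singular
    # values are compared to an absolute threshold (sines of principal angles).
    proj = np.vstack([np.eye(n) - R @ R.T, np.eye(n) - Q @ Q.T])
    _, sv, Vt = np.linalg.svd(proj)
    atol = np.sqrt(rank_tol)
    S1 = Vt[int(np.sum(sv > atol)):].T
    if np.any((sv > atol / 10) & (sv <= atol * 10)):
        warnings.append("subspace-intersection rank ambiguous near rank_tol")
    S2 = _complement_within(S1, R, rank_tol)  # reachable & observable
    S3 = _complement_within(S1, Q, rank_tol)  # unreachable & unobservable
    # complement of span(R, Q) = span(S1, S2, S3)
    union, _ = _orth(np.hstack([S1, S2, S3]), rank_tol)
    S4 = _complement_within(union, np.eye(n), rank_tol)

    dims = SubspaceDims(S1.shape[1], S2.shape[1], S3.shape[1], S4.shape[1])
    if sum(dims) != n:
        raise np.linalg.LinAlgError(
            f"Kalman subspace dimensions {tuple(dims)} do not sum to n={n}; "
            "rank tolerance may be unsuitable for this system"
        )

    Pinv = np.hstack([S1, S2, S3, S4])
    P = np.linalg.inv(Pinv)
    At = P @ sys.A @ Pinv
    Bt = P @ sys.B
    Ct = sys.C @ Pinv

    i0 = dims.reach_unobs
    i1 = i0 + dims.reach_obs
    minimal = LinearSystem(At[i0:i1, i0:i1], Bt[i0:i1], Ct[:, i0:i1]) if dims.reach_obs else None
    if minimal is None:
        # phenotype is identically zero; represent by a 1-d zero system
        minimal = LinearSystem(
            np.zeros((1, 1)), np.zeros((1, sys.m)), np.zeros((sys.l, 1))
        )
    return KalmanDecomposition(
        P=P,
        dims=dims,
        transformed=(At, Bt, Ct),
        minimal=minimal,
        warnings=tuple(warnings),
    )


def minimal_realization(sys: LinearSystem, rank_tol: float = RANK_TOL) -> LinearSystem:
    """The smallest-dimension system with the same impulse response: the
    reachable-observable block of the Kalman decomposition."""
    return kalman_decomposition(sys, rank_tol).minimal


def hankel_rank(sys: LinearSystem, rank_tol: float = RANK_TOL) -> int:
    """Rank of the block-Hankel matrix of Markov parameters.

    H[i, j] = C A^(i+j) B for i, j = 0..n-1.  Its rank equals the minimal
    state dimension, giving an oracle for :func:`minimal_realization` that
    never constructs the decomposition.
    """
    M = markov_parameters(sys, 2 * sys.n - 1 if sys.n > 1 else 1)
    blocks = [[M[i + j] for j in range(sys.n)] for i in range(sys.n)] if sys.n > 1 else [[M[0]]]
    H = np.block(blocks)
    s = np.linalg.svd(H, compute_uv=False)
    rank, _ = _svd_rank(s, rank_tol)
    return rank


#: Kalman classes a padded (phenotypically inert) dimension may occupy.
PAD_CLASSES = ("reach_unobs", "unreach_unobs", "unreach_obs")


def pad_nonminimal(
    sys: LinearSystem,
    n_extra: int,
    classes: Sequence[str] | None = None,
    seed: int | np.random.Generator = 0,
    coupling_scale: float = 1.0,
    mix: bool = True,
) -> LinearSystem:
    """Embed ``sys`` in a larger network without changing its phenotype.

    Extra kryptotype dimensions are assigned to the three phenotypically
    inert Kalman classes (``classes`` defaults to cycling through all
    three); couplings are randomized uniform on [-coupling_scale,
    coupling_scale] but only in blocks the Kalman staircase pattern allows
    to be nonzero, so the impulse response is exactly preserved.  With
    ``mix`` the result is conjugated by a random orthogonal matrix to hide
    the block structure (still phenotype-preserving).
    """
    if n_extra < 1:
        raise ValueError("n_extra must be >= 1")
    if classes is None:
        classes = [PAD_CLASSES[k % 3] for k in range(n_extra)]
    classes = list(classes)
    if len(classes) == 0:
        raise ValueError("classes must be nonempty")
    if len(classes) != n_extra:
        raise ValueError(f"need one class per extra dimension ({n_extra}), got {len(classes)}")
    bad = set(classes) - set(PAD_CLASSES)
    if bad:
        raise ValueError(f"unknown pad classes {sorted(bad)}; allowed: {PAD_CLASSES}")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = classes.count("reach_unobs")
    q = classes.count("unreach_unobs")
    r = classes.count("unreach_obs")
    n, m, l = sys.n, sys.m, sys.l
    N = n + n_extra

    def U(rows, cols):
        return coupling_scale * rng.uniform(-1.0, 1.0, size=(rows, cols))

    # block order: (reach-unobs p, reach-obs n, unreach-unobs q, unreach-obs r)
    A = np.zeros((N, N))
    s0, s1, s2, s3 = 0, p, p + n, p + n + q
    A[s0:s1, s0:s1] = U(p, p)
    A[s0:s1, s1:s2] = U(p, n)
    A[s0:s1, s2:s3] = U(p, q)
    A[s0:s1, s3:] = U(p, r)
    A[s1:s2, s1:s2] = sys.A
    A[s1:s2, s3:] = U(n, r)
    A[s2:s3, s2:s3] = U(q, q)
    A[s2:s3, s3:] = U(q, r)
    A[s3:, s3:] = U(r, r)

    B = np.zeros((N, m))
    B[s0:s1] = U(p, m)
    B[s1:s2] = sys.B

    C = np.zeros((l, N))
    C[:, s1:s2] = sys.C
    C[:, s3:] = U(l, r)

    padded = LinearSystem(A, B, C)
    if mix:
        V = np.linalg.qr(rng.standard_normal((N, N)))[0]
        padded = LinearSystem(V @ A @ V.T, V @ B, C @ V.T)
    return padded


@dataclass(frozen=True)
class NeutralTangent:
    """First-order neutral directions of the equivalence set at a system.

    ``algebra_basis`` is an orthonormal (Frobenius) basis of the allowed
    generator matrices Z; ``generators`` are the linearly independent
    perturbation triples (ZA - AZ, ZB, -CZ) they induce, and ``dimension``
    is the number of such independent directions (the computed value is
    authoritative; the generic count for the fixed-B,C mode is
    (n - m)(n - l), see :func:`generic_tangent_dimension`).
    """

    generators: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    Z: tuple[np.ndarray, ...]
    algebra_basis: tuple[np.ndarray, ...]
    dimension: int
    constraint_mode: str

    @property
    def algebra_dim(self) -> int:
        """Dimension of the allowed generator algebra {Z}."""
        return len(self.algebra_basis)


def generic_tangent_dimension(n: int, m: int, l: int) -> int:
    """Generic fixed-B,C neutral dimension (n - m)(n - l).

    Counting constraints naively gives n(n - l - m): n*m from ZB = 0 plus
    l*n from CZ = 0.  But the l*m functionals Z |-> c_i' Z b_j lie in both
    sets, so only n(m + l) - l*m constraints are independent and the
    generic null-space dimension is n^2 - nm - ln + lm = (n - m)(n - l).
    The two-gene oscillator is the smallest illustration: its equivalent
    family with B, C fixed is one-dimensional, matching (2-1)(2-1) = 1
    (the naive count gives 0).  For special systems the dimension can still
    differ; the computed :class:`NeutralTangent` dimension is authoritative.
    """
    return (n - m) * (n - l)


def neutral_tangent(
    sys: LinearSystem,
    constraint_mode: str = "fixed_BC",
    rank_tol: float = RANK_TOL,
) -> NeutralTangent:
    """Generators of first-order phenotype-preserving perturbations.

    An infinitesimal change of basis V = I + eps Z moves the system along
    (ZA - AZ, ZB, -CZ) while leaving h(t) unchanged to first order.
    Constraint modes restrict which coefficients may move:

    * ``free``      -- any Z (A, B and C all free to change);
    * ``fixed_B``   -- ZB = 0 (input coupling held fixed);
    * ``fixed_C``   -- CZ = 0 (read-out held fixed);
    * ``fixed_BC``  -- both, so only A moves.
    """
    if constraint_mode not in CONSTRAINT_MODES:
        raise ValueError(f"constraint_mode must be one of {CONSTRAINT_MODES}")
    n, m, l = sys.n, sys.m, sys.l
    A, B, C = sys.A, sys.B, sys.C

    # constraint matrix on vec(Z): rows are ZB = 0 and/or CZ = 0
    rows = []
    if constraint_mode in ("fixed_B", "fixed_BC"):
        # (ZB)_{ij} = sum_k Z_{ik} B_{kj}  ->  kron(I_n, B.T) on row-major vec
        rows.append(np.kron(np.eye(n), B.T))
    if constraint_mode in ("fixed_C", "fixed_BC"):
        # (CZ)_{ij} = sum_k C_{ik} Z_{kj}  ->  kron(C, I_n)
        rows.append(np.kron(C, np.eye(n)))
    if rows:
        M = np.vstack(rows)
        Zbasis, _ = _null(M, n * n, rank_tol)
    else:
        Zbasis = np.eye(n * n)

    Zs = [Zbasis[:, k].reshape(n, n) for k in range(Zbasis.shape[1])]
    if not Zs:
        return NeutralTangent((), (), (), 0, constraint_mode)

    def triple(Z):
        return (Z @ A - A @ Z, Z @ B, -C @ Z)

    G = np.stack([np.concatenate([v.ravel() for v in triple(Z)]) for Z in Zs])
    Usvd, s, Vt = np.linalg.svd(G, full_matrices=False)
    rank, _ = _svd_rank(s, rank_tol)

    generators = []
    Zg = []
    for j in range(rank):
        Zj = sum(Usvd[i, j] * Zs[i] for i in range(len(Zs))) / s[j]
        Zg.append(Zj)
        dA = Vt[j, : n * n].reshape(n, n)
        dB = Vt[j, n * n : n * n + n * m].reshape(n, m)
        dC = Vt[j, n * n + n * m :].reshape(l, n)
        generators.append((dA, dB, dC))

    return NeutralTangent(
        generators=tuple(generators),
        Z=tuple(Zg),
        algebra_basis=tuple(Zs),
        dimension=rank,
        constraint_mode=constraint_mode,
    )


def apply_generator(
    sys: LinearSystem, gen: tuple[np.ndarray, np.ndarray, np.ndarray], eps: float
) -> LinearSystem:
    """The system displaced by eps along a tangent generator triple."""
    dA, dB, dC = gen
    return LinearSystem(sys.A + eps * dA, sys.B + eps * dB, sys.C + eps * dC)


def exp_neutral(sys: LinearSystem, Z: np.ndarray) -> LinearSystem:
    """The exact (finite) neutral move: conjugation by V = expm(Z).

    Unlike the first-order step this stays exactly on the equivalence set;
    if ZB = 0 and CZ = 0 then B and C are unchanged as well.
    """
    V = expm(Z)
    Vinv = np.linalg.inv(V)
    return LinearSystem(V @ sys.A @ Vinv, V @ sys.B, sys.C @ Vinv)
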
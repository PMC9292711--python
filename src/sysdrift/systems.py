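"""Linear time-invariant models of gene regulatory networks.

A network of ``n`` interacting molecules (the *kryptotype* -- the internal
state hidden from selection) driven by an ``m``-dimensional environmental
input ``u(t)`` and read out through an ``l``-dimensional *phenotype* is
modelled as

    dk/dt = A k(t) + B u(t),      phi(t) = C k(t),      k(0) = 0,

where ``A`` holds regulatory coefficients (``A[i, j] > 0``: molecule j
upregulates molecule i), ``B`` couples the environment to transcription and
``C`` maps internal concentrations to the traits selection sees.  The full
input--output behaviour is summarised by the impulse response

    h(t) = C expm(A t) B,

an ``l x m`` matrix function of time: the phenotype is the convolution of
the input with ``h``.  Two systems with the same ``h`` are *phenotypically
equivalent* -- indistinguishable to selection under every input -- even
when their wiring differs radically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.integrate import solve_ivp

__all__ = [
    "LinearSystem",
    "Trajectory",
    "ImpulseResponseSamples",
    "make_system",
    "impulse_response",
    "simulate",
    "coordinate_change",
    "markov_parameters",
    "phenotypically_equivalent",
    "oscillator",
    "oscillator_family",
    "random_system",
    "default_time_grid",
]

#: Default relative tolerance on Markov parameters for equivalence testing.
EQUIVALENCE_RTOL = 1e-8

#: Reciprocal-condition-number floor below which a coordinate change is
#: rejected as numerically singular.
RCOND_MIN = 1e-12


@dataclass(frozen=True)
class LinearSystem:
    """An (A, B, C) triple: regulatory matrix, input and output couplings.

    Attributes
    ----------
    A : (n, n) ndarray
        Regulatory coefficients, units of inverse time.
    B : (n, m) ndarray
        Environmental input coupling.
    C : (l, n) ndarray
        Phenotype read-out.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.asarray(self.B, dtype=float)
        if B.ndim == 1:
            B = B[:, None]
        C = np.asarray(self.C, dtype=float)
        if C.ndim == 1:
            C = C[None, :]
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        n = A.shape[0]
        if B.shape[0] != n:
            raise ValueError(
                f"row mismatch between A ({A.shape}) and B ({B.shape})"
            )
        if C.shape[1] != n:
            raise ValueError(
                f"column mismatch between A ({A.shape}) and C ({C.shape})"
            )
        for name, M in (("A", A), ("B", B), ("C", C)):
            if M.size == 0:
                raise ValueError(f"{name} is empty")
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains non-finite entries")
        A.setflags(write=False)
        B.setflags(write=False)
        C.setflags(write=False)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)

    @property
    def n(self) -> int:
        """Kryptotype (state) dimension."""
        return self.A.shape[0]

    @property
    def m(self) -> int:
        """Input dimension."""
        return self.B.shape[1]

    @property
    def l(self) -> int:
        """Output (phenotype) dimension."""
        return self.C.shape[0]

    def h(self, t: float) -> np.ndarray:
        """Impulse response C expm(A t) B at a single time."""
        return self.C @ expm(self.A * float(t)) @ self.B

    def __repr__(self) -> str:
        return f"LinearSystem(n={self.n}, m={self.m}, l={self.l})"


@dataclass(frozen=True)
class Trajectory:
    """A simulated path: times, kryptotype k(t), phenotype phi(t), input u(t)."""

    times: np.ndarray
    kryptotype: np.ndarray  # (T, n)
    phenotype: np.ndarray  # (T, l)
    input: np.ndarray  # (T, m)


@dataclass(frozen=True)
class ImpulseResponseSamples:
    """Samples of h(t) = C expm(At) B on a time grid; values has shape (T, l, m)."""

    times: np.ndarray
    values: np.ndarray


def make_system(A, B, C) -> LinearSystem:
    """Validate and assemble an (A, B, C) triple into a :class:`LinearSystem`."""
    return LinearSystem(A, B, C)


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if not np.all(np.isfinite(times)):
        raise ValueError("times contains non-finite values")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def default_time_grid(t_max: float = 4 * np.pi, points: int = 400) -> np.ndarray:
    """Uniform grid on [0, t_max]; the default window spans two periods of the
    oscillator examples."""
    return np.linspace(0.0, t_max, points)


def impulse_response(sys: LinearSystem, times) -> ImpulseResponseSamples:
    """Sample h(t) = C expm(A t) B on an increasing grid of nonnegative times."""
    times = _check_times(times)
    values = np.empty((len(times), sys.l, sys.m))
    for k, t in enumerate(times):
        values[k] = sys.C @ expm(sys.A * t) @ sys.B
    return ImpulseResponseSamples(times=times, values=values)


def simulate(
    sys: LinearSystem,
    u: Callable[[float], np.ndarray] | None,
    times,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the network ODE from k(0) = 0 under input ``u``.

    ``u`` maps time to an input vector of length ``m`` (scalars accepted for
    m = 1); ``None`` means zero input.  The kryptotype solves
    dk/dt = A k + B u and the phenotype is C k.
    """
    times = _check_times(times)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        prepended = True
    else:
        prepended = False

    if u is None:
        uf = lambda t: np.zeros(sys.m)
    else:
        def uf(t, _u=u):
            val = np.atleast_1d(np.asarray(_u(t), dtype=float))
            if val.shape != (sys.m,):
                raise ValueError(
                    f"input function returned shape {val.shape}, expected ({sys.m},)"
                )
            if not np.all(np.isfinite(val)):
                raise ValueError(f"input function returned non-finite value at t={t}")
            return val

    def rhs(t, k):
        return sys.A @ k + sys.B @ uf(t)

    sol = solve_ivp(
        rhs,
        (0.0, times[-1]),
        np.zeros(sys.n),
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="DOP853",
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    kry = sol.y.T
    if prepended:
        times, kry = times[1:], kry[1:]
    phen = kry @ sys.C.T
    inputs = np.stack([uf(t) for t in times])
    return Trajectory(times=times, kryptotype=kry, phenotype=phen, input=inputs)


def rectangular_impulse(width: float = 1e-3, mass: float = 1.0, component: int = 0):
    """A unit-mass rectangular pulse on [0, width): the sampled stand-in for a
    delta-function input.  As width -> 0 the response converges to h(t)."""
    if width <= 0:
        raise ValueError("pulse width must be positive")

    def u(t, _w=width, _h=mass / width, _c=component):
        return np.array([_h if 0.0 <= t < _w else 0.0])

    return u


def coordinate_change(sys: LinearSystem, V: np.ndarray) -> LinearSystem:
    """Apply the change of basis V: (A, B, C) -> (V A V^-1, V B, C V^-1).

    The result is phenotypically equivalent to ``sys``: the impulse response
    is untouched because C V^-1 expm(V A V^-1 t) V B = C expm(A t) B.
    Biologically this rewires every regulatory interaction at once while
    leaving the input--output behaviour invariant.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n = sys.n
    if V.shape != (n, n):
        raise ValueError(f"V must be {n}x{n}, got {V.shape}")
    # reciprocal condition number guard against (near-)singular V
    sv = np.linalg.svd(V, compute_uv=False)
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if not np.isfinite(rcond) or rcond < RCOND_MIN:
        raise np.linalg.LinAlgError(
            f"V is singular or ill-conditioned (rcond={rcond:.2e} < {RCOND_MIN:.0e})"
        )
    Vinv = np.linalg.inv(V)
    return LinearSystem(V @ sys.A @ Vinv, V @ sys.B, sys.C @ Vinv)


def markov_parameters(sys: LinearSystem, count: int) -> np.ndarray:
    """The first ``count`` Markov parameters C A^k B, k = 0 .. count-1.

    Returns an array of shape (count, l, m).  These are the Taylor
    coefficients of h(t) at t = 0 (up to factorials) and give a
    finite-dimensional certificate of phenotypic equivalence.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    out = np.empty((count, sys.l, sys.m))
    X = sys.B
    for k in range(count):
        out[k] = sys.C @ X
        X = sys.A @ X
    return out


def phenotypically_equivalent(
    sys1: LinearSystem, sys2: LinearSystem, tol: float = EQUIVALENCE_RTOL
) -> bool:
    """Do two systems share the impulse response h(t) for all t >= 0?

    Checked through the first n1 + n2 Markov parameters: by
    Cayley--Hamilton, agreement of C A^k B for k < n1 + n2 implies equality
    of the two matrix exponential series for all t, so this finite test is
    exact up to the relative tolerance ``tol`` (normalised by the largest
    parameter magnitude).  State dimensions may differ; input and output
    dimensions must match.
    """
    if sys1.m != sys2.m or sys1.l != sys2.l:
        raise ValueError(
            f"input/output dimensions differ: ({sys1.m},{sys1.l}) vs ({sys2.m},{sys2.l})"
        )
    count = sys1.n + sys2.n
    m1 = markov_parameters(sys1, count)
    m2 = markov_parameters(sys2, count)
    scale = max(np.abs(m1).max(), np.abs(m2).max(), 1e-300)
    return bool(np.abs(m1 - m2).max() <= tol * scale)


def oscillator() -> LinearSystem:
    """The two-gene oscillator: gene 2 upregulates gene 1, gene 1 represses
    gene 2, both driven equally by the input, phenotype = gene-1 level.

    Its impulse response is h(t) = sin t + cos t.
    """
    return LinearSystem(
        A=np.array([[0.0, 1.0], [-1.0, 0.0]]),
        B=np.array([[1.0], [1.0]]),
        C=np.array([[1.0, 0.0]]),
    )


def oscillator_family(tau: float, tol: float = 1e-9) -> LinearSystem:
    """The one-parameter family A(tau) of all minimal two-gene systems
    phenotypically equivalent to the oscillator with B and C held fixed.

    A(tau) = (1 / (tau + 1)) * [[tau, 1], [-(2 tau (tau+1) + 1), -tau]],
    defined for tau != -1.  It equals V A(0) V^-1 for
    V = [[1, 0], [-tau, tau + 1]], the general invertible V with V B = B and
    C V = C; A(0) is the oscillator itself.  Every member has trace 0 and
    determinant 1, so h(t) = sin t + cos t throughout the family.
    """
    tau = float(tau)
    if abs(tau + 1.0) <= tol:
        raise ValueError("tau = -1 is outside the family (change of basis degenerates)")
    A = np.array(
        [
            [tau, 1.0],
            [-(2.0 * tau * (tau + 1.0) + 1.0), -tau],
        ]
    ) / (tau + 1.0)
    base = oscillator()
    return LinearSystem(A, base.B, base.C)


def random_system(
    n: int,
    m: int = 1,
    l: int = 1,
    seed: int | np.random.Generator = 0,
    spectral_bound: float | None = None,
) -> LinearSystem:
    """A reproducible pseudo-random system with standard-normal entries.

    If ``spectral_bound`` is given, A is shifted by a multiple of the
    identity so the largest real part of its eigenvalues is at most the
    bound (used to make stable fixtures).
    """
    if min(n, m, l) < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A = rng.standard_normal((n, n))
    if spectral_bound is not None:
        shift = np.max(np.linalg.eigvals(A).real) - spectral_bound
        if shift > 0:
            A = A - shift * np.eye(n)
    B = rng.standard_normal((n, m))
    C = rng.standard_normal((l, n))
    return LinearSystem(A, B, C)
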
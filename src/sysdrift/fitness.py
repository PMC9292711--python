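"""Weighted distance to the phenotypic optimum and hybrid-breakdown curves.

How far a system's phenotype is from optimal is quantified by a weighted
L2 difference between impulse responses,

    D(h) = ( Int_0^T rho(t) || h(t) - h0(t) ||^2 dt )^(1/2),

with exponential weight rho(t) = exp(-sigma t) and sigma = 1/(4 pi) by
default, so fitness reflects the dynamics over a few multiples of 2 pi but
not longer.  h0 is the impulse response of the optimal system.

Evaluation routes (all operate on the augmented difference system with
block-diagonal state matrix, stacked inputs and differenced outputs, whose
impulse response is h - h0):

* ``lyapunov``   -- unbounded horizon: shift the augmented matrix by
  sigma/2 and solve a continuous-time Lyapunov equation for the
  observability Gramian; requires the shifted matrix to be Hurwitz,
  otherwise the integral diverges (D = +inf under the ``infinite`` policy).
* ``gramian``    -- finite horizon: the finite-horizon Gramian from a
  single block matrix exponential (Van Loan's construction); exact to
  matrix-exponential accuracy for any system, stable or not.
* ``quadrature`` -- adaptive quadrature of the integrand; the slow
  reference route used to cross-check the other two.

The breakdown experiments sweep parental divergence eps along the
equivalent-oscillator family A(eps): F1 hybrids sit at the parental
midpoint and are at distance ~ eps^2 from optimum (curvature of the
neutral set), while F2 segregants scatter off the set at distance ~ eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.integrate import quad

from . import genetics
from .systems import LinearSystem, oscillator, oscillator_family

__all__ = [
    "DistanceSpec",
    "distance_to_optimum",
    "is_divergent",
    "breakdown_curve",
    "scaling_exponents",
    "DEFAULT_SIGMA",
    "DEFAULT_HORIZON",
]

#: rho(t) = exp(-t / 4 pi)
DEFAULT_SIGMA = 1.0 / (4.0 * np.pi)

#: Default truncation horizon 20 * 2 pi: the weight has decayed to e^-10 and
#: the functional reflects "a few multiples of 2 pi, but not longer".
DEFAULT_HORIZON = 40.0 * np.pi

_METHODS = ("quadrature", "lyapunov", "gramian")


@dataclass(frozen=True)
class DistanceSpec:
    """Controls the distance functional: the optimum h0, the weight decay
    sigma, the horizon (None = unbounded) and the evaluation method
    (None = lyapunov when unbounded, gramian when truncated).

    ``divergence_policy`` decides what an unbounded-horizon divergent
    integral returns: ``"infinite"`` gives +inf, ``"truncate"`` falls back
    to the truncated functional at ``fallback_horizon``.
    """

    optimum: LinearSystem
    sigma: float = DEFAULT_SIGMA
    horizon: float | None = None
    method: str | None = None
    divergence_policy: str = "infinite"
    fallback_horizon: float = DEFAULT_HORIZON

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.method is not None and self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.method == "lyapunov" and self.horizon is not None:
            raise ValueError("the lyapunov method requires an unbounded horizon")
        if self.divergence_policy not in ("infinite", "truncate"):
            raise ValueError("divergence_policy must be 'infinite' or 'truncate'")
        if self.horizon is not None and self.horizon <= 0:
            raise ValueError("horizon must be positive")


def _augmented(sys: LinearSystem, optimum: LinearSystem):
    """Block system whose impulse response is h(t) - h0(t)."""
    if sys.m != optimum.m or sys.l != optimum.l:
        raise ValueError(
            f"system ({sys.m} inputs, {sys.l} outputs) and optimum "
            f"({optimum.m}, {optimum.l}) are not comparable"
        )
    n1, n2 = sys.n, optimum.n
    Ab = np.zeros((n1 + n2, n1 + n2))
    Ab[:n1, :n1] = sys.A
    Ab[n1:, n1:] = optimum.A
    Bb = np.vstack([sys.B, optimum.B])
    Cb = np.hstack([sys.C, -optimum.C])
    return Ab, Bb, Cb


def is_divergent(sys: LinearSystem, spec: DistanceSpec) -> bool:
    """Does the unbounded-horizon integral diverge?  True iff the sigma/2
    shifted augmented matrix is not strictly Hurwitz."""
    Ab, _, _ = _augmented(sys, spec.optimum)
    return bool(np.max(np.linalg.eigvals(Ab).real) >= spec.sigma / 2.0)


def _gramian_finite(As, CtC, T):
    """Finite-horizon observability Gramian Int_0^T e^{As' t} C'C e^{As t} dt.

    Van Loan's construction -- expm([[-As', C'C], [0, As]] dt) = [[.., H],
    [0, E]] gives the Gramian over dt as E' H -- combined with interval
    doubling W(2t) = W(t) + e^{As' t} W(t) e^{As t}, which keeps the block
    exponential well-scaled for long horizons and non-Hurwitz As.
    """
    k = As.shape[0]
    scale = max(np.linalg.norm(As, 2), np.linalg.norm(CtC, 2), 1e-12)
    doublings = max(0, int(np.ceil(np.log2(scale * T))))
    dt = T / 2**doublings
    M = np.zeros((2 * k, 2 * k))
    M[:k, :k] = -As.T
    M[:k, k:] = CtC
    M[k:, k:] = As
    EM = expm(M * dt)
    E = EM[k:, k:]
    W = E.T @ EM[:k, k:]
    for _ in range(doublings):
        W = W + E.T @ W @ E
        E = E @ E
        if not np.all(np.isfinite(W)):  # astronomically divergent dynamics
            return np.full_like(W, np.inf)
    return W


def distance_to_optimum(sys: LinearSystem, spec: DistanceSpec) -> float:
    """Evaluate D(h) for ``sys`` against the optimum in ``spec``.

    Returns a nonnegative float, or +inf for a divergent unbounded-horizon
    integral under the ``infinite`` policy.
    """
    Ab, Bb, Cb = _augmented(sys, spec.optimum)
    As = Ab - (spec.sigma / 2.0) * np.eye(Ab.shape[0])
    method = spec.method
    horizon = spec.horizon

    if horizon is None:
        hurwitz = np.max(np.linalg.eigvals(As).real) < 0
        if not hurwitz:
            if spec.divergence_policy == "infinite":
                return np.inf
            horizon = spec.fallback_horizon
            if method in (None, "lyapunov"):
                method = "gramian"
        elif method is None:
            method = "lyapunov"

    if method == "lyapunov":
        Q = solve_continuous_lyapunov(As.T, -Cb.T @ Cb)
        d2 = float(np.trace(Bb.T @ Q @ Bb))
        return float(np.sqrt(max(d2, 0.0)))

    if method is None:
        method = "gramian"

    if method == "gramian":
        if horizon is None:
            # stable unbounded integral evaluated by Gramian at a horizon long
            # enough that the remaining tail is below double precision
            decay = -np.max(np.linalg.eigvals(As).real)
            horizon = min(40.0 / max(decay, 1e-3), 1e5)
        W = _gramian_finite(As, Cb.T @ Cb, horizon)
        d2 = float(np.trace(Bb.T @ W @ Bb))
        return float(np.sqrt(max(d2, 0.0)))

    # adaptive quadrature of rho(t) ||h(t) - h0(t)||_F^2
    def integrand(t):
        H = Cb @ expm(Ab * t) @ Bb
        return np.exp(-spec.sigma * t) * float(np.sum(H * H))

    upper = np.inf if horizon is None else horizon
    d2, _ = quad(integrand, 0.0, upper, epsabs=1e-10, epsrel=1e-10, limit=800)
    return float(np.sqrt(max(d2, 0.0)))


def _default_family(eps: float) -> tuple[LinearSystem, LinearSystem]:
    return oscillator(), oscillator_family(eps)


def breakdown_curve(
    eps_list,
    design: str = "f2_enumerated",
    spec: DistanceSpec | None = None,
    weighting: str = "mendelian",
    rng: np.random.Generator | None = None,
    family=None,
    n_f2: int = 500,
    dosage: float | None = 2.0,
) -> pd.DataFrame:
    """Mean hybrid distance from optimum as parental divergence eps grows.

    For each eps, parents are the (phenotypically equivalent) pair returned
    by ``family(eps)`` -- by default the oscillator A(0) and A(eps) -- made
    homozygous over one locus per A coefficient.  The F1 (parental
    midpoint) and the F2 ensemble (enumerated 3^L classes, or ``n_f2``
    sampled offspring for design "f2_sampled") are scored with
    :func:`distance_to_optimum`.

    Returns a DataFrame with columns eps, genetic_distance, f1_distance,
    f2_distance, f2_frac_divergent, n_f2, weighting.
    """
    if design not in ("f1", "f2_enumerated", "f2_sampled"):
        raise ValueError("design must be f1, f2_enumerated or f2_sampled")
    if weighting not in ("mendelian", "uniform"):
        raise ValueError("weighting must be 'mendelian' or 'uniform'")
    family = family or _default_family
    if spec is None:
        spec = DistanceSpec(optimum=oscillator(), horizon=DEFAULT_HORIZON)
    if design == "f2_sampled" and rng is None:
        raise ValueError("sampled F2 design requires an rng")

    rows = []
    for eps in np.asarray(eps_list, dtype=float):
        pa, pb = family(eps)
        lmap = genetics.a_matrix_loci(pa.n, pa.m, pa.l)
        g1 = genetics.homozygote(lmap, pa)
        g2 = genetics.homozygote(lmap, pb)
        f1_sys = genetics.diploid_system(genetics.f1_hybrid(g1, g2), dosage=dosage)
        f1_d = distance_to_optimum(f1_sys, spec)

        f2_d = np.nan
        frac_div = np.nan
        nf2 = 0
        if design != "f1":
            if design == "f2_enumerated":
                ens = genetics.f2_enumerate(g1, g2, dosage=dosage)
                w = ens.uniform_weights if weighting == "uniform" else ens.weights
            else:
                ens = genetics.f2_sample(g1, g2, n_f2, rng, dosage=dosage)
                w = ens.weights
            dists = np.array([distance_to_optimum(s, spec) for s in ens.systems])
            div = np.array([is_divergent(s, spec) for s in ens.systems])
            finite = np.isfinite(dists)
            f2_d = float(np.sum(w[finite] * dists[finite]) / np.sum(w[finite])) if finite.any() else np.inf
            frac_div = float(np.sum(w * div))
            nf2 = len(ens)

        rows.append(
            dict(
                eps=float(eps),
                genetic_distance=genetics.genetic_distance(pa, pb),
                f1_distance=f1_d,
                f2_distance=f2_d,
                f2_frac_divergent=frac_div,
                n_f2=nf2,
                weighting=weighting,
            )
        )
    return pd.DataFrame(rows)


def scaling_exponents(
    curve: pd.DataFrame, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Log-log slopes of mean F1 and F2 distance against eps.

    F1 hybrids lie at the parental midpoint and so only feel the curvature
    of the neutral set: slope 2.  F2 segregants leave the set at first
    order: slope 1.  ``window`` restricts the fit to eps in [lo, hi];
    at least four finite points are required.
    """
    df = curve
    if window is not None:
        lo, hi = window
        df = df[(df["eps"] >= lo) & (df["eps"] <= hi)]
    df = df[(df["eps"] > 0)]

    def slope(col):
        sub = df[np.isfinite(df[col]) & (df[col] > 0)]
        if len(sub) < 4:
            raise ValueError(
                f"need >= 4 finite positive points to fit {col}; got {len(sub)} "
                "(try a truncating distance spec or a smaller-eps window)"
            )
        return float(np.polyfit(np.log(sub["eps"]), np.log(sub[col]), 1)[0])

    return slope("f1_distance"), slope("f2_distance")
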
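"""Neutral system drift and the divergence clock of speciation.

Under stabilizing selection on the phenotype, a population's mean network
wanders along the phenotypic-equivalence set.  The walk is realized in the
symmetry group: the neutral generator algebra {Z} (with ZB = 0 and CZ = 0
when B and C are constrained) gets an orthonormal basis, per-generation
Gaussian increments with variance V_G / N_e are accumulated into algebra
coordinates s_t, and the population mean at generation t is the
conjugation of the ancestral system by V = expm(Z(s_t)).  Every visited
system is *exactly* phenotypically equivalent to the ancestor -- the walk
never needs projecting back onto the neutral set -- and each coordinate is
an exact Gaussian random walk: Var(s_t) = t V_G / N_e per direction, and
the difference of two independent lineages has twice that variance.

Composing the clock with hybrid breakdown: parental divergence after t
generations is eps ~ sqrt(t V_G / N_e), F2 hybrids fall off the neutral
set at distance ~ eps, so mean squared F2 distance -- and hence the loss
of hybrid fitness under a locally quadratic fitness function
w = max(0, 1 - c D^2) -- grows linearly in t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import genetics
from .equivalence import NeutralTangent, neutral_tangent
from .fitness import DistanceSpec, DEFAULT_HORIZON, distance_to_optimum, is_divergent
from .systems import LinearSystem

__all__ = [
    "DriftConfig",
    "DriftTrajectory",
    "drift_walk",
    "coordinate_walks",
    "divergence_experiment",
]


@dataclass(frozen=True)
class DriftConfig:
    """Population-genetic parameters of the neutral walk.

    VG is the additive genetic variance per neutral direction and Ne the
    effective population size; the population mean moves a Gaussian amount
    with variance VG/Ne per generation along each orthonormal direction of
    the constrained generator algebra.
    """

    VG: float
    Ne: float
    generations: int
    constraint_mode: str = "fixed_BC"
    replicates: int = 1

    def __post_init__(self):
        if self.VG < 0:
            raise ValueError("VG must be nonnegative")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    @property
    def step_sd(self) -> float:
        return float(np.sqrt(self.VG / self.Ne))


@dataclass(frozen=True)
class DriftTrajectory:
    """A single lineage: algebra coordinates for every generation and the
    population-mean system materialized at the stored generations."""

    generations: np.ndarray  # stored generation indices
    systems: tuple[LinearSystem, ...]
    algebra_coordinates: np.ndarray  # (t_max + 1, dim), every generation
    tangent: NeutralTangent


def _algebra(sys0: LinearSystem, mode: str) -> NeutralTangent:
    tangent = neutral_tangent(sys0, mode)
    if tangent.algebra_dim == 0:
        raise ValueError(
            f"system has no neutral directions under constraint mode {mode!r}"
        )
    return tangent


def system_at(sys0: LinearSystem, tangent: NeutralTangent, coords) -> LinearSystem:
    """The system reached from sys0 by the group element expm(Z(coords))."""
    coords = np.asarray(coords, dtype=float)
    Z = sum(c * Zb for c, Zb in zip(coords, tangent.algebra_basis))
    V = expm(Z)
    Vinv = np.linalg.inv(V)
    return LinearSystem(V @ sys0.A @ Vinv, V @ sys0.B, sys0.C @ Vinv)


def coordinate_walks(
    dim: int, cfg: DriftConfig, rng: np.random.Generator, replicates: int | None = None
) -> np.ndarray:
    """Cumulative algebra coordinates, shape (replicates, generations + 1, dim).

    Pure Gaussian random walks with per-generation, per-direction variance
    VG/Ne; row 0 of every replicate is the origin.
    """
    R = cfg.replicates if replicates is None else replicates
    steps = rng.normal(0.0, cfg.step_sd, size=(R, cfg.generations, dim))
    coords = np.zeros((R, cfg.generations + 1, dim))
    np.cumsum(steps, axis=1, out=coords[:, 1:])
    return coords


def drift_walk(
    sys0: LinearSystem,
    cfg: DriftConfig,
    rng: np.random.Generator,
    store: np.ndarray | list | None = None,
) -> DriftTrajectory:
    """One lineage drifting neutrally for ``cfg.generations`` generations.

    ``store`` lists the generations at which the population-mean system is
    materialized (default: ten evenly spaced checkpoints plus 0 and the
    final generation); coordinates are recorded every generation.
    """
    tangent = _algebra(sys0, cfg.constraint_mode)
    coords = coordinate_walks(tangent.algebra_dim, cfg, rng, replicates=1)[0]
    t_max = cfg.generations
    if store is None:
        store = np.unique(np.linspace(0, t_max, min(t_max + 1, 11)).astype(int))
    store = np.asarray(store, dtype=int)
    if np.any(store < 0) or np.any(store > t_max):
        raise ValueError("stored generations must lie in [0, generations]")
    systems = tuple(system_at(sys0, tangent, coords[t]) for t in store)
    return DriftTrajectory(
        generations=store,
        systems=systems,
        algebra_coordinates=coords,
        tangent=tangent,
    )


def divergence_experiment(
    sys0: LinearSystem,
    cfg: DriftConfig,
    checkpoints,
    rng: np.random.Generator,
    spec: DistanceSpec | None = None,
    f2_design: str = "enumerate",
    n_f2: int = 200,
    fitness_c: float = 1.0,
    locus_map: genetics.LocusMap | None = None,
    dosage: float | None = 2.0,
) -> pd.DataFrame:
    """Two lineages drift apart; their hybrids break down on a linear clock.

    ``cfg.replicates`` independent pairs of lineages drift from ``sys0``.
    At each checkpoint generation, each lineage mean is treated as a
    homozygous parental population; the F1 and an F2 ensemble (enumerated
    3^L classes, or ``n_f2`` sampled offspring when f2_design="sample") are
    formed over ``locus_map`` (default: one locus per A coefficient) and
    scored against ``spec`` (default: truncated-horizon distance to sys0).
    Fitness is the locally quadratic w = max(0, 1 - c D^2).

    Returns one row per (replicate, checkpoint) with columns: replicate, t,
    genetic_distance, coord_distance2, f1_distance, f2_distance,
    f2_frac_divergent, f1_fitness, f2_fitness.
    """
    if f2_design not in ("enumerate", "sample"):
        raise ValueError("f2_design must be 'enumerate' or 'sample'")
    tangent = _algebra(sys0, cfg.constraint_mode)
    checkpoints = np.asarray(sorted(set(int(t) for t in checkpoints)), dtype=int)
    if np.any(checkpoints < 0) or np.any(checkpoints > cfg.generations):
        raise ValueError("checkpoints must lie in [0, generations]")
    if spec is None:
        spec = DistanceSpec(optimum=sys0, horizon=DEFAULT_HORIZON)
    if locus_map is None:
        locus_map = genetics.a_matrix_loci(sys0.n, sys0.m, sys0.l)

    def fitness(d):
        return max(0.0, 1.0 - fitness_c * d * d) if np.isfinite(d) else 0.0

    dim = tangent.algebra_dim
    coords_a = coordinate_walks(dim, cfg, rng)
    coords_b = coordinate_walks(dim, cfg, rng)

    rows = []
    for r in range(cfg.replicates):
        for t in checkpoints:
            sa = system_at(sys0, tangent, coords_a[r, t])
            sb = system_at(sys0, tangent, coords_b[r, t])
            ga = genetics.homozygote(locus_map, sa)
            gb = genetics.homozygote(locus_map, sb)
            f1_sys = genetics.diploid_system(
                genetics.f1_hybrid(ga, gb), dosage=dosage
            )
            f1_d = distance_to_optimum(f1_sys, spec)
            if f2_design == "enumerate":
                ens = genetics.f2_enumerate(ga, gb, dosage=dosage)
                w = ens.weights
            else:
                ens = genetics.f2_sample(ga, gb, n_f2, rng, dosage=dosage)
                w = ens.weights
            dists = np.array([distance_to_optimum(s, spec) for s in ens.systems])
            div = np.array([is_divergent(s, spec) for s in ens.systems])
            finite = np.isfinite(dists)
            f2_d = (
                float(np.sum(w[finite] * dists[finite]) / np.sum(w[finite]))
                if finite.any()
                else np.inf
            )
            f2_w = float(np.sum(w * np.array([fitness(d) for d in dists])))
            rows.append(
                dict(
                    replicate=r,
                    t=int(t),
                    genetic_distance=genetics.genetic_distance(sa, sb),
                    coord_distance2=float(
                        np.sum((coords_a[r, t] - coords_b[r, t]) ** 2)
                    ),
                    f1_distance=f1_d,
                    f2_distance=f2_d,
                    f2_frac_divergent=float(np.sum(w * div)),
                    f1_fitness=fitness(f1_d),
                    f2_fitness=f2_w,
                )
            )
    return pd.DataFrame(rows)
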
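"""Reproducible table recipes for the worked oscillator experiments.

Each recipe builds its inputs in code, runs the library and returns tidy
DataFrames (written as TSV when an output directory is given):

* ``fig1`` -- the two-gene oscillator's phenotype phi(t) = sin t + cos t;
* ``fig2`` -- the equivalent family A(tau): identical gene-1 (phenotype)
  dynamics for A(0) and A(-2), diverging gene-2 (hidden) dynamics;
* ``fig5`` -- F1 and all 81 enumerated F2 hybrid phenotypes for parents
  A(0) x A(eps), eps in {1/100, 1/10, 1/2};
* ``fig6`` -- mean F1/F2 hybrid distance from optimum against parental
  divergence (the hybrid-breakdown curve).

All recipes are deterministic; stochastic variants take a seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import fitness, genetics
from .systems import (
    default_time_grid,
    impulse_response,
    oscillator,
    oscillator_family,
)

__all__ = ["run_figure", "FIGURE_RECIPES"]

FIG5_EPS = (1.0 / 100.0, 1.0 / 10.0, 1.0 / 2.0)


def _fig1(seed: int = 0) -> dict[str, pd.DataFrame]:
    times = default_time_grid()
    h = impulse_response(oscillator(), times).values[:, 0, 0]
    return {"fig1_phenotype": pd.DataFrame({"time": times, "phenotype": h})}


def _fig2(seed: int = 0) -> dict[str, pd.DataFrame]:
    times = default_time_grid()
    taus = (0.0, -2.0)
    frames = {}
    rows = []
    from scipy.linalg import expm

    for tau in taus:
        sys = oscillator_family(tau)
        for t in times:
            k = expm(sys.A * t) @ sys.B  # kryptotype of the impulse response
            rows.append(
                dict(tau=tau, time=t, gene1=float(k[0, 0]), gene2=float(k[1, 0]))
            )
    frames["fig2_dynamics"] = pd.DataFrame(rows)
    tau_grid = np.linspace(-4.0, 4.0, 81)
    tau_grid = tau_grid[np.abs(tau_grid + 1.0) > 1e-9]
    fam = []
    for tau in tau_grid:
        A = oscillator_family(tau).A
        fam.append(
            dict(tau=tau, a11=A[0, 0], a12=A[0, 1], a21=A[1, 0], a22=A[1, 1])
        )
    frames["fig2_family"] = pd.DataFrame(fam)
    return frames


def _fig5(seed: int = 0) -> dict[str, pd.DataFrame]:
    times = default_time_grid()
    rows = []
    for eps in FIG5_EPS:
        pa, pb = oscillator(), oscillator_family(eps)
        lmap = genetics.a_matrix_loci(2)
        g1, g2 = genetics.homozygote(lmap, pa), genetics.homozygote(lmap, pb)
        parent_h = impulse_response(pa, times).values[:, 0, 0]
        f1 = genetics.diploid_system(genetics.f1_hybrid(g1, g2))
        f1_h = impulse_response(f1, times).values[:, 0, 0]
        for t, hp, hf in zip(times, parent_h, f1_h):
            rows.append(dict(eps=eps, kind="parent", genotype=-1, time=t, phenotype=hp))
            rows.append(dict(eps=eps, kind="F1", genotype=0, time=t, phenotype=hf))
        ens = genetics.f2_enumerate(g1, g2)
        for gid, sys in enumerate(ens.systems):
            h = impulse_response(sys, times).values[:, 0, 0]
            for t, v in zip(times, h):
                rows.append(dict(eps=eps, kind="F2", genotype=gid, time=t, phenotype=v))
    return {"fig5_hybrid_phenotypes": pd.DataFrame(rows)}


def _fig6(seed: int = 0) -> dict[str, pd.DataFrame]:
    eps_grid = np.geomspace(1e-3, 0.5, 13)
    curve = fitness.breakdown_curve(eps_grid)
    return {"fig6_breakdown_curve": curve}


FIGURE_RECIPES = {"fig1": _fig1, "fig2": _fig2, "fig5": _fig5, "fig6": _fig6}


def run_figure(
    recipe: str, outdir: str | Path | None = None, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Run a figure recipe; write each table as ``<name>.tsv`` under outdir."""
    if recipe not in FIGURE_RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {sorted(FIGURE_RECIPES)}")
    tables = FIGURE_RECIPES[recipe](seed=seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return tables
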
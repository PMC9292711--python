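"""Neutral system drift and the speciation clock.

Two allopatric populations start as identical perfect oscillators and drift
independently along the neutral ridge (every visited network keeps the exact
optimal phenotype).  Their hybrids nevertheless decay: after t generations
the lineages differ by ~ sqrt(2 t VG/Ne) in the neutral coordinate, F2
hybrids fall off the ridge at first order, and mean squared F2 distance --
hence hybrid-fitness loss -- grows linearly in t.
"""

import numpy as np

import sysdrift as sd

cfg = sd.DriftConfig(VG=1e-3, Ne=1000, generations=320, replicates=40)
rng = np.random.default_rng(0)

# a single lineage: exactly neutral wandering
traj = sd.drift_walk(sd.oscillator(), cfg, np.random.default_rng(1))
final = traj.systems[-1]
print("population-mean A after", cfg.generations, "generations:\n",
      np.round(final.A, 4))
print("still phenotypically optimal:",
      sd.phenotypically_equivalent(sd.oscillator(), final, 1e-6))

df = sd.divergence_experiment(
    sd.oscillator(), cfg, [0, 40, 80, 160, 320], rng
)
m = df.assign(d2=df.f2_distance**2).groupby("t").agg(
    genetic=("genetic_distance", "mean"),
    f1=("f1_distance", "mean"),
    f2=("f2_distance", "mean"),
    f2_d2=("d2", "mean"),
    fitness=("f2_fitness", "mean"),
)
print("\n   t   genetic_d   mean F1 D   mean F2 D   mean F2 D^2  mean F2 fitness")
for t, r in m.iterrows():
    print(f"  {t:4d}  {r.genetic:9.4f}  {r.f1:10.6f}  {r.f2:10.5f}"
          f"  {r.f2_d2:11.6f}  {r.fitness:8.4f}")

x, y = m.index.values[1:].astype(float), m.f2_d2.values[1:]
b = (x @ y) / (x @ x)
print(f"\nF2 D^2 per generation: {b:.3e} (linear clock: D^2 ~ t VG/Ne)")
# Mean F2 D^2 doubles when t doubles while F1 D stays an order of magnitude
# smaller -- reproductive isolation accumulates on a linear timescale even
# though nothing about either parental phenotype ever changed.
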
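"""Haldane's rule from X-linked network coefficients.

Puts the second column of A (gene-2 regulation) on the X chromosome with
Drosophila-like dosage compensation (factor 2).  F1 daughters average the
parental networks; F1 sons carry a purely maternal X column next to averaged
autosomes -- a coefficient mixture otherwise only produced in F2s -- and so
sit further from the phenotypic optimum than their sisters.
"""

import numpy as np

import sysdrift as sd
from sysdrift import genetics as g

spec = sd.DistanceSpec(optimum=sd.oscillator(), horizon=sd.DEFAULT_HORIZON)
xmap = g.a_matrix_loci(2, x_columns=[1])  # column 2 of A is X-linked

print("  eps    D(F1 male)  D(F1 female)  ratio")
for eps in (0.05, 0.1, 0.2):
    father = g.homozygote(xmap, sd.oscillator(), sex="male")
    mother = g.homozygote(xmap, sd.oscillator_family(eps), sex="female")
    son = g.diploid_system(g.haldane_f1(father, mother, "male"), dosage=2.0)
    daughter = g.diploid_system(g.haldane_f1(father, mother, "female"))
    dm = sd.distance_to_optimum(son, spec)
    df = sd.distance_to_optimum(daughter, spec)
    print(f"  {eps:4.2f}  {dm:10.4f}  {df:12.4f}  {dm / df:6.2f}")

# The heterogametic sex is consistently worse off: with one X the son's
# X-linked coefficients are fixed maternal rather than averaged, exactly the
# homozygous-mixed state that drives F2 breakdown.
eps = 0.1
father = g.homozygote(xmap, sd.oscillator(), sex="male")
mother = g.homozygote(xmap, sd.oscillator_family(eps), sex="female")
son = g.diploid_system(g.haldane_f1(father, mother, "male"), dosage=2.0)
print("\nF1 son's A (averaged autosomal column | maternal X column):\n",
      np.round(son.A, 4))
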
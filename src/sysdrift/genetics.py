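"""Diploid genetics over network coefficients: meiosis, hybrids, Haldane's rule.

Each varying coefficient of (A, B, C) is encoded by a nonrecombining,
unlinked locus (the simplest genetic architecture; multi-coefficient loci
express cis linkage of, e.g., a promoter row).  A diploid carries two
haplotypes -- two full coefficient assignments -- and expresses the system
that *averages* them coefficient-wise: ((A' + A'')/2, (B' + B'')/2,
(C' + C'')/2).  Meiosis draws one allele per locus independently.

F1 hybrids of two homozygous populations are heterozygous everywhere and
express the parental midpoint; F2s (offspring of two F1s) segregate
independently per locus, so with L loci there are 3^L genotype classes --
each coefficient homozygous for either parent or intermediate -- which is
what drives hybrid breakdown between phenotypically equivalent parents.

Sex chromosomes: loci may be X-linked.  Males are hemizygous (single,
maternal X allele), and dosage compensation upregulates the single copy by
a factor ``dosage`` / 2 relative to its weight in a homozygote (dosage = 2,
the Drosophila-like default, makes a hemizygous male match an X-homozygous
female).  An F1 male's X-linked coefficients come entirely from its mother
while autosomal ones are parental averages -- a coefficient mixture
otherwise only seen in F2s, which is why the heterogametic sex breaks down
first (Haldane's rule).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .systems import LinearSystem

__all__ = [
    "Locus",
    "LocusMap",
    "Haplotype",
    "DiploidGenotype",
    "HybridEnsemble",
    "a_matrix_loci",
    "haplotype_from_system",
    "homozygote",
    "diploid_system",
    "gamete",
    "cross",
    "f1_hybrid",
    "f2_sample",
    "f2_enumerate",
    "haldane_f1",
    "genetic_distance",
]

Address = tuple[str, int, int]  # (matrix tag "A"|"B"|"C", row, col)

MENDELIAN = (0.25, 0.5, 0.25)  # P(hom-p1), P(het), P(hom-p2) per locus in an F2


@dataclass(frozen=True)
class Locus:
    """A nonrecombining genetic locus controlling one or more coefficients."""

    name: str
    addresses: tuple[Address, ...]
    chromosome: str = "autosome"  # "autosome" or "X"

    def __post_init__(self):
        if self.chromosome not in ("autosome", "X"):
            raise ValueError(f"chromosome must be 'autosome' or 'X', got {self.chromosome!r}")
        if not self.addresses:
            raise ValueError(f"locus {self.name!r} has no coefficient addresses")


@dataclass(frozen=True)
class LocusMap:
    """Genetic architecture: which coefficients vary and how they are packaged
    into unlinked loci, for systems of dimensions (n, m, l)."""

    loci: tuple[Locus, ...]
    n: int
    m: int
    l: int

    def __post_init__(self):
        if not self.loci:
            raise ValueError("a LocusMap needs at least one locus")
        bounds = {"A": (self.n, self.n), "B": (self.n, self.m), "C": (self.l, self.n)}
        seen: set[Address] = set()
        names: set[str] = set()
        for locus in self.loci:
            if locus.name in names:
                raise ValueError(f"duplicate locus name {locus.name!r}")
            names.add(locus.name)
            for tag, i, j in locus.addresses:
                if tag not in bounds:
                    raise ValueError(f"unknown matrix tag {tag!r} in locus {locus.name!r}")
                r, c = bounds[tag]
                if not (0 <= i < r and 0 <= j < c):
                    raise ValueError(
                        f"address {(tag, i, j)} of locus {locus.name!r} out of bounds for "
                        f"{tag} ({r}x{c})"
                    )
                if (tag, i, j) in seen:
                    raise ValueError(f"address {(tag, i, j)} assigned to more than one locus")
                seen.add((tag, i, j))

    @property
    def x_loci(self) -> tuple[Locus, ...]:
        return tuple(l for l in self.loci if l.chromosome == "X")

    def compatible_with(self, other: "LocusMap") -> bool:
        return self == other


def a_matrix_loci(
    n: int, m: int = 1, l: int = 1, x_columns: Sequence[int] = ()
) -> LocusMap:
    """One locus per entry of A (the default architecture); columns listed in
    ``x_columns`` are X-linked, the rest autosomal.  B and C are invariant."""
    x_columns = set(x_columns)
    loci = tuple(
        Locus(
            name=f"A{i + 1}{j + 1}",
            addresses=(("A", i, j),),
            chromosome="X" if j in x_columns else "autosome",
        )
        for i in range(n)
        for j in range(n)
    )
    return LocusMap(loci=loci, n=n, m=m, l=l)


@dataclass(frozen=True)
class Haplotype:
    """One allele (tuple of coefficient values) per locus; a value of None
    marks a hemizygously absent X allele."""

    alleles: Mapping[str, tuple[float, ...] | None]

    def __post_init__(self):
        object.__setattr__(self, "alleles", dict(self.alleles))

    def __getitem__(self, name: str):
        return self.alleles[name]


def haplotype_from_system(locus_map: LocusMap, sys: LinearSystem) -> Haplotype:
    """Read the allele values a system carries at every locus."""
    mats = {"A": sys.A, "B": sys.B, "C": sys.C}
    return Haplotype(
        {
            locus.name: tuple(float(mats[t][i, j]) for t, i, j in locus.addresses)
            for locus in locus_map.loci
        }
    )


@dataclass(frozen=True)
class DiploidGenotype:
    """Two haplotypes over a shared locus map, plus the invariant coefficients.

    ``base`` supplies every coefficient not governed by a locus.  ``hap1`` is
    maternal, ``hap2`` paternal; in males the paternal X alleles are absent
    (None).
    """

    locus_map: LocusMap
    base: LinearSystem
    hap1: Haplotype
    hap2: Haplotype
    sex: str = "unsexed"  # "female", "male" or "unsexed"

    def __post_init__(self):
        if self.sex not in ("female", "male", "unsexed"):
            raise ValueError(f"sex must be female/male/unsexed, got {self.sex!r}")
        for locus in self.locus_map.loci:
            a1, a2 = self.hap1[locus.name], self.hap2[locus.name]
            if a1 is None:
                raise ValueError(f"maternal allele missing at locus {locus.name!r}")
            if a2 is None and not (self.sex == "male" and locus.chromosome == "X"):
                raise ValueError(
                    f"paternal allele missing at non-hemizygous locus {locus.name!r}"
                )
            if self.sex == "male" and locus.chromosome == "X" and a2 is not None:
                raise ValueError(
                    f"male genotype carries a paternal X allele at {locus.name!r}"
                )

    @property
    def is_homozygous(self) -> bool:
        # a hemizygous X locus (single allele) counts as homozygous
        return all(
            self.hap2[l.name] is None or self.hap1[l.name] == self.hap2[l.name]
            for l in self.locus_map.loci
        )

    def system(self, dosage: float | None = 2.0) -> LinearSystem:
        return diploid_system(self, dosage=dosage)


def homozygote(
    locus_map: LocusMap, sys: LinearSystem, sex: str = "unsexed"
) -> DiploidGenotype:
    """The genotype of an individual from a population fixed for ``sys``."""
    hap = haplotype_from_system(locus_map, sys)
    hap2 = hap
    if sex == "male" and locus_map.x_loci:
        alleles = dict(hap.alleles)
        for locus in locus_map.x_loci:
            alleles[locus.name] = None
        hap2 = Haplotype(alleles)
    return DiploidGenotype(locus_map=locus_map, base=sys, hap1=hap, hap2=hap2, sex=sex)


def diploid_system(g: DiploidGenotype, dosage: float | None = 2.0) -> LinearSystem:
    """The expressed system: the coefficient-wise average of the two
    haplotypes, with hemizygous X alleles contributing (dosage/2) x allele."""
    A = g.base.A.copy()
    B = g.base.B.copy()
    C = g.base.C.copy()
    mats = {"A": A, "B": B, "C": C}
    for locus in g.locus_map.loci:
        a1, a2 = g.hap1[locus.name], g.hap2[locus.name]
        if a2 is None:  # hemizygous male X locus
            if dosage is None:
                raise ValueError(
                    "male genotype with X-linked loci requires a dosage-compensation "
                    "factor (dosage=2 reproduces a homozygote's contribution)"
                )
            vals = tuple((dosage / 2.0) * v for v in a1)
        else:
            vals = tuple((v1 + v2) / 2.0 for v1, v2 in zip(a1, a2))
        for (tag, i, j), v in zip(locus.addresses, vals):
            mats[tag][i, j] = v
    return LinearSystem(A, B, C)


def gamete(g: DiploidGenotype, rng: np.random.Generator) -> Haplotype:
    """One meiotic product: an independent fair draw between the two alleles
    at every locus (loci are unlinked and nonrecombining).  For a male, X
    loci carry only the maternal allele, which every X-bearing gamete
    transmits."""
    alleles = {}
    for locus in g.locus_map.loci:
        a1, a2 = g.hap1[locus.name], g.hap2[locus.name]
        if a2 is None:
            alleles[locus.name] = a1
        else:
            alleles[locus.name] = a1 if rng.random() < 0.5 else a2
    return Haplotype(alleles)


@dataclass(frozen=True)
class HybridEnsemble:
    """A weighted collection of offspring genotypes and their expressed systems."""

    genotypes: tuple[DiploidGenotype, ...]
    systems: tuple[LinearSystem, ...]
    weights: np.ndarray
    generation: str  # "F1" or "F2"
    states: tuple[tuple[int, ...], ...] | None = None  # per-locus 0/1/2 for enumerations
    uniform_weights: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.genotypes) != len(self.systems) or len(self.systems) != len(w):
            raise ValueError("genotypes, systems and weights must have equal length")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.genotypes)


def _check_same_map(p1: DiploidGenotype, p2: DiploidGenotype):
    if p1.locus_map != p2.locus_map:
        raise ValueError("parents carry incompatible locus maps")


def cross(
    p1: DiploidGenotype,
    p2: DiploidGenotype,
    n_offspring: int,
    rng: np.random.Generator,
    generation: str = "F1",
    dosage: float | None = 2.0,
) -> HybridEnsemble:
    """Sample offspring, one gamete from each parent, equal weights."""
    _check_same_map(p1, p2)
    genotypes = tuple(
        DiploidGenotype(
            locus_map=p1.locus_map,
            base=p1.base,
            hap1=gamete(p1, rng),
            hap2=gamete(p2, rng),
        )
        for _ in range(n_offspring)
    )
    systems = tuple(diploid_system(g, dosage=dosage) for g in genotypes)
    return HybridEnsemble(
        genotypes=genotypes,
        systems=systems,
        weights=np.full(n_offspring, 1.0 / n_offspring),
        generation=generation,
    )


def f1_hybrid(p1: DiploidGenotype, p2: DiploidGenotype) -> DiploidGenotype:
    """The (deterministic) F1 between two homozygous parents."""
    _check_same_map(p1, p2)
    if not (p1.is_homozygous and p2.is_homozygous):
        raise ValueError("deterministic F1 requires homozygous parents")
    return DiploidGenotype(
        locus_map=p1.locus_map, base=p1.base, hap1=p1.hap1, hap2=p2.hap1
    )


def f2_sample(
    p1: DiploidGenotype,
    p2: DiploidGenotype,
    n_offspring: int,
    rng: np.random.Generator,
    dosage: float | None = 2.0,
) -> HybridEnsemble:
    """Sampled F2s: offspring of two independently formed F1s of homozygous
    parents (with homozygous parents all F1s are the same heterozygote)."""
    f1 = f1_hybrid(p1, p2)
    ens = cross(f1, f1, n_offspring, rng, generation="F2", dosage=dosage)
    return ens


def f2_enumerate(
    p1: DiploidGenotype,
    p2: DiploidGenotype,
    cap: int = 3**12,
    dosage: float | None = 2.0,
) -> HybridEnsemble:
    """All 3^L F2 genotype classes between homozygous parents.

    Per locus an F2 is homozygous-p1 (state 0, prob 1/4), heterozygous
    (state 1, prob 1/2) or homozygous-p2 (state 2, prob 1/4); with the four
    A coefficients of the two-gene examples as loci this is the 3^4 = 81
    member enumeration.  Mendelian product weights are the default; uniform
    weights over classes are stored alongside.
    """
    _check_same_map(p1, p2)
    if not (p1.is_homozygous and p2.is_homozygous):
        raise ValueError("f2_enumerate requires homozygous parents")
    L = len(p1.locus_map.loci)
    total = 3**L
    if total > cap:
        raise ValueError(
            f"3^{L} = {total} genotype classes exceed cap={cap}; draw F2s with "
            "f2_sample instead"
        )
    loci = p1.locus_map.loci
    genotypes, states, weights = [], [], []
    for state in itertools.product((0, 1, 2), repeat=L):
        al1, al2, w = {}, {}, 1.0
        for locus, s in zip(loci, state):
            x, y = p1.hap1[locus.name], p2.hap1[locus.name]
            if s == 0:
                al1[locus.name], al2[locus.name] = x, x
            elif s == 1:
                al1[locus.name], al2[locus.name] = x, y
            else:
                al1[locus.name], al2[locus.name] = y, y
            w *= MENDELIAN[s]
        genotypes.append(
            DiploidGenotype(
                locus_map=p1.locus_map,
                base=p1.base,
                hap1=Haplotype(al1),
                hap2=Haplotype(al2),
            )
        )
        states.append(state)
        weights.append(w)
    systems = tuple(diploid_system(g, dosage=dosage) for g in genotypes)
    return HybridEnsemble(
        genotypes=tuple(genotypes),
        systems=systems,
        weights=np.asarray(weights),
        generation="F2",
        states=tuple(states),
        uniform_weights=np.full(total, 1.0 / total),
    )


def haldane_f1(
    father: DiploidGenotype,
    mother: DiploidGenotype,
    sex: str,
    dosage: float | None = 2.0,
    rng: np.random.Generator | None = None,
) -> DiploidGenotype:
    """An F1 offspring of sexed parents under X-linked inheritance.

    Daughters receive one X allele from each parent; sons receive their X
    alleles from the mother only (hemizygous) and express them with the
    dosage-compensation factor.  Autosomal loci segregate normally.  With
    homozygous parents no randomness is involved; heterozygous parents
    require ``rng``.
    """
    _check_same_map(father, mother)
    if sex not in ("male", "female"):
        raise ValueError("offspring sex must be 'male' or 'female'")
    if not father.locus_map.x_loci:
        raise ValueError("locus map has no X-linked loci; use cross() for autosomes")
    if rng is None:
        if not (father.is_homozygous and mother.is_homozygous):
            raise ValueError("heterozygous parents require an rng for meiosis")
        maternal = mother.hap1
        paternal = father.hap1
    else:
        maternal = gamete(mother, rng)
        paternal = gamete(father, rng)

    if sex == "female":
        hap2 = paternal
    else:
        alleles = dict(paternal.alleles)
        for locus in father.locus_map.x_loci:
            alleles[locus.name] = None
        hap2 = Haplotype(alleles)
    offspring = DiploidGenotype(
        locus_map=father.locus_map,
        base=father.base,
        hap1=maternal,
        hap2=hap2,
        sex=sex,
    )
    # fail early if the hemizygote cannot be expressed
    diploid_system(offspring, dosage=dosage)
    return offspring


def genetic_distance(
    s1: LinearSystem, s2: LinearSystem, include_bc: bool = False
) -> float:
    """Frobenius distance between regulatory matrices,
    (sum_ij (A1_ij - A2_ij)^2)^(1/2); optionally include B and C."""
    if (s1.n, s1.m, s1.l) != (s2.n, s2.m, s2.l):
        raise ValueError("systems must share dimensions")
    d2 = float(np.sum((s1.A - s2.A) ** 2))
    if include_bc:
        d2 += float(np.sum((s1.B - s2.B) ** 2)) + float(np.sum((s1.C - s2.C) ** 2))
    return float(np.sqrt(d2))
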
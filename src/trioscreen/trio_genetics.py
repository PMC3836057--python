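"""Trio genotypes and Mendelian conditional moments.

A trio is a father, mother and offspring genotyped at the same biallelic
marker, with genotypes coded additively as the count of the designated
(minor) allele, in {0, 1, 2}.  Conditioning on the parental genotype pair
S = (father, mother), the offspring genotype X has an exact Mendelian
distribution obtained by enumerating the four equally likely transmissions
(one allele from each parent's pair).  The conditional mean E(X|S) and
variance Var(X|S) of that distribution are the building blocks of the
family-based association tests in :mod:`trioscreen.assoc_core`: E(X|S) is
the "expected marker score" used by the conditional-mean (screening) model,
and X - E(X|S) is the within-family deviation the confirmatory test is
built on, which is what makes it robust to population stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrioGenotypeRecord",
    "TrioMarker",
    "MarkerPanel",
    "offspring_distribution",
    "conditional_mean",
    "conditional_variance",
    "mendel_check",
    "simulate_trio_genotypes",
]

_GENOTYPES = (0, 1, 2)

# allele pairs carried by each genotype (count of minor allele)
_ALLELE_PAIRS = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _check_genotype(g: int, who: str) -> int:
    if g not in _GENOTYPES:
        raise ValueError(f"{who} genotype must be 0, 1 or 2; got {g!r}")
    return int(g)


@dataclass(frozen=True)
class TrioGenotypeRecord:
    """Minor-allele counts of one trio at one marker."""

    father: int
    mother: int
    offspring: int

    def __post_init__(self) -> None:
        _check_genotype(self.father, "father")
        _check_genotype(self.mother, "mother")
        _check_genotype(self.offspring, "offspring")


def offspring_distribution(father: int, mother: int) -> np.ndarray:
    """Exact distribution of the offspring minor-allele count given parents.

    Enumerates the 4 equally likely transmissions (each parent passes one of
    its two alleles uniformly at random). Returns probabilities over
    offspring genotypes 0, 1, 2 summing to 1.
    """
    f = _ALLELE_PAIRS[_check_genotype(father, "father")]
    m = _ALLELE_PAIRS[_check_genotype(mother, "mother")]
    probs = np.zeros(3)
    for af in f:
        for am in m:
            probs[af + am] += 0.25
    return probs


def conditional_mean(father: int, mother: int) -> float:
    """E(X|S): expected offspring count given the parental pair.

    Equals (father + mother) / 2 for autosomal Mendelian transmission.
    """
    probs = offspring_distribution(father, mother)
    return float(probs @ np.arange(3))


def conditional_variance(father: int, mother: int) -> float:
    """Var(X|S); equals (number of heterozygous parents) / 4."""
    probs = offspring_distribution(father, mother)
    g = np.arange(3)
    mu = probs @ g
    return float(probs @ (g - mu) ** 2)


def mendel_check(record: TrioGenotypeRecord) -> bool:
    """True iff the offspring genotype is possible given the parents."""
    probs = offspring_distribution(record.father, record.mother)
    return bool(probs[record.offspring] > 0.0)


# ---------------------------------------------------------------------------
# panels


@dataclass(frozen=True)
class TrioMarker:
    """All trios at a single marker (1-D arrays over trios).

    Missing genotypes are encoded as -1; downstream tests drop incomplete
    trios per marker.
    """

    father: np.ndarray
    mother: np.ndarray
    offspring: np.ndarray
    maf: float = float("nan")
    name: str = "snp"

    @property
    def n_trios(self) -> int:
        return int(self.father.shape[0])

    @property
    def complete(self) -> np.ndarray:
        """Boolean mask of trios with all three genotypes observed."""
        return (self.father >= 0) & (self.mother >= 0) & (self.offspring >= 0)

    @property
    def exs(self) -> np.ndarray:
        """E(X|S) per trio: (father + mother) / 2."""
        return (self.father + self.mother) / 2.0

    @property
    def informative(self) -> np.ndarray:
        """Trios with at least one heterozygous parent (Var(X|S) > 0)."""
        return (self.father == 1) | (self.mother == 1)

    def records(self):
        for f, m, o in zip(self.father, self.mother, self.offspring):
            yield TrioGenotypeRecord(int(f), int(m), int(o))


@dataclass
class MarkerPanel:
    """Trio genotypes at one or more markers.

    Arrays are shaped ``(n_markers, n_trios)``; all markers cover the same
    trios in the same order. ``populations`` optionally labels each trio's
    subpopulation (used by the stratification simulations).
    """

    father: np.ndarray
    mother: np.ndarray
    offspring: np.ndarray
    maf: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    trio_ids: list[str] | None = None
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.father = np.atleast_2d(np.asarray(self.father))
        self.mother = np.atleast_2d(np.asarray(self.mother))
        self.offspring = np.atleast_2d(np.asarray(self.offspring))
        self.maf = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if not (self.father.shape == self.mother.shape == self.offspring.shape):
            raise ValueError("father/mother/offspring arrays must share a shape")
        if self.maf.shape[0] != self.father.shape[0]:
            raise ValueError("one minor-allele frequency per marker is required")
        if not self.marker_ids:
            self.marker_ids = [f"snp{j + 1}" for j in range(self.n_markers)]
        if self.trio_ids is None:
            self.trio_ids = [f"trio{i + 1}_o" for i in range(self.n_trios)]

    @property
    def n_markers(self) -> int:
        return int(self.father.shape[0])

    @property
    def n_trios(self) -> int:
        return int(self.father.shape[1])

    def marker(self, j: int) -> TrioMarker:
        return TrioMarker(
            father=self.father[j],
            mother=self.mother[j],
            offspring=self.offspring[j],
            maf=float(self.maf[j]),
            name=self.marker_ids[j],
        )

    def markers(self):
        return (self.marker(j) for j in range(self.n_markers))

    @classmethod
    def concat(cls, panels: list["MarkerPanel"]) -> "MarkerPanel":
        """Stack panels marker-wise (same trios in each panel)."""
        if not panels:
            raise ValueError("nothing to concatenate")
        n = panels[0].n_trios
        if any(p.n_trios != n for p in panels):
            raise ValueError("panels cover different trio sets")
        return cls(
            father=np.vstack([p.father for p in panels]),
            mother=np.vstack([p.mother for p in panels]),
            offspring=np.vstack([p.offspring for p in panels]),
            maf=np.concatenate([p.maf for p in panels]),
            marker_ids=[mid for p in panels for mid in p.marker_ids],
            trio_ids=panels[0].trio_ids,
            populations=panels[0].populations,
        )


# ---------------------------------------------------------------------------
# simulation


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _validate_maf(maf, n_trios: int) -> np.ndarray:
    p = np.broadcast_to(np.asarray(maf, dtype=float), (n_trios,))
    if not np.all(np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError(f"minor allele frequency must be finite and in [0, 1]")
    return p


def draw_trio_marker(rng: np.random.Generator, maf, n_trios: int) -> tuple:
    """One marker's trios: parents are HWE draws, offspring Mendelian.

    ``maf`` may be a scalar or a per-trio array (used for stratified
    populations). Returns (father, mother, offspring) int8 arrays.
    """
    p = _validate_maf(maf, n_trios)[:, None]
    father_alleles = rng.random((n_trios, 2)) < p
    mother_alleles = rng.random((n_trios, 2)) < p
    idx = np.arange(n_trios)
    transmit_f = father_alleles[idx, rng.integers(0, 2, n_trios)].astype(np.int8)
    transmit_m = mother_alleles[idx, rng.integers(0, 2, n_trios)].astype(np.int8)
    father = father_alleles.sum(axis=1).astype(np.int8)
    mother = mother_alleles.sum(axis=1).astype(np.int8)
    offspring = transmit_f + transmit_m
    return father, mother, offspring


def redraw_offspring(marker: TrioMarker, rng: np.random.Generator) -> TrioMarker:
    """Resample the offspring genotype given the parents (new transmission).

    The parental genotypes (and hence E(X|S) and the screening step) are
    untouched; only the within-family transmission is redrawn.
    """
    n = marker.n_trios
    fa = np.array([_ALLELE_PAIRS[g] for g in np.clip(marker.father, 0, 2)])
    ma = np.array([_ALLELE_PAIRS[g] for g in np.clip(marker.mother, 0, 2)])
    idx = np.arange(n)
    off = fa[idx, rng.integers(0, 2, n)] + ma[idx, rng.integers(0, 2, n)]
    return TrioMarker(
        father=marker.father,
        mother=marker.mother,
        offspring=off.astype(np.int8),
        maf=marker.maf,
        name=marker.name,
    )


def simulate_trio_genotypes(n_trios: int, maf: float, seed) -> MarkerPanel:
    """Simulate one marker's trios under HWE and random mating.

    Each parent is the sum of two independent Bernoulli(maf) allele draws;
    the offspring receives one uniformly chosen allele from each parent, so
    every record is Mendel-consistent by construction.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    rng = as_rng(seed)
    father, mother, offspring = draw_trio_marker(rng, maf, n_trios)
    return MarkerPanel(
        father=father[None, :],
        mother=mother[None, :],
        offspring=offspring[None, :],
        maf=np.array([float(maf)]),
    )
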
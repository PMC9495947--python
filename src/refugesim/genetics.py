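"""Biallelic, generational population genetics.

One autosomal locus with a susceptibility allele S and a resistance allele R.
Genotype bookkeeping, Hardy-Weinberg initialization frequencies, Mendelian
crosses and random mating within a pool are the only genetic machinery the
simulator needs: inheritance is monogenic, there is no mutation, and mating
happens only within a species.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Genotype(Enum):
    """Single-locus genotype; RS is unordered (no parental-origin distinction)."""

    SS = "SS"
    RS = "RS"
    RR = "RR"

    @property
    def index(self) -> int:
        return _GENOTYPE_ORDER.index(self)

    @property
    def n_R(self) -> int:
        """Number of R alleles carried (0, 1 or 2)."""
        return self.index


_GENOTYPE_ORDER = (Genotype.SS, Genotype.RS, Genotype.RR)
GENOTYPES = _GENOTYPE_ORDER


class Species(Enum):
    """The two competing noctuid species; no hybridization."""

    SF = "SF"  # Spodoptera frugiperda
    HA = "HA"  # Helicoverpa armigera

    @property
    def index(self) -> int:
        return 0 if self is Species.SF else 1


SPECIES = (Species.SF, Species.HA)


class EmptyPoolError(ValueError):
    """Raised when a statistic of an empty mating pool is requested."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype census of one species in one pool (quadrant or lattice)."""

    n_SS: int = 0
    n_RS: int = 0
    n_RR: int = 0

    def __post_init__(self) -> None:
        if min(self.n_SS, self.n_RS, self.n_RR) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_SS + self.n_RS + self.n_RR

    def as_tuple(self) -> tuple[int, int, int]:
        """Counts in (SS, RS, RR) order."""
        return (self.n_SS, self.n_RS, self.n_RR)

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_SS + other.n_SS,
            self.n_RS + other.n_RS,
            self.n_RR + other.n_RR,
        )


def hw_genotype_frequencies(p_R: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies (f_RR, f_RS, f_SS) at R frequency ``p_R``.

    Returns ``(p^2, 2 p (1 - p), (1 - p)^2)``.
    """
    if not 0.0 <= p_R <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p_R}")
    q = 1.0 - p_R
    return (p_R * p_R, 2.0 * p_R * q, q * q)


def cross(parent_a: Genotype, parent_b: Genotype) -> dict[Genotype, float]:
    """Mendelian offspring distribution of a single-locus cross.

    Each parent transmits R with probability ``n_R / 2``; the returned
    probabilities sum to 1.
    """
    ra = parent_a.n_R / 2.0
    rb = parent_b.n_R / 2.0
    p_rr = ra * rb
    p_ss = (1.0 - ra) * (1.0 - rb)
    return {
        Genotype.SS: p_ss,
        Genotype.RS: 1.0 - p_rr - p_ss,
        Genotype.RR: p_rr,
    }


def gamete_frequency(counts: GenotypeCounts) -> float:
    """R-allele frequency in the gamete pool produced by ``counts``."""
    if counts.total == 0:
        raise EmptyPoolError("cannot compute gamete frequency of an empty pool")
    return (2 * counts.n_RR + counts.n_RS) / (2 * counts.total)


def allele_frequency(counts: GenotypeCounts) -> float:
    """R-allele frequency of a census; undefined (raises) for an empty pool."""
    return gamete_frequency(counts)


def pool_mating_offspring(counts: GenotypeCounts) -> dict[Genotype, float]:
    """Offspring genotype distribution under random mating in one pool.

    Offspring are drawn i.i.d. from the Hardy-Weinberg distribution at the
    pool's gamete frequency (infinite-gamete approximation; no explicit pair
    formation, no sexes).
    """
    p = gamete_frequency(counts)  # raises EmptyPoolError on an empty pool
    f_rr, f_rs, f_ss = hw_genotype_frequencies(p)
    return {Genotype.SS: f_ss, Genotype.RS: f_rs, Genotype.RR: f_rr}
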
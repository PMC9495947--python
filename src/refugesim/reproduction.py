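"""Adult stage: quadrant pools, dispersal, mating and oviposition.

After the competition phase, every surviving larva becomes one adult in the
pool of the lattice quadrant containing its cell. Adults disperse between
the four quadrants of the 2x2 layout (50% remain, 25% to each of the two
orthogonal neighbor quadrants), then mate at random within their
post-dispersal quadrant pool.

Reproduction applies the fitness cost of resistance: a genotype's effective
reproductive capacity is ``(1 - cost) * Ro(species, crop)`` (default cost
0.25 for RR, 0 for RS and SS), and gametes are contributed in proportion to
effective capacity, so the cost acts exactly once, at reproduction.

Empty cells are colonized with probability W given by relative fitness: the
local per-species pressure is (occupied neighbors of the species) x (mean
effective Ro of the species' quadrant pool), normalized by the ceiling
8 x max effective Ro on the crop. One uniform draw per empty cell decides
occupancy, a fecundity-weighted lottery picks the colonizing species, and
the genotype comes from that species' quadrant mating distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    GENOTYPES,
    SPECIES,
    GenotypeCounts,
    Genotype,
    Species,
)
from .lattice import EMPTY, Lattice, NeighborhoodView, STRAIN_SPECIES
from .payoffs import CROPS

QUADRANTS = ("A", "B", "C", "D")  # A=top-left, B=top-right, C=bottom-left, D=bottom-right

#: Orthogonal neighbors in the 2x2 quadrant layout (no diagonal migration).
QUADRANT_NEIGHBORS = {"A": ("B", "C"), "B": ("A", "D"), "C": ("A", "D"), "D": ("B", "C")}


@dataclass(frozen=True)
class QuadrantScheme:
    """Adult permanence/migration rates between quadrants."""

    stay: float = 0.50
    migrate: float = 0.25

    def __post_init__(self) -> None:
        if abs(self.stay + 2 * self.migrate - 1.0) > 1e-12:
            raise ValueError(
                f"stay + 2 * migrate must equal 1, got {self.stay} + 2*{self.migrate}"
            )


_DEFAULT_RO = {
    Species.SF: {"corn": 1.0, "soybean": 0.8, "cotton": 0.6},
    Species.HA: {"cotton": 1.0, "soybean": 1.0, "corn": 0.5},
}


@dataclass(frozen=True)
class FitnessTable:
    """Reproductive capacity Ro per species and crop, with resistance costs.

    Ro is a relative offspring number (dimensionless). Defaults rank hosts
    qualitatively — corn is the primary host of S. frugiperda, H. armigera
    does relatively better on cotton and soybean than on corn — and carry
    provenance "spec default"; they are configurable.
    """

    ro: dict[Species, dict[str, float]] = field(
        default_factory=lambda: {sp: dict(t) for sp, t in _DEFAULT_RO.items()}
    )
    cost_RR: float = 0.25
    cost_RS: float = 0.0

    def __post_init__(self) -> None:
        for sp, table in self.ro.items():
            for crop, r in table.items():
                if r <= 0:
                    raise ValueError(f"Ro must be positive, got {r} for {sp} on {crop}")
        for cost in (self.cost_RR, self.cost_RS):
            if not 0.0 <= cost <= 1.0:
                raise ValueError(f"fitness cost must lie in [0, 1], got {cost}")

    def cost(self, genotype: Genotype) -> float:
        if genotype is Genotype.RR:
            return self.cost_RR
        if genotype is Genotype.RS:
            return self.cost_RS
        return 0.0

    def effective_ro(self, species: Species, genotype: Genotype, crop: str) -> float:
        return (1.0 - self.cost(genotype)) * self.ro[species][crop]

    def genotype_weights(self, species: Species, crop: str) -> np.ndarray:
        """Effective Ro per genotype, (SS, RS, RR) order."""
        return np.array([self.effective_ro(species, g, crop) for g in GENOTYPES])

    def max_effective_ro(self, crop: str) -> float:
        return max(
            self.effective_ro(sp, g, crop) for sp in SPECIES for g in GENOTYPES
        )


class AdultPools:
    """Adult census per quadrant, species and genotype: shape (4, 2, 3)."""

    def __init__(self, counts: np.ndarray | None = None):
        if counts is None:
            counts = np.zeros((4, 2, 3), dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (4, 2, 3):
            raise ValueError("pool counts must have shape (4 quadrants, 2 species, 3 genotypes)")
        if (counts < 0).any():
            raise ValueError("pool counts must be non-negative")
        self.counts = counts

    def get(self, quadrant: str, species: Species) -> GenotypeCounts:
        q = QUADRANTS.index(quadrant)
        n = self.counts[q, species.index]
        return GenotypeCounts(int(n[0]), int(n[1]), int(n[2]))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "AdultPools":
        return AdultPools(self.counts.copy())


def quadrant_index_map(height: int, width: int) -> np.ndarray:
    """(h, w) array of quadrant indices; half-open splits at h//2 and w//2."""
    rows = (np.arange(height) >= height // 2).astype(np.int8)
    cols = (np.arange(width) >= width // 2).astype(np.int8)
    return 2 * rows[:, None] + cols[None, :]


def survivors_to_pools(lattice: Lattice) -> AdultPools:
    """Every surviving larva becomes one adult in its cell's quadrant pool."""
    qmap = quadrant_index_map(lattice.height, lattice.width)
    counts = np.zeros((4, 2, 3), dtype=np.int64)
    occ = lattice.grid != EMPTY
    strains = lattice.grid[occ].astype(int)
    quads = qmap[occ].astype(int)
    np.add.at(counts, (quads, strains // 3, strains % 3), 1)
    return AdultPools(counts)


def disperse(
    pools: AdultPools,
    scheme: QuadrantScheme = QuadrantScheme(),
    rng: np.random.Generator | None = None,
) -> AdultPools:
    """Multinomial adult dispersal; total adults are conserved exactly."""
    if rng is None:
        rng = np.random.default_rng()
    probs = [scheme.stay, scheme.migrate, scheme.migrate]
    out = np.zeros_like(pools.counts)
    for qi, q in enumerate(QUADRANTS):
        n1, n2 = (QUADRANTS.index(n) for n in QUADRANT_NEIGHBORS[q])
        for si in range(2):
            for gi in range(3):
                n = int(pools.counts[qi, si, gi])
                if n == 0:
                    continue
                stay, m1, m2 = rng.multinomial(n, probs)
                out[qi, si, gi] += stay
                out[n1, si, gi] += m1
                out[n2, si, gi] += m2
    return AdultPools(out)


def weighted_offspring_distribution(
    counts: GenotypeCounts, weights: np.ndarray
) -> np.ndarray | None:
    """Offspring genotype distribution under fecundity-weighted random mating.

    Each adult contributes gametes in proportion to its effective Ro, so the
    gamete R frequency is ``(2 n_RR w_RR + n_RS w_RS) / (2 sum n_g w_g)``;
    offspring genotypes are Hardy-Weinberg at that frequency, returned in
    (SS, RS, RR) order. Returns None for an empty (or zero-weight) pool.
    """
    n = np.asarray(counts.as_tuple(), dtype=float)
    w = np.asarray(weights, dtype=float)
    wtot = float((n * w).sum())
    if counts.total == 0 or wtot == 0.0:
        return None
    p = (2.0 * n[2] * w[2] + n[1] * w[1]) / (2.0 * wtot)
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def reproductive_success(
    pool: GenotypeCounts, fitness: FitnessTable, species: Species, crop: str
) -> float:
    """Egg weight of one species' quadrant pool: sum of count x effective Ro."""
    n = np.asarray(pool.as_tuple(), dtype=float)
    return float((n * fitness.genotype_weights(species, crop)).sum())


def mean_effective_ro(
    pool: GenotypeCounts, fitness: FitnessTable, species: Species, crop: str
) -> float:
    """Per-capita effective reproductive capacity of a pool (0 if empty)."""
    if pool.total == 0:
        return 0.0
    return reproductive_success(pool, fitness, species, crop) / pool.total


def occupation_probability(
    view: NeighborhoodView | np.ndarray,
    quadrant_pools: dict[Species, GenotypeCounts],
    fitness: FitnessTable,
    crop: str,
) -> dict[Species, float]:
    """Per-species colonization probability W of one empty cell.

    ``view`` is the empty cell's neighbor census (a NeighborhoodView or a
    length-6 per-strain count vector). W is the species' local fecundity
    pressure — neighbor count times the quadrant pool's mean effective Ro —
    normalized by the ceiling 8 x max effective Ro on the crop.
    """
    counts = view.neighbor_counts if isinstance(view, NeighborhoodView) else np.asarray(view)
    ceiling = 8.0 * fitness.max_effective_ro(crop)
    out = {}
    for sp in SPECIES:
        n_neighbors = int(counts[sp.index * 3 : sp.index * 3 + 3].sum())
        mro = mean_effective_ro(quadrant_pools[sp], fitness, sp, crop)
        out[sp] = min(1.0, n_neighbors * mro / ceiling)
    return out


def reproduction_fields(shape: tuple[int, int], rng: np.random.Generator) -> dict:
    """Per-cell uniform fields consumed by one reproduction phase."""
    return {
        "u_occ": rng.random(shape),
        "u_species": rng.random(shape),
        "u_geno": rng.random(shape),
    }


def apply_reproduction(
    grid: np.ndarray,
    pools: AdultPools,
    fitness: FitnessTable,
    crop: str,
    fields: dict,
) -> np.ndarray:
    """Oviposition into empty cells as a pure function of uniform fields.

    Occupied cells are never overwritten. Each empty cell is tested once: one
    uniform draw against the summed species W decides occupancy, a second
    picks the species proportionally to its W, and a third draws the genotype
    from the species' quadrant mating distribution.
    """
    from .lattice import neighbor_strain_counts

    h, w = grid.shape
    qmap = quadrant_index_map(h, w)
    counts = neighbor_strain_counts(grid)
    sp_neighbors = np.stack([counts[0:3].sum(axis=0), counts[3:6].sum(axis=0)])

    ceiling = 8.0 * fitness.max_effective_ro(crop)
    # per (quadrant, species): mean effective Ro and offspring genotype CDF
    mro = np.zeros((4, 2))
    geno_cdf = np.zeros((4, 2, 3))
    for qi, q in enumerate(QUADRANTS):
        for sp in SPECIES:
            pool = pools.get(q, sp)
            mro[qi, sp.index] = mean_effective_ro(pool, fitness, sp, crop)
            dist = weighted_offspring_distribution(
                pool, fitness.genotype_weights(sp, crop)
            )
            if dist is not None:
                geno_cdf[qi, sp.index] = np.cumsum(dist)

    W = sp_neighbors * mro.T[:, qmap] / ceiling  # (2, h, w)
    W = np.minimum(W, 1.0)
    W_total = W.sum(axis=0)
    empty = grid == EMPTY
    colonize = empty & (W_total > 0) & (fields["u_occ"] <= np.minimum(W_total, 1.0))

    pick_sf = fields["u_species"] * W_total <= W[0]
    sp_idx = np.where(pick_sf, 0, 1)

    c1 = geno_cdf[qmap, sp_idx, 0]
    c2 = geno_cdf[qmap, sp_idx, 1]
    geno = (fields["u_geno"] > c1).astype(np.int8) + (fields["u_geno"] > c2).astype(np.int8)

    new = grid.copy()
    new[colonize] = (sp_idx * 3 + geno)[colonize].astype(np.int8)
    return new


def reproduction_phase(
    lattice: Lattice,
    pools: AdultPools,
    fitness: FitnessTable,
    crop: str,
    rng: np.random.Generator,
) -> Lattice:
    """One oviposition phase; advances the generation counter by 1."""
    fields = reproduction_fields(lattice.grid.shape, rng)
    new = apply_reproduction(lattice.grid, pools, fitness, crop, fields)
    return Lattice(new, lattice.generation + 1)
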
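"""The cellular automaton's competition layer.

A toroidal grid (default 100x100) in which every cell is either empty or
holds exactly one larva of one of the six strains. Each generation the
competition phase is applied synchronously: every occupied cell is evaluated
against the pre-update state of its Moore neighborhood (radius 1, eight
neighbors), may draw at most one encounter, and survives an encounter with
the payoff probability rho_s of its strain against the drawn opponent.

Encounter rule: the encounter probability of a focal larva is the number of
eligible competitors among its eight neighbors divided by eight (the focal
larva occupies the ninth cell of the 3x3 window and is never its own
competitor). Eligibility depends on the interaction mode: same-species
larvae only (``intra_only``) or any larva (``intra_plus_inter``). A uniform
draw on [0.00001, 1] decides whether the encounter happens; the opponent is
then sampled uniformly among the eligible neighbors.

The phase is implemented as a deterministic function of per-cell uniform
random fields drawn up front, which makes the update manifestly synchronous:
no cell's outcome can depend on any visit order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import GENOTYPES, SPECIES, GenotypeCounts, Genotype, Species, hw_genotype_frequencies
from .payoffs import INTRA_ONLY, INTRA_PLUS_INTER, MissingPayoffError, PayoffMatrix, StrainKey, STRAINS

EMPTY = -1

#: Moore-neighborhood offsets of radius 1 (the 8 cells around the focal cell).
MOORE_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)

#: Species index (0=SF, 1=HA) of each dense strain index.
STRAIN_SPECIES = np.array([0, 0, 0, 1, 1, 1])

ENCOUNTER_U_LOW = 0.00001


@dataclass
class Lattice:
    """Periodic grid of larvae; ``grid[r, c]`` is a strain index or EMPTY."""

    grid: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2:
            raise ValueError("lattice grid must be 2-dimensional")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def occupied_count(self) -> int:
        return int((self.grid != EMPTY).sum())

    def strain_counts(self) -> np.ndarray:
        """Census over the six strains, dense-index order."""
        occupied = self.grid[self.grid != EMPTY]
        return np.bincount(occupied, minlength=6)[:6]

    def genotype_counts(self, species: Species) -> GenotypeCounts:
        c = self.strain_counts()
        base = species.index * 3
        return GenotypeCounts(int(c[base]), int(c[base + 1]), int(c[base + 2]))

    def copy(self) -> "Lattice":
        return Lattice(self.grid.copy(), self.generation)

    def to_frame(self):
        """Occupied cells as a tidy table (generation, row, col, species, genotype)."""
        import pandas as pd

        rows, cols = np.nonzero(self.grid != EMPTY)
        strains = self.grid[rows, cols]
        return pd.DataFrame(
            {
                "generation": self.generation,
                "row": rows,
                "col": cols,
                "species": [STRAINS[s].species.value for s in strains],
                "genotype": [STRAINS[s].genotype.value for s in strains],
            }
        )


@dataclass
class NeighborhoodView:
    """The 3x3 window around an occupied focal cell.

    ``neighbor_counts[s]`` is the number of the 8 surrounding cells holding a
    larva of dense strain index ``s``; the focal larva itself is excluded.
    """

    focal: StrainKey
    neighbor_counts: np.ndarray = field(default_factory=lambda: np.zeros(6, dtype=int))

    def eligible_counts(self, mode: str) -> np.ndarray:
        counts = np.asarray(self.neighbor_counts, dtype=int)
        if mode == INTRA_ONLY:
            counts = counts * (STRAIN_SPECIES == self.focal.species.index)
        elif mode != INTRA_PLUS_INTER:
            raise ValueError(f"unknown interaction mode {mode!r}")
        return counts


def neighborhood_view(lattice: Lattice, row: int, col: int) -> NeighborhoodView:
    s = lattice.grid[row, col]
    if s == EMPTY:
        raise ValueError(f"cell ({row}, {col}) is empty; no focal larva")
    counts = np.zeros(6, dtype=int)
    h, w = lattice.grid.shape
    for dr, dc in MOORE_OFFSETS:
        v = lattice.grid[(row + dr) % h, (col + dc) % w]
        if v != EMPTY:
            counts[v] += 1
    return NeighborhoodView(STRAINS[s], counts)


def encounter_probability(view: NeighborhoodView, mode: str) -> float:
    """Fraction of the window occupied by eligible competitors, out of 8."""
    return float(view.eligible_counts(mode).sum()) / 8.0


def draw_encounter(
    view: NeighborhoodView, mode: str, rng: np.random.Generator
) -> StrainKey | None:
    """At most one encounter: uniform compliance draw, then a uniform opponent."""
    eligible = view.eligible_counts(mode)
    total = int(eligible.sum())
    u = ENCOUNTER_U_LOW + (1.0 - ENCOUNTER_U_LOW) * rng.random()
    if total == 0 or u > total / 8.0:
        return None
    idx = rng.choice(6, p=eligible / total)
    return STRAINS[idx]


def resolve_survival(
    focal: StrainKey,
    opponent: StrainKey,
    payoffs: PayoffMatrix,
    rng: np.random.Generator,
) -> bool:
    """Bernoulli survival of the focal larva at its payoff against the opponent."""
    rho = payoffs.lookup(focal, opponent)
    return bool(rng.random() <= rho)


# ----------------------------------------------------------- vectorized phase


def neighbor_strain_counts(grid: np.ndarray) -> np.ndarray:
    """(6, h, w) array: per cell, neighbors of each strain on the torus."""
    onehot = np.stack([(grid == s) for s in range(6)]).astype(np.int16)
    counts = np.zeros_like(onehot)
    for dr, dc in MOORE_OFFSETS:
        counts += np.roll(onehot, shift=(dr, dc), axis=(1, 2))
    return counts


def competition_fields(shape: tuple[int, int], rng: np.random.Generator) -> dict:
    """Per-cell uniform fields consumed by one competition phase."""
    return {
        "u_enc": ENCOUNTER_U_LOW + (1.0 - ENCOUNTER_U_LOW) * rng.random(shape),
        "u_opp": rng.random(shape),
        "u_surv": rng.random(shape),
    }


def apply_competition(
    grid: np.ndarray, payoff_array: np.ndarray, mode: str, fields: dict
) -> np.ndarray:
    """Synchronous competition update as a pure function of uniform fields.

    ``payoff_array`` is the 6x6 dense payoff lookup (NaN where the matrix has
    no entry). Cells that draw no encounter are unaffected; larvae that lose
    their encounter leave their cell empty.
    """
    occupied = grid != EMPTY
    counts = neighbor_strain_counts(grid)
    focal = np.where(occupied, grid, 0).astype(np.intp)
    if mode == INTRA_ONLY:
        focal_sp = STRAIN_SPECIES[focal]
        eligible = counts * (STRAIN_SPECIES[:, None, None] == focal_sp[None, :, :])
    elif mode == INTRA_PLUS_INTER:
        eligible = counts
    else:
        raise ValueError(f"unknown interaction mode {mode!r}")
    total = eligible.sum(axis=0)
    encounter = occupied & (fields["u_enc"] <= total / 8.0) & (total > 0)

    # uniform opponent among eligible neighbors: invert the per-cell CDF
    cum = np.cumsum(eligible, axis=0)
    r = fields["u_opp"] * total
    opponent = (r[None, :, :] < cum).argmax(axis=0)

    rho = payoff_array[focal, opponent]
    if np.isnan(rho[encounter]).any():
        bad = encounter & np.isnan(rho)
        rr, cc = np.argwhere(bad)[0]
        raise MissingPayoffError(
            f"missing payoff for focal {STRAINS[int(grid[rr, cc])]} vs "
            f"opponent {STRAINS[int(opponent[rr, cc])]}"
        )
    dead = encounter & (fields["u_surv"] > rho)
    new = grid.copy()
    new[dead] = EMPTY
    return new


def competition_phase(
    lattice: Lattice,
    payoffs: PayoffMatrix,
    mode: str,
    rng: np.random.Generator,
) -> Lattice:
    """One synchronous competition phase over the whole lattice."""
    fields = competition_fields(lattice.grid.shape, rng)
    new = apply_competition(lattice.grid, payoffs.as_array(), mode, fields)
    return Lattice(new, lattice.generation)


# ------------------------------------------------------------- initialization


def init_lattice(
    width: int = 100,
    height: int = 100,
    occupancy: float = 0.5,
    species_mix: float = 0.5,
    p_R: float | dict[Species, float] = 0.1,
    rng: np.random.Generator | None = None,
) -> Lattice:
    """Independent per-cell initialization at generation 0.

    Each cell is occupied with probability ``occupancy``; an occupied cell is
    S. frugiperda with probability ``species_mix`` (else H. armigera), and its
    genotype is drawn from the Hardy-Weinberg distribution at the species'
    initial resistance-allele frequency ``p_R``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"occupancy fraction must lie in [0, 1], got {occupancy}")
    if not 0.0 <= species_mix <= 1.0:
        raise ValueError(f"species mix must lie in [0, 1], got {species_mix}")
    if isinstance(p_R, dict):
        p_by_species = {sp: float(p_R[sp]) for sp in SPECIES}
    else:
        p_by_species = {sp: float(p_R) for sp in SPECIES}

    grid = np.full((height, width), EMPTY, dtype=np.int8)
    occ = rng.random((height, width)) < occupancy
    is_sf = rng.random((height, width)) < species_mix
    u_geno = rng.random((height, width))
    for sp in SPECIES:
        f_rr, f_rs, f_ss = hw_genotype_frequencies(p_by_species[sp])
        # genotype CDF in (SS, RS, RR) order
        c1, c2 = f_ss, f_ss + f_rs
        mask = occ & (is_sf if sp is Species.SF else ~is_sf)
        geno = (u_geno > c1).astype(np.int8) + (u_geno > c2).astype(np.int8)
        grid[mask] = sp.index * 3 + geno[mask]
    return Lattice(grid, generation=0)
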
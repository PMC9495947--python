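"""Adult pools, quadrant dispersal, fecundity-weighted mating, oviposition."""

import numpy as np
import pytest

from refugesim.genetics import GenotypeCounts, Genotype, Species
from refugesim.lattice import EMPTY, Lattice, NeighborhoodView, init_lattice
from refugesim.payoffs import INTRA_ONLY, INTRA_PLUS_INTER, StrainKey
from refugesim.reproduction import (
    QUADRANT_NEIGHBORS,
    QUADRANTS,
    AdultPools,
    FitnessTable,
    QuadrantScheme,
    apply_reproduction,
    disperse,
    mean_effective_ro,
    occupation_probability,
    quadrant_index_map,
    reproduction_fields,
    reproduction_phase,
    reproductive_success,
    survivors_to_pools,
    weighted_offspring_distribution,
)

from conftest import uniform_matrix


class TestQuadrantScheme:
    def test_rates_sum_to_one(self):
        s = QuadrantScheme()
        assert s.stay + 2 * s.migrate == 1.0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            QuadrantScheme(stay=0.5, migrate=0.3)

    def test_each_quadrant_has_two_orthogonal_neighbors(self):
        for q, nbrs in QUADRANT_NEIGHBORS.items():
            assert len(nbrs) == 2 and q not in nbrs
        # symmetric adjacency
        for q, nbrs in QUADRANT_NEIGHBORS.items():
            for n in nbrs:
                assert q in QUADRANT_NEIGHBORS[n]


class TestSurvivorsToPools:
    def test_empty_lattice_gives_empty_pools(self):
        lat = Lattice(np.full((10, 10), EMPTY, dtype=np.int8))
        assert survivors_to_pools(lat).total == 0

    def test_single_quadrant_occupancy(self):
        grid = np.full((10, 10), EMPTY, dtype=np.int8)
        grid[0:5, 0:5] = 0  # Sf-SS in quadrant A only
        pools = survivors_to_pools(Lattice(grid))
        assert pools.get("A", Species.SF).total == 25
        for q in ("B", "C", "D"):
            assert pools.get(q, Species.SF).total == 0
            assert pools.get(q, Species.HA).total == 0

    def test_pool_totals_equal_occupied_count(self, rng):
        lat = init_lattice(width=30, height=30, rng=rng)
        pools = survivors_to_pools(lat)
        assert pools.total == lat.occupied_count


class TestDisperse:
    def test_conserves_adults_exactly_every_replicate(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 200, size=(4, 2, 3))
            pools = AdultPools(counts)
            out = disperse(pools, rng=rng)
            assert out.total == pools.total
            # species x genotype classes are individually conserved
            assert np.array_equal(out.counts.sum(axis=0), counts.sum(axis=0))

    def test_expected_split_50_25_25(self, rng):
        counts = np.zeros((4, 2, 3), dtype=int)
        counts[0, 0, 0] = 1000  # 1000 Sf-SS adults in A
        out = disperse(AdultPools(counts), rng=rng)
        stayed = out.counts[0, 0, 0]
        sd = np.sqrt(1000 * 0.5 * 0.5)
        assert abs(stayed - 500) < 3 * sd
        for nbr in QUADRANT_NEIGHBORS["A"]:
            moved = out.counts[QUADRANTS.index(nbr), 0, 0]
            assert abs(moved - 250) < 3 * np.sqrt(1000 * 0.25 * 0.75)
        assert out.counts[QUADRANTS.index("D"), 0, 0] == 0  # no diagonal moves

    def test_no_adults_no_movement(self, rng):
        out = disperse(AdultPools(), rng=rng)
        assert out.total == 0

    def test_symmetric_pools_stay_balanced_in_expectation(self, rng):
        counts = np.full((4, 2, 3), 400, dtype=int)
        out = disperse(AdultPools(counts), rng=rng)
        # stationarity of the uniform distribution: each quadrant keeps ~400
        for q in range(4):
            n = out.counts[q, 0, 0]
            assert abs(n - 400) < 4 * np.sqrt(400)


class TestFitnessTable:
    def test_rr_pays_quarter_cost_by_default(self):
        f = FitnessTable()
        for sp in Species:
            for crop in ("cotton", "corn", "soybean"):
                ratio = f.effective_ro(sp, Genotype.RR, crop) / f.effective_ro(
                    sp, Genotype.SS, crop
                )
                assert ratio == pytest.approx(0.75)
                assert f.effective_ro(sp, Genotype.RS, crop) == f.effective_ro(
                    sp, Genotype.SS, crop
                )

    def test_invalid_cost_rejected(self):
        with pytest.raises(ValueError):
            FitnessTable(cost_RR=1.5)


class TestReproductiveSuccess:
    def test_monomorphic_ss_pool(self):
        f = FitnessTable()
        r = f.ro[Species.SF]["corn"]
        assert reproductive_success(
            GenotypeCounts(40, 0, 0), f, Species.SF, "corn"
        ) == pytest.approx(40 * r)

    def test_rr_pool_discounted_by_cost(self):
        f = FitnessTable(cost_RR=0.25)
        r = f.ro[Species.HA]["cotton"]
        assert reproductive_success(
            GenotypeCounts(0, 0, 40), f, Species.HA, "cotton"
        ) == pytest.approx(0.75 * 40 * r)

    def test_fecundity_weighted_gamete_frequency_oracle(self):
        """Equal SS and RR counts with cost 0.25: enumerate each adult's gamete
        contribution directly; p_R = 0.75 / 1.75."""
        counts = GenotypeCounts(30, 0, 30)
        f = FitnessTable(cost_RR=0.25)
        w = f.genotype_weights(Species.SF, "soybean")
        # direct enumeration: each SS adult contributes w_SS S-gametes,
        # each RR adult w_RR R-gametes
        r_gametes = 30 * w[2]
        total = 30 * w[0] + 30 * w[2]
        oracle_p = r_gametes / total
        assert oracle_p == pytest.approx(0.75 / 1.75)
        dist = weighted_offspring_distribution(counts, w)
        p = dist[1] / 2 + dist[2]  # expected R allele frequency of offspring
        assert p == pytest.approx(oracle_p)

    def test_empty_pool_produces_no_distribution(self):
        f = FitnessTable()
        w = f.genotype_weights(Species.SF, "corn")
        assert weighted_offspring_distribution(GenotypeCounts(), w) is None


class TestOccupationProbability:
    def setup_method(self):
        self.fitness = FitnessTable()

    def test_no_neighbors_and_empty_pool_gives_zero(self):
        pools = {sp: GenotypeCounts() for sp in Species}
        view = NeighborhoodView(StrainKey(Species.SF, Genotype.SS), np.zeros(6, dtype=int))
        W = occupation_probability(view.neighbor_counts, pools, self.fitness, "corn")
        assert W[Species.SF] == 0.0 and W[Species.HA] == 0.0

    def test_full_window_of_max_fitness_species_reaches_ceiling(self):
        # Sf on corn has the maximum effective Ro; an SS-only pool has no cost
        pools = {
            Species.SF: GenotypeCounts(50, 0, 0),
            Species.HA: GenotypeCounts(),
        }
        counts = np.array([8, 0, 0, 0, 0, 0])
        W = occupation_probability(counts, pools, self.fitness, "corn")
        assert W[Species.SF] == pytest.approx(1.0)

    def test_equal_pressure_species_get_equal_w(self):
        fitness = FitnessTable(
            ro={Species.SF: {"corn": 1.0}, Species.HA: {"corn": 1.0}}
        )
        pools = {
            Species.SF: GenotypeCounts(10, 0, 0),
            Species.HA: GenotypeCounts(10, 0, 0),
        }
        counts = np.array([2, 0, 0, 2, 0, 0])
        W = occupation_probability(counts, pools, fitness, "corn")
        assert W[Species.SF] == pytest.approx(W[Species.HA])


class TestReproductionPhase:
    def test_no_adults_leaves_lattice_unchanged_but_advances_generation(self, rng):
        lat = Lattice(np.full((10, 10), EMPTY, dtype=np.int8), generation=3)
        out = reproduction_phase(lat, AdultPools(), FitnessTable(), "corn", rng)
        assert out.generation == 4
        assert out.occupied_count == 0

    def test_never_overwrites_occupied_cells(self, rng):
        lat = init_lattice(width=20, height=20, occupancy=0.5, rng=rng)
        pools = survivors_to_pools(lat)
        out = reproduction_phase(lat, pools, FitnessTable(), "cotton", rng)
        occupied_before = lat.grid != EMPTY
        assert np.array_equal(out.grid[occupied_before], lat.grid[occupied_before])

    def test_monomorphic_ss_population_stays_ss(self, rng):
        grid = np.full((16, 16), EMPTY, dtype=np.int8)
        grid[rng.random((16, 16)) < 0.5] = 0  # Sf-SS only
        lat = Lattice(grid)
        pools = survivors_to_pools(lat)
        out = reproduction_phase(lat, pools, FitnessTable(), "corn", rng)
        present = set(np.unique(out.grid)) - {EMPTY}
        assert present <= {0}

    def test_colonizer_genotypes_come_from_quadrant_distribution(self, rng):
        # quadrant A pool is pure RR: every new colonist in A must be RR
        grid = np.full((20, 20), EMPTY, dtype=np.int8)
        grid[0:10, 0:10][rng.random((10, 10)) < 0.6] = 2  # Sf-RR in A
        lat = Lattice(grid)
        pools = survivors_to_pools(lat)
        # suppress dispersal so pools B-D stay empty
        out = reproduction_phase(lat, pools, FitnessTable(), "corn", rng)
        new = (out.grid != EMPTY) & (lat.grid == EMPTY)
        assert new.sum() > 0
        assert set(np.unique(out.grid[new])) <= {2}


def _neutral_generation(lat, payoffs, fitness, crop, seed_tuple):
    """One full generation with explicit seeds (competition + reproduction)."""
    from refugesim.lattice import competition_phase
    from refugesim.rng import substream

    master, rep, gen = seed_tuple
    lat = competition_phase(
        lat, payoffs, INTRA_PLUS_INTER, substream(master, rep, "comp", gen)
    )
    pools = survivors_to_pools(lat)
    pools = disperse(pools, rng=substream(master, rep, "disp", gen))
    return reproduction_phase(lat, pools, fitness, crop, substream(master, rep, "rep", gen))


def test_neutral_generation_step_is_martingale():
    """With zero fitness cost and equal payoffs the allele frequency drifts
    without direction: the 50-replicate mean trajectory stays within 3 SE of
    its initial value."""
    from refugesim.genetics import allele_frequency

    payoffs = uniform_matrix(0.5)
    fitness = FitnessTable(cost_RR=0.0)
    finals = []
    for rep in range(50):
        lat = init_lattice(
            width=40, height=40, p_R=0.1, rng=np.random.default_rng(900 + rep)
        )
        for gen in range(40):
            lat = _neutral_generation(lat, payoffs, fitness, "corn", (77, rep, gen))
        counts = lat.genotype_counts(Species.SF) + lat.genotype_counts(Species.HA)
        finals.append(allele_frequency(counts))
    mean = np.mean(finals)
    se = np.std(finals, ddof=1) / np.sqrt(len(finals))
    assert abs(mean - 0.1) < 3 * se


def test_higher_fitness_cost_lowers_equilibrium_r_frequency():
    """Single-species neutral-payoff runs: expected R frequency after 60
    generations decreases strictly over the cost grid {0, 0.25, 0.5}."""
    from refugesim.genetics import allele_frequency

    payoffs = uniform_matrix(0.5, mode=INTRA_ONLY)
    means = []
    for cost in (0.0, 0.25, 0.5):
        fitness = FitnessTable(cost_RR=cost)
        finals = []
        for rep in range(30):
            lat = init_lattice(
                width=24, height=24, species_mix=1.0, p_R=0.3,
                rng=np.random.default_rng(3000 + rep),
            )
            for gen in range(60):
                from refugesim.lattice import competition_phase
                from refugesim.rng import substream

                lat = competition_phase(
                    lat, payoffs, INTRA_ONLY, substream(5, rep, f"c{cost}", gen)
                )
                pools = survivors_to_pools(lat)
                pools = disperse(pools, rng=substream(5, rep, f"d{cost}", gen))
                lat = reproduction_phase(
                    lat, pools, fitness, "corn", substream(5, rep, f"r{cost}", gen)
                )
            counts = lat.genotype_counts(Species.SF)
            finals.append(0.0 if counts.total == 0 else allele_frequency(counts))
        means.append(np.mean(finals))
    assert means[0] > means[1] > means[2]
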
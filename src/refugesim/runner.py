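"""Scenario orchestration: the full experiment grid and its outputs.

A scenario is one (crop, interaction mode, heterozygote behavior) cell of
the study grid, run as independent replicates (default 50) of a fixed
number of generations (default 100) on a 100x100 lattice. Each generation
applies, in order: larval competition, survivor-to-adult transition into
quadrant pools, quadrant dispersal, and reproduction (mating + oviposition).

The tracked output is the resistance-allele frequency trajectory per
species — the relative frequency of R in [0, 1] among the larvae occupying
the lattice — together with genotype counts, occupancy and extinction
flags, recorded at generation 0 (the initial state, before any update) and
after every generation step.

Interaction mode ``intra_only`` is run as two independent single-species
simulations, one per species (or one, if the scenario restricts to a single
species); ``intra_plus_inter`` runs both species on one shared lattice.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genetics import GenotypeCounts, Genotype, Species, allele_frequency
from .lattice import Lattice, competition_phase, init_lattice
from .payoffs import (
    CROPS,
    INTRA_ONLY,
    INTRA_PLUS_INTER,
    MODES,
    HeterozygoteBehavior,
    PayoffMatrix,
    StrainKey,
    expand_heterozygotes,
    load_fixture,
    with_overrides,
)
from .reproduction import (
    AdultPools,
    FitnessTable,
    QuadrantScheme,
    disperse,
    reproduction_phase,
    survivors_to_pools,
)
from .rng import RngStream

TRAJECTORY_COLUMNS = [
    "scenario_id",
    "replicate",
    "generation",
    "species",
    "n_SS",
    "n_RS",
    "n_RR",
    "p_R",
    "occupied",
    "extinct",
]

TERMINAL_LABELS = ("fixation_R", "fixation_S", "polymorphic", "extinct")


@dataclass
class SimulationConfig:
    """One scenario's settings; defaults reproduce the study conditions."""

    crop: str
    mode: str
    heterozygote_behavior: HeterozygoteBehavior
    width: int = 100
    height: int = 100
    generations: int = 100
    replicates: int = 50
    initial_p_R: float = 0.1
    occupancy: float = 0.5
    species_mix: float = 0.5  # fraction of occupied cells that are S. frugiperda
    seed: int = 0
    species: Species | None = None  # restrict an intra_only run to one species
    fitness: FitnessTable = field(default_factory=FitnessTable)
    quadrant_scheme: QuadrantScheme = field(default_factory=QuadrantScheme)
    payoff_overrides: dict[tuple[StrainKey, StrainKey], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise ValueError(f"unknown crop {self.crop!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if isinstance(self.heterozygote_behavior, str):
            self.heterozygote_behavior = HeterozygoteBehavior(self.heterozygote_behavior)
        if isinstance(self.species, str):
            self.species = Species(self.species)
        if self.species is not None and self.mode != INTRA_ONLY:
            raise ValueError("a single-species restriction requires mode intra_only")
        for name in ("width", "height", "generations", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("initial_p_R", "occupancy", "species_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def scenario_id(self) -> str:
        sid = f"{self.crop}_{self.mode}_{self.heterozygote_behavior.value}"
        if self.species is not None:
            sid += f"_{self.species.value}"
        return sid

    def build_payoffs(self) -> PayoffMatrix:
        """Fixture -> optional overrides -> heterozygote expansion."""
        matrix = load_fixture(self.crop, self.mode)
        if self.payoff_overrides:
            matrix = with_overrides(matrix, self.payoff_overrides)
        return expand_heterozygotes(matrix, self.heterozygote_behavior)

    def to_dict(self) -> dict:
        d = {
            "crop": self.crop,
            "mode": self.mode,
            "heterozygote_behavior": self.heterozygote_behavior.value,
            "width": self.width,
            "height": self.height,
            "generations": self.generations,
            "replicates": self.replicates,
            "initial_p_R": self.initial_p_R,
            "occupancy": self.occupancy,
            "species_mix": self.species_mix,
            "seed": self.seed,
            "species": None if self.species is None else self.species.value,
            "cost_RR": self.fitness.cost_RR,
            "cost_RS": self.fitness.cost_RS,
            "ro": {sp.value: dict(t) for sp, t in self.fitness.ro.items()},
            "stay_rate": self.quadrant_scheme.stay,
            "migration_rate": self.quadrant_scheme.migrate,
        }
        if self.payoff_overrides:
            d["payoff_overrides"] = [
                {
                    "focal_species": f.species.value,
                    "focal_genotype": f.genotype.value,
                    "opponent_species": o.species.value,
                    "opponent_genotype": o.genotype.value,
                    "rho_s": rho,
                }
                for (f, o), rho in self.payoff_overrides.items()
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        ro_raw = d.pop("ro", None)
        fitness_kwargs = {}
        if ro_raw is not None:
            fitness_kwargs["ro"] = {
                Species(sp): {c: float(r) for c, r in t.items()} for sp, t in ro_raw.items()
            }
        if "cost_RR" in d:
            fitness_kwargs["cost_RR"] = float(d.pop("cost_RR"))
        if "cost_RS" in d:
            fitness_kwargs["cost_RS"] = float(d.pop("cost_RS"))
        scheme = QuadrantScheme(
            stay=float(d.pop("stay_rate", 0.50)),
            migrate=float(d.pop("migration_rate", 0.25)),
        )
        overrides = {}
        for ov in d.pop("payoff_overrides", []) or []:
            focal = StrainKey(Species(ov["focal_species"]), Genotype(ov["focal_genotype"]))
            opp = StrainKey(Species(ov["opponent_species"]), Genotype(ov["opponent_genotype"]))
            overrides[(focal, opp)] = float(ov["rho_s"])
        return cls(
            fitness=FitnessTable(**fitness_kwargs),
            quadrant_scheme=scheme,
            payoff_overrides=overrides,
            **{k: v for k, v in d.items() if v is not None or k == "species"},
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def step(
    lattice: Lattice,
    payoffs: PayoffMatrix,
    config: SimulationConfig,
    rng: RngStream,
    label: str = "",
) -> tuple[Lattice, AdultPools]:
    """One full generation: competition -> adults -> dispersal -> reproduction."""
    gen = lattice.generation
    lattice = competition_phase(
        lattice, payoffs, config.mode, rng.generator(label + "competition", gen)
    )
    pools = survivors_to_pools(lattice)
    pools = disperse(pools, config.quadrant_scheme, rng.generator(label + "disperse", gen))
    lattice = reproduction_phase(
        lattice, pools, config.fitness, config.crop,
        rng.generator(label + "reproduction", gen),
    )
    return lattice, pools


def _record(
    rows: list,
    config: SimulationConfig,
    replicate: int,
    generation: int,
    lattice: Lattice | None,
    species_list: list[Species],
    extinct_at: dict[Species, int | None],
) -> None:
    occupied = 0 if lattice is None else lattice.occupied_count
    for sp in species_list:
        if lattice is None:
            counts = GenotypeCounts()
        else:
            counts = lattice.genotype_counts(sp)
        if counts.total == 0 and extinct_at[sp] is None:
            extinct_at[sp] = generation
        extinct = extinct_at[sp] is not None
        p = math.nan if counts.total == 0 else allele_frequency(counts)
        rows.append(
            (
                config.scenario_id,
                replicate,
                generation,
                sp.value,
                counts.n_SS,
                counts.n_RS,
                counts.n_RR,
                p,
                occupied,
                extinct,
            )
        )


def _run_lattice(
    config: SimulationConfig,
    payoffs: PayoffMatrix,
    replicate: int,
    species: Species | None,
) -> list:
    """One replicate on one lattice (both species, or a single-species run)."""
    tag = "both" if species is None else species.value
    rng = RngStream(config.seed, replicate)
    if species is None:
        mix = config.species_mix
        species_list = [Species.SF, Species.HA]
    else:
        mix = 1.0 if species is Species.SF else 0.0
        species_list = [species]
    lattice = init_lattice(
        width=config.width,
        height=config.height,
        occupancy=config.occupancy,
        species_mix=mix,
        p_R=config.initial_p_R,
        rng=rng.generator(f"{tag}:init"),
    )
    rows: list = []
    extinct_at: dict[Species, int | None] = {sp: None for sp in species_list}
    _record(rows, config, replicate, 0, lattice, species_list, extinct_at)
    for gen in range(1, config.generations + 1):
        if lattice.occupied_count == 0:
            # total extinction: remaining generations are no-ops
            _record(rows, config, replicate, gen, lattice, species_list, extinct_at)
            continue
        lattice, _ = step(lattice, payoffs, config, rng, label=f"{tag}:")
        _record(rows, config, replicate, gen, lattice, species_list, extinct_at)
    return rows


def run_replicate(
    config: SimulationConfig,
    replicate: int,
    payoffs: PayoffMatrix | None = None,
) -> pd.DataFrame:
    """Full trajectory of one replicate (per generation x species)."""
    if payoffs is None:
        payoffs = config.build_payoffs()
    if config.mode == INTRA_ONLY:
        targets = [config.species] if config.species is not None else [Species.SF, Species.HA]
        rows = []
        for sp in targets:
            rows.extend(_run_lattice(config, payoffs, replicate, sp))
    else:
        rows = _run_lattice(config, payoffs, replicate, None)
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


@dataclass
class ScenarioResult:
    """Replicate trajectories plus the summaries derived from them."""

    config: SimulationConfig
    trajectories: pd.DataFrame
    summary: pd.DataFrame
    terminal: pd.DataFrame
    payoff_provenance: dict[str, int]

    @property
    def scenario_id(self) -> str:
        return self.config.scenario_id

    def mean_trajectory(self, species: Species) -> pd.Series:
        s = self.summary[self.summary["species"] == species.value]
        return s.set_index("generation")["mean_p_R"]


def summarize_trajectories(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-generation replicate mean and 2.5-97.5 percentile envelope of p_R.

    Replicates in which the species is extinct at a generation carry no
    allele frequency and are excluded from that generation's statistics.
    """
    def agg(group: pd.DataFrame) -> pd.Series:
        p = group["p_R"].dropna()
        if len(p) == 0:
            mean = lo = hi = math.nan
        else:
            mean = float(p.mean())
            lo, hi = (float(x) for x in np.percentile(p, [2.5, 97.5]))
        return pd.Series(
            {
                "mean_p_R": mean,
                "q025_p_R": lo,
                "q975_p_R": hi,
                "mean_occupied": float(group["occupied"].mean()),
                "n_replicates": int(len(group)),
                "n_extinct": int(group["extinct"].sum()),
            }
        )

    out = (
        traj.groupby(["scenario_id", "species", "generation"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return out


def classify_terminal(traj: pd.DataFrame) -> pd.DataFrame:
    """Terminal-state label per (replicate, species) from the final generation."""
    last_gen = traj["generation"].max()
    final = traj[traj["generation"] == last_gen]
    rows = []
    for row in final.itertuples(index=False):
        total = row.n_SS + row.n_RS + row.n_RR
        if total == 0:
            label = "extinct"
        elif row.p_R == 1.0:
            label = "fixation_R"
        elif row.p_R == 0.0:
            label = "fixation_S"
        else:
            label = "polymorphic"
        rows.append((row.scenario_id, row.replicate, row.species, label))
    return pd.DataFrame(rows, columns=["scenario_id", "replicate", "species", "terminal"])


def run_scenario(config: SimulationConfig) -> ScenarioResult:
    """All replicates of one scenario, with derived independent seeds."""
    payoffs = config.build_payoffs()
    frames = [
        run_replicate(config, rep, payoffs) for rep in range(config.replicates)
    ]
    traj = pd.concat(frames, ignore_index=True)
    return ScenarioResult(
        config=config,
        trajectories=traj,
        summary=summarize_trajectories(traj),
        terminal=classify_terminal(traj),
        payoff_provenance=payoffs.provenance_counts(),
    )


def plateau_mean(
    result: ScenarioResult, species: Species, start_generation: int = 51
) -> float:
    """Replicate-mean allele frequency averaged over the plateau window
    (generations ``start_generation``..end)."""
    s = result.mean_trajectory(species)
    return float(s[s.index >= start_generation].mean())


def peak_mean(result: ScenarioResult, species: Species) -> tuple[float, int]:
    """Maximum over generations of the replicate-mean allele frequency,
    with the generation at which it is reached."""
    s = result.mean_trajectory(species).dropna()
    gen = int(s.idxmax())
    return float(s.loc[gen]), gen


def _binom_tail(k: int, n: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 1/2); exact."""
    return sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n


def resistance_evolved(
    result: ScenarioResult,
    species: Species,
    alpha: float = 0.01,
    start_generation: int = 51,
) -> bool:
    """Sign test for sustained resistance evolution in one scenario.

    A replicate counts as "risen" if its plateau allele frequency (mean over
    generations ``start_generation``..end) exceeds the initial frequency.
    Only replicates in which the species survives to the final generation
    vote: an excluded (extinct) population cannot evolve resistance — the
    model reports that outcome through the terminal-state classification
    instead. Evolution is declared when significantly more than half of the
    voting replicates rose (exact binomial sign test at level ``alpha``).
    """
    traj = result.trajectories
    traj = traj[traj["species"] == species.value]
    p0 = result.config.initial_p_R
    last_gen = traj["generation"].max()
    rises = []
    for _, g in traj.groupby("replicate"):
        final = g[g["generation"] == last_gen]
        if final["extinct"].any():
            continue
        plateau = g[g["generation"] >= start_generation]["p_R"].mean()
        rises.append(plateau > p0)
    n = len(rises)
    if n == 0:
        return False
    k = sum(rises)
    return k > n / 2 and _binom_tail(k, n) < alpha


def derived_seed(master_seed: int, scenario_id: str) -> int:
    """Scenario-specific seed below 2**31, derived from a master seed."""
    seq = np.random.SeedSequence([int(master_seed), zlib.crc32(scenario_id.encode())])
    return int(seq.generate_state(1)[0] % (2**31))


def paper_grid(master_seed: int = 0, **overrides) -> list[SimulationConfig]:
    """The full study grid: 3 crops x 3 heterozygote behaviors x
    (intra+inter, and intra-only per species)."""
    configs = []
    for crop in CROPS:
        for bh in HeterozygoteBehavior:
            cells: list[dict] = [{"mode": INTRA_PLUS_INTER}]
            cells += [{"mode": INTRA_ONLY, "species": sp} for sp in Species]
            for cell in cells:
                cfg = SimulationConfig(
                    crop=crop, heterozygote_behavior=bh, **cell, **overrides
                )
                cfg.seed = derived_seed(master_seed, cfg.scenario_id)
                configs.append(cfg)
    return configs


def run_grid(configs: list[SimulationConfig], outdir: str | Path) -> dict:
    """Run every scenario, writing per-scenario trajectory and summary CSVs
    plus a JSON manifest. Failures are reported per scenario; completed
    scenarios are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "scenarios": [], "failures": []}
    for config in configs:
        sid = config.scenario_id
        try:
            result = run_scenario(config)
        except Exception as exc:  # noqa: BLE001 - partial failure is reported
            manifest["failures"].append({"scenario_id": sid, "error": repr(exc)})
            continue
        traj_path = outdir / f"{sid}_trajectories.csv"
        summary_path = outdir / f"{sid}_summary.csv"
        result.trajectories.to_csv(traj_path, index=False)
        result.summary.to_csv(summary_path, index=False)
        manifest["scenarios"].append(
            {
                "scenario_id": sid,
                "config": config.to_dict(),
                "payoff_provenance": result.payoff_provenance,
                "trajectories": traj_path.name,
                "summary": summary_path.name,
                "terminal_counts": result.terminal.groupby(["species", "terminal"])
                .size()
                .reset_index(name="n")
                .to_dict(orient="records"),
            }
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def plot_scenario(result: ScenarioResult, path: str | Path) -> None:
    """Mean trajectory with the 2.5-97.5% replicate envelope, per species."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"SF": "tab:orange", "HA": "tab:blue"}
    names = {"SF": "S. frugiperda", "HA": "H. armigera"}
    for sp, group in result.summary.groupby("species"):
        g = group.sort_values("generation")
        ax.plot(g["generation"], g["mean_p_R"], label=names[sp], color=colors[sp])
        ax.fill_between(
            g["generation"], g["q025_p_R"], g["q975_p_R"], alpha=0.2, color=colors[sp]
        )
    ax.set_xlabel("generation")
    ax.set_ylabel("resistance-allele frequency")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(result.scenario_id)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
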
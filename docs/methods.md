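# Methods

## Model structure

One generation applies four phases in order: larval competition on the
lattice, survivor-to-adult transition into quadrant pools, adult dispersal
between quadrants, and reproduction (quadrant mating plus oviposition into
empty cells). Generation 0 is the recorded initial state, before any
update, so "frequency at generation g" counts g completed generation steps.

### Genetics

Resistance is monogenic, autosomal and biallelic (S = susceptibility,
R = resistance allele); there is no mutation, no sex structure, and no
hybridization — mating happens only within a species. Inheritance of
resistance is incompletely recessive in the underlying biology, but since
the simulated refuge applies no insecticide mortality, dominance has no
direct phenotype here; the heterozygote enters the dynamics only through
its competition-behavior scenario (below) and through the (default zero)
heterozygote fitness cost. Mating is implemented as offspring sampled
i.i.d. from the pool's gamete-frequency distribution (infinite-gamete
approximation within a quadrant) rather than explicit pair formation:
with only "random mating among all adults" specified, the two are
equivalent in expectation and the pool form is exact for the statistics
we track.

### Competition payoffs

ρs(focal, opponent) is the probability that a focal larva survives a
five-day competition encounter; matrices are ordered and never
symmetrized (the two sides of one pairing are distinct observations, and
can differ sharply — e.g. corn Ha-SS 0.00 vs Sf-RR 0.25). Intraspecific
and interspecific values come from two separate cage experiments; in
`intra_plus_inter` mode same-species encounters use the intraspecific
entries and cross-species encounters the interspecific ones.

Only homozygote strains were assayed, and only a subset of cells is
reported numerically. The fixtures transcribe every reported value
(`printed`). Remaining homozygote cells are filled with the mean of the
focal species' printed values for the same crop and experiment
(`default`) — a deliberately simple, auditable policy, consistent with
most unreported pairings being described as "not significantly
different". Default cells are overridable per-cell in the run config, and
the CLI refuses to run a scenario containing default cells without an
explicit `--allow-default-payoffs` acknowledgement; provenance counts are
stamped into every manifest.

Heterozygote behavior scenarios: each RS-involving cell has an SS-based
value (every RS in the pair replaced by the same-species SS strain) and an
RR-based value (RS replaced by RR). 00RR takes the SS-based value, 100RR
the RR-based value, 50RR their midpoint — the median of two numbers being
their mean, this is the only reading under which the heterozygote is
"intermediate between the homozygotes".

### Encounter rule

The source text defers its occupation/vacancy game rules to earlier work
without restating them, so the engine defines the rule explicitly from the
fragments that are stated: per larva per generation, one uniform draw on
[0.00001, 1] is tested against k/8 where k is the count of eligible
competitors among the 8 Moore neighbors (the focal larva occupies the
ninth window cell and is never its own competitor); on success one
opponent is drawn uniformly among those competitors and the focal larva
survives a Bernoulli(ρs) trial. At most one encounter per larva per
generation. The 0.00001 lower bound of the compliance draw is reproduced
verbatim although it is practically equivalent to 0. A related wording
issue: the source's definition of its second interaction case reads
"intraspecific (competition between individuals of different species)";
it is read here as interspecific.

The update is synchronous: all outcomes are evaluated against the
pre-update state. Internally the phase is a deterministic function of
per-cell uniform random fields drawn up front, which makes visit-order
independence exact (tested bit-exactly against a scalar per-cell
reference).

`intra_only` mode is run as independent single-species simulations (one
per species), matching the per-species panels of the intraspecific
experiment.

### Reproduction, dispersal, fitness cost

Quadrants A–D tile the lattice 2×2 (half-open splits at h//2, w//2);
adults stay with probability 0.50 or move to each of the two orthogonal
neighbor quadrants with probability 0.25 (no diagonal migration — the
stated rates leave no mass for it). Dispersal is multinomial per
(quadrant, species, genotype) class and conserves adults exactly.

The 25% fitness cost of resistance acts once, at reproduction: effective
reproductive capacity is (1 − cost_g) · Ro(species, crop) with
cost_RR = 0.25 and cost_RS = 0 by default (the cost is attributed to
resistant individuals; with incomplete recessivity the heterozygote
default is no cost; both are configurable). Gametes are contributed in
proportion to effective capacity ("fecundity weighting"), so a pool of
equal SS and RR counts has gamete R-frequency 0.75/1.75 ≈ 0.4286.

Ro values are not printed in the source (it defers to host-plant biology
references); the defaults rank hosts qualitatively — Sf: corn 1.0,
soybean 0.8, cotton 0.6; Ha: cotton 1.0, soybean 1.0, corn 0.5 — and are
configurable. They are the package's own calibration choice, recorded in
every config echo.

Oviposition: the probability W that an empty cell is colonized is given by
relative fitness. The exact normalization is not stated in the source, so
the engine documents its choice: per species,
W = (occupied same-species neighbors × mean effective Ro of the species'
quadrant pool) / (8 × max effective Ro over species and genotypes on the
crop), capped at 1. One uniform draw against ΣW decides occupancy, a
second draws the species proportionally to W, a third draws the genotype
from the species' quadrant mating distribution. Occupied cells are never
overwritten; surviving larvae retain their cells between generations, so
genotype turnover happens through deaths and colonization of empty cells.

### Randomness and reproducibility

One master seed per scenario. Replicate streams are derived by replicate
index, and every phase of every generation gets its own labelled
substream (numpy `SeedSequence` over (seed, replicate, phase-label hash,
generation)), so replicates are independent by construction — deleting
one never perturbs another — and adding a phase never shifts the draws of
existing phases. Identical (seed, replicate) pairs reproduce trajectories
bit-exactly; grid outputs are byte-identical across reruns.

## Bioassay layer

The assay design is two arms of five 3rd-instar larvae per cage, four
cages per treatment, daily survival counts for five days. Kaplan–Meier
curves and the two-sample log-rank test are computed with lifelines;
cage labels are carried in the records but the estimator pools cages,
matching per-arm curves (a cage-level frailty would be a robustness
extension, not the default). No multiplicity correction is applied across
pairwise log-rank comparisons. The payoff estimate is the day-5
product-limit survival, which coincides with the raw surviving fraction
when nothing is censored before day 5.

Because no raw assay records are deposited, the generator is synthetic:
death days follow a geometric model with constant daily hazard h solving
(1 − h)^5 = ρs, survivors censored at day 5. Constant hazard is the
minimal assumption matching an endpoint-only target; the per-day hazard
schedule is configurable for curve-shape experiments. Consequently the
generator reproduces day-5 endpoints and realistic censoring structure,
but not the shape of the empirical survival curves — tests passing on
synthetic records validate the estimators, not the biology of the curves.

## Problem sizes used in tests

Full-scale checks (the scenario-level bounds and the qualitative
H. armigera panels) run at the study defaults: 100×100 lattice, 50
replicates, 100 generations. Statistical property checks that do not
depend on lattice size (neutral martingale, cost monotonicity, neutrality
of competition) use smaller lattices (24×24 to 50×50) and 30–50
replicates, sizes at which the Monte-Carlo envelopes are already tight;
the log-rank type-I error uses 2000 resimulations at the assay's real
n = 20 per arm.

"Sustained resistance evolution" in a scenario is decided by an exact
binomial sign test at level 0.01 over replicates: a replicate votes
"risen" if its plateau frequency (mean over generations 51–100) exceeds
the initial 0.1, and only replicates in which the species survives to the
final generation vote — an extinct population cannot evolve resistance;
competitive exclusion of a whole species is reported separately through
the terminal-state classification (fixation_R / fixation_S / polymorphic /
extinct per replicate).

## Known limitations

* The payoff matrices are only partially recoverable from the published
  text; default-filled cells materially shape some panels. In particular,
  the unreported cotton Ha-RR interspecific cells default to the mean of
  Ha's printed interspecific values (0.075), which strongly disfavors
  resistant Ha there: under these defaults Ha resistance does not rise in
  cotton under 00RR/50RR, unlike the published panels. The corresponding
  check is left failing rather than tuned, since any value restoring the
  published behavior would be invented.
* No within-generation larval movement, egg/larval stage structure,
  density-dependent fecundity, adult mortality schedules, multi-larva
  plants, or inter-crop landscape movement.
* No mutation or immigration: an allele lost is lost forever, so long runs
  ultimately absorb at fixation or extinction.
* Temperature effects on competition and cannibalism are outside scope.
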
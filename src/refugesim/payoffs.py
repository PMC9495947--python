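"""Strain-vs-strain survival payoff matrices.

Each matrix entry ``(focal, opponent) -> rho_s`` is the probability that a
focal larva survives a five-day competition encounter with an opponent of a
given strain on a given crop. Matrices are ordered: the entry for
``(A, B)`` is A's survival against B, the entry for ``(B, A)`` is B's — the
two sides of the same pairing come from the same cage but are distinct
observations and are never symmetrized.

Intraspecific and interspecific values come from two separate bioassay
experiments; a matrix in ``intra_plus_inter`` mode uses intraspecific values
for same-species encounters and interspecific values for cross-species
encounters, while ``intra_only`` carries same-species entries exclusively.

Bioassays measured only homozygote strains (SS, RR). Heterozygote (RS)
entries are produced by one of three behavior scenarios: RS competes exactly
like the same-species SS strain (00RR), exactly like the RR strain (100RR),
or at the midpoint of the two (50RR).

Every entry carries a provenance flag:

``printed``
    transcribed from the published bioassay results (fixture files),
``default``
    gap-filled by the documented policy (mean of the focal species'
    transcribed values for that crop and experiment),
``expanded``
    produced by a heterozygote-behavior scenario,
``estimated``
    produced by the bioassay survival-analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from statistics import fmean
from typing import Iterable

import pandas as pd

from .genetics import GENOTYPES, SPECIES, Genotype, Species

CROPS = ("cotton", "corn", "soybean")

INTRA_ONLY = "intra_only"
INTRA_PLUS_INTER = "intra_plus_inter"
MODES = (INTRA_ONLY, INTRA_PLUS_INTER)


class HeterozygoteBehavior(Enum):
    """Competition-behavior scenario assigned to the heterozygote strain."""

    BH_00RR = "00RR"
    BH_50RR = "50RR"
    BH_100RR = "100RR"


@dataclass(frozen=True, order=True)
class StrainKey:
    """A competitor class: (species, genotype), e.g. Sf-RR."""

    species: Species
    genotype: Genotype

    @property
    def index(self) -> int:
        """Dense strain index in [0, 6): species block of three genotypes."""
        return self.species.index * 3 + self.genotype.index

    def with_genotype(self, genotype: Genotype) -> "StrainKey":
        return StrainKey(self.species, genotype)

    def __str__(self) -> str:
        name = "Sf" if self.species is Species.SF else "Ha"
        return f"{name}-{self.genotype.value}"


#: All six strains in dense-index order (Sf-SS, Sf-RS, Sf-RR, Ha-SS, Ha-RS, Ha-RR).
STRAINS = tuple(StrainKey(sp, g) for sp in SPECIES for g in GENOTYPES)

_HOMOZYGOTES = (Genotype.SS, Genotype.RR)


class MissingPayoffError(KeyError):
    """Lookup of a payoff entry that does not exist in the matrix."""


@dataclass(frozen=True)
class PayoffEntry:
    rho: float
    provenance: str
    source_quote: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"survival probability must lie in [0, 1], got {self.rho}")


class PayoffMatrix:
    """Ordered (focal, opponent) -> survival-probability map for one crop."""

    def __init__(
        self,
        crop: str,
        mode: str,
        entries: dict[tuple[StrainKey, StrainKey], PayoffEntry],
    ):
        if crop not in CROPS:
            raise ValueError(f"unknown crop {crop!r}; expected one of {CROPS}")
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        if mode == INTRA_ONLY:
            for focal, opp in entries:
                if focal.species is not opp.species:
                    raise ValueError(
                        f"interspecific entry ({focal}, {opp}) not allowed in {INTRA_ONLY}"
                    )
        self.crop = crop
        self.mode = mode
        self.entries = dict(entries)

    def lookup(self, focal: StrainKey, opponent: StrainKey) -> float:
        try:
            return self.entries[(focal, opponent)].rho
        except KeyError:
            raise MissingPayoffError(
                f"no payoff entry for focal {focal} vs opponent {opponent} "
                f"(crop={self.crop}, mode={self.mode})"
            ) from None

    def entry(self, focal: StrainKey, opponent: StrainKey) -> PayoffEntry:
        try:
            return self.entries[(focal, opponent)]
        except KeyError:
            raise MissingPayoffError(
                f"no payoff entry for focal {focal} vs opponent {opponent}"
            ) from None

    def provenance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries.values():
            counts[e.provenance] = counts.get(e.provenance, 0) + 1
        return counts

    def as_array(self):
        """6x6 float array indexed by StrainKey.index; NaN where absent."""
        import numpy as np

        arr = np.full((6, 6), np.nan)
        for (focal, opp), e in self.entries.items():
            arr[focal.index, opp.index] = e.rho
        return arr

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (focal, opp), e in sorted(
            self.entries.items(), key=lambda kv: (kv[0][0].index, kv[0][1].index)
        ):
            rows.append(
                {
                    "crop": self.crop,
                    "mode": "intra" if focal.species is opp.species else "inter",
                    "focal_species": focal.species.value,
                    "focal_genotype": focal.genotype.value,
                    "opponent_species": opp.species.value,
                    "opponent_genotype": opp.genotype.value,
                    "rho_s": e.rho,
                    "provenance": e.provenance,
                    "source_quote": e.source_quote,
                }
            )
        return pd.DataFrame(rows, columns=FIXTURE_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps the round-trip bit-exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: str | None = None) -> "PayoffMatrix":
        entries = {}
        crops = frame["crop"].unique()
        if len(crops) != 1:
            raise ValueError(f"matrix frame must cover exactly one crop, got {list(crops)}")
        has_inter = False
        for row in frame.itertuples(index=False):
            focal = StrainKey(Species(row.focal_species), Genotype(row.focal_genotype))
            opp = StrainKey(Species(row.opponent_species), Genotype(row.opponent_genotype))
            has_inter = has_inter or focal.species is not opp.species
            quote = "" if pd.isna(row.source_quote) else str(row.source_quote)
            entries[(focal, opp)] = PayoffEntry(float(row.rho_s), str(row.provenance), quote)
        if mode is None:
            mode = INTRA_PLUS_INTER if has_inter else INTRA_ONLY
        return cls(str(crops[0]), mode, entries)

    @classmethod
    def read_csv(cls, path: str | Path, mode: str | None = None) -> "PayoffMatrix":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(frame, mode=mode)


FIXTURE_COLUMNS = [
    "crop",
    "mode",
    "focal_species",
    "focal_genotype",
    "opponent_species",
    "opponent_genotype",
    "rho_s",
    "provenance",
    "source_quote",
]


def _fixture_frame(crop: str) -> pd.DataFrame:
    if crop not in CROPS:
        raise ValueError(f"unknown crop {crop!r}; expected one of {CROPS}")
    ref = resources.files("refugesim.data") / f"payoffs_{crop}.csv"
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path)
    bad = frame[(frame["rho_s"] < 0) | (frame["rho_s"] > 1)]
    if not bad.empty:
        raise ValueError(f"fixture for {crop} has rho_s outside [0, 1]:\n{bad}")
    return frame


def _required_pairs(mode: str) -> Iterable[tuple[StrainKey, StrainKey]]:
    """Ordered homozygote pairs a matrix of the given mode must cover."""
    homo = [StrainKey(sp, g) for sp in SPECIES for g in _HOMOZYGOTES]
    for focal in homo:
        for opp in homo:
            if mode == INTRA_ONLY and focal.species is not opp.species:
                continue
            yield focal, opp


def load_fixture(crop: str, mode: str = INTRA_PLUS_INTER) -> PayoffMatrix:
    """Homozygote-only payoff matrix for a crop.

    Transcribed assay values are flagged ``printed``. Homozygote cells the
    published results do not report numerically (pairings described only as
    "not significantly different", and both sides of unreported pairings) are
    filled with the mean of the focal species' printed values for the same
    crop and experiment, flagged ``default``.
    """
    frame = _fixture_frame(crop)
    printed: dict[tuple[StrainKey, StrainKey], PayoffEntry] = {}
    for row in frame.itertuples(index=False):
        focal = StrainKey(Species(row.focal_species), Genotype(row.focal_genotype))
        opp = StrainKey(Species(row.opponent_species), Genotype(row.opponent_genotype))
        printed[(focal, opp)] = PayoffEntry(
            float(row.rho_s), "printed", str(row.source_quote)
        )

    def experiment(focal: StrainKey, opp: StrainKey) -> str:
        return "intra" if focal.species is opp.species else "inter"

    entries: dict[tuple[StrainKey, StrainKey], PayoffEntry] = {}
    for focal, opp in _required_pairs(mode):
        if (focal, opp) in printed:
            entries[(focal, opp)] = printed[(focal, opp)]
            continue
        exp = experiment(focal, opp)
        peers = [
            e.rho
            for (f, o), e in printed.items()
            if f.species is focal.species and experiment(f, o) == exp
        ]
        if not peers:  # fall back to the species' printed values in either experiment
            peers = [e.rho for (f, o), e in printed.items() if f.species is focal.species]
        if not peers:
            raise ValueError(
                f"no printed value for species {focal.species.value} on {crop}; "
                f"cannot default-fill ({focal}, {opp})"
            )
        entries[(focal, opp)] = PayoffEntry(fmean(peers), "default")
    return PayoffMatrix(crop, mode, entries)


def _substitute(strain: StrainKey, genotype: Genotype) -> StrainKey:
    """Replace an RS strain with the same-species homozygote ``genotype``."""
    if strain.genotype is Genotype.RS:
        return strain.with_genotype(genotype)
    return strain


def expand_heterozygotes(matrix: PayoffMatrix, bh: HeterozygoteBehavior) -> PayoffMatrix:
    """Add every RS-involving entry to a homozygote matrix.

    Each RS-involving cell has an SS-based value (every RS in the pair
    replaced by the same-species SS strain) and an RR-based value (every RS
    replaced by RR). Under 00RR the cell takes the SS-based value, under
    100RR the RR-based value, and under 50RR their midpoint (the median of
    the two homozygote-based values). Existing entries are never modified,
    so the expansion is idempotent.
    """
    entries = dict(matrix.entries)
    for focal in STRAINS:
        for opp in STRAINS:
            if matrix.mode == INTRA_ONLY and focal.species is not opp.species:
                continue
            if focal.genotype is not Genotype.RS and opp.genotype is not Genotype.RS:
                continue
            values = []
            needed = [Genotype.SS, Genotype.RR] if bh is HeterozygoteBehavior.BH_50RR else []
            if bh is HeterozygoteBehavior.BH_00RR:
                needed = [Genotype.SS]
            elif bh is HeterozygoteBehavior.BH_100RR:
                needed = [Genotype.RR]
            for g in needed:
                f_sub, o_sub = _substitute(focal, g), _substitute(opp, g)
                try:
                    values.append(matrix.entries[(f_sub, o_sub)].rho)
                except KeyError:
                    raise MissingPayoffError(
                        f"cannot expand ({focal}, {opp}) under {bh.value}: "
                        f"missing homozygote entry ({f_sub}, {o_sub})"
                    ) from None
            entries[(focal, opp)] = PayoffEntry(fmean(values), "expanded")
    return PayoffMatrix(matrix.crop, matrix.mode, entries)


def with_overrides(
    matrix: PayoffMatrix,
    overrides: dict[tuple[StrainKey, StrainKey], float],
    provenance: str = "override",
) -> PayoffMatrix:
    """Copy of ``matrix`` with selected cells replaced (e.g. config overrides)."""
    entries = dict(matrix.entries)
    for key, rho in overrides.items():
        old = entries.get(key)
        quote = old.source_quote if old else ""
        entries[key] = PayoffEntry(float(rho), provenance, quote)
    return PayoffMatrix(matrix.crop, matrix.mode, entries)
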
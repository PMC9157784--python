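"""Incidence data model and I/O for aquatic plant surveys.

A survey is a set of sample units (100 m grid cells) in which species
presence is recorded at discrete stations.  For analysis, station-level
detections are collapsed to unit-level presence/absence booleans: a
species is counted at most once per sample unit, and the unit's richness
is the aggregate over its stations.  Units with zero detections are kept
in the matrix (and in the unit count m) — plant-free units are real
sampling effort and the richness estimators depend on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ORIGINS = ("native", "non_native")
GROWTH_FORMS = ("submerged", "emergent", "floating", "free_floating", "other")


@dataclass(frozen=True)
class SpeciesRecord:
    """One taxon: short unique code, display name, origin and growth form."""

    code: str
    name: str = ""
    origin: str = "native"
    growth_form: str = "submerged"

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}, got {self.origin!r}")
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(
                f"growth_form must be one of {GROWTH_FORMS}, got {self.growth_form!r}"
            )


@dataclass(frozen=True)
class SampleUnit:
    """One sample unit (grid cell) with planar centroid coordinates in metres."""

    unit_id: str
    x: float = 0.0
    y: float = 0.0
    zone: str = "unzoned"
    mean_depth: float = 0.0
    max_depth: float | None = None
    habitat: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError(f"mean_depth must be >= 0 for unit {self.unit_id}")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError(f"max_depth must be >= 0 for unit {self.unit_id}")


class IncidenceMatrix:
    """Boolean sample-unit x species presence table with attribute tables.

    Parameters
    ----------
    presence
        Boolean DataFrame indexed by unit_id with one column per species code.
    species
        DataFrame indexed by code with columns name, origin, growth_form.
    units
        Optional DataFrame indexed by unit_id with unit metadata (x, y, zone,
        mean_depth, max_depth, habitat columns).  Defaults to bare ids.
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        species: pd.DataFrame,
        units: pd.DataFrame | None = None,
    ) -> None:
        if presence.index.has_duplicates:
            raise ValueError("duplicate unit ids in presence table")
        if presence.columns.has_duplicates:
            raise ValueError("duplicate species codes in presence table")
        missing = set(presence.columns) - set(species.index)
        if missing:
            raise ValueError(f"species table missing codes: {sorted(missing)}")
        self.presence = presence.astype(bool)
        self.species = species.loc[list(presence.columns)]
        if units is None:
            units = pd.DataFrame(index=presence.index)
        else:
            missing_units = set(presence.index) - set(units.index)
            if missing_units:
                raise ValueError(f"unit table missing ids: {sorted(missing_units)}")
            units = units.loc[presence.index]
        self.units = units

    @property
    def m(self) -> int:
        return len(self.presence)

    @property
    def species_codes(self) -> list[str]:
        return list(self.presence.columns)

    def per_species_frequency(self) -> pd.Series:
        """Incidence frequency (number of units occupied) per species."""
        return self.presence.sum(axis=0).astype(int)

    def per_unit_richness(self) -> pd.Series:
        return self.presence.sum(axis=1).astype(int)

    def subset_units(self, unit_ids: Sequence[str]) -> "IncidenceMatrix":
        return IncidenceMatrix(
            self.presence.loc[list(unit_ids)], self.species, self.units
        )


@dataclass(frozen=True)
class IncidenceCounts:
    """Sufficient statistics of an incidence matrix for richness estimation.

    m: number of sample units; incidences: tally of all species occurrences;
    per_species: frequency per species; Sobs: observed richness; Q1/Q2:
    uniques/duplicates (species occurring in exactly one / two units).
    """

    m: int
    incidences: int
    per_species: tuple[int, ...]
    Sobs: int
    Q1: int
    Q2: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.per_species)
        if self.m <= 0:
            raise ValueError("m must be a positive integer")
        if freqs.size and freqs.max() > self.m:
            raise ValueError("a species frequency exceeds the number of units")
        if self.Sobs != int((freqs >= 1).sum()):
            raise ValueError("Sobs inconsistent with per-species frequencies")
        if self.incidences != int(freqs.sum()):
            raise ValueError("incidences inconsistent with per-species frequencies")
        if self.Q1 + self.Q2 > self.Sobs:
            raise ValueError("Q1 + Q2 cannot exceed Sobs")

    @classmethod
    def from_frequencies(cls, freqs: Iterable[int], m: int) -> "IncidenceCounts":
        """Build counts directly from per-species incidence frequencies.

        Printed survey summaries (m, frequencies) are valid inputs on their
        own; no presence matrix is required.
        """
        f = np.asarray([int(v) for v in freqs])
        if (f < 0).any():
            raise ValueError("frequencies must be non-negative")
        return cls(
            m=int(m),
            incidences=int(f.sum()),
            per_species=tuple(int(v) for v in f),
            Sobs=int((f >= 1).sum()),
            Q1=int((f == 1).sum()),
            Q2=int((f == 2).sum()),
        )

    @classmethod
    def from_q(cls, m: int, Sobs: int, Q1: int, Q2: int,
               incidences: int | None = None) -> "IncidenceCounts":
        """Build counts from the published summary (m, Sobs, Q1, Q2).

        A frequency vector consistent with the given marginals is synthesised:
        Q1 ones, Q2 twos, and the remaining Sobs−Q1−Q2 species assigned
        frequencies ≥ 3 summing to `incidences` when it is provided.
        """
        rest = Sobs - Q1 - Q2
        if rest < 0:
            raise ValueError("Q1 + Q2 cannot exceed Sobs")
        freqs = [1] * Q1 + [2] * Q2
        if incidences is None:
            freqs += [3] * rest
        else:
            remaining = incidences - Q1 - 2 * Q2
            if rest:
                if not (3 * rest <= remaining <= m * rest):
                    raise ValueError("incidences inconsistent with m, Sobs, Q1, Q2")
                base, extra = divmod(remaining, rest)
                tail = [base + 1] * extra + [base] * (rest - extra)
                freqs += tail
            elif remaining:
                raise ValueError("incidences inconsistent with Q1, Q2 when Sobs=Q1+Q2")
        return cls.from_frequencies(freqs, m)


@dataclass(frozen=True)
class EndpointSummary:
    """Per-unit means of the richness endpoints reported for each survey."""

    total: float
    rare_5: float
    rare_20: float
    non_native: float

    def __post_init__(self) -> None:
        if self.rare_5 > self.total + 1e-9 or self.non_native > self.total + 1e-9:
            raise ValueError("endpoint means cannot exceed mean total richness")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_species_table(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    df = _as_df(path_or_df)
    required = {"code", "origin"}
    if not required.issubset(df.columns):
        raise ValueError(f"species table needs columns {sorted(required)}")
    bad = set(df["origin"]) - set(ORIGINS)
    if bad:
        raise ValueError(f"unknown origin levels: {sorted(bad)}")
    if "name" not in df.columns:
        df = df.assign(name=df["code"])
    if "growth_form" not in df.columns:
        df = df.assign(growth_form="submerged")
    if df["code"].duplicated().any():
        raise ValueError("duplicate species codes in species table")
    return df.set_index("code")


def read_unit_table(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    df = _as_df(path_or_df)
    if "unit_id" not in df.columns:
        raise ValueError("unit table needs a unit_id column")
    df = df.astype({"unit_id": str})
    if df["unit_id"].duplicated().any():
        raise ValueError("duplicate unit ids in unit table")
    return df.set_index("unit_id")


def _as_df(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    return pd.read_csv(path_or_df)


def read_incidence(
    long_records: str | Path | pd.DataFrame,
    species_table: str | Path | pd.DataFrame,
    unit_table: str | Path | pd.DataFrame | None = None,
) -> IncidenceMatrix:
    """Collapse long detection records to a unit-level incidence matrix.

    ``long_records`` has columns unit_id, species_code and optionally
    station_id; one row per detection.  Duplicate (unit, species) rows —
    the same species at several stations of a unit — collapse silently to
    a single presence.  Units listed in ``unit_table`` but absent from the
    records are retained with all-false rows.
    """
    recs = _as_df(long_records)
    needed = {"unit_id", "species_code"}
    if not needed.issubset(recs.columns):
        raise ValueError(f"long records need columns {sorted(needed)}")
    recs = recs.astype({"unit_id": str, "species_code": str})
    species = read_species_table(species_table)
    unknown = set(recs["species_code"]) - set(species.index)
    if unknown:
        raise ValueError(f"unknown species code(s): {sorted(unknown)}")
    units = read_unit_table(unit_table) if unit_table is not None else None
    if units is not None:
        unknown_units = set(recs["unit_id"]) - set(units.index)
        if unknown_units:
            raise ValueError(f"unknown unit id(s): {sorted(unknown_units)}")
        unit_ids = list(units.index)
    else:
        unit_ids = sorted(recs["unit_id"].unique())
    presence = pd.DataFrame(
        False, index=pd.Index(unit_ids, name="unit_id"), columns=list(species.index)
    )
    for uid, code in recs[["unit_id", "species_code"]].itertuples(index=False):
        presence.at[uid, code] = True
    return IncidenceMatrix(presence, species, units)


def read_wide(
    wide: str | Path | pd.DataFrame,
    species_table: str | Path | pd.DataFrame,
    unit_table: str | Path | pd.DataFrame | None = None,
) -> IncidenceMatrix:
    """Read a wide 0/1 table (unit_id column + one column per species code)."""
    df = _as_df(wide)
    if "unit_id" not in df.columns:
        raise ValueError("wide table needs a unit_id column")
    df = df.astype({"unit_id": str}).set_index("unit_id")
    species = read_species_table(species_table)
    unknown = set(df.columns) - set(species.index)
    if unknown:
        raise ValueError(f"unknown species code(s): {sorted(unknown)}")
    units = read_unit_table(unit_table) if unit_table is not None else None
    return IncidenceMatrix(df.astype(bool), species, units)


def to_wide_csv(matrix: IncidenceMatrix, path: str | Path) -> None:
    matrix.presence.astype(int).reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def tally_counts(matrix: IncidenceMatrix) -> IncidenceCounts:
    """Tally m, incidences, per-species frequencies, Sobs, Q1 and Q2."""
    if matrix.m == 0:
        raise ValueError("cannot tally an empty matrix")
    freqs = matrix.per_species_frequency()
    return IncidenceCounts.from_frequencies(freqs.to_numpy(), matrix.m)


def endpoint_summary(
    matrix: IncidenceMatrix,
    rare_fractions: Sequence[float] = (0.05, 0.20),
) -> EndpointSummary:
    """Per-unit mean richness for total, rare and non-native endpoints.

    A species is rare at fraction f iff its incidence frequency is strictly
    below f times the survey's total incidences.
    """
    for f in rare_fractions:
        if not 0 < f < 1:
            raise ValueError(f"rare fraction must be in (0, 1), got {f}")
    freqs = matrix.per_species_frequency()
    total_inc = int(freqs.sum())
    if total_inc <= 0:
        raise ValueError("endpoint summary requires at least one incidence")
    pres = matrix.presence.to_numpy()
    f5, f20 = rare_fractions
    rare5 = (freqs < f5 * total_inc).to_numpy() & (freqs > 0).to_numpy()
    rare20 = (freqs < f20 * total_inc).to_numpy() & (freqs > 0).to_numpy()
    nonnat = (matrix.species["origin"] == "non_native").to_numpy()
    return EndpointSummary(
        total=float(pres.sum(axis=1).mean()),
        rare_5=float(pres[:, rare5].sum(axis=1).mean()),
        rare_20=float(pres[:, rare20].sum(axis=1).mean()),
        non_native=float(pres[:, nonnat].sum(axis=1).mean()),
    )


def native_nonnative_relationship(
    matrix: IncidenceMatrix,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of per-unit native vs non-native richness.

    Returns (r, pairs) where pairs has columns native, non_native per unit.
    When either series has zero variance the correlation is undefined and
    NaN is returned (never 0).
    """
    if matrix.m < 3:
        raise ValueError("need at least 3 units for a correlation")
    nonnat = (matrix.species["origin"] == "non_native").to_numpy()
    pres = matrix.presence.to_numpy()
    pairs = pd.DataFrame(
        {
            "native": pres[:, ~nonnat].sum(axis=1),
            "non_native": pres[:, nonnat].sum(axis=1),
        },
        index=matrix.presence.index,
    )
    if pairs["native"].nunique() < 2 or pairs["non_native"].nunique() < 2:
        return float("nan"), pairs
    r, _ = stats.pearsonr(pairs["native"], pairs["non_native"])
    return float(r), pairs


def euphotic_depth(secchi_m: float, factor: float = 2.5) -> float:
    """Euphotic-zone depth (m) as a multiple of Secchi transparency.

    The conventional rule of thumb places the factor between 2 and 3; a
    factor outside that range is computed anyway with a warning.
    """
    if secchi_m <= 0:
        raise ValueError("Secchi depth must be positive")
    if not 2 <= factor <= 3:
        warnings.warn(
            f"euphotic factor {factor} outside the conventional [2, 3] range",
            stacklevel=2,
        )
    return secchi_m * factor
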
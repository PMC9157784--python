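"""Synthetic coastal landscapes, plant communities and the rake-toss survey.

The generator emulates the statistical structure the analysis pipeline
assumes for a Great Lakes coastal site:

* an axis-aligned grid of 100 m cells with depth increasing away from a
  shoreline (plus seeded noise), shoreline-type segments, boat launches,
  marinas and dock clusters, from which all habitat variables are derived;
* a plant community whose per-species occupancy declines logistically
  with depth (most occupancy shallower than 6 m), is hard-zeroed beyond a
  cutoff depth (8 m by default), is boosted near introduction-pathway
  features, and shares a cell-level suitability multiplier across native
  and non-native species so their per-unit richness is positively
  correlated; one-fifth of the pool is non-native by default and species
  base occupancies are heavy-tailed so surveys yield uniques and
  duplicates;
* a station/rake-toss observation process: four stations per sampled
  unit, a minimum of four tosses per station with per-toss per-species
  Bernoulli detection, extra tosses while the latest toss still adds a
  species new to the station, and a visual-detection bonus for floating
  and emergent growth forms.

Every stage is deterministic under its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    RichnessSurface,
    SampleFrame,
    assign_weights,
    interpolate_richness,
    spatially_balanced_sample,
)
from .diversity import chao2, ice_cv, select_variant
from .habitat import HABITAT_VARIABLES
from .incidence import GROWTH_FORMS, IncidenceMatrix, read_incidence, tally_counts


@dataclass
class LandscapeConfig:
    nx: int = 30
    ny: int = 20
    cell_size: float = 100.0
    #: depth gained per metre of distance from the shoreline (y = 0 edge)
    depth_slope: float = 0.006
    depth_noise_sd: float = 0.4
    max_depth: float = 12.0
    #: depth below which a cell counts as fully littoral
    littoral_depth: float = 4.0
    n_boat_launches: int = 2
    n_marinas: int = 1
    dock_fraction: float = 0.3
    zone_depth_threshold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0 or self.cell_size <= 0:
            raise ValueError("grid dimensions and cell size must be positive")


@dataclass
class CommunityConfig:
    s_true: int = 40
    non_native_fraction: float = 0.2
    #: logistic depth response: occupancy halves at the midpoint depth
    depth_midpoint: float = 4.0
    depth_scale: float = 1.0
    hard_depth_cutoff: float = 8.0
    #: multiplicative occupancy boost within `feature_radius` of a launch/marina
    feature_boost: float = 1.5
    feature_radius: float = 300.0
    #: lognormal sigma of species base occupancies (incidence heterogeneity)
    occupancy_sigma: float = 1.0
    base_occupancy: float = 0.18
    #: lognormal sigma of the cell suitability shared by all species
    suitability_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.non_native_fraction <= 1:
            raise ValueError("non_native_fraction must lie in [0, 1]")
        if self.s_true <= 0:
            raise ValueError("species pool must be positive")


@dataclass
class ObservationConfig:
    stations_per_unit: int = 4
    min_tosses: int = 4
    max_tosses: int = 12
    #: per-toss, per-species detection probability given presence in the cell
    p_detect_toss: float = 0.25
    #: extra one-off visual detection probability for conspicuous growth forms
    visual_bonus: dict[str, float] = field(
        default_factory=lambda: {
            "floating": 0.5, "free_floating": 0.5, "emergent": 0.5
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_tosses < 1 or self.max_tosses < self.min_tosses:
            raise ValueError("need max_tosses >= min_tosses >= 1")
        if not 0 <= self.p_detect_toss <= 1:
            raise ValueError("detection probability must lie in [0, 1]")


@dataclass
class TrueCommunity:
    presence: pd.DataFrame          # cell x species booleans
    species: pd.DataFrame           # code -> name, origin, growth_form
    config: CommunityConfig

    @property
    def s_true(self) -> int:
        """Number of species present in at least one cell."""
        return int((self.presence.sum(axis=0) > 0).sum())

    def per_species_frequency(self) -> pd.Series:
        return self.presence.sum(axis=0).astype(int)

    def regional_pool(self, cell_ids: Sequence[str] | None = None) -> int:
        pres = self.presence if cell_ids is None else self.presence.loc[list(cell_ids)]
        return int((pres.sum(axis=0) > 0).sum())


def config_hash(*configs) -> str:
    blob = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def generate_landscape(config: LandscapeConfig) -> SampleFrame:
    """Generate a gridded coastal sample frame with all habitat attributes.

    The shoreline runs along y = 0; depth grows with distance from shore
    (slope * distance, plus seeded Gaussian noise, clipped to [0,
    max_depth]).  Shore cells are divided into soft/hard/moderate segments
    and carry dock clusters; boat launches and marinas sit at random shore
    positions.  All habitat variables are filled per cell, with distance
    measures taken from the cell edge (centroid distance minus half a cell
    side, floored at zero).
    """
    rng = np.random.default_rng(config.seed)
    nx, ny, cs = config.nx, config.ny, config.cell_size
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    ix, iy = ix.ravel(), iy.ravel()
    x = (ix + 0.5) * cs
    y = (iy + 0.5) * cs
    ids = np.array([f"r{r}c{c}" for r, c in zip(iy, ix)])

    shore_dist = y  # distance to the y=0 shoreline
    depth = config.depth_slope * shore_dist + rng.normal(0, config.depth_noise_sd, x.size)
    depth = np.clip(depth, 0.0, config.max_depth)

    # shoreline segmentation into soft / hard / moderate thirds, shuffled
    seg_types = np.array(["soft", "hard", "moderate"])[
        rng.permutation(np.arange(nx) * 3 // nx)
    ]
    shore_x = (np.arange(nx) + 0.5) * cs
    # dock clusters on a random subset of shore segments
    docked = rng.random(nx) < config.dock_fraction
    lots_of_docks = docked & (rng.random(nx) < 0.5)
    launches = shore_x[rng.choice(nx, size=config.n_boat_launches, replace=False)]
    marinas = shore_x[rng.choice(nx, size=config.n_marinas, replace=False)]

    half = cs / 2.0

    def edge_dist(dc: np.ndarray) -> np.ndarray:
        return np.clip(dc - half, 0.0, None)

    def dist_to_shore_subset(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return np.full(x.size, float((nx + ny) * cs))
        sx = shore_x[mask]
        d = np.sqrt((x[:, None] - sx[None, :]) ** 2 + y[:, None] ** 2)
        return edge_dist(d.min(axis=1))

    def pct_shore(mask: np.ndarray, radius: float = 500.0) -> np.ndarray:
        within = np.abs(x[:, None] - shore_x[None, :]) <= radius
        denom = np.clip(within.sum(axis=1), 1, None)
        return 100.0 * (within & mask[None, :]).sum(axis=1) / denom

    attrs = pd.DataFrame(index=pd.Index(ids, name="id"))
    attrs["x"] = x
    attrs["y"] = y
    attrs["mean_depth"] = depth
    attrs["max_depth"] = np.clip(depth + np.abs(rng.normal(0.3, 0.2, x.size)),
                                 0, config.max_depth)
    attrs["percent_littoral_zone"] = np.clip(
        100.0 * (1.0 - (depth - config.littoral_depth / 2) / config.littoral_depth),
        0.0, 100.0,
    )
    fetch_base = shore_dist + (np.minimum(x, nx * cs - x))
    attrs["maximum_fetch"] = fetch_base * (1 + rng.normal(0, 0.05, x.size)).clip(0.5)
    attrs["min_distance_soft_shore"] = dist_to_shore_subset(seg_types == "soft")
    attrs["min_distance_hard_shore"] = dist_to_shore_subset(seg_types == "hard")
    attrs["min_distance_moderate_shore"] = dist_to_shore_subset(seg_types == "moderate")
    attrs["min_distance_any_shore"] = edge_dist(y)
    attrs["percent_soft_shore"] = pct_shore(seg_types == "soft")
    attrs["percent_hard_shore"] = pct_shore(seg_types == "hard")
    attrs["percent_moderate_shore"] = pct_shore(seg_types == "moderate")
    attrs["min_distance_boat_launch"] = edge_dist(
        np.sqrt((x[:, None] - launches[None, :]) ** 2 + y[:, None] ** 2).min(axis=1)
    )
    attrs["min_distance_marina"] = edge_dist(
        np.sqrt((x[:, None] - marinas[None, :]) ** 2 + y[:, None] ** 2).min(axis=1)
    )
    if docked.any():
        dx = shore_x[docked]
        ddist = np.sqrt((x[:, None] - dx[None, :]) ** 2 + y[:, None] ** 2)
        attrs["mid_distance_docked_shore"] = edge_dist(np.median(ddist, axis=1))
    else:
        attrs["mid_distance_docked_shore"] = float((nx + ny) * cs)
    attrs["min_distance_lots_of_docks"] = dist_to_shore_subset(lots_of_docks)
    attrs["proportion_shore_to_water"] = 1.0 / (1.0 + y / cs)
    attrs["percent_lots_of_docks"] = pct_shore(lots_of_docks)
    attrs["percent_docks"] = pct_shore(docked)
    attrs["large_marina_presence"] = (
        attrs["min_distance_marina"] < 1000.0
    ).astype(float)
    attrs["zone"] = np.where(depth < config.zone_depth_threshold, "shallow", "deep")
    attrs["weight"] = 1.0
    return SampleFrame(attrs, cs)


def habitat_table(frame: SampleFrame) -> pd.DataFrame:
    """The habitat-variable columns of a landscape frame."""
    return frame.cells[list(HABITAT_VARIABLES)].copy()


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------

def generate_community(landscape: SampleFrame, config: CommunityConfig) -> TrueCommunity:
    """Sample per-cell species presence from the occupancy model.

    P(present) = base_j * logistic depth response * cell suitability *
    pathway-feature boost, clipped to [0, 1] and hard-zeroed beyond the
    depth cutoff.  base_j is lognormal across species (heavy-tailed, so
    surveys produce uniques and duplicates); the cell suitability is a
    single lognormal multiplier shared by every species, which induces
    the positive native/non-native richness correlation.
    """
    rng = np.random.default_rng(config.seed)
    cells = landscape.cells
    depth = cells["mean_depth"].to_numpy(float)

    s = config.s_true
    n_nonnat = int(round(config.non_native_fraction * s))
    codes = [f"sp{i:03d}" for i in range(s)]
    origin = np.array(["non_native"] * n_nonnat + ["native"] * (s - n_nonnat))
    forms = rng.choice(
        GROWTH_FORMS, size=s, p=[0.54, 0.16, 0.10, 0.10, 0.10]
    )
    species = pd.DataFrame(
        {"name": codes, "origin": origin, "growth_form": forms},
        index=pd.Index(codes, name="code"),
    )

    base = config.base_occupancy * rng.lognormal(0.0, config.occupancy_sigma, s)
    depth_resp = 1.0 / (1.0 + np.exp((depth - config.depth_midpoint) / config.depth_scale))
    suitability = rng.lognormal(0.0, config.suitability_sigma, len(cells))
    near_feature = (
        (cells["min_distance_boat_launch"] < config.feature_radius)
        | (cells["min_distance_marina"] < config.feature_radius)
    ).to_numpy()
    boost = np.where(near_feature, config.feature_boost, 1.0)
    p = np.clip(
        base[None, :] * (depth_resp * suitability * boost)[:, None], 0.0, 1.0
    )
    p[depth > config.hard_depth_cutoff, :] = 0.0
    presence = pd.DataFrame(
        rng.random(p.shape) < p, index=cells.index, columns=codes
    )
    return TrueCommunity(presence=presence, species=species, config=config)


# ---------------------------------------------------------------------------
# Observation process
# ---------------------------------------------------------------------------

def simulate_survey(
    community: TrueCommunity,
    selected_cells: Sequence[str],
    config: ObservationConfig | None = None,
) -> pd.DataFrame:
    """Simulate the station/rake-toss survey over the selected cells.

    Returns long-format detection records (unit_id, station_id,
    species_code), one row per species detected at a station; every
    selected unit appears in the survey even with zero detections (units
    without rows are reconstructed downstream from the unit table).

    Tosses are Bernoulli per species present in the cell.  Each station
    performs the minimum number of tosses, then keeps tossing while the
    most recent toss added a species new to that station (up to
    ``max_tosses``); conspicuous growth forms get a one-off visual
    detection chance per station.
    """
    cfg = config or ObservationConfig()
    rng = np.random.default_rng(cfg.seed)
    missing = set(selected_cells) - set(community.presence.index)
    if missing:
        raise ValueError(f"selected cells not in landscape: {sorted(missing)}")
    pres = community.presence.loc[list(selected_cells)].to_numpy()
    codes = np.asarray(community.presence.columns)
    vis_p = np.array(
        [cfg.visual_bonus.get(f, 0.0) for f in community.species["growth_form"]]
    )
    n_units, s = pres.shape
    st = cfg.stations_per_unit
    T = cfg.max_tosses
    # toss outcomes for all potential tosses: (units, stations, tosses, species)
    det = (
        rng.random((n_units, st, T, s)) < cfg.p_detect_toss
    ) & pres[:, None, None, :]
    visual = (rng.random((n_units, st, s)) < vis_p[None, None, :]) & pres[:, None, :]

    cum = np.cumsum(det, axis=2) > 0          # union of tosses 0..t
    new_any = np.empty((n_units, st, T), dtype=bool)
    new_any[:, :, 0] = det[:, :, 0].any(axis=-1)
    new_any[:, :, 1:] = (det[:, :, 1:] & ~cum[:, :, :-1]).any(axis=-1)
    # station stops at the first toss index >= min_tosses whose predecessor
    # added nothing new; equivalently keep tossing while the latest toss did
    tosses_used = np.full((n_units, st), T)
    for t in range(cfg.min_tosses, T + 1):
        can_stop = ~new_any[:, :, t - 1]
        stop_now = can_stop & (tosses_used == T) if t < T else (tosses_used == T)
        if t < T:
            tosses_used = np.where(stop_now, t, tosses_used)
    keep = np.arange(T)[None, None, :, None] < tosses_used[:, :, None, None]
    station_det = (det & keep).any(axis=2) | visual

    recs = []
    uid_arr = np.asarray(list(selected_cells))
    for u in range(n_units):
        for k in range(st):
            for j in np.nonzero(station_det[u, k])[0]:
                recs.append((uid_arr[u], f"st{k + 1}", codes[j]))
    return pd.DataFrame(recs, columns=["unit_id", "station_id", "species_code"])


def survey_matrix(
    community: TrueCommunity,
    selected_cells: Sequence[str],
    records: pd.DataFrame,
    landscape: SampleFrame | None = None,
) -> IncidenceMatrix:
    """Build the unit-level incidence matrix for a simulated survey.

    All selected units are retained (all-false rows for zero detections).
    """
    unit_table = pd.DataFrame({"unit_id": list(selected_cells)})
    if landscape is not None:
        meta = landscape.cells.loc[list(selected_cells)].reset_index(names="unit_id")
        unit_table = meta
    species_table = community.species.reset_index()
    return read_incidence(records, species_table, unit_table)


# ---------------------------------------------------------------------------
# End-to-end experiments
# ---------------------------------------------------------------------------

def recovery_experiment(
    m_values: Sequence[int],
    n_seeds: int = 200,
    landscape_config: LandscapeConfig | None = None,
    community_config: CommunityConfig | None = None,
    observation_config: ObservationConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Score Chao2 recovery of true regional richness across effort levels.

    For each m and seed, a uniform-weight GRTS survey of m units is
    simulated and the auto-selected Chao2 estimate compared to the true
    species pool of the landscape.  Returns one row per m with the median
    bias (Sest − S_true), median absolute bias and CI coverage.
    """
    lc = landscape_config or LandscapeConfig()
    cc = community_config or CommunityConfig()
    oc = observation_config or ObservationConfig()
    landscape = generate_landscape(lc)
    community = generate_community(landscape, cc)
    s_true = community.s_true
    rows = []
    for m in m_values:
        biases, covered = [], []
        for k in range(n_seeds):
            seed = (base_seed * 100003 + m * 1009 + k) % (2**31 - 1)
            sel = spatially_balanced_sample(landscape, m, seed=seed)
            recs = simulate_survey(
                community, sel,
                ObservationConfig(**{**asdict(oc), "seed": seed + 1}),
            )
            matrix = survey_matrix(community, sel, recs)
            counts = tally_counts(matrix)
            est = chao2(counts, select_variant(ice_cv(counts)))
            biases.append(est.Sest - s_true)
            covered.append(est.ci_low <= s_true <= est.ci_high)
        rows.append({
            "m": m,
            "median_bias": float(np.median(biases)),
            "median_abs_bias": float(np.median(np.abs(biases))),
            "ci_coverage": float(np.mean(covered)),
            "s_true": s_true,
        })
    return pd.DataFrame(rows)


def adaptive_vs_dispersed(
    n_pairs: int = 200,
    total_effort: int = 40,
    landscape_config: LandscapeConfig | None = None,
    community_config: CommunityConfig | None = None,
    observation_config: ObservationConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Paired comparison: two-stage richness-weighted vs single-stage design.

    The dispersed design draws ``total_effort`` units uniformly; the
    adaptive design spends half the effort on a uniform first stage, fits
    an IDW richness surface from the observed per-unit richness, converts
    it to percentile weights, and draws the second half from the remaining
    cells with those weights.  Returns per-pair species totals and whether
    the adaptive design detected at least as many species.
    """
    lc = landscape_config or LandscapeConfig()
    cc = community_config or CommunityConfig()
    oc = observation_config or ObservationConfig()
    landscape = generate_landscape(lc)
    community = generate_community(landscape, cc)
    half = total_effort // 2
    rows = []
    for k in range(n_pairs):
        seed = (base_seed * 100003 + 7919 * k) % (2**31 - 1)
        # dispersed single stage
        sel_d = spatially_balanced_sample(landscape, total_effort, seed=seed)
        recs_d = simulate_survey(
            community, sel_d, ObservationConfig(**{**asdict(oc), "seed": seed + 1})
        )
        s_dispersed = recs_d["species_code"].nunique()
        # adaptive two stage
        sel_1 = spatially_balanced_sample(landscape, half, seed=seed + 2)
        recs_1 = simulate_survey(
            community, sel_1, ObservationConfig(**{**asdict(oc), "seed": seed + 3})
        )
        matrix_1 = survey_matrix(community, sel_1, recs_1)
        observed = matrix_1.per_unit_richness().to_dict()
        surface = interpolate_richness(
            observed, landscape, method="idw",
            depth_mask_m=cc.hard_depth_cutoff - 2.0,
        )
        weighted = assign_weights(landscape, "percentile_surface", surface=surface)
        rest = SampleFrame(
            weighted.cells.drop(index=list(sel_1)), landscape.cell_size
        )
        sel_2 = spatially_balanced_sample(rest, half, seed=seed + 4)
        recs_2 = simulate_survey(
            community, sel_2, ObservationConfig(**{**asdict(oc), "seed": seed + 5})
        )
        s_adaptive = pd.concat([recs_1, recs_2])["species_code"].nunique()
        rows.append({
            "pair": k,
            "s_dispersed": s_dispersed,
            "s_adaptive": s_adaptive,
            "adaptive_at_least": s_adaptive >= s_dispersed,
        })
    return pd.DataFrame(rows)
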
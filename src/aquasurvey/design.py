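"""Sample frames, inclusion weights and spatially balanced (GRTS) selection.

The survey's sample frame is an axis-aligned grid of square cells (100 m
per side by default), each carrying a zone label, depth and habitat
attributes, and an inclusion weight.  Selection uses generalized random
tessellation stratified (GRTS) sampling: cells are mapped to a quadrant-
recursive randomized address, selected by systematic probability-
proportional-to-size sampling along that address order, and returned in
reverse hierarchical order so that any prefix of the output is itself a
spatially balanced sample.

Between survey years, observed richness is interpolated back onto the
frame (inverse-distance weighting by default, ordinary kriging optional),
masked to depths that can support plants, and converted to inclusion
weights through a percentile-class weight map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.stats import rankdata

#: inclusion weight per percentile class of the predicted richness surface,
#: highest class first: (percentile break, weight); cells below the last
#: break get the floor weight.
DEFAULT_WEIGHT_MAP: tuple[tuple[float, float], ...] = (
    (90.0, 0.6),
    (80.0, 0.5),
    (70.0, 0.4),
    (60.0, 0.3),
    (50.0, 0.2),
)
DEFAULT_FLOOR_WEIGHT = 0.1
DEFAULT_CELL_SIZE = 100.0
DEFAULT_DEPTH_MASK_M = 6.0


@dataclass
class WeightMap:
    breaks: tuple[tuple[float, float], ...] = DEFAULT_WEIGHT_MAP
    floor: float = DEFAULT_FLOOR_WEIGHT

    def __post_init__(self) -> None:
        weights = [w for _, w in self.breaks] + [self.floor]
        if any(not 0 < w <= 1 for w in weights):
            raise ValueError("weights must lie in (0, 1]")
        if list(weights) != sorted(weights, reverse=True):
            raise ValueError("weights must be non-increasing down the percentile classes")

    def weight_for_percentile(self, pct: np.ndarray) -> np.ndarray:
        out = np.full(pct.shape, self.floor, dtype=float)
        for brk, w in sorted(self.breaks):  # ascending so higher classes overwrite
            out = np.where(pct >= brk, w, out)
        return out


@dataclass
class DesignConfig:
    n_samples: int
    min_zone_fraction: float = 0.10
    zone_allocation: Mapping[str, float] | None = None
    depth_mask_m: float | None = DEFAULT_DEPTH_MASK_M
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_zone_fraction < 1:
            raise ValueError("min_zone_fraction must lie in [0, 1)")
        if self.zone_allocation is not None:
            total = sum(self.zone_allocation.values())
            if total > 1 + 1e-9:
                raise ValueError("zone allocations must sum to at most 1")


class SampleFrame:
    """Grid of square cells with zone, depth, habitat and inclusion weight.

    ``cells`` is a DataFrame indexed by cell id with at least columns
    x, y (centroid metres), zone, mean_depth, weight.
    """

    def __init__(self, cells: pd.DataFrame, cell_size: float = DEFAULT_CELL_SIZE) -> None:
        if cell_size <= 0:
            raise ValueError("cell size must be positive")
        if cells.index.has_duplicates:
            raise ValueError("duplicate cell ids")
        cells = cells.copy()
        if "weight" not in cells.columns:
            cells["weight"] = 1.0
        if (cells["weight"] <= 0).any():
            raise ValueError("weights must be positive")
        if "zone" not in cells.columns:
            cells["zone"] = "unzoned"
        self.cells = cells
        self.cell_size = float(cell_size)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def weights(self) -> pd.Series:
        return self.cells["weight"]

    def with_weights(self, weights: pd.Series | np.ndarray) -> "SampleFrame":
        out = self.cells.copy()
        out["weight"] = np.asarray(weights, dtype=float)
        return SampleFrame(out, self.cell_size)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.cells.reset_index(names="id").to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cell_size: float = DEFAULT_CELL_SIZE) -> "SampleFrame":
        return cls(pd.read_csv(path).set_index("id"), cell_size)

    def to_geojson(self, path: str | Path,
                   selected_order: Mapping[str, int] | None = None) -> None:
        """Square Polygon per cell with properties id, zone, weight[, selected_order]."""
        h = self.cell_size / 2.0
        feats = []
        for cid, row in self.cells.iterrows():
            x, y = float(row["x"]), float(row["y"])
            ring = [[x - h, y - h], [x + h, y - h], [x + h, y + h], [x - h, y + h],
                    [x - h, y - h]]
            props = {"id": cid, "zone": row["zone"], "weight": float(row["weight"])}
            if selected_order is not None and cid in selected_order:
                props["selected_order"] = int(selected_order[cid])
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            })
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "SampleFrame":
        data = json.loads(Path(path).read_text())
        rows = {}
        side = DEFAULT_CELL_SIZE
        for feat in data["features"]:
            ring = feat["geometry"]["coordinates"][0]
            xs = [p[0] for p in ring]
            ys = [p[1] for p in ring]
            side = max(xs) - min(xs)
            props = dict(feat["properties"])
            cid = props.pop("id")
            rows[cid] = {
                "x": (max(xs) + min(xs)) / 2.0,
                "y": (max(ys) + min(ys)) / 2.0,
                **props,
            }
        return cls(pd.DataFrame.from_dict(rows, orient="index"), side)


@dataclass
class RichnessSurface:
    """Per-cell predicted or interpolated richness with a depth-mask flag."""

    values: pd.Series
    masked: pd.Series

    def __post_init__(self) -> None:
        if (self.values.loc[~self.masked] < 0).any():
            raise ValueError("surface values must be non-negative")


# ---------------------------------------------------------------------------
# Frame construction
# ---------------------------------------------------------------------------

def build_frame(
    extent: tuple[float, float, float, float] | None = None,
    cell_size: float = DEFAULT_CELL_SIZE,
    mask: pd.Series | None = None,
    zones: Mapping[str, Sequence[str]] | pd.Series | None = None,
    attributes: pd.DataFrame | None = None,
) -> SampleFrame:
    """Overlay an axis-aligned grid of square cells on a rectangular extent.

    ``extent`` is (xmin, ymin, xmax, ymax) in metres; cells are addressed by
    their lower-left corner on half-open intervals and labelled r{row}c{col}.
    ``mask`` (boolean, indexed by cell id) keeps only True cells; ``zones``
    maps zone label -> cell ids (or a per-cell Series); ``attributes`` joins
    extra per-cell columns (e.g. mean_depth, habitat variables).
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if extent is None:
        raise ValueError("an extent is required")
    xmin, ymin, xmax, ymax = extent
    nx = int(math.ceil((xmax - xmin) / cell_size - 1e-9))
    ny = int(math.ceil((ymax - ymin) / cell_size - 1e-9))
    if nx <= 0 or ny <= 0:
        raise ValueError("extent is empty")
    rows = []
    for iy in range(ny):
        for ix in range(nx):
            rows.append({
                "id": f"r{iy}c{ix}",
                "x": xmin + (ix + 0.5) * cell_size,
                "y": ymin + (iy + 0.5) * cell_size,
            })
    cells = pd.DataFrame(rows).set_index("id")
    if mask is not None:
        cells = cells.loc[mask.reindex(cells.index, fill_value=False)]
    if zones is None:
        cells["zone"] = "unzoned"
    elif isinstance(zones, pd.Series):
        cells["zone"] = zones.reindex(cells.index).fillna("unzoned")
    else:
        cells["zone"] = "unzoned"
        for label, ids in zones.items():
            cells.loc[cells.index.intersection(ids), "zone"] = label
    if attributes is not None:
        cells = cells.join(attributes, how="left")
    cells["weight"] = 1.0
    return SampleFrame(cells, cell_size)


# ---------------------------------------------------------------------------
# Inclusion weights
# ---------------------------------------------------------------------------

def assign_weights(
    frame: SampleFrame,
    mode: Literal["uniform_zone", "depth_strata", "percentile_surface"],
    zone_allocation: Mapping[str, float] | None = None,
    depth_threshold: float = 4.0,
    shallow_fraction: float = 0.75,
    surface: RichnessSurface | None = None,
    weight_map: WeightMap | None = None,
    masked_policy: Literal["min_weight", "exclude"] = "min_weight",
) -> SampleFrame:
    """Set per-cell inclusion weights by one of three schemes.

    uniform_zone
        Equal weights, or expected effort proportional to ``zone_allocation``
        (per-cell weight within a zone = allocation / cell count, rescaled
        to a maximum of 1).
    depth_strata
        Allocate ``shallow_fraction`` of effort to cells with mean depth
        below ``depth_threshold`` and the rest to deeper cells.
    percentile_surface
        Rank unmasked cells by a predicted-richness surface and map
        percentile classes to weights (highest decile most likely).
        Masked cells get the floor weight, or are dropped from the frame
        when ``masked_policy="exclude"``.
    """
    cells = frame.cells
    if mode == "uniform_zone":
        if zone_allocation is None:
            return frame.with_weights(np.ones(len(cells)))
        w = np.empty(len(cells))
        for zone, alloc in zone_allocation.items():
            sel = (cells["zone"] == zone).to_numpy()
            if not sel.any():
                raise ValueError(f"zone {zone!r} has no cells")
            w[sel] = alloc / sel.sum()
        unallocated = ~cells["zone"].isin(zone_allocation).to_numpy()
        if unallocated.any():
            raise ValueError("every zone needs an allocation in uniform_zone mode")
        return frame.with_weights(w / w.max())
    if mode == "depth_strata":
        if "mean_depth" not in cells.columns:
            raise ValueError("depth_strata mode needs a mean_depth column")
        shallow = (cells["mean_depth"] < depth_threshold).to_numpy()
        if not shallow.any() or shallow.all():
            raise ValueError("depth_strata needs both shallow and deep cells")
        w = np.where(shallow, shallow_fraction / shallow.sum(),
                     (1 - shallow_fraction) / (~shallow).sum())
        return frame.with_weights(w / w.max())
    if mode == "percentile_surface":
        if surface is None:
            raise ValueError("percentile_surface mode needs a richness surface")
        wm = weight_map or WeightMap()
        masked = surface.masked.reindex(cells.index, fill_value=True)
        vals = surface.values.reindex(cells.index)
        un = ~masked.to_numpy()
        if un.sum() == 0:
            raise ValueError("all cells are masked")
        # percentile rank over unmasked cells, "(rank-1)/n*100" so the top
        # 10% of cells land in the >=90th class exactly
        pct = np.zeros(len(cells))
        ranks = rankdata(vals.to_numpy()[un], method="ordinal")
        pct[un] = (ranks - 1) / un.sum() * 100.0
        w = wm.weight_for_percentile(pct)
        w[~un] = wm.floor
        out = frame.with_weights(w)
        if masked_policy == "exclude":
            out = SampleFrame(out.cells.loc[un], frame.cell_size)
        return out
    raise ValueError(f"unknown weighting mode {mode!r}")


# ---------------------------------------------------------------------------
# GRTS selection
# ---------------------------------------------------------------------------

def _randomized_addresses(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Quadrant-recursive randomized address for each point.

    Points are scaled into a 2^L x 2^L lattice; at every node of the
    implicit quadtree the four child quadrants are independently permuted,
    and a point's address is the concatenation of its (randomized) quadrant
    digits.  Sorting by address gives the hierarchically randomized order.
    """
    n = x.size
    span = max(x.max() - x.min(), y.max() - y.min(), 1e-9) * (1 + 1e-9)
    levels = max(1, math.ceil(math.log2(math.sqrt(n))) + 1)
    scale = (2**levels) / span
    ix = np.floor((x - x.min()) * scale).astype(np.int64)
    iy = np.floor((y - y.min()) * scale).astype(np.int64)
    ix = np.clip(ix, 0, 2**levels - 1)
    iy = np.clip(iy, 0, 2**levels - 1)
    addr = np.zeros(n, dtype=np.int64)
    node = np.zeros(n, dtype=np.int64)  # randomized-path node index per level
    for lev in range(levels):
        bit = levels - 1 - lev
        digit = ((ix >> bit) & 1) | (((iy >> bit) & 1) << 1)
        # one random permutation of the 4 quadrants per distinct node
        perms = np.argsort(rng.random((4**lev, 4)), axis=1)
        rdigit = perms[node, digit]
        addr = addr * 4 + rdigit
        node = node * 4 + rdigit
    # ties (several cells in one lattice site) broken by a random key
    return addr * n + rng.permutation(n) % n


def _reverse_hierarchical_order(k: int) -> np.ndarray:
    """Order 0..k-1 by reversed base-4 digits (reverse hierarchical order)."""
    if k <= 1:
        return np.arange(k)
    digits = max(1, math.ceil(math.log(k, 4)))
    keys = np.empty(k, dtype=np.int64)
    for i in range(k):
        v, rev = i, 0
        for _ in range(digits):
            rev = rev * 4 + v % 4
            v //= 4
        keys[i] = rev
    return np.argsort(keys, kind="stable")


def spatially_balanced_sample(
    frame: SampleFrame, n: int, seed: int = 0
) -> list[str]:
    """Draw a GRTS sample of n cells, probability proportional to weight.

    Cells are ordered by quadrant-recursive randomized addresses, then a
    systematic probability-proportional-to-size draw with a random start is
    taken along that order, so each cell's inclusion probability is exactly
    n * w_i / sum(w) (weights are rescaled if any such probability would
    exceed 1).  The result is returned in reverse hierarchical order: any
    prefix is itself a spatially balanced sample.  Deterministic per seed.
    """
    cells = frame.cells
    npos = int((cells["weight"] > 0).sum())
    if n > npos:
        raise ValueError(f"cannot select {n} cells from {npos} with positive weight")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    order = np.argsort(
        _randomized_addresses(
            cells["x"].to_numpy(float), cells["y"].to_numpy(float), rng
        )
    )
    w = cells["weight"].to_numpy(float)[order]
    pi = n * w / w.sum()
    while pi.max() > 1 + 1e-12:  # cap certainty cells and re-spread
        over = pi >= 1
        pi[over] = 1.0
        rest = n - over.sum()
        if rest <= 0:
            pi[~over] = 0.0
            break
        pi[~over] = rest * w[~over] / w[~over].sum()
    cum = np.concatenate([[0.0], np.cumsum(pi)])
    hits = rng.random() + np.arange(n)
    idx = np.searchsorted(cum, hits, side="right") - 1
    selected = order[np.clip(idx, 0, len(order) - 1)]
    ids = cells.index.to_numpy()[selected]
    return list(ids[_reverse_hierarchical_order(len(ids))])


def srs_sample(frame: SampleFrame, n: int, seed: int = 0) -> list[str]:
    """Simple random sample without replacement, probability ∝ weight.

    Baseline (not spatially balanced) used for design comparisons.
    """
    rng = np.random.default_rng(seed)
    cells = frame.cells
    w = cells["weight"].to_numpy(float)
    ids = cells.index.to_numpy()
    if n > len(ids):
        raise ValueError("n exceeds frame size")
    chosen = rng.choice(len(ids), size=n, replace=False, p=w / w.sum())
    return list(ids[chosen])


def spatial_balance_variance(frame: SampleFrame, selection: Sequence[str]) -> float:
    """Voronoi-based spatial balance metric of a selection (lower = better).

    Each frame cell is assigned to its nearest selected cell; the metric is
    the variance over selected cells of the summed inclusion probabilities
    of their Voronoi neighbourhoods.  A perfectly balanced sample gives
    every selected cell an equal share.
    """
    cells = frame.cells
    pts = cells.loc[list(selection), ["x", "y"]].to_numpy(float)
    allpts = cells[["x", "y"]].to_numpy(float)
    w = cells["weight"].to_numpy(float)
    pi = len(selection) * w / w.sum()
    _, owner = cKDTree(pts).query(allpts)
    sums = np.bincount(owner, weights=pi, minlength=len(selection))
    return float(np.var(sums))


def enforce_zone_minimum(
    selection: Sequence[str],
    frame: SampleFrame,
    min_zone_fraction: float = 0.10,
    seed: int = 0,
    basis: Literal["zone_cells", "selection"] = "zone_cells",
) -> list[str]:
    """Top up the selection so every zone meets its minimum quota.

    The minimum per zone is ceil(min_zone_fraction * zone cell count)
    (``basis="zone_cells"``, the default: a lower bound relative to the
    zone's total sample units) or ceil(min_zone_fraction * len(selection))
    (``basis="selection"``).  Deficits are filled by continuing that zone's
    own reverse-hierarchical GRTS order (a fresh zone-restricted draw with
    the given seed), so added cells remain spatially balanced within the
    zone.  The selection only grows.
    """
    cells = frame.cells
    selection = list(selection)
    selected = set(selection)
    infeasible = []
    for zone, zcells in cells.groupby("zone"):
        quota_base = len(zcells) if basis == "zone_cells" else len(selection)
        need = math.ceil(min_zone_fraction * quota_base)
        if need > len(zcells):
            infeasible.append(zone)
    if infeasible:
        raise ValueError(f"zone minimum infeasible for zones: {sorted(infeasible)}")
    out = selection
    for zone, zcells in cells.groupby("zone"):
        quota_base = len(zcells) if basis == "zone_cells" else len(selection)
        need = math.ceil(min_zone_fraction * quota_base)
        have = sum(1 for s in selection if cells.at[s, "zone"] == zone)
        if have >= need:
            continue
        zframe = SampleFrame(zcells, frame.cell_size)
        reserve = [c for c in spatially_balanced_sample(zframe, len(zcells), seed)
                   if c not in selected]
        extra = reserve[: need - have]
        out = out + extra
        selected.update(extra)
    return out


# ---------------------------------------------------------------------------
# Richness surface interpolation
# ---------------------------------------------------------------------------

def interpolate_richness(
    observed: Mapping[str, float] | pd.Series,
    frame: SampleFrame,
    method: Literal["idw", "ordinary_kriging"] = "idw",
    power: float = 2.0,
    depth_mask_m: float | None = DEFAULT_DEPTH_MASK_M,
) -> RichnessSurface:
    """Interpolate observed per-cell richness onto the whole frame.

    IDW (inverse-distance weighting, default power 2) is the reference
    method and an exact interpolator at observed cells; ordinary kriging
    with an exponential variogram is optional.  Cells with mean depth
    greater than ``depth_mask_m`` are flagged masked (no percentile class
    downstream); pass None to disable the mask for sites that are not
    depth limited.
    """
    obs = pd.Series(dict(observed), dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 observed cells")
    missing = set(obs.index) - set(frame.cells.index)
    if missing:
        raise ValueError(f"observed cells not in frame: {sorted(missing)}")
    cells = frame.cells
    pts = cells.loc[obs.index, ["x", "y"]].to_numpy(float)
    vals = obs.to_numpy(float)
    targets = cells[["x", "y"]].to_numpy(float)
    if np.ptp(vals) == 0:
        pred = np.full(len(cells), vals[0])
    elif method == "idw":
        d = np.sqrt(((targets[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        exact = d < 1e-9
        with np.errstate(divide="ignore"):
            wts = 1.0 / d**power
        wts[exact.any(axis=1)] = 0.0
        pred = np.where(
            exact.any(axis=1),
            vals[np.argmin(np.where(exact, 0.0, np.inf), axis=1)],
            (wts @ vals) / np.clip(wts.sum(axis=1), 1e-300, None),
        )
    elif method == "ordinary_kriging":
        pred = _ordinary_kriging(pts, vals, targets)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    pred = np.clip(pred, 0.0, None)
    values = pd.Series(pred, index=cells.index)
    if depth_mask_m is not None and "mean_depth" in cells.columns:
        masked = cells["mean_depth"] > depth_mask_m
    else:
        masked = pd.Series(False, index=cells.index)
    return RichnessSurface(values=values, masked=masked)


def _exp_variogram(h: np.ndarray, nugget: float, sill: float, rng_: float) -> np.ndarray:
    return nugget + sill * (1.0 - np.exp(-h / np.maximum(rng_, 1e-9)))


def _ordinary_kriging(pts: np.ndarray, vals: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Ordinary kriging with a least-squares exponential variogram fit."""
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(len(pts), k=1)
    h, sv = d[iu], 0.5 * (vals[iu[0]] - vals[iu[1]]) ** 2
    # bin the empirical semivariogram to stabilise the fit
    nbins = min(12, max(4, h.size // 5))
    edges = np.linspace(0, h.max() * (1 + 1e-9), nbins + 1)
    which = np.digitize(h, edges) - 1
    hb, svb = [], []
    for b in range(nbins):
        msk = which == b
        if msk.any():
            hb.append(h[msk].mean())
            svb.append(sv[msk].mean())
    hb, svb = np.asarray(hb), np.asarray(svb)
    try:
        p0 = (0.0, max(svb.max(), 1e-9), max(hb.mean(), 1e-9))
        popt, _ = curve_fit(
            _exp_variogram, hb, svb, p0=p0,
            bounds=([0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError:
        popt = (0.0, float(np.var(vals)), float(max(hb.mean(), 1e-9)))
    gamma = _exp_variogram(d, *popt)
    k = len(pts)
    A = np.ones((k + 1, k + 1))
    A[:k, :k] = gamma
    A[k, k] = 0.0
    dt = np.sqrt(((targets[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    B = np.ones((targets.shape[0], k + 1))
    B[:, :k] = _exp_variogram(dt, *popt)
    try:
        lam = np.linalg.solve(A, B.T)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(A, B.T, rcond=None)[0]
    return lam[:k].T @ vals


# ---------------------------------------------------------------------------
# Design summary
# ---------------------------------------------------------------------------

def design_summary(frame: SampleFrame, selection: Sequence[str]) -> pd.DataFrame:
    """Per-zone spatial coverage of the design: cells, surveyed, proportion, area.

    Areas are in hectares (cells x cell_size^2 / 10^4).
    """
    cells = frame.cells
    sel = set(selection)
    rows = []
    for zone, zcells in cells.groupby("zone", sort=True):
        n = len(zcells)
        surveyed = sum(1 for c in zcells.index if c in sel)
        rows.append({
            "zone": zone,
            "cells": n,
            "cells_surveyed": surveyed,
            "proportion_surveyed": surveyed / n if n else 0.0,
            "area_ha": n * frame.cell_size**2 / 1e4,
        })
    return pd.DataFrame(rows).set_index("zone")
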
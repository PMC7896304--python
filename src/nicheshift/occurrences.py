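"""Presence/pseudoabsence preparation.

Turns range inputs into modelling-ready occurrence tables:

* range polygons are rasterized to presence cells at a 10% cell-overlap
  threshold after keeping only extant, native, breeding/resident
  sub-polygons (presence code 1-2, origin code 1, seasonality code 1-2);
* species present in fewer than 10 grid cells are excluded as
  range-restricted;
* 1,000 pseudoabsence cells are sampled uniformly without replacement from
  the zoogeographic realm(s) in which the species occurs, never falling on
  a presence cell (if fewer are available, all eligible cells are taken
  and the shortfall logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry

from .world.climate import ClimateGrid
from .world.grid import Cell, GridSpec
from .world.regions import RegionMaps
from .world.species import SpeciesRecord

logger = logging.getLogger(__name__)

OVERLAP_THRESHOLD = 0.10
MIN_PRESENCE_CELLS = 10
N_PSEUDOABSENCES = 1000

KEEP_PRESENCE_CODES = (1, 2)
KEEP_ORIGIN_CODES = (1,)
KEEP_SEASONAL_CODES = (1, 2)


@dataclass
class OccurrenceTable:
    """Modelling table for one species.

    ``data`` columns: row, col, label (1 presence / 0 pseudoabsence),
    block (pandas nullable Int64, filled by the blocking stage), then one
    column per climate variable.
    """

    species_id: str
    data: pd.DataFrame

    @property
    def n_presences(self) -> int:
        return int((self.data["label"] == 1).sum())

    @property
    def n_pseudoabsences(self) -> int:
        return int((self.data["label"] == 0).sum())

    def design(self, variables: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) matrices for the given predictor variables."""
        X = self.data[list(variables)].to_numpy(dtype=float)
        y = self.data["label"].to_numpy(dtype=int)
        return X, y


def _cell_polygon(grid: GridSpec, row: int, col: int):
    # map coordinates: x along columns, y increasing northwards
    y_top = grid.n_rows - row
    return box(col, y_top - 1, col + 1, y_top)


def rasterize_range(
    features: list[dict] | dict,
    grid: GridSpec,
    species_id: str = "?",
) -> set[Cell]:
    """Rasterize coded range polygons to presence cells.

    ``features`` is a GeoJSON FeatureCollection (or list of features) whose
    properties carry integer ``presence``, ``origin`` and ``seasonal``
    codes.  A cell is presence when the retained sub-polygons cover at
    least 10% of its area.  Geometry coordinates are in map units where one
    cell is the unit square (column index eastwards, row 0 the top row).
    """
    if isinstance(features, dict):
        features = features.get("features", [features])
    geoms = []
    for f in features:
        props = f.get("properties", {})
        if (
            props.get("presence") in KEEP_PRESENCE_CODES
            and props.get("origin") in KEEP_ORIGIN_CODES
            and props.get("seasonal") in KEEP_SEASONAL_CODES
        ):
            geom = f["geometry"]
            g = geom if isinstance(geom, BaseGeometry) else shape(geom)
            if not g.is_valid:
                raise ValueError(
                    f"invalid range geometry for species {species_id}"
                )
            geoms.append(g)
    if not geoms:
        return set()
    from shapely.ops import unary_union

    merged = unary_union(geoms)
    out: set[Cell] = set()
    minx, miny, maxx, maxy = merged.bounds
    r_hi = min(grid.n_rows, int(np.ceil(grid.n_rows - miny)))
    r_lo = max(0, int(np.floor(grid.n_rows - maxy)))
    c_lo = max(0, int(np.floor(minx)))
    c_hi = min(grid.n_cols, int(np.ceil(maxx)))
    for r in range(r_lo, r_hi):
        for c in range(c_lo, c_hi):
            cell = _cell_polygon(grid, r, c)
            frac = merged.intersection(cell).area / cell.area
            if frac >= OVERLAP_THRESHOLD - 1e-12:
                out.add((r, c))
    return out


def filter_restricted(
    species: list[SpeciesRecord],
    min_cells: int = MIN_PRESENCE_CELLS,
) -> tuple[list[SpeciesRecord], pd.DataFrame]:
    """Drop range-restricted species (fewer than ``min_cells`` presences).

    Returns the retained list and an exclusion report with one row per
    excluded species (columns: species_id, n_cells, reason).
    """
    kept, rows = [], []
    for sp in species:
        n = len(sp.presence_cells)
        if n >= min_cells:
            kept.append(sp)
        else:
            rows.append(
                {
                    "species_id": sp.species_id,
                    "n_cells": n,
                    "reason": "empty_range" if n == 0 else "range_restricted",
                }
            )
    report = pd.DataFrame(rows, columns=["species_id", "n_cells", "reason"])
    return kept, report


def occupied_realms(sp: SpeciesRecord, regions: RegionMaps) -> tuple[int, ...]:
    """Realms containing at least one presence cell."""
    arr = sp.presence_array()
    return tuple(sorted(set(
        int(v) for v in regions.realm_of[arr[:, 0], arr[:, 1]]
    )))


def sample_pseudoabsences(
    sp: SpeciesRecord,
    regions: RegionMaps,
    climate: ClimateGrid,
    n: int = N_PSEUDOABSENCES,
    seed: int = 0,
    variables: tuple[str, ...] | None = None,
) -> OccurrenceTable:
    """Build the occurrence table: presences plus realm-constrained
    pseudoabsences with climate values attached.

    Pseudoabsence cells are drawn uniformly without replacement from cells
    of the species' occupied realm(s), excluding its presence cells.
    """
    variables = variables or tuple(climate.layers)
    realms = occupied_realms(sp, regions)
    realm_mask = np.isin(regions.realm_of, realms)
    pres = sp.presence_array()
    pres_mask = np.zeros(regions.grid.shape, dtype=bool)
    pres_mask[pres[:, 0], pres[:, 1]] = True
    eligible = realm_mask & ~pres_mask
    er, ec = np.nonzero(eligible)
    if len(er) == 0:
        raise ValueError(
            f"species {sp.species_id}: no eligible pseudoabsence cells "
            f"in realm(s) {realms}"
        )
    # canonical cell order, then a seeded draw: invariant to enumeration order
    order = np.lexsort((ec, er))
    er, ec = er[order], ec[order]
    rng = np.random.default_rng(seed)
    if len(er) < n:
        logger.info(
            "species %s: pseudoabsence shortfall, %d eligible < %d requested",
            sp.species_id, len(er), n,
        )
        take = np.arange(len(er))
    else:
        take = rng.choice(len(er), size=n, replace=False)
    ar, ac = er[take], ec[take]

    rows = np.concatenate([pres[:, 0], ar])
    cols = np.concatenate([pres[:, 1], ac])
    labels = np.concatenate([np.ones(len(pres), int), np.zeros(len(ar), int)])
    data = pd.DataFrame({"row": rows, "col": cols, "label": labels})
    data["block"] = pd.array([pd.NA] * len(data), dtype="Int64")
    vals = climate.values_at(rows, cols, variables)
    for j, v in enumerate(variables):
        data[v] = vals[:, j]
    return OccurrenceTable(species_id=sp.species_id, data=data)
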
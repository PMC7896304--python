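"""Spatially disaggregated blocking for cross-validation.

Noncontiguous ecoregion portions (fragments) are the sampling units; they
are grouped into 10 blocks so that total area and mean bioclimate are
approximately equal across blocks.  Grouping is a greedy balancing pass:
fragments sorted by area descending are assigned one by one to the block
that minimizes a weighted imbalance score combining the spread of block
areas and of area-weighted climate means (each variable standardized).
Blocks are global — shared by every species; a species' folds are the
intersection of its occurrence rows with each block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import OccurrenceTable
from .world.climate import ClimateGrid
from .world.regions import RegionMaps

logger = logging.getLogger(__name__)

N_BLOCKS = 10


@dataclass
class BlockAssignment:
    """fragment id -> block id, with per-block summaries."""

    block_of: dict[int, int]
    n_blocks: int
    summaries: pd.DataFrame  # per block: n_cells, area, mean climate
    imbalance: float

    def block_map(self, regions: RegionMaps) -> np.ndarray:
        """(n_rows, n_cols) array of block ids."""
        out = np.full(regions.grid.shape, -1, dtype=int)
        for frag, blk in self.block_of.items():
            out[regions.fragment_of == frag] = blk
        return out


def build_fragments(
    regions: RegionMaps, climate: ClimateGrid,
    variables: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-fragment area and mean climate from the current grid.

    Returns a table with fragment_id, ecoregion, n_cells, area and one
    ``mean_<var>`` column per climate variable.
    """
    variables = variables or tuple(climate.layers)
    rows = []
    for frag in range(regions.n_fragments):
        mask = regions.fragment_of == frag
        n = int(mask.sum())
        if n == 0:
            continue
        row = {
            "fragment_id": frag,
            "ecoregion": int(regions.ecoregion_of[mask][0]),
            "n_cells": n,
            "area": n * regions.grid.cell_area,
        }
        for v in variables:
            row[f"mean_{v}"] = float(climate.layers[v][mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def imbalance_score(
    fragments: pd.DataFrame,
    block_of: dict[int, int],
    n_blocks: int,
    area_weight: float = 1.0,
    climate_weight: float = 1.0,
) -> float:
    """Weighted imbalance of a candidate assignment.

    Area term: coefficient of variation of block total areas.  Climate
    term: per variable, the standard deviation across blocks of the
    area-weighted block climate mean, in units of the between-fragment
    standard deviation of that variable; averaged over variables.
    """
    mean_cols = [c for c in fragments.columns if c.startswith("mean_")]
    areas = np.zeros(n_blocks)
    wsum = {c: np.zeros(n_blocks) for c in mean_cols}
    for _, fr in fragments.iterrows():
        b = block_of[int(fr["fragment_id"])]
        areas[b] += fr["area"]
        for c in mean_cols:
            wsum[c][b] += fr["area"] * fr[c]
    if np.any(areas == 0):
        return np.inf
    area_term = areas.std() / areas.mean()
    climate_terms = []
    for c in mean_cols:
        block_means = wsum[c] / areas
        sd = fragments[c].std()
        if sd == 0 or not np.isfinite(sd):
            continue
        climate_terms.append(block_means.std() / sd)
    climate_term = float(np.mean(climate_terms)) if climate_terms else 0.0
    return area_weight * area_term + climate_weight * climate_term


def assign_blocks(
    fragments: pd.DataFrame,
    n_blocks: int = N_BLOCKS,
    seed: int = 0,
    area_weight: float = 1.0,
    climate_weight: float = 1.0,
    envelope_coverage: float = 0.8,
) -> BlockAssignment:
    """Greedy balanced grouping of fragments into blocks.

    Fragments are sorted by area descending (seeded shuffle breaks exact
    area ties) and each is placed in the block whose resulting imbalance
    score is smallest.  After assignment, each block's climate min-max
    envelope is checked to cover at least ``envelope_coverage`` of the
    global envelope per variable; shortfalls are logged, not fatal.
    """
    if len(fragments) < n_blocks:
        raise ValueError(
            f"only {len(fragments)} fragments for {n_blocks} blocks; "
            "use coarser ecoregions or fewer blocks"
        )
    mean_cols = [c for c in fragments.columns if c.startswith("mean_")]
    rng = np.random.default_rng(seed)
    frags = fragments.sample(frac=1.0, random_state=rng.integers(2**31)) \
        .sort_values("area", ascending=False, kind="stable")

    areas = np.zeros(n_blocks)
    wsum = np.zeros((n_blocks, len(mean_cols)))
    sds = np.array([
        fragments[c].std() if fragments[c].std() > 0 else 1.0
        for c in mean_cols
    ])
    block_of: dict[int, int] = {}
    # seed every block with one of the n_blocks largest fragments, so no
    # block stays empty; then place the rest greedily
    seeded = 0
    for _, fr in frags.iterrows():
        fid = int(fr["fragment_id"])
        a = fr["area"]
        cl = fr[mean_cols].to_numpy(dtype=float)
        if seeded < n_blocks:
            block_of[fid] = seeded
            areas[seeded] += a
            wsum[seeded] += a * cl
            seeded += 1
            continue
        best_b, best_score = None, None
        for b in range(n_blocks):
            areas[b] += a
            wsum[b] += a * cl
            # incremental score: CV of areas over all blocks (empty blocks
            # penalized) + mean normalized sd of nonempty-block climate means
            area_term = areas.std() / areas.mean()
            nz = areas > 0
            bm = wsum[nz] / areas[nz, None]
            climate_term = float(np.mean(bm.std(axis=0) / sds)) if nz.sum() > 1 else 0.0
            score = area_weight * area_term + climate_weight * climate_term
            areas[b] -= a
            wsum[b] -= a * cl
            if best_score is None or score < best_score - 1e-12:
                best_b, best_score = b, score
        block_of[fid] = best_b
        areas[best_b] += a
        wsum[best_b] += a * cl

    # summaries and envelope check
    rows = []
    for b in range(n_blocks):
        fids = [f for f, bb in block_of.items() if bb == b]
        sub = fragments[fragments["fragment_id"].isin(fids)]
        row = {"block": b, "n_fragments": len(fids),
               "n_cells": int(sub["n_cells"].sum()),
               "area": float(sub["area"].sum())}
        for c in mean_cols:
            w = sub["area"].to_numpy()
            row[c] = float(np.average(sub[c], weights=w)) if len(sub) else np.nan
        rows.append(row)
    summaries = pd.DataFrame(rows)
    for c in mean_cols:
        glo = fragments[c].max() - fragments[c].min()
        if glo <= 0:
            continue
        for b in range(n_blocks):
            fids = [f for f, bb in block_of.items() if bb == b]
            sub = fragments[fragments["fragment_id"].isin(fids)]
            cov = (sub[c].max() - sub[c].min()) / glo
            if cov < envelope_coverage:
                logger.info(
                    "block %d covers %.0f%% of the %s envelope "
                    "(target %.0f%%)", b, 100 * cov, c,
                    100 * envelope_coverage,
                )
    score = imbalance_score(fragments, block_of, n_blocks,
                            area_weight, climate_weight)
    return BlockAssignment(
        block_of=block_of, n_blocks=n_blocks,
        summaries=summaries, imbalance=score,
    )


def label_occurrences(
    table: OccurrenceTable,
    assignment: BlockAssignment,
    regions: RegionMaps,
) -> OccurrenceTable:
    """Attach each occurrence row's fragment's block id."""
    rows = table.data["row"].to_numpy()
    cols = table.data["col"].to_numpy()
    frags = regions.fragment_of[rows, cols]
    blocks = np.array([assignment.block_of[int(f)] for f in frags])
    data = table.data.copy()
    data["block"] = pd.array(blocks, dtype="Int64")
    return OccurrenceTable(species_id=table.species_id, data=data)
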
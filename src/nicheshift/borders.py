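"""Transboundary and border-barrier statistics.

All statistics reduce to set logic over (species, border) pairs:

* a species *bisects* border (A, B) when it has at least one observed
  presence cell in each of A and B;
* a species *shifts* across (A, B) when it currently occupies exactly one
  side (say A) and its projected future niche gains at least one cell in
  the other, currently unoccupied, country B — counted once per border,
  in either direction;
* a nonflying mammal is *barrier-blocked* when its shift condition holds
  on at least one fortified border.

"Current" occupancy always means the observed range raster, not the
modelled current niche.  Equal-area cells make cell counts proportional
to area, so all fractions are cell-count ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble.model import EnsembleProjection
from .world.regions import BorderGraph, RegionMaps
from .world.species import SpeciesRecord

logger = logging.getLogger(__name__)


def current_country_set(
    sp: SpeciesRecord, regions: RegionMaps
) -> tuple[set[int], bool]:
    """Countries holding >= 1 presence cell; flag = transboundary (>= 2)."""
    arr = sp.presence_array()
    if len(arr) == 0:
        raise ValueError(f"species {sp.species_id} has no presence cells")
    cs = {int(c) for c in regions.country_of[arr[:, 0], arr[:, 1]]}
    return cs, len(cs) >= 2


def species_by_country(
    species: list[SpeciesRecord], regions: RegionMaps
) -> dict[int, set[str]]:
    """country id -> set of species ids with >= 1 presence cell there."""
    out: dict[int, set[str]] = {c: set() for c in range(regions.n_countries)}
    for sp in species:
        cs, _ = current_country_set(sp, regions)
        for c in cs:
            out[c].add(sp.species_id)
    return out


def border_bisection_counts(
    species: list[SpeciesRecord],
    graph: BorderGraph,
    regions: RegionMaps,
) -> pd.DataFrame:
    """Per-border counts of bisecting species and bisecting threatened
    species; a species bisects (A, B) iff it occurs in both A and B."""
    country_sets = {
        sp.species_id: current_country_set(sp, regions)[0] for sp in species
    }
    threatened = {sp.species_id for sp in species if sp.is_threatened}
    rows = []
    for a, b in sorted(graph.borders):
        bis = [
            sid for sid, cs in country_sets.items() if a in cs and b in cs
        ]
        rows.append(
            {
                "border_id": graph.border_id(a, b),
                "country_a": a,
                "country_b": b,
                "barrier": bool(graph.graph.edges[a, b]["barrier"]),
                "n_bisecting": len(bis),
                "n_bisecting_threatened": sum(
                    1 for s in bis if s in threatened
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["border_id", "country_a", "country_b", "barrier",
                 "n_bisecting", "n_bisecting_threatened"],
    )


def transboundary_richness_fraction(
    stats: pd.DataFrame,
    species: list[SpeciesRecord],
    regions: RegionMaps,
) -> pd.DataFrame:
    """Add ``bisecting_fraction``: bisecting species over the distinct
    species found in either country of the border."""
    by_country = species_by_country(species, regions)
    fracs = []
    for _, row in stats.iterrows():
        pool = by_country.get(int(row["country_a"]), set()) | by_country.get(
            int(row["country_b"]), set()
        )
        fracs.append(row["n_bisecting"] / len(pool) if pool else np.nan)
    out = stats.copy()
    out["bisecting_fraction"] = fracs
    return out


@dataclass
class SpeciesShiftProfile:
    """Where one species' projected niche sits relative to its countries."""

    species_id: str
    scenario_id: str | None
    current_countries: set[int]
    future_cells_by_country: dict[int, int]
    new_country_fraction: float | None  # None when the future niche is empty
    niche_lost: bool = False
    shifted_borders: set[tuple[int, int]] = field(default_factory=set)
    blocked_borders: set[tuple[int, int]] = field(default_factory=set)
    unattributed_jumps: set[int] = field(default_factory=set)


def new_country_fraction(
    sp: SpeciesRecord,
    projection: EnsembleProjection,
    regions: RegionMaps,
) -> SpeciesShiftProfile:
    """Fraction of future-occupied cells in countries where the species is
    not currently found; flags the species "niche lost" when the future
    map is empty."""
    cur, _ = current_country_set(sp, regions)
    rr, cc = np.nonzero(projection.binary)
    counts: dict[int, int] = {}
    for c in regions.country_of[rr, cc]:
        counts[int(c)] = counts.get(int(c), 0) + 1
    total = sum(counts.values())
    if total == 0:
        logger.info("species %s: empty future niche (%s)",
                    sp.species_id, projection.scenario_id)
        return SpeciesShiftProfile(
            species_id=sp.species_id,
            scenario_id=projection.scenario_id,
            current_countries=cur,
            future_cells_by_country={},
            new_country_fraction=None,
            niche_lost=True,
        )
    new = sum(n for c, n in counts.items() if c not in cur)
    return SpeciesShiftProfile(
        species_id=sp.species_id,
        scenario_id=projection.scenario_id,
        current_countries=cur,
        future_cells_by_country=counts,
        new_country_fraction=new / total,
    )


def new_country_shares(
    profiles: list[SpeciesShiftProfile],
    thresholds: tuple[float, float] = (0.5, 0.2),
) -> dict[str, float]:
    """Summary shares of species whose new-country fraction exceeds 0.5
    (strict) and reaches at least 0.2, over species with a defined
    fraction."""
    defined = [p.new_country_fraction for p in profiles
               if p.new_country_fraction is not None]
    if not defined:
        return {"share_over_half": np.nan, "share_at_least_fifth": np.nan,
                "n_defined": 0}
    arr = np.array(defined)
    hi, lo = thresholds
    return {
        "share_over_half": float((arr > hi).mean()),
        "share_at_least_fifth": float((arr >= lo).mean()),
        "n_defined": len(arr),
    }


def attach_border_shifts(
    profile: SpeciesShiftProfile,
    graph: BorderGraph,
) -> SpeciesShiftProfile:
    """Resolve which borders a species' projected shift crosses.

    Border (A, B) is crossed when one country is currently occupied, the
    other is not, the unoccupied one gains >= 1 future cell, and the two
    are graph-adjacent.  Gained countries not adjacent to any currently
    occupied country are recorded as unattributed jumps.  Barrier-flagged
    crossed borders populate ``blocked_borders``.
    """
    gained = {
        c for c, n in profile.future_cells_by_country.items()
        if n > 0 and c not in profile.current_countries
    }
    shifted, blocked = set(), set()
    attributed: set[int] = set()
    for a, b in graph.borders:
        ina, inb = a in profile.current_countries, b in profile.current_countries
        if ina == inb:
            continue
        new_side = b if ina else a
        if new_side in gained:
            shifted.add((a, b))
            attributed.add(new_side)
            if graph.graph.edges[a, b]["barrier"]:
                blocked.add((a, b))
    profile.shifted_borders = shifted
    profile.blocked_borders = blocked
    profile.unattributed_jumps = gained - attributed
    return profile


def per_border_shift_counts(
    species: list[SpeciesRecord],
    projections: dict[str, EnsembleProjection],
    graph: BorderGraph,
    regions: RegionMaps,
) -> tuple[pd.DataFrame, list[SpeciesShiftProfile]]:
    """Count species whose niches shift across each border (either
    direction, once per species per border).

    ``projections`` maps species_id to that species' future projection.
    Returns the per-border table plus the per-species profiles.
    """
    profiles = []
    for sp in species:
        proj = projections.get(sp.species_id)
        if proj is None:
            continue
        prof = new_country_fraction(sp, proj, regions)
        profiles.append(attach_border_shifts(prof, graph))
    rows = []
    for a, b in sorted(graph.borders):
        n = sum(1 for p in profiles if (a, b) in p.shifted_borders)
        rows.append(
            {
                "border_id": graph.border_id(a, b),
                "country_a": a,
                "country_b": b,
                "barrier": bool(graph.graph.edges[a, b]["barrier"]),
                "n_shift_species": n,
            }
        )
    return (
        pd.DataFrame(rows, columns=["border_id", "country_a", "country_b",
                                    "barrier", "n_shift_species"]),
        profiles,
    )


def normalized_shift_counts(
    shift_stats: pd.DataFrame,
    species: list[SpeciesRecord],
    regions: RegionMaps,
) -> pd.DataFrame:
    """Add ``normalized_shift``: shifts over the distinct current species
    richness of the two countries combined."""
    by_country = species_by_country(species, regions)
    vals = []
    for _, row in shift_stats.iterrows():
        pool = by_country.get(int(row["country_a"]), set()) | by_country.get(
            int(row["country_b"]), set()
        )
        vals.append(row["n_shift_species"] / len(pool) if pool else np.nan)
    out = shift_stats.copy()
    out["normalized_shift"] = vals
    return out


def barrier_blocked_species(
    species: list[SpeciesRecord],
    projections: dict[str, EnsembleProjection],
    graph: BorderGraph,
    regions: RegionMaps,
) -> dict:
    """Border-barrier analysis for nonflying mammals.

    Returns a dict with: ``bisection`` — current-range bisection counts
    restricted to barrier borders; ``blocked_species`` — ids whose shift
    condition holds on >= 1 barrier border; ``per_barrier`` — blocked
    counts per barrier border.  Flying species never enter.
    """
    terrestrial = [sp for sp in species if sp.is_nonflying_mammal]
    barrier_edges = set(graph.barrier_edges())
    if not barrier_edges:
        logger.warning("no barrier borders in the graph; empty result")
        empty = pd.DataFrame(
            columns=["border_id", "country_a", "country_b", "barrier",
                     "n_bisecting", "n_bisecting_threatened"]
        )
        return {"bisection": empty, "blocked_species": set(),
                "per_barrier": pd.DataFrame(
                    columns=["border_id", "country_a", "country_b",
                             "n_blocked"]),
                "n_nonflying_mammals": len(terrestrial)}
    bis = border_bisection_counts(terrestrial, graph, regions)
    bis = bis[bis["barrier"]].reset_index(drop=True)
    _, profiles = per_border_shift_counts(
        terrestrial, projections, graph, regions
    )
    blocked = {p.species_id for p in profiles if p.blocked_borders}
    rows = []
    for a, b in sorted(barrier_edges):
        n = sum(1 for p in profiles if (a, b) in p.blocked_borders)
        rows.append({"border_id": graph.border_id(a, b), "country_a": a,
                     "country_b": b, "n_blocked": n})
    return {
        "bisection": bis,
        "blocked_species": blocked,
        "per_barrier": pd.DataFrame(
            rows, columns=["border_id", "country_a", "country_b", "n_blocked"]
        ),
        "n_nonflying_mammals": len(terrestrial),
    }
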
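"""Virtual species with known Gaussian climatic niches.

Each species' suitability is a product of independent Gaussian response
curves over a random subset of "true" climate variables:

    suit(cell) = exp( -sum_v (x_v(cell) - opt_v)^2 / (2 * breadth_v^2) )

Optima are drawn from the interior quantiles of the variable's current
distribution; breadths are expressed in units of the variable's spatial
standard deviation.  The species occupies exactly the cells of its home
realm(s) whose suitability reaches a prevalence-calibrated quantile cutoff,
so presences are a deterministic function of the stored truth — the ground
truth the recovery tests exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .climate import ClimateGrid
from .grid import Cell
from .regions import RegionMaps

logger = logging.getLogger(__name__)

#: variables a species' truth may draw on (the niche-defining set)
DEFAULT_TRUTH_VARS = (
    "temp_mean",
    "temp_seasonality",
    "prec_wettest",
    "prec_driest",
    "prec_seasonality",
)


@dataclass
class NicheTruth:
    """Known suitability function of a synthetic species."""

    optima: dict[str, float]
    breadths: dict[str, float]
    cutoff: float
    realms: tuple[int, ...]

    def suitability(self, climate: ClimateGrid) -> np.ndarray:
        """Per-cell suitability in (0, 1] under the given climate."""
        z = np.zeros(climate.grid.shape)
        for v, opt in self.optima.items():
            z += (climate.layers[v] - opt) ** 2 / (2.0 * self.breadths[v] ** 2)
        return np.exp(-z)

    def occupancy(self, climate: ClimateGrid, regions: RegionMaps) -> np.ndarray:
        """True binary occupancy: super-cutoff suitability within home realms."""
        mask = np.isin(regions.realm_of, self.realms)
        return (self.suitability(climate) >= self.cutoff) & mask


@dataclass
class SpeciesRecord:
    species_id: str
    taxon_group: str  # "bird" | "mammal"
    tags: frozenset[str] = frozenset()  # subset of {flying, nonflying, threatened}
    presence_cells: set[Cell] = field(default_factory=set)
    truth: NicheTruth | None = None

    @property
    def is_threatened(self) -> bool:
        return "threatened" in self.tags

    @property
    def is_nonflying_mammal(self) -> bool:
        return self.taxon_group == "mammal" and "nonflying" in self.tags

    def presence_array(self) -> np.ndarray:
        """(n, 2) array of presence (row, col), sorted for determinism."""
        return np.array(sorted(self.presence_cells), dtype=int).reshape(-1, 2)


def gen_species(
    climate: ClimateGrid,
    regions: RegionMaps,
    n_species: int = 20,
    niche_breadth_range: tuple[float, float] = (0.6, 1.4),
    prevalence_range: tuple[float, float] = (0.1, 0.4),
    seed: int = 0,
    n_truth_vars: tuple[int, int] = (1, 2),
    truth_vars: tuple[str, ...] = DEFAULT_TRUTH_VARS,
    min_presences: int = 10,
    bird_fraction: float = 0.5,
    bat_fraction: float = 0.1,
    threatened_fraction: float = 0.2,
    max_retries: int = 20,
) -> list[SpeciesRecord]:
    """Generate virtual species on the current climate.

    ``prevalence_range`` bounds the fraction of home-realm cells occupied.
    Species whose calibrated range falls below ``min_presences`` cells are
    regenerated up to ``max_retries`` times, then reported and dropped.
    """
    if climate.epoch != "current":
        raise ValueError("species must be generated on the current climate")
    rng = np.random.default_rng(seed)
    out: list[SpeciesRecord] = []
    i = 0
    while len(out) < n_species:
        attempts = 0
        rec = None
        while attempts < max_retries:
            attempts += 1
            k = int(rng.integers(n_truth_vars[0], n_truth_vars[1] + 1))
            vars_ = tuple(rng.choice(truth_vars, size=k, replace=False))
            optima, breadths = {}, {}
            for v in vars_:
                lay = climate.layers[v]
                optima[v] = float(np.quantile(lay, rng.uniform(0.25, 0.75)))
                breadths[v] = float(
                    max(lay.std() * rng.uniform(*niche_breadth_range), 1e-6)
                )
            truth = NicheTruth(optima=optima, breadths=breadths, cutoff=0.0,
                               realms=())
            suit = truth.suitability(climate)
            # home realm = the realm holding the most suitable cell
            best = np.unravel_index(int(np.argmax(suit)), suit.shape)
            home = int(regions.realm_of[best])
            truth.realms = (home,)
            realm_mask = regions.realm_of == home
            prevalence = float(rng.uniform(*prevalence_range))
            truth.cutoff = float(
                np.quantile(suit[realm_mask], 1.0 - prevalence)
            )
            occ = truth.occupancy(climate, regions)
            if occ.sum() >= min_presences:
                rr, cc = np.nonzero(occ)
                taxon = "bird" if rng.uniform() < bird_fraction else "mammal"
                tags = set()
                if taxon == "bird" or rng.uniform() < bat_fraction:
                    tags.add("flying")
                else:
                    tags.add("nonflying")
                if rng.uniform() < threatened_fraction:
                    tags.add("threatened")
                rec = SpeciesRecord(
                    species_id=f"sp{i:04d}",
                    taxon_group=taxon,
                    tags=frozenset(tags),
                    presence_cells={(int(r), int(c)) for r, c in zip(rr, cc)},
                    truth=truth,
                )
                break
        if rec is None:
            logger.warning(
                "species slot %d: empty range after %d retries; skipped",
                i, max_retries,
            )
        else:
            out.append(rec)
        i += 1
        if i > n_species * (max_retries + 1):
            break
    return out
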
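"""Synthetic realms, ecoregions, fragments, countries and borders.

Realms are contiguous latitudinal bands.  Within each realm, ecoregions are
grown from several seeded nuclei by nearest-seed assignment, with more
nuclei than ecoregion labels so that single ecoregions recur as disjoint
patches — the "noncontiguous portions" that later become the spatial
blocking units.  Countries partition the whole grid by nearest-seed
assignment.  The border graph connects every pair of countries that share
at least one 4-adjacent cell pair, and a configurable fraction of borders
carries a fortification barrier flag.

4-connectivity defines both fragment contiguity and country adjacency
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .grid import GridSpec


@dataclass
class RegionMaps:
    """Per-cell region labels; each map is an (n_rows, n_cols) int array."""

    grid: GridSpec
    realm_of: np.ndarray
    ecoregion_of: np.ndarray
    fragment_of: np.ndarray
    country_of: np.ndarray

    @property
    def n_countries(self) -> int:
        return int(self.country_of.max()) + 1

    @property
    def n_fragments(self) -> int:
        return int(self.fragment_of.max()) + 1

    def country_latitudes(self):
        """Mean pseudo-latitude per country, as a dict country -> degrees."""
        lat = self.grid.latitude_field()
        out = {}
        for c in range(self.n_countries):
            mask = self.country_of == c
            out[c] = float(lat[mask].mean())
        return out


@dataclass
class BorderGraph:
    """Country adjacency with per-border identity and barrier flags.

    Wraps a :class:`networkx.Graph` whose edges carry ``border_id``,
    ``barrier`` (bool) and ``cell_pairs`` — the list of 4-adjacent cell
    pairs ``((r1, c1), (r2, c2))`` spanning the two countries.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def borders(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def barrier_edges(self) -> list[tuple[int, int]]:
        return [
            tuple(sorted(e))
            for e, d in self.graph.edges.items()
            if d["barrier"]
        ]

    def border_id(self, a: int, b: int) -> str:
        return self.graph.edges[a, b]["border_id"]


def _nearest_seed_labels(
    rows: np.ndarray, cols: np.ndarray, seeds: np.ndarray
) -> np.ndarray:
    """Label each (row, col) with the index of its nearest seed (squared
    Euclidean; ties broken by lower seed index)."""
    d2 = (rows[:, None] - seeds[None, :, 0]) ** 2 + (
        cols[:, None] - seeds[None, :, 1]
    ) ** 2
    return np.argmin(d2, axis=1)


def _label_fragments(ecoregion_of: np.ndarray) -> np.ndarray:
    """4-connected components within each ecoregion, numbered globally."""
    frag = np.full(ecoregion_of.shape, -1, dtype=int)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    next_id = 0
    for eco in np.unique(ecoregion_of):
        lab, n = ndimage.label(ecoregion_of == eco, structure=structure)
        for k in range(1, n + 1):
            frag[lab == k] = next_id
            next_id += 1
    return frag


def adjacency_pairs(country_of: np.ndarray):
    """All 4-adjacent cell pairs spanning two different countries.

    Yields ``(a, b, (r1, c1), (r2, c2))`` with a < b.  This vectorized scan
    is the production path; the tests contain an independent brute-force
    loop over every cell pair.
    """
    n_rows, n_cols = country_of.shape
    out = []
    # vertical neighbours
    a = country_of[:-1, :]
    b = country_of[1:, :]
    rr, cc = np.nonzero(a != b)
    for r, c in zip(rr, cc):
        ca, cb = int(country_of[r, c]), int(country_of[r + 1, c])
        lo, hi = min(ca, cb), max(ca, cb)
        out.append((lo, hi, (int(r), int(c)), (int(r) + 1, int(c))))
    # horizontal neighbours
    a = country_of[:, :-1]
    b = country_of[:, 1:]
    rr, cc = np.nonzero(a != b)
    for r, c in zip(rr, cc):
        ca, cb = int(country_of[r, c]), int(country_of[r, c + 1])
        lo, hi = min(ca, cb), max(ca, cb)
        out.append((lo, hi, (int(r), int(c)), (int(r), int(c) + 1)))
    return out


def build_border_graph(
    country_of: np.ndarray,
    barrier_fraction: float = 0.15,
    seed: int = 0,
) -> BorderGraph:
    """Derive the border graph from a country map.

    A seeded random subset of ``round(barrier_fraction * n_borders)``
    borders is flagged as fortified.
    """
    g = nx.Graph()
    g.add_nodes_from(range(int(country_of.max()) + 1))
    for a, b, p, q in adjacency_pairs(country_of):
        if not g.has_edge(a, b):
            g.add_edge(a, b, border_id=f"B{a:03d}_{b:03d}", barrier=False,
                       cell_pairs=[])
        g.edges[a, b]["cell_pairs"].append((p, q))
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    n_barriers = int(round(barrier_fraction * len(edges)))
    if n_barriers > 0:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(edges), size=n_barriers, replace=False)
        for i in chosen:
            a, b = edges[i]
            g.edges[a, b]["barrier"] = True
    return BorderGraph(graph=g)


def gen_regions(
    grid: GridSpec,
    n_realms: int = 2,
    n_ecoregions: int = 12,
    n_countries: int = 8,
    seed: int = 0,
    barrier_fraction: float = 0.15,
    patches_per_ecoregion: float = 2.0,
) -> tuple[RegionMaps, BorderGraph]:
    """Generate region maps and the derived border graph.

    ``n_ecoregions`` is the total across realms; each ecoregion is seeded
    with on average ``patches_per_ecoregion`` nuclei, so ecoregions are
    typically disjoint and fragment into several blocking units.
    """
    if not (1 <= n_realms <= n_ecoregions):
        raise ValueError("need 1 <= n_realms <= n_ecoregions")
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    if n_countries > grid.n_cells:
        raise ValueError(
            f"n_countries={n_countries} exceeds cell count {grid.n_cells}"
        )
    rng = np.random.default_rng(seed)

    # realms: contiguous latitudinal bands of near-equal height
    realm_of = np.zeros(grid.shape, dtype=int)
    bounds = np.linspace(0, grid.n_rows, n_realms + 1).astype(int)
    for i in range(n_realms):
        realm_of[bounds[i]:bounds[i + 1], :] = i

    # ecoregions: nearest-nucleus growth within each realm
    eco_per_realm = np.array_split(np.arange(n_ecoregions), n_realms)
    ecoregion_of = np.zeros(grid.shape, dtype=int)
    for i in range(n_realms):
        ecos = eco_per_realm[i]
        if len(ecos) == 0:
            continue
        rr, cc = np.nonzero(realm_of == i)
        n_nuclei = max(len(ecos), int(round(len(ecos) * patches_per_ecoregion)))
        idx = rng.choice(len(rr), size=min(n_nuclei, len(rr)), replace=False)
        seeds = np.column_stack([rr[idx], cc[idx]])
        lab = _nearest_seed_labels(rr, cc, seeds)
        ecoregion_of[rr, cc] = ecos[lab % len(ecos)]

    fragment_of = _label_fragments(ecoregion_of)

    # countries: nearest-nucleus partition of the whole grid
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                         indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    idx = rng.choice(grid.n_cells, size=n_countries, replace=False)
    seeds = np.column_stack([rr[idx], cc[idx]])
    country_of = _nearest_seed_labels(rr, cc, seeds).reshape(grid.shape)

    regions = RegionMaps(
        grid=grid, realm_of=realm_of, ecoregion_of=ecoregion_of,
        fragment_of=fragment_of, country_of=country_of,
    )
    borders = build_border_graph(
        country_of, barrier_fraction=barrier_fraction, seed=seed + 1
    )
    return regions, borders
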
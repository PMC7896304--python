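"""Synthetic-world generators: determinism, partitions, adjacency oracle,
virtual-species consistency and covariate gradients."""

import numpy as np
import pytest

from nicheshift.world import (
    ALL_VARS,
    GCMS,
    SCENARIOS,
    FutureDeltaSpec,
    GridSpec,
    gen_climate,
    gen_covariates,
    gen_regions,
    gen_species,
)
from nicheshift.world.climate import DEFAULT_WARMING
from nicheshift.world.regions import adjacency_pairs, build_border_graph


def brute_force_edges(country_of):
    """Oracle: scan every pair of cells for 4-adjacency across countries."""
    n_rows, n_cols = country_of.shape
    edges = set()
    pairs = {}
    for r1 in range(n_rows):
        for c1 in range(n_cols):
            for r2 in range(n_rows):
                for c2 in range(n_cols):
                    if abs(r1 - r2) + abs(c1 - c2) != 1:
                        continue
                    a, b = country_of[r1, c1], country_of[r2, c2]
                    if a == b:
                        continue
                    e = (min(a, b), max(a, b))
                    edges.add(e)
                    pairs.setdefault(e, set()).add(
                        tuple(sorted(((r1, c1), (r2, c2))))
                    )
    return edges, pairs


class TestClimate:
    def test_zero_delta_future_equals_current_exactly(self):
        grid = GridSpec(8, 8)
        cur, fut = gen_climate(grid, seed=1,
                               future_delta_spec=FutureDeltaSpec.zero())
        for clim in fut.values():
            for v in ALL_VARS:
                assert np.array_equal(clim.layers[v], cur.layers[v])

    def test_same_seed_bit_identical(self):
        grid = GridSpec(10, 10)
        a_cur, a_fut = gen_climate(grid, seed=9)
        b_cur, b_fut = gen_climate(grid, seed=9)
        for v in ALL_VARS:
            assert np.array_equal(a_cur.layers[v], b_cur.layers[v])
        k = ("rcp85", "gcm_b")
        assert np.array_equal(a_fut[k].layers["prec_driest"],
                              b_fut[k].layers["prec_driest"])

    def test_high_emissions_mean_warming_matches_configured_delta(self):
        grid = GridSpec(40, 40)
        cur, fut = gen_climate(grid, seed=3)
        warming = np.mean([
            fut[("rcp85", g)].layers["temp_mean"].mean() for g in GCMS
        ]) - cur.layers["temp_mean"].mean()
        # Monte-Carlo tolerance on the smooth anomaly term
        assert warming == pytest.approx(DEFAULT_WARMING["rcp85"], abs=0.4)

    def test_scenario_ladder_ordered_by_warming(self):
        grid = GridSpec(30, 30)
        cur, fut = gen_climate(grid, seed=4)
        means = [
            np.mean([fut[(s, g)].layers["temp_mean"].mean() for g in GCMS])
            for s in SCENARIOS
        ]
        assert means == sorted(means)

    def test_nonnegative_layers(self):
        cur, fut = gen_climate(GridSpec(15, 15), seed=5)
        for clim in [cur, *fut.values()]:
            for v in ("prec_mean", "prec_driest", "temp_seasonality"):
                assert (clim.layers[v] >= 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="autocorr_range"):
            gen_climate(GridSpec(8, 8), seed=0, autocorr_range=0)
        with pytest.raises(ValueError, match="4x4"):
            GridSpec(3, 8)
        with pytest.raises(ValueError, match="cell_area"):
            GridSpec(8, 8, cell_area=-1)


class TestRegions:
    def test_partition_property(self, small_world):
        regions = small_world["regions"]
        for m in (regions.realm_of, regions.ecoregion_of,
                  regions.fragment_of, regions.country_of):
            assert m.shape == regions.grid.shape
            assert (m >= 0).all()

    def test_fragments_lie_within_single_ecoregion(self, small_world):
        regions = small_world["regions"]
        for f in range(regions.n_fragments):
            ecos = np.unique(regions.ecoregion_of[regions.fragment_of == f])
            assert len(ecos) == 1

    def test_single_country_world_has_no_borders(self):
        regions, graph = gen_regions(GridSpec(6, 6), n_realms=1,
                                     n_ecoregions=2, n_countries=1, seed=0)
        assert len(graph.borders) == 0

    def test_two_country_split_has_one_border_with_six_pairs(self):
        country_of = np.zeros((6, 6), dtype=int)
        country_of[:, 3:] = 1  # straight vertical split
        graph = build_border_graph(country_of, barrier_fraction=0.0)
        assert graph.borders == [(0, 1)]
        assert len(graph.graph.edges[0, 1]["cell_pairs"]) == 6

    def test_border_graph_matches_brute_force_oracle(self):
        regions, graph = gen_regions(GridSpec(9, 9), n_realms=2,
                                     n_ecoregions=4, n_countries=8, seed=17)
        oracle_edges, oracle_pairs = brute_force_edges(regions.country_of)
        assert set(graph.borders) == oracle_edges
        for e in oracle_edges:
            got = {
                tuple(sorted(p))
                for p in graph.graph.edges[e]["cell_pairs"]
            }
            assert got == oracle_pairs[e]
        fast = {(a, b) for a, b, _, _ in adjacency_pairs(regions.country_of)}
        assert fast == oracle_edges

    def test_too_many_countries_rejected(self):
        with pytest.raises(ValueError, match="n_countries"):
            gen_regions(GridSpec(4, 4), n_realms=1, n_ecoregions=1,
                        n_countries=20, seed=0)

    def test_barrier_fraction_applied(self, small_world):
        graph = small_world["graph"]
        n_barriers = len(graph.barrier_edges())
        assert n_barriers == round(0.3 * len(graph.borders))


class TestSpecies:
    def test_presences_are_exactly_super_cutoff_cells(self, small_world):
        # recompute suitability independently and compare partitions
        regions = small_world["regions"]
        current = small_world["current"]
        for sp in small_world["species"]:
            suit = sp.truth.suitability(current)
            realm_mask = np.isin(regions.realm_of, sp.truth.realms)
            rr, cc = np.nonzero(realm_mask)
            occupied = {
                (int(r), int(c)) for r, c in zip(rr, cc)
                if suit[r, c] >= sp.truth.cutoff
            }
            assert occupied == sp.presence_cells

    def test_occupied_min_suitability_exceeds_unoccupied_max(self, small_world):
        regions = small_world["regions"]
        current = small_world["current"]
        sp = small_world["species"][0]
        suit = sp.truth.suitability(current)
        realm_mask = np.isin(regions.realm_of, sp.truth.realms)
        occ_mask = np.zeros_like(realm_mask)
        for r, c in sp.presence_cells:
            occ_mask[r, c] = True
        assert suit[occ_mask].min() >= suit[realm_mask & ~occ_mask].max()

    def test_determinism(self, small_world):
        again = gen_species(small_world["current"], small_world["regions"],
                            n_species=10, seed=7)
        for a, b in zip(small_world["species"], again):
            assert a.presence_cells == b.presence_cells
            assert a.tags == b.tags

    def test_huge_breadth_saturates_home_realm(self):
        grid = GridSpec(12, 12)
        current, _ = gen_climate(grid, seed=2)
        regions, _ = gen_regions(grid, n_realms=2, n_ecoregions=4,
                                 n_countries=3, seed=3)
        sp = gen_species(current, regions, n_species=1,
                         niche_breadth_range=(50.0, 50.0),
                         prevalence_range=(1.0, 1.0), seed=4)[0]
        realm_cells = int(np.isin(regions.realm_of, sp.truth.realms).sum())
        assert len(sp.presence_cells) == realm_cells

    def test_nonflying_implies_mammal(self, small_world):
        for sp in small_world["species"]:
            if "nonflying" in sp.tags:
                assert sp.taxon_group == "mammal"

    def test_rejects_future_climate(self, small_world):
        fut = next(iter(small_world["futures"].values()))
        with pytest.raises(ValueError, match="current"):
            gen_species(fut, small_world["regions"], n_species=1, seed=0)


class TestCovariates:
    def test_values_within_documented_ranges(self, small_world):
        tab = small_world["covariates"].table
        from nicheshift.world import GOVERNANCE_INDICATORS

        for ind in GOVERNANCE_INDICATORS:
            assert tab[ind].between(-2.5, 2.5).all()
        assert (tab["gdp_per_capita"] > 0).all()
        assert (tab["co2_per_capita"] > 0).all()

    def test_strong_gradient_correlates_with_latitude(self):
        grid = GridSpec(30, 30)
        regions, _ = gen_regions(grid, n_realms=1, n_ecoregions=4,
                                 n_countries=30, seed=11)
        cov = gen_covariates(regions, seed=12, gradient_strength=2.0)
        score = cov.governance_score()
        lat = cov.table["latitude"]
        assert np.corrcoef(score, lat)[0, 1] > 0.5

    def test_zero_gradient_is_null(self):
        grid = GridSpec(30, 30)
        regions, _ = gen_regions(grid, n_realms=1, n_ecoregions=4,
                                 n_countries=30, seed=11)
        rs = []
        for s in range(20):
            cov = gen_covariates(regions, seed=s, gradient_strength=0.0)
            rs.append(np.corrcoef(cov.governance_score(),
                                  cov.table["latitude"])[0, 1])
        # zero expected correlation: the mean over replicates is near 0
        assert abs(np.mean(rs)) < 0.15

    def test_negative_gradient_strength_rejected(self, small_world):
        with pytest.raises(ValueError, match="gradient_strength"):
            gen_covariates(small_world["regions"], gradient_strength=-1)
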
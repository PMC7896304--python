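"""Transboundary and barrier statistics against brute-force oracles.

The oracle world: random species occupancy blobs on a multi-country grid,
with "future" maps taken from known truth occupancy so the counting logic
is exercised independently of any model fitting.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicheshift.borders import (
    barrier_blocked_species,
    border_bisection_counts,
    current_country_set,
    new_country_fraction,
    new_country_shares,
    normalized_shift_counts,
    per_border_shift_counts,
    species_by_country,
    transboundary_richness_fraction,
)
from nicheshift.ensemble.model import EnsembleProjection
from nicheshift.world import GridSpec, gen_regions
from nicheshift.world.species import SpeciesRecord


def random_world(seed=0, n_species=30, n_countries=12, shape=(15, 15)):
    rng = np.random.default_rng(seed)
    grid = GridSpec(*shape)
    regions, graph = gen_regions(
        grid, n_realms=1, n_ecoregions=3, n_countries=n_countries,
        seed=seed, barrier_fraction=0.25,
    )
    species, futures = [], {}
    for i in range(n_species):
        n_cur = int(rng.integers(3, 25))
        idx = rng.choice(grid.n_cells, size=n_cur, replace=False)
        cells = {(int(k // shape[1]), int(k % shape[1])) for k in idx}
        taxon = "bird" if rng.random() < 0.4 else "mammal"
        tags = {"flying"} if taxon == "bird" or rng.random() < 0.15 else {
            "nonflying"}
        if rng.random() < 0.3:
            tags.add("threatened")
        sp = SpeciesRecord(species_id=f"s{i:03d}", taxon_group=taxon,
                           tags=frozenset(tags), presence_cells=cells)
        species.append(sp)
        fut = np.zeros(shape, bool)
        n_fut = int(rng.integers(0, 25))
        if n_fut:
            fidx = rng.choice(grid.n_cells, size=n_fut, replace=False)
            fut[(fidx // shape[1]), (fidx % shape[1])] = True
        futures[sp.species_id] = EnsembleProjection(
            species_id=sp.species_id, epoch="future", scenario_id="rcp85",
            gcm_ids=("gcm_a",), fraction=fut.astype(float), binary=fut,
            domain=np.ones(shape, bool), n_projections=120,
        )
    return regions, graph, species, futures


def oracle_country_set(sp, regions):
    return {int(regions.country_of[r, c]) for r, c in sp.presence_cells}


def oracle_bisection(species, graph, regions):
    out = {}
    for a, b in graph.borders:
        n = n_thr = 0
        for sp in species:
            cs = oracle_country_set(sp, regions)
            if a in cs and b in cs:
                n += 1
                if "threatened" in sp.tags:
                    n_thr += 1
        out[(a, b)] = (n, n_thr)
    return out


def oracle_shifts(species, futures, graph, regions):
    out = {e: 0 for e in graph.borders}
    for sp in species:
        cs = oracle_country_set(sp, regions)
        fut = futures[sp.species_id].binary
        rr, cc = np.nonzero(fut)
        fut_countries = {int(x) for x in regions.country_of[rr, cc]}
        for a, b in graph.borders:
            for here, there in ((a, b), (b, a)):
                if here in cs and there not in cs and there in fut_countries:
                    out[(a, b)] += 1
                    break  # once per species per border
    return out


class TestCurrentCountrySet:
    def test_matches_cell_lookup_oracle(self):
        regions, graph, species, _ = random_world(seed=1)
        for sp in species:
            got, flag = current_country_set(sp, regions)
            oracle = oracle_country_set(sp, regions)
            assert got == oracle
            assert flag == (len(oracle) >= 2)

    def test_single_country_range_not_transboundary(self):
        regions, graph, species, _ = random_world(seed=2)
        c0_cells = [(int(r), int(c)) for r, c in
                    zip(*np.nonzero(regions.country_of == 0))][:5]
        sp = SpeciesRecord(species_id="x", taxon_group="mammal",
                           presence_cells=set(c0_cells))
        got, flag = current_country_set(sp, regions)
        assert got == {0} and not flag


class TestBisection:
    def test_matches_brute_force_oracle(self):
        regions, graph, species, _ = random_world(seed=3)
        stats = border_bisection_counts(species, graph, regions)
        oracle = oracle_bisection(species, graph, regions)
        for _, row in stats.iterrows():
            e = (row["country_a"], row["country_b"])
            assert (row["n_bisecting"], row["n_bisecting_threatened"]) == \
                oracle[e]

    def test_normalized_fraction_oracle(self):
        regions, graph, species, _ = random_world(seed=4)
        stats = border_bisection_counts(species, graph, regions)
        stats = transboundary_richness_fraction(stats, species, regions)
        for _, row in stats.iterrows():
            a, b = row["country_a"], row["country_b"]
            pool = {
                sp.species_id for sp in species
                if oracle_country_set(sp, regions) & {a, b}
            }
            expect = row["n_bisecting"] / len(pool) if pool else np.nan
            assert row["bisecting_fraction"] == pytest.approx(expect)
            if pool:
                assert 0.0 <= row["bisecting_fraction"] <= 1.0


class TestNewCountryFraction:
    def _profile(self, cur_cells, fut_mask, regions):
        sp = SpeciesRecord(species_id="x", taxon_group="mammal",
                           presence_cells=cur_cells)
        proj = EnsembleProjection(
            species_id="x", epoch="future", scenario_id="rcp85",
            gcm_ids=(), fraction=fut_mask.astype(float), binary=fut_mask,
            domain=np.ones(fut_mask.shape, bool), n_projections=120,
        )
        return new_country_fraction(sp, proj, regions)

    def test_future_within_current_countries_is_zero(self):
        regions, _, _, _ = random_world(seed=5)
        cells = {(int(r), int(c)) for r, c in
                 zip(*np.nonzero(regions.country_of == 0))}
        fut = regions.country_of == 0
        prof = self._profile(cells, fut, regions)
        assert prof.new_country_fraction == 0.0

    def test_future_entirely_new_is_one(self):
        regions, _, _, _ = random_world(seed=6)
        cells = {(int(r), int(c)) for r, c in
                 zip(*np.nonzero(regions.country_of == 0))}
        fut = regions.country_of == 1
        prof = self._profile(cells, fut, regions)
        assert prof.new_country_fraction == 1.0

    def test_forced_arithmetic_four_of_ten(self):
        regions = gen_regions(GridSpec(10, 10), n_realms=1, n_ecoregions=2,
                              n_countries=2, seed=7)[0]
        cur = {(int(r), int(c)) for r, c in
               zip(*np.nonzero(regions.country_of == 0))}
        in0 = [(int(r), int(c)) for r, c in
               zip(*np.nonzero(regions.country_of == 0))]
        in1 = [(int(r), int(c)) for r, c in
               zip(*np.nonzero(regions.country_of == 1))]
        fut = np.zeros(regions.grid.shape, bool)
        for cell in in0[:6] + in1[:4]:
            fut[cell] = True
        prof = self._profile(cur, fut, regions)
        assert prof.new_country_fraction == pytest.approx(0.4)

    def test_empty_future_flags_niche_lost(self):
        regions, _, _, _ = random_world(seed=8)
        cells = {(0, 0)}
        fut = np.zeros(regions.grid.shape, bool)
        prof = self._profile(cells, fut, regions)
        assert prof.niche_lost and prof.new_country_fraction is None

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_fraction_in_unit_interval_and_monotone(self, seed):
        """Bounds plus monotonicity: adding future cells only inside
        currently occupied countries never increases the fraction."""
        regions, _, species, futures = random_world(seed=seed % 50,
                                                    n_species=3)
        rng = np.random.default_rng(seed)
        sp = species[seed % len(species)]
        proj = futures[sp.species_id]
        prof = new_country_fraction(sp, proj, regions)
        if prof.new_country_fraction is None:
            return
        assert 0.0 <= prof.new_country_fraction <= 1.0
        cs, _ = current_country_set(sp, regions)
        own = np.isin(regions.country_of, list(cs))
        grown = proj.binary | (own & (rng.random(own.shape) < 0.3))
        proj2 = EnsembleProjection(
            species_id=sp.species_id, epoch="future", scenario_id="rcp85",
            gcm_ids=(), fraction=grown.astype(float), binary=grown,
            domain=proj.domain, n_projections=120,
        )
        prof2 = new_country_fraction(sp, proj2, regions)
        assert prof2.new_country_fraction <= prof.new_country_fraction + 1e-12

    def test_shares_consistent_with_profiles(self):
        regions, graph, species, futures = random_world(seed=9)
        _, profiles = per_border_shift_counts(species, futures, graph,
                                              regions)
        shares = new_country_shares(profiles)
        fracs = [p.new_country_fraction for p in profiles
                 if p.new_country_fraction is not None]
        assert shares["n_defined"] == len(fracs)
        assert shares["share_over_half"] == pytest.approx(
            np.mean([f > 0.5 for f in fracs]))
        assert shares["share_at_least_fifth"] == pytest.approx(
            np.mean([f >= 0.2 for f in fracs]))


class TestShiftCounts:
    def test_matches_brute_force_oracle(self):
        regions, graph, species, futures = random_world(seed=10)
        stats, _ = per_border_shift_counts(species, futures, graph, regions)
        oracle = oracle_shifts(species, futures, graph, regions)
        for _, row in stats.iterrows():
            e = (row["country_a"], row["country_b"])
            assert row["n_shift_species"] == oracle[e]

    def test_species_present_both_sides_never_counts(self):
        regions, graph, species, futures = random_world(seed=11)
        a, b = graph.borders[0]
        cells = set()
        for cc in (a, b):
            rr, cols = np.nonzero(regions.country_of == cc)
            cells.update({(int(r), int(c)) for r, c in zip(rr, cols)})
        sp = SpeciesRecord(species_id="x", taxon_group="mammal",
                           presence_cells=cells)
        fut = np.ones(regions.grid.shape, bool)
        proj = EnsembleProjection(
            species_id="x", epoch="future", scenario_id="rcp85",
            gcm_ids=(), fraction=fut.astype(float), binary=fut,
            domain=fut.copy(), n_projections=120,
        )
        stats, _ = per_border_shift_counts([sp], {"x": proj}, graph, regions)
        row = stats[(stats["country_a"] == a) & (stats["country_b"] == b)]
        assert int(row["n_shift_species"].iloc[0]) == 0

    def test_normalized_shift_oracle(self):
        regions, graph, species, futures = random_world(seed=12)
        stats, _ = per_border_shift_counts(species, futures, graph, regions)
        stats = normalized_shift_counts(stats, species, regions)
        by_country = species_by_country(species, regions)
        for _, row in stats.iterrows():
            pool = by_country[row["country_a"]] | by_country[row["country_b"]]
            expect = row["n_shift_species"] / len(pool) if pool else np.nan
            assert row["normalized_shift"] == pytest.approx(expect)


class TestBarriers:
    def test_blocked_matches_oracle_and_excludes_fliers(self):
        regions, graph, species, futures = random_world(seed=13)
        out = barrier_blocked_species(species, futures, graph, regions)
        barrier_edges = set(graph.barrier_edges())
        assert barrier_edges, "world must have barrier borders"
        nonflying = [sp for sp in species if sp.is_nonflying_mammal]
        oracle_blocked = set()
        for sp in nonflying:
            cs = oracle_country_set(sp, regions)
            fut = futures[sp.species_id].binary
            rr, cc = np.nonzero(fut)
            fc = {int(x) for x in regions.country_of[rr, cc]}
            for a, b in barrier_edges:
                for here, there in ((a, b), (b, a)):
                    if here in cs and there not in cs and there in fc:
                        oracle_blocked.add(sp.species_id)
        assert out["blocked_species"] == oracle_blocked
        fliers = {sp.species_id for sp in species
                  if not sp.is_nonflying_mammal}
        assert not (out["blocked_species"] & fliers)

    def test_no_barriers_empties_blocked_set(self):
        regions, graph, species, futures = random_world(seed=14)
        for e in graph.graph.edges:
            graph.graph.edges[e]["barrier"] = False
        out = barrier_blocked_species(species, futures, graph, regions)
        assert out["blocked_species"] == set()

    def test_blocked_subset_of_shifters_on_barrier_edges(self):
        regions, graph, species, futures = random_world(seed=15)
        nonflying = [sp for sp in species if sp.is_nonflying_mammal]
        _, profiles = per_border_shift_counts(nonflying, futures, graph,
                                              regions)
        out = barrier_blocked_species(species, futures, graph, regions)
        shifting = {p.species_id for p in profiles
                    if p.shifted_borders & set(graph.barrier_edges())}
        assert out["blocked_species"] == shifting
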
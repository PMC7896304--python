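"""Shared synthetic-world fixtures.

Heavy objects are session-scoped: the small world backs most unit tests,
the recovery study backs the ensemble bookkeeping and niche-recovery
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from nicheshift import blocking, occurrences as occ
from nicheshift.ensemble import EnsembleConfig, NicheEnsembleModel
from nicheshift.world import (
    GCMS,
    GridSpec,
    gen_climate,
    gen_covariates,
    gen_regions,
    gen_species,
)
from nicheshift.world.species import DEFAULT_TRUTH_VARS


@pytest.fixture(scope="session")
def small_world():
    """20x20 world with 2 realms, 8 ecoregions, 6 countries, 10 species."""
    grid = GridSpec(20, 20)
    current, futures = gen_climate(grid, seed=5)
    regions, graph = gen_regions(
        grid, n_realms=2, n_ecoregions=8, n_countries=6, seed=6,
        barrier_fraction=0.3,
    )
    species = gen_species(current, regions, n_species=10, seed=7)
    covariates = gen_covariates(regions, seed=8)
    return {
        "grid": grid, "current": current, "futures": futures,
        "regions": regions, "graph": graph, "species": species,
        "covariates": covariates,
    }


@pytest.fixture(scope="session")
def recovery_study():
    """Full ensemble study on a 40x40 single-realm world: 20 virtual
    species with 500+ presence cells each, fitted with the desk-scale
    profile, projected to current and the high-emissions scenario.

    Returns per-species records with fit counts, projection counts,
    truth-AUC of the current ensemble and future-niche Jaccard.
    """
    from nicheshift.ensemble.metrics import evaluate_auc

    grid = GridSpec(40, 40)
    current, futures = gen_climate(grid, seed=42)
    regions, _ = gen_regions(
        grid, n_realms=1, n_ecoregions=12, n_countries=8, seed=43
    )
    species = gen_species(
        current, regions, n_species=20,
        prevalence_range=(0.35, 0.5), seed=44,
    )
    frags = blocking.build_fragments(
        regions, current, variables=DEFAULT_TRUTH_VARS
    )
    assignment = blocking.assign_blocks(frags, seed=45)
    cfg = EnsembleConfig.fast()
    records = []
    for i, sp in enumerate(species):
        table = occ.sample_pseudoabsences(
            sp, regions, current, seed=100 + i
        )
        table = blocking.label_occurrences(table, assignment, regions)
        res = NicheEnsembleModel(table, DEFAULT_TRUTH_VARS, cfg).fit(
            seed=200 + i
        )
        domain = np.isin(
            regions.realm_of, occ.occupied_realms(sp, regions)
        )
        proj_cur = res.project(current, domain)
        proj_fut = res.project(
            [futures[("rcp85", g)] for g in GCMS], domain
        )
        truth_now = sp.truth.occupancy(current, regions)
        truth_auc = evaluate_auc(
            proj_cur.fraction[domain], truth_now[domain].astype(int)
        )
        votes = sum(
            sp.truth.occupancy(futures[("rcp85", g)], regions).astype(int)
            for g in GCMS
        )
        truth_fut = votes >= 2  # GCM-majority true future niche
        inter = int((truth_fut & proj_fut.binary).sum())
        union = int((truth_fut | proj_fut.binary).sum())
        records.append({
            "species": sp,
            "results": res,
            "n_fits": len(res.model_fits),
            "n_current_projections": proj_cur.n_projections,
            "n_future_projections": proj_fut.n_projections,
            "truth_auc": truth_auc,
            "future_jaccard": inter / union if union else 1.0,
            "projection_current": proj_cur,
            "projection_future": proj_fut,
        })
    return {
        "grid": grid, "regions": regions, "species": species,
        "records": records, "config": cfg,
    }
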
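"""Stage orchestration with file chaining and provenance.

Stages run in the order
``world -> prep -> select -> block -> ensemble -> national -> borders``;
each consumes the CSV artifacts of its upstream stages, so any stage can
be rerun from disk.  Every stage writes a provenance record (config hash,
seed, input/output digests, counts) under ``<outdir>/provenance/``.

All artifacts are plain CSV/JSON.  The ensemble stage both fits and
projects (fitted models live only in memory); its projection CSVs are the
interface consumed by the national and borders stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blocking, borders as borders_mod, occurrences, predictors, richness
from .ensemble.model import EnsembleProjection, NicheEnsembleModel
from .runconfig import RunConfig
from .world import (
    ALL_VARS,
    GCMS,
    ClimateGrid,
    CountryCovariates,
    GridSpec,
    NicheTruth,
    RegionMaps,
    SpeciesRecord,
    build_border_graph,
    gen_climate,
    gen_covariates,
    gen_regions,
    gen_species,
)

logger = logging.getLogger(__name__)

STAGES = ("world", "prep", "select", "block", "ensemble", "national", "borders")


class StageError(RuntimeError):
    pass


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(
            f"stage {stage!r}: required artifact {path} is missing; "
            "run the upstream stage first"
        )
    return path


class Pipeline:
    """End-to-end runner bound to one :class:`RunConfig`."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.state: dict = {}

    # -- provenance ------------------------------------------------------

    def _provenance(self, stage: str, inputs: list[Path],
                    outputs: list[Path], counts: dict) -> dict:
        rec = {
            "stage": stage,
            "config_hash": hashlib.sha256(
                yaml.safe_dump(self.config.to_dict()).encode()
            ).hexdigest()[:16],
            "seed": self.config.stage_seed(stage),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "inputs": {str(p): _digest(p) for p in inputs},
            "outputs": {str(p): _digest(p) for p in outputs},
            "counts": counts,
        }
        pdir = self.outdir / "provenance"
        pdir.mkdir(parents=True, exist_ok=True)
        with open(pdir / f"{stage}.json", "w") as fh:
            json.dump(rec, fh, indent=1)
        return rec

    # -- world -----------------------------------------------------------

    def run_world(self) -> dict:
        cfg = self.config.world
        seed = self.config.stage_seed("world")
        grid = GridSpec(cfg.n_rows, cfg.n_cols, cfg.cell_area)
        current, futures = gen_climate(
            grid, seed=seed, autocorr_range=cfg.autocorr_range
        )
        regions, graph = gen_regions(
            grid, n_realms=cfg.n_realms, n_ecoregions=cfg.n_ecoregions,
            n_countries=cfg.n_countries, seed=seed + 1,
            barrier_fraction=cfg.barrier_fraction,
        )
        species = gen_species(
            current, regions, n_species=cfg.n_species,
            niche_breadth_range=(cfg.niche_breadth_lo, cfg.niche_breadth_hi),
            prevalence_range=(cfg.prevalence_lo, cfg.prevalence_hi),
            seed=seed + 2,
        )
        covariates = gen_covariates(
            regions, seed=seed + 3, gradient_strength=cfg.gradient_strength
        )
        self.state.update(
            grid=grid, current=current, futures=futures, regions=regions,
            graph=graph, species=species, covariates=covariates,
        )
        wdir = self.outdir / "world"
        wdir.mkdir(parents=True, exist_ok=True)
        outputs = []
        outputs.append(self._write_climate(wdir / "climate_current.csv", current))
        for (scen, gcm), clim in futures.items():
            outputs.append(self._write_climate(
                wdir / f"climate_{scen}_{gcm}.csv", clim))
        outputs.append(self._write_regions(wdir / "regions.csv", regions))
        outputs.append(self._write_borders(wdir / "borders.csv", graph))
        outputs.append(self._write_species(wdir, species))
        p = wdir / "covariates.csv"
        covariates.table.to_csv(p)
        outputs.append(p)
        p = wdir / "grid.json"
        with open(p, "w") as fh:
            json.dump({"n_rows": grid.n_rows, "n_cols": grid.n_cols,
                       "cell_area": grid.cell_area}, fh)
        outputs.append(p)
        return self._provenance("world", [], outputs, {
            "n_species": len(species),
            "n_countries": regions.n_countries,
            "n_borders": len(graph.borders),
            "n_fragments": regions.n_fragments,
        })

    @staticmethod
    def _write_climate(path: Path, clim: ClimateGrid) -> Path:
        clim.table().to_csv(path, index=False)
        return path

    @staticmethod
    def _write_regions(path: Path, regions: RegionMaps) -> Path:
        g = regions.grid
        rr, cc = np.meshgrid(np.arange(g.n_rows), np.arange(g.n_cols),
                             indexing="ij")
        pd.DataFrame({
            "row": rr.ravel(), "col": cc.ravel(),
            "realm": regions.realm_of.ravel(),
            "ecoregion": regions.ecoregion_of.ravel(),
            "fragment": regions.fragment_of.ravel(),
            "country": regions.country_of.ravel(),
        }).to_csv(path, index=False)
        return path

    @staticmethod
    def _write_borders(path: Path, graph) -> Path:
        rows = [
            {"border_id": graph.border_id(a, b), "country_a": a,
             "country_b": b,
             "barrier": bool(graph.graph.edges[a, b]["barrier"]),
             "n_cell_pairs": len(graph.graph.edges[a, b]["cell_pairs"])}
            for a, b in sorted(graph.borders)
        ]
        pd.DataFrame(rows, columns=["border_id", "country_a", "country_b",
                                    "barrier", "n_cell_pairs"]).to_csv(
            path, index=False)
        return path

    @staticmethod
    def _write_species(wdir: Path, species: list[SpeciesRecord]) -> Path:
        pres_rows, meta_rows = [], []
        for sp in species:
            for r, c in sorted(sp.presence_cells):
                pres_rows.append({"species_id": sp.species_id, "row": r,
                                  "col": c})
            meta_rows.append({
                "species_id": sp.species_id,
                "taxon_group": sp.taxon_group,
                "tags": "|".join(sorted(sp.tags)),
                "truth": json.dumps({
                    "optima": sp.truth.optima,
                    "breadths": sp.truth.breadths,
                    "cutoff": sp.truth.cutoff,
                    "realms": list(sp.truth.realms),
                }) if sp.truth else "",
            })
        pd.DataFrame(pres_rows).to_csv(wdir / "species_presences.csv",
                                       index=False)
        pd.DataFrame(meta_rows).to_csv(wdir / "species_meta.csv", index=False)
        return wdir / "species_meta.csv"

    # -- loading ---------------------------------------------------------

    def _load_world(self) -> None:
        if "grid" in self.state:
            return
        wdir = self.outdir / "world"
        gpath = _require(wdir / "grid.json", "load")
        gd = json.loads(gpath.read_text())
        grid = GridSpec(**gd)
        reg = pd.read_csv(_require(wdir / "regions.csv", "load"))
        shape = grid.shape

        def as_map(col):
            out = np.zeros(shape, dtype=int)
            out[reg["row"], reg["col"]] = reg[col]
            return out

        regions = RegionMaps(
            grid=grid, realm_of=as_map("realm"),
            ecoregion_of=as_map("ecoregion"),
            fragment_of=as_map("fragment"), country_of=as_map("country"),
        )
        bdf = pd.read_csv(_require(wdir / "borders.csv", "load"))
        graph = build_border_graph(regions.country_of, barrier_fraction=0.0)
        for _, row in bdf.iterrows():
            a, b = int(row["country_a"]), int(row["country_b"])
            graph.graph.edges[a, b]["barrier"] = bool(row["barrier"])

        def load_climate(path, epoch, scen=None, gcm=None):
            df = pd.read_csv(path)
            layers = {}
            for v in ALL_VARS:
                lay = np.zeros(shape)
                lay[df["row"], df["col"]] = df[v]
                layers[v] = lay
            return ClimateGrid(grid=grid, layers=layers, epoch=epoch,
                               scenario_id=scen, gcm_id=gcm)

        current = load_climate(
            _require(wdir / "climate_current.csv", "load"), "current")
        futures = {}
        for p in sorted(wdir.glob("climate_rcp*.csv")):
            scen, gcm = p.stem.split("_", 2)[1:]
            futures[(scen, gcm)] = load_climate(p, "future", scen, gcm)
        pres = pd.read_csv(wdir / "species_presences.csv")
        meta = pd.read_csv(wdir / "species_meta.csv")
        species = []
        for _, m in meta.iterrows():
            cells = pres[pres["species_id"] == m["species_id"]]
            truth = None
            if isinstance(m["truth"], str) and m["truth"]:
                td = json.loads(m["truth"])
                truth = NicheTruth(
                    optima=td["optima"], breadths=td["breadths"],
                    cutoff=td["cutoff"], realms=tuple(td["realms"]),
                )
            species.append(SpeciesRecord(
                species_id=m["species_id"],
                taxon_group=m["taxon_group"],
                tags=frozenset(str(m["tags"]).split("|")) if m["tags"] else frozenset(),
                presence_cells={(int(r), int(c)) for r, c in
                                zip(cells["row"], cells["col"])},
                truth=truth,
            ))
        covariates = CountryCovariates(
            table=pd.read_csv(wdir / "covariates.csv", index_col="country")
        )
        self.state.update(
            grid=grid, current=current, futures=futures, regions=regions,
            graph=graph, species=species, covariates=covariates,
        )

    # -- prep ------------------------------------------------------------

    def run_prep(self) -> dict:
        self._load_world()
        cfg = self.config.prep
        seed = self.config.stage_seed("prep")
        species, report = occurrences.filter_restricted(
            self.state["species"], min_cells=cfg.min_presence_cells
        )
        tables = {}
        for i, sp in enumerate(species):
            tables[sp.species_id] = occurrences.sample_pseudoabsences(
                sp, self.state["regions"], self.state["current"],
                n=cfg.n_pseudoabsences, seed=seed + i,
            )
        self.state["retained"] = species
        self.state["tables"] = tables
        pdir = self.outdir / "prep"
        (pdir / "occurrences").mkdir(parents=True, exist_ok=True)
        outputs = []
        for sid, t in tables.items():
            p = pdir / "occurrences" / f"{sid}.csv"
            t.data.to_csv(p, index=False)
            outputs.append(p)
        p = pdir / "exclusions.csv"
        report.to_csv(p, index=False)
        outputs.append(p)
        return self._provenance("prep", [self.outdir / "world" / "species_presences.csv"],
                                outputs, {
            "n_species_in": len(self.state["species"]),
            "n_species_retained": len(species),
            "n_excluded": len(report),
        })

    def _load_tables(self) -> None:
        if "tables" in self.state:
            return
        self._load_world()
        odir = _require(self.outdir / "prep" / "occurrences", "load")
        tables = {}
        for p in sorted(odir.glob("*.csv")):
            df = pd.read_csv(p)
            df["block"] = df["block"].astype("Int64")
            tables[p.stem] = occurrences.OccurrenceTable(
                species_id=p.stem, data=df
            )
        if not tables:
            raise StageError("no occurrence tables under " + str(odir))
        self.state["tables"] = tables
        ids = set(tables)
        self.state["retained"] = [
            sp for sp in self.state["species"] if sp.species_id in ids
        ]

    # -- select ----------------------------------------------------------

    def run_select(self) -> dict:
        self._load_tables()
        cfg = self.config.selection
        sdir = self.outdir / "select"
        sdir.mkdir(parents=True, exist_ok=True)
        if not cfg.enabled:
            # documented alternative: skip the funnel, use the standard five
            from .world.species import DEFAULT_TRUTH_VARS

            winner_p = sdir / "winner.json"
            with open(winner_p, "w") as fh:
                json.dump({"predictors": list(DEFAULT_TRUTH_VARS),
                           "tally": None, "n_species_tested": 0,
                           "winner_fraction": None}, fh)
            self.state["selected_predictors"] = tuple(DEFAULT_TRUTH_VARS)
            return self._provenance("select", [], [winner_p], {
                "n_candidates": 0, "n_species_tested": 0,
                "winner": "+".join(DEFAULT_TRUTH_VARS),
            })
        seed = self.config.stage_seed("select")
        rng = np.random.default_rng(seed)
        tables = list(self.state["tables"].values())
        k = min(cfg.n_test_species, len(tables))
        idx = rng.choice(len(tables), size=k, replace=False)
        sample_tables = [tables[i] for i in sorted(idx)]
        climate_sample = self.state["current"].table()[list(ALL_VARS)]
        tally, audit = predictors.select_predictors(
            tuple(ALL_VARS), climate_sample, sample_tables,
            min_size=cfg.min_size, max_size=cfg.max_size, r_max=cfg.r_max,
            config=self.config.ensemble_config(),
        )
        self.state["selected_predictors"] = tally.winner
        audit_p = sdir / "selection_audit.csv"
        audit.to_csv(audit_p, index=False)
        winner_p = sdir / "winner.json"
        with open(winner_p, "w") as fh:
            json.dump({"predictors": list(tally.winner),
                       "tally": tally.counts[tally.winner],
                       "n_species_tested": tally.n_species_tested,
                       "winner_fraction": tally.winner_fraction}, fh)
        return self._provenance("select", [], [audit_p, winner_p], {
            "n_candidates": int(audit["status"].eq("final_pool").sum()),
            "n_species_tested": tally.n_species_tested,
            "winner": "+".join(tally.winner),
        })

    def _load_selection(self) -> None:
        if "selected_predictors" in self.state:
            return
        p = _require(self.outdir / "select" / "winner.json", "load")
        self.state["selected_predictors"] = tuple(
            json.loads(p.read_text())["predictors"]
        )

    # -- block -----------------------------------------------------------

    def run_block(self) -> dict:
        self._load_tables()
        self._load_selection()
        cfg = self.config.blocking
        frags = blocking.build_fragments(
            self.state["regions"], self.state["current"],
            variables=self.state["selected_predictors"],
        )
        assignment = blocking.assign_blocks(
            frags, n_blocks=cfg.n_blocks,
            seed=self.config.stage_seed("block"),
            area_weight=cfg.area_weight, climate_weight=cfg.climate_weight,
        )
        labelled = {
            sid: blocking.label_occurrences(t, assignment,
                                            self.state["regions"])
            for sid, t in self.state["tables"].items()
        }
        self.state["assignment"] = assignment
        self.state["tables"] = labelled
        bdir = self.outdir / "block"
        bdir.mkdir(parents=True, exist_ok=True)
        frags.to_csv(bdir / "fragments.csv", index=False)
        pd.DataFrame(
            [{"fragment_id": f, "block": b}
             for f, b in sorted(assignment.block_of.items())]
        ).to_csv(bdir / "assignment.csv", index=False)
        assignment.summaries.to_csv(bdir / "block_summary.csv", index=False)
        for sid, t in labelled.items():
            t.data.to_csv(self.outdir / "prep" / "occurrences" / f"{sid}.csv",
                          index=False)
        return self._provenance("block", [], [
            bdir / "fragments.csv", bdir / "assignment.csv",
            bdir / "block_summary.csv",
        ], {
            "n_fragments": len(frags),
            "n_blocks": cfg.n_blocks,
            "imbalance": assignment.imbalance,
        })

    # -- ensemble (fit + project) ---------------------------------------

    def run_ensemble(self) -> dict:
        self._load_tables()
        self._load_selection()
        preds = self.state["selected_predictors"]
        econf = self.config.ensemble_config()
        seed = self.config.stage_seed("ensemble")
        regions = self.state["regions"]
        scenarios = sorted({self.config.aggregation.scenario,
                            self.config.borders.scenario})
        audit_rows, n_fits = [], 0
        projections: dict[str, dict[str, EnsembleProjection]] = {}
        edir = self.outdir / "ensemble"
        (edir / "projections").mkdir(parents=True, exist_ok=True)
        for i, sp in enumerate(self.state["retained"]):
            table = self.state["tables"][sp.species_id]
            res = NicheEnsembleModel(table, preds, econf).fit(seed=seed + i)
            audit_rows.append(res.audit_table())
            n_fits += len(res.model_fits)
            domain = np.isin(regions.realm_of,
                             occurrences.occupied_realms(sp, regions))
            projections[sp.species_id] = {}
            cur = res.project(self.state["current"], domain)
            projections[sp.species_id]["current"] = cur
            self._write_projection(edir, sp.species_id, "current", cur)
            for scen in scenarios:
                clims = [self.state["futures"][(scen, g)] for g in GCMS]
                proj = res.project(clims, domain)
                projections[sp.species_id][scen] = proj
                self._write_projection(edir, sp.species_id, scen, proj)
        self.state["projections"] = projections
        audit = pd.concat(audit_rows, ignore_index=True)
        audit_p = edir / "model_audit.csv"
        audit.to_csv(audit_p, index=False)
        return self._provenance("ensemble", [], [audit_p], {
            "n_species": len(self.state["retained"]),
            "n_model_fits": n_fits,
            "mean_auc": float(audit["auc"].mean()),
            "scenarios": scenarios,
        })

    @staticmethod
    def _write_projection(edir: Path, sid: str, scen: str,
                          proj: EnsembleProjection) -> Path:
        rr, cc = np.nonzero(proj.domain)
        p = edir / "projections" / f"{sid}_{scen}.csv"
        pd.DataFrame({
            "row": rr, "col": cc,
            "fraction": proj.fraction[rr, cc],
            "binary": proj.binary[rr, cc].astype(int),
        }).to_csv(p, index=False)
        meta = {"species_id": sid, "scenario": scen,
                "epoch": proj.epoch, "n_projections": proj.n_projections,
                "unreliable": proj.unreliable,
                "gcm_ids": list(proj.gcm_ids)}
        with open(edir / "projections" / f"{sid}_{scen}.json", "w") as fh:
            json.dump(meta, fh)
        return p

    def _load_projections(self) -> None:
        if "projections" in self.state:
            return
        self._load_world()
        pdir = _require(self.outdir / "ensemble" / "projections", "load")
        grid = self.state["grid"]
        projections: dict[str, dict[str, EnsembleProjection]] = {}
        for p in sorted(pdir.glob("*.csv")):
            sid, scen = p.stem.rsplit("_", 1)
            df = pd.read_csv(p)
            meta = json.loads((pdir / f"{p.stem}.json").read_text())
            fraction = np.full(grid.shape, np.nan)
            binary = np.zeros(grid.shape, dtype=bool)
            domain = np.zeros(grid.shape, dtype=bool)
            fraction[df["row"], df["col"]] = df["fraction"]
            binary[df["row"], df["col"]] = df["binary"].astype(bool)
            domain[df["row"], df["col"]] = True
            projections.setdefault(sid, {})[scen] = EnsembleProjection(
                species_id=sid, epoch=meta["epoch"],
                scenario_id=None if scen == "current" else scen,
                gcm_ids=tuple(meta["gcm_ids"]), fraction=fraction,
                binary=binary, domain=domain,
                n_projections=meta["n_projections"],
                unreliable=meta["unreliable"],
            )
        if not projections:
            raise StageError("no projections under " + str(pdir))
        self.state["projections"] = projections

    # -- national --------------------------------------------------------

    def _taxon_filter(self, taxon: str) -> set[str]:
        """Species ids matching a taxon-group filter ('both' keeps all)."""
        return {
            sp.species_id for sp in self.state["species"]
            if taxon == "both" or sp.taxon_group == taxon
        }

    def run_national(self) -> dict:
        self._load_projections()
        scen = self.config.aggregation.scenario
        keep = self._taxon_filter(self.config.aggregation.taxon)
        projections = {
            sid: pr for sid, pr in self.state["projections"].items()
            if sid in keep
        }
        cur = richness.richness_map(
            [pr["current"] for pr in projections.values()])
        fut = richness.richness_map(
            [pr[scen] for pr in projections.values() if scen in pr])
        change = richness.percent_change_map(cur, fut)
        table = richness.national_mean_change(change, self.state["regions"])
        ndir = self.outdir / "national"
        ndir.mkdir(parents=True, exist_ok=True)
        table.to_csv(ndir / "national_change.csv", index=False)
        coef_rows = []
        for cov in ("governance", "gdp", "co2"):
            try:
                res = richness.fit_covariate_model(
                    table, self.state["covariates"], cov)
                coef_rows.append({
                    "covariate": cov, "slope": res.slope,
                    "ci_lo": res.conf_int[0], "ci_hi": res.conf_int[1],
                    "p_value": res.p_value, "n": res.n_countries,
                })
            except ValueError as e:
                logger.warning("covariate model %s skipped: %s", cov, e)
        coefs = pd.DataFrame(coef_rows)
        coefs.to_csv(ndir / "covariate_models.csv", index=False)
        self.state["national_change"] = table
        return self._provenance("national", [], [
            ndir / "national_change.csv", ndir / "covariate_models.csv",
        ], {"scenario": scen, "n_countries": len(table)})

    # -- borders ---------------------------------------------------------

    def run_borders(self) -> dict:
        if not self.config.borders.enabled:
            logger.info("borders stage disabled")
            return {}
        self._load_projections()
        scen = self.config.borders.scenario
        regions = self.state["regions"]
        graph = self.state["graph"]
        keep = self._taxon_filter(self.config.borders.taxon)
        species = [sp for sp in self.state["species"]
                   if sp.species_id in self.state["projections"]
                   and sp.species_id in keep]
        futures = {
            sid: pr[scen] for sid, pr in self.state["projections"].items()
            if scen in pr
        }
        bis = borders_mod.border_bisection_counts(species, graph, regions)
        bis = borders_mod.transboundary_richness_fraction(
            bis, species, regions)
        shifts, profiles = borders_mod.per_border_shift_counts(
            species, futures, graph, regions)
        shifts = borders_mod.normalized_shift_counts(shifts, species, regions)
        stats = bis.merge(
            shifts[["border_id", "n_shift_species", "normalized_shift"]],
            on="border_id")
        barrier = borders_mod.barrier_blocked_species(
            species, futures, graph, regions)
        n_tb = sum(
            1 for sp in species
            if borders_mod.current_country_set(sp, regions)[1]
        )
        shares = borders_mod.new_country_shares(profiles)
        bdir = self.outdir / "borders"
        bdir.mkdir(parents=True, exist_ok=True)
        stats.to_csv(bdir / "border_stats.csv", index=False)
        pd.DataFrame([
            {"species_id": p.species_id,
             "new_country_fraction": p.new_country_fraction,
             "niche_lost": p.niche_lost,
             "n_shifted_borders": len(p.shifted_borders),
             "n_blocked_borders": len(p.blocked_borders)}
            for p in profiles
        ]).to_csv(bdir / "shift_profiles.csv", index=False)
        barrier["per_barrier"].to_csv(bdir / "barrier_counts.csv", index=False)
        summary = {
            "scenario": scen,
            "n_species": len(species),
            "share_transboundary": n_tb / len(species) if species else np.nan,
            **shares,
            "n_blocked_nonflying_mammals": len(barrier["blocked_species"]),
            "n_nonflying_mammals": barrier["n_nonflying_mammals"],
        }
        with open(bdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        self.state["border_summary"] = summary
        return self._provenance("borders", [], [
            bdir / "border_stats.csv", bdir / "shift_profiles.csv",
            bdir / "barrier_counts.csv", bdir / "summary.json",
        ], summary)

    # -- entry points ----------------------------------------------------

    def run_stage(self, stage: str) -> dict:
        runner = {
            "world": self.run_world, "prep": self.run_prep,
            "select": self.run_select, "block": self.run_block,
            "ensemble": self.run_ensemble, "national": self.run_national,
            "borders": self.run_borders,
        }.get(stage)
        if runner is None:
            raise StageError(f"unknown stage {stage!r}; choose from {STAGES}")
        return runner()

    def run_all(self) -> dict:
        records = {}
        for stage in STAGES:
            if stage == "borders" and not self.config.borders.enabled:
                continue
            records[stage] = self.run_stage(stage)
        summary = {
            "stages": {s: r.get("counts", {}) for s, r in records.items()},
            "border_summary": self.state.get("border_summary", {}),
        }
        with open(self.outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return summary
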
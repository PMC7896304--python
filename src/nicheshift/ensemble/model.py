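"""Ensemble niche model: model object, fitted results, projections.

:class:`NicheEnsembleModel` is constructed from a block-labelled occurrence
table and fits the four families under leave-one-block-out cross-validation
(:meth:`fit`), yielding a :class:`NicheEnsembleResults` that carries the
(up to) 40 per-fold model fits with their held-out AUCs and thresholds.
Projection onto one or several climate grids produces an
:class:`EnsembleProjection`: every model scores every domain cell, is
binarized by its own threshold, and the per-cell occupancy fraction is the
AUC-weighted mean of those binary layers; the ensemble map is that
fraction binarized at 0.5.  A future epoch pools the 40 fits across the
three pseudo-GCMs, giving 120 contributing projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..occurrences import OccurrenceTable
from ..world.climate import ClimateGrid
from .config import EnsembleConfig
from .families import FAMILY_FITTERS

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """One fitted family on nine blocks, evaluated on the tenth."""

    species_id: str
    family: str
    held_out_block: int
    hyperparameters: dict
    auc: float
    threshold: float
    predictors: tuple[str, ...]
    predict_fn: object  # callable (n, k) matrix -> probability vector

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_fn(X)


@dataclass
class EnsembleProjection:
    """AUC-weighted occupancy for one species x epoch x scenario."""

    species_id: str
    epoch: str
    scenario_id: str | None
    gcm_ids: tuple[str, ...]
    fraction: np.ndarray  # (n_rows, n_cols), nan outside the domain
    binary: np.ndarray  # boolean occupancy, False outside the domain
    domain: np.ndarray  # boolean projection-domain mask
    n_projections: int
    unreliable: bool = False

    def occupied_cells(self) -> set[tuple[int, int]]:
        rr, cc = np.nonzero(self.binary)
        return {(int(r), int(c)) for r, c in zip(rr, cc)}


class NicheEnsembleModel:
    """Ensemble climatic-niche model for one species.

    Parameters
    ----------
    table : OccurrenceTable
        Presence/pseudoabsence rows with block labels already attached.
    predictors : tuple of str
        The selected predictor variables (typically five).
    config : EnsembleConfig, optional
        Family hyperparameters; defaults to the full-scale tuning rules.
    """

    def __init__(
        self,
        table: OccurrenceTable,
        predictors: tuple[str, ...],
        config: EnsembleConfig | None = None,
    ):
        if table.data["block"].isna().any():
            raise ValueError(
                f"species {table.species_id}: occurrence table has rows "
                "without block labels; run the blocking stage first"
            )
        self.table = table
        self.predictors = tuple(predictors)
        self.config = config or EnsembleConfig()

    def fit(self, seed: int = 0) -> "NicheEnsembleResults":
        X, y = self.table.design(self.predictors)
        blocks = self.table.data["block"].to_numpy(dtype=int)
        fits: list[ModelFit] = []
        family_info: dict[str, dict] = {}
        for fi, family in enumerate(self.config.families):
            fitter = FAMILY_FITTERS[family]
            fam_fits, info = fitter(X, y, blocks, self.config, seed=seed + fi)
            family_info[family] = info
            for b, predict, auc, thr in fam_fits:
                fits.append(
                    ModelFit(
                        species_id=self.table.species_id,
                        family=family,
                        held_out_block=b,
                        hyperparameters=dict(info),
                        auc=float(auc),
                        threshold=float(thr),
                        predictors=self.predictors,
                        predict_fn=predict,
                    )
                )
        n_expected = len(self.config.families) * len(np.unique(blocks))
        if len(fits) < n_expected:
            logger.info(
                "species %s: %d of %d model fits survived",
                self.table.species_id, len(fits), n_expected,
            )
        return NicheEnsembleResults(
            model=self, model_fits=fits, family_info=family_info
        )


@dataclass
class NicheEnsembleResults:
    """Fitted ensemble: per-fold model fits plus projection methods."""

    model: NicheEnsembleModel
    model_fits: list[ModelFit]
    family_info: dict[str, dict] = field(default_factory=dict)

    @property
    def species_id(self) -> str:
        return self.model.table.species_id

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.model_fits]))

    def audit_table(self) -> pd.DataFrame:
        """One row per model fit: family, block, AUC, threshold, tuning."""
        rows = []
        for f in self.model_fits:
            rows.append(
                {
                    "species_id": f.species_id,
                    "family": f.family,
                    "held_out_block": f.held_out_block,
                    "auc": f.auc,
                    "threshold": f.threshold,
                    "hyperparameters": repr(f.hyperparameters),
                }
            )
        return pd.DataFrame(rows)

    def project(
        self,
        climates: list[ClimateGrid] | ClimateGrid,
        domain: np.ndarray,
    ) -> EnsembleProjection:
        """Project the fitted ensemble onto one or more climate grids.

        ``climates`` is one current-epoch grid (40 projections) or the
        list of pseudo-GCM grids for one future scenario (3 x 40 = 120).
        ``domain`` is a boolean cell mask (the species' projection domain,
        typically its occupied realms).  Weights are renormalized over
        surviving model fits; fewer than
        ``config.min_reliable_projections`` marks the result unreliable.
        """
        if isinstance(climates, ClimateGrid):
            climates = [climates]
        epochs = {c.epoch for c in climates}
        if len(epochs) != 1:
            raise ValueError("all climates in one projection share an epoch")
        epoch = epochs.pop()
        scenarios = {c.scenario_id for c in climates}
        if len(scenarios) != 1:
            raise ValueError("all climates in one projection share a scenario")
        rr, cc = np.nonzero(domain)
        shape = climates[0].grid.shape
        num = np.zeros(len(rr))
        den = 0.0
        n_proj = 0
        for clim in climates:
            Xd = clim.values_at(rr, cc, self.model.predictors)
            for f in self.model_fits:
                p = f.predict(Xd)
                num += f.auc * (p >= f.threshold)
                den += f.auc
                n_proj += 1
        fraction = np.full(shape, np.nan)
        binary = np.zeros(shape, dtype=bool)
        if den > 0:
            frac = num / den
            fraction[rr, cc] = frac
            binary[rr, cc] = frac >= 0.5
        unreliable = n_proj < self.model.config.min_reliable_projections
        if unreliable:
            logger.warning(
                "species %s: only %d contributing projections; flagged "
                "unreliable", self.species_id, n_proj,
            )
        return EnsembleProjection(
            species_id=self.species_id,
            epoch=epoch,
            scenario_id=climates[0].scenario_id,
            gcm_ids=tuple(c.gcm_id for c in climates if c.gcm_id),
            fraction=fraction,
            binary=binary,
            domain=domain.copy(),
            n_projections=n_proj,
            unreliable=unreliable,
        )

    def summary(self) -> str:
        """Plain-text summary of per-family cross-validated performance."""
        lines = [
            f"Ensemble climatic-niche model: species {self.species_id}",
            f"predictors: {', '.join(self.model.predictors)}",
            f"model fits: {len(self.model_fits)}  mean AUC: {self.mean_auc:.3f}",
            "-" * 64,
            f"{'family':<16}{'fits':>5}{'mean AUC':>10}{'mean thr':>10}  tuning",
        ]
        df = self.audit_table()
        for fam, info in self.family_info.items():
            sub = df[df["family"] == fam]
            if len(sub) == 0:
                lines.append(f"{fam:<16}{0:>5}{'-':>10}{'-':>10}  {info}")
                continue
            lines.append(
                f"{fam:<16}{len(sub):>5}{sub['auc'].mean():>10.3f}"
                f"{sub['threshold'].mean():>10.3f}  "
                + ", ".join(f"{k}={v}" for k, v in info.items()
                            if k not in ("mean_auc", "summed_deviance"))
            )
        return "\n".join(lines)
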
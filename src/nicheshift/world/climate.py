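"""Synthetic bioclimate surfaces.

Eight candidate bioclimatic variables are generated, four of temperature
class and four of precipitation class, mirroring the classic candidate set
used in coarse-scale climatic-niche modelling (annual means, seasonality,
and monthly extremes of temperature and precipitation).  Each layer is a
deterministic latitudinal gradient plus spatially autocorrelated noise
(Gaussian-filtered white noise with a configurable filter radius).  The
derived extreme/mean pairs are built to be strongly correlated, as their
real-world counterparts are, so that the collinearity filter downstream has
realistic work to do.

Future surfaces are the current surface plus per-scenario additive deltas,
perturbed per pseudo-GCM by a smooth anomaly field, for four scenarios
emulating the RCP 2.6 / 4.5 / 6.0 / 8.5 ladder and three pseudo-GCMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec

TEMPERATURE_VARS = (
    "temp_mean",
    "temp_seasonality",
    "temp_max_warmest",
    "temp_min_coldest",
)
PRECIPITATION_VARS = (
    "prec_mean",
    "prec_seasonality",
    "prec_wettest",
    "prec_driest",
)
ALL_VARS = TEMPERATURE_VARS + PRECIPITATION_VARS

#: class label ("temperature" / "precipitation") per variable
VAR_CLASS = {v: "temperature" for v in TEMPERATURE_VARS}
VAR_CLASS.update({v: "precipitation" for v in PRECIPITATION_VARS})

#: layers that can never be negative
NONNEGATIVE_VARS = ("temp_seasonality",) + PRECIPITATION_VARS

SCENARIOS = ("rcp26", "rcp45", "rcp60", "rcp85")
GCMS = ("gcm_a", "gcm_b", "gcm_c")

#: default mean warming (deg C) per scenario by 2070; ordered so the
#: RCP 8.5 analogue carries the largest shift
DEFAULT_WARMING = {"rcp26": 1.0, "rcp45": 1.8, "rcp60": 2.2, "rcp85": 3.7}


@dataclass(frozen=True)
class ClimateGrid:
    """One epoch/scenario/GCM of gridded climate.

    ``layers`` maps variable name to an (n_rows, n_cols) float array; every
    layer covers the same cell set by construction.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    epoch: str  # "current" | "future"
    scenario_id: str | None = None
    gcm_id: str | None = None

    def table(self, variables: tuple[str, ...] | None = None):
        """Per-cell table of layer values (row, col, variables...)."""
        import pandas as pd

        variables = variables or tuple(self.layers)
        rr, cc = np.meshgrid(
            np.arange(self.grid.n_rows), np.arange(self.grid.n_cols), indexing="ij"
        )
        data = {"row": rr.ravel(), "col": cc.ravel()}
        for v in variables:
            data[v] = self.layers[v].ravel()
        return pd.DataFrame(data)

    def values_at(self, rows: np.ndarray, cols: np.ndarray,
                  variables: tuple[str, ...]) -> np.ndarray:
        """(n_cells, n_vars) matrix of layer values at the given cells."""
        return np.column_stack(
            [self.layers[v][rows, cols] for v in variables]
        )


@dataclass(frozen=True)
class FutureDeltaSpec:
    """Additive per-variable shifts per scenario, plus pseudo-GCM spread.

    ``shifts`` maps scenario id -> variable -> mean additive delta.
    ``gcm_spread`` scales both a per-GCM offset and a smooth anomaly field
    around the scenario-mean delta; zero makes all GCMs identical and, with
    all-zero shifts, makes every future layer equal the current one exactly.
    """

    shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    gcm_spread: float = 0.1

    @classmethod
    def default(cls) -> "FutureDeltaSpec":
        shifts = {}
        for scen, warm in DEFAULT_WARMING.items():
            shifts[scen] = {
                "temp_mean": warm,
                "temp_max_warmest": warm * 1.2,
                "temp_min_coldest": warm * 1.1,
                "temp_seasonality": warm * 0.3,
                "prec_mean": -4.0 * warm,
                "prec_wettest": 5.0 * warm,
                "prec_driest": -3.0 * warm,
                "prec_seasonality": 2.5 * warm,
            }
        return cls(shifts=shifts)

    @classmethod
    def zero(cls) -> "FutureDeltaSpec":
        return cls(
            shifts={s: {v: 0.0 for v in ALL_VARS} for s in SCENARIOS},
            gcm_spread=0.0,
        )


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float, sd: float) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to marginal sd ``sd``."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="nearest")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return smooth * sd


def gen_climate(
    grid: GridSpec,
    seed: int,
    autocorr_range: float = 3.0,
    future_delta_spec: FutureDeltaSpec | None = None,
) -> tuple[ClimateGrid, dict[tuple[str, str], ClimateGrid]]:
    """Generate the current climate and a future grid per (scenario, GCM).

    Returns ``(current, futures)`` where ``futures`` maps
    ``(scenario_id, gcm_id)`` to a future :class:`ClimateGrid`.
    Deterministic given ``seed``.
    """
    if autocorr_range <= 0:
        raise ValueError(f"autocorr_range must be positive, got {autocorr_range}")
    spec = future_delta_spec if future_delta_spec is not None else FutureDeltaSpec.default()
    rng = np.random.default_rng(seed)
    lat = grid.latitude_field()
    abslat = np.abs(lat)
    shape = grid.shape
    sig = autocorr_range

    noise = {v: _smooth_noise(rng, shape, sig, 1.0) for v in ALL_VARS}

    layers: dict[str, np.ndarray] = {}
    # temperature class: warm near the equator, seasonal toward the pole
    layers["temp_mean"] = 28.0 - 0.40 * abslat + 5.0 * noise["temp_mean"]
    layers["temp_max_warmest"] = (
        layers["temp_mean"] + 8.0 + 2.0 * noise["temp_max_warmest"]
    )
    layers["temp_min_coldest"] = (
        layers["temp_mean"] - 12.0 - 0.08 * abslat + 2.5 * noise["temp_min_coldest"]
    )
    layers["temp_seasonality"] = np.clip(
        4.0 + 0.28 * abslat + 5.5 * noise["temp_seasonality"], 0.0, None
    )
    # precipitation class: wet tropics, drier and more seasonal poleward
    layers["prec_mean"] = np.clip(
        40.0 + 160.0 * np.exp(-abslat / 30.0) + 48.0 * noise["prec_mean"], 0.0, None
    )
    layers["prec_wettest"] = np.clip(
        2.1 * layers["prec_mean"] + 30.0 * noise["prec_wettest"], 0.0, None
    )
    layers["prec_driest"] = np.clip(
        18.0 + 0.25 * abslat + 9.0 * noise["prec_driest"], 0.0, None
    )
    layers["prec_seasonality"] = np.clip(
        45.0 + 0.3 * abslat + 14.0 * noise["prec_seasonality"], 0.0, None
    )

    current = ClimateGrid(grid=grid, layers=layers, epoch="current")

    futures: dict[tuple[str, str], ClimateGrid] = {}
    for scen in SCENARIOS:
        scen_shift = spec.shifts.get(scen, {})
        for gi, gcm in enumerate(GCMS):
            # per-(scenario, gcm) stream derived from the master stream
            sub = np.random.default_rng(
                [seed, SCENARIOS.index(scen), gi, 0x5EED]
            )
            # deterministic per-GCM bias in [-1, 1] plus smooth anomaly
            bias = (gi - (len(GCMS) - 1) / 2.0)
            flayers = {}
            for v in ALL_VARS:
                shift = float(scen_shift.get(v, 0.0))
                if spec.gcm_spread > 0:
                    mag = abs(shift) if shift != 0 else 0.0
                    delta = (
                        shift
                        + spec.gcm_spread * mag * bias
                        + _smooth_noise(sub, shape, sig, spec.gcm_spread * mag)
                    )
                else:
                    delta = shift
                lay = layers[v] + delta
                if v in NONNEGATIVE_VARS:
                    lay = np.clip(lay, 0.0, None)
                flayers[v] = lay
            futures[(scen, gcm)] = ClimateGrid(
                grid=grid, layers=flayers, epoch="future",
                scenario_id=scen, gcm_id=gcm,
            )
    return current, futures
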
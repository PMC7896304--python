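"""Ensemble configuration with the full-scale tuning rules as defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FAMILIES = ("glm_poly", "gam_spline", "random_forest", "boosted_trees")


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the four model families.

    Defaults implement the full-scale tuning rules: a 3^k polynomial-degree
    search for the GLM, spline smooths for the additive model, an mtry grid
    of 1-3 with a 1,000 + 500-step tree-count rule for the random forest,
    and shrinkage 0.001 with 5,000 trees and interaction depth 1-4 for the
    boosted trees.  :meth:`fast` returns a documented desk-scale profile
    for simulation studies on small synthetic worlds.
    """

    families: tuple[str, ...] = FAMILIES
    n_blocks: int = 10

    # GLM with polynomial terms
    glm_max_degree: int = 3
    glm_ridge_c: float = 1.0  # inverse L2 strength; stabilizes separable fits

    # additive spline model
    gam_n_knots: int = 5
    gam_degree: int = 3
    gam_smoothing: float = 1.0  # second-difference roughness penalty weight

    # random forest
    rf_mtry_grid: tuple[int, ...] = (1, 2, 3)
    rf_initial_trees: int = 1000
    rf_tree_step: int = 500
    rf_gain_tol: float = 0.01  # stop when relative AUC gain < 1%
    rf_max_steps: int = 10

    # boosted trees
    brt_learning_rate: float = 0.001
    brt_n_trees: int = 5000
    brt_complexity_grid: tuple[int, ...] = (1, 2, 3, 4)
    brt_min_child: int = 5

    min_reliable_projections: int = 20

    @classmethod
    def fast(cls, **overrides) -> "EnsembleConfig":
        """Desk-scale profile for virtual-species simulation runs: smaller
        tree counts and a stronger boosting shrinkage suited to tables of
        a few hundred to ~2,000 rows."""
        cfg = cls(
            rf_initial_trees=100,
            rf_tree_step=50,
            brt_learning_rate=0.05,
            brt_n_trees=300,
        )
        return replace(cfg, **overrides)
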
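"""Systematic predictor-subset selection.

The candidate funnel: enumerate every subset of 3-8 of the eight candidate
bioclimatic variables (219 subsets), discard those lacking either a
temperature or a precipitation variable (10 of the 219), discard subsets
containing a variable pair with |Pearson r| > 0.7 on a climate sample, and
rank the survivors by fitting the additive-spline model per test species,
marking the top AIC quartile, and tallying how often each subset lands in
it.  The subset with the highest tally wins (ties broken by smaller size,
then lexicographically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ensemble.config import EnsembleConfig
from .ensemble.families import gam_aic
from .occurrences import OccurrenceTable
from .world.climate import VAR_CLASS

logger = logging.getLogger(__name__)

R_MAX = 0.7


@dataclass(frozen=True)
class VariableSubset:
    members: tuple[str, ...]  # sorted
    status: str = "candidate"  # candidate | discarded_class |
    #                            discarded_collinear | final_pool

    def with_status(self, status: str) -> "VariableSubset":
        return VariableSubset(members=self.members, status=status)


@dataclass
class SelectionTally:
    """Top-quartile appearance counts per candidate subset."""

    counts: dict[tuple[str, ...], int]
    n_species_tested: int
    n_failures: int = 0
    winner: tuple[str, ...] | None = None
    winner_fraction: float = 0.0  # share of species with the winner on top quartile

    def table(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(m), "size": len(m), "tally": c}
            for m, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows).sort_values(
            "tally", ascending=False, ignore_index=True
        )


def enumerate_subsets(
    variables: tuple[str, ...],
    min_size: int = 3,
    max_size: int = 8,
) -> list[VariableSubset]:
    """All subsets of sizes ``min_size``..``max_size``, each exactly once."""
    if len(set(variables)) != len(variables):
        raise ValueError("variable names must be distinct")
    out = []
    for k in range(min_size, min(max_size, len(variables)) + 1):
        for comb in combinations(sorted(variables), k):
            out.append(VariableSubset(members=comb))
    return out


def filter_class_balance(
    subsets: list[VariableSubset],
    class_of: dict[str, str] | None = None,
) -> tuple[list[VariableSubset], int]:
    """Keep subsets containing at least one variable of each class."""
    class_of = class_of or VAR_CLASS
    kept, discarded = [], 0
    for s in subsets:
        classes = {class_of[v] for v in s.members}
        if {"temperature", "precipitation"} <= classes:
            kept.append(s)
        else:
            discarded += 1
    return kept, discarded


def filter_collinearity(
    subsets: list[VariableSubset],
    climate_sample: pd.DataFrame,
    r_max: float = R_MAX,
) -> tuple[list[VariableSubset], pd.DataFrame]:
    """Discard subsets containing a pair with |r| > ``r_max`` (strict).

    ``climate_sample`` holds one column per variable over sample cells.
    A constant variable (undefined correlation) counts as a violation for
    every pair containing it and is reported.
    """
    variables = sorted({v for s in subsets for v in s.members})
    if len(climate_sample) < 3:
        raise ValueError("climate sample needs at least 3 rows")
    sub = climate_sample[variables]
    constant = [v for v in variables if sub[v].nunique() <= 1]
    corr = sub.corr().abs()
    bad_pairs = set()
    report_rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r = corr.loc[a, b]
            violates = (a in constant) or (b in constant) or (
                np.isnan(r)
            ) or (r > r_max)
            if violates:
                bad_pairs.add((a, b))
                report_rows.append({
                    "var_a": a, "var_b": b,
                    "abs_r": float(r) if np.isfinite(r) else np.nan,
                    "constant": a in constant or b in constant,
                })
    kept = []
    for s in subsets:
        ok = all(
            (a, b) not in bad_pairs
            for a, b in combinations(sorted(s.members), 2)
        )
        kept.append(s.with_status("final_pool" if ok else "discarded_collinear"))
    retained = [s for s in kept if s.status == "final_pool"]
    report = pd.DataFrame(
        report_rows, columns=["var_a", "var_b", "abs_r", "constant"]
    )
    return retained, report


def rank_by_quartile_tally(
    subsets: list[VariableSubset],
    species_tables: list[OccurrenceTable],
    aic_fn=None,
    config: EnsembleConfig | None = None,
) -> SelectionTally:
    """Fit the additive-spline model per (species, subset), rank subsets by
    AIC within each species, and tally top-quartile appearances.

    The top quartile is the ``ceil(n/4)`` best AIC ranks; AIC ties are
    broken by fewer members.  Model failures skip the (species, subset)
    pair with the denominator adjusted for that species.
    """
    if len(subsets) < 1:
        raise ValueError("need at least one candidate subset")
    config = config or EnsembleConfig()
    if aic_fn is None:
        def aic_fn(table: OccurrenceTable, members: tuple[str, ...]) -> float:
            X, y = table.design(members)
            return gam_aic(X, y, config)

    counts: dict[tuple[str, ...], int] = {s.members: 0 for s in subsets}
    n_failures = 0
    per_species_top: list[set[tuple[str, ...]]] = []
    for table in species_tables:
        aics = []
        for s in subsets:
            try:
                aics.append((aic_fn(table, s.members), len(s.members), s.members))
            except Exception:
                logger.info(
                    "AIC fit failed: species %s subset %s; skipped",
                    table.species_id, s.members,
                )
                n_failures += 1
        if not aics:
            per_species_top.append(set())
            continue
        aics.sort(key=lambda t: (t[0], t[1], t[2]))
        q = int(np.ceil(len(aics) / 4))
        top = {m for _, _, m in aics[:q]}
        for m in top:
            counts[m] += 1
        per_species_top.append(top)

    # tie-break: max tally, then smaller subset, then lexicographic
    best_tally = max(counts.values())
    tied = [m for m, c in counts.items() if c == best_tally]
    tied.sort(key=lambda m: (len(m), m))
    winner = tied[0]
    n_tested = len(species_tables)
    frac = (
        sum(winner in top for top in per_species_top) / n_tested
        if n_tested else 0.0
    )
    return SelectionTally(
        counts=counts,
        n_species_tested=n_tested,
        n_failures=n_failures,
        winner=winner,
        winner_fraction=frac,
    )


def select_predictors(
    variables: tuple[str, ...],
    climate_sample: pd.DataFrame,
    species_tables: list[OccurrenceTable],
    min_size: int = 3,
    max_size: int = 8,
    r_max: float = R_MAX,
    config: EnsembleConfig | None = None,
) -> tuple[SelectionTally, pd.DataFrame]:
    """Run the full funnel; returns the tally plus an audit table of every
    enumerated subset with its final status."""
    subsets = enumerate_subsets(variables, min_size, max_size)
    balanced, n_class_discarded = filter_class_balance(subsets)
    final_pool, _ = filter_collinearity(balanced, climate_sample, r_max)
    if not final_pool:
        raise ValueError("collinearity filter discarded every subset")
    tally = rank_by_quartile_tally(final_pool, species_tables, config=config)
    status_of = {s.members: "final_pool" for s in final_pool}
    for s in balanced:
        status_of.setdefault(s.members, "discarded_collinear")
    audit = pd.DataFrame(
        [
            {
                "subset": "+".join(s.members),
                "size": len(s.members),
                "status": status_of.get(s.members, "discarded_class"),
                "tally": tally.counts.get(s.members, np.nan),
            }
            for s in subsets
        ]
    )
    logger.info(
        "subset funnel: %d enumerated, %d class-discarded, %d final pool",
        len(subsets), n_class_discarded, len(final_pool),
    )
    return tally, audit
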
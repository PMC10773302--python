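"""Factorial parameter sweeps with replication and trend summaries.

A sweep enumerates the cross product of Pa, Pn and Pr values for each model
variant, runs a fixed number of independent replicates per parameter set,
collects final-step metrics, and aggregates them into per-parameter-set
means and standard deviations.  Replicate seeds are a deterministic
function of (base_seed, parameter-set index, replicate index), so the whole
experiment is a pure function of the grid definition.

The reference design is a 9 x 6 x 3 grid (Pa 0-0.8 by 0.1, Pn 0.3-0.8 by
0.1, Pr in {0.001, 0.01, 0.05}) of 162 parameter sets with 100 replicates
of 1000 steps each; reduced grids run the same machinery at smaller sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ModelParams, run_simulation

__all__ = [
    "ExperimentGrid",
    "default_grid",
    "replicate_seed",
    "run_experiment",
    "summarize",
    "trend_report",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "n_associations",
    "n_avoidances",
    "density",
    "weak_transitivity",
    "modularity",
    "n_communities",
)


@dataclass(frozen=True)
class ExperimentGrid:
    """Factorial design over inheritance parameters.

    The parameter sets are the cross product ``pa_values x pn_values x
    pr_values``, run for every variant in ``variants`` with ``replicates``
    independent replicates each.
    """

    pa_values: tuple = (0.0,)
    pn_values: tuple = (0.5,)
    pr_values: tuple = (0.01,)
    variants: tuple = ("one_step",)
    replicates: int = 1
    base_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pa_values", tuple(self.pa_values))
        object.__setattr__(self, "pn_values", tuple(self.pn_values))
        object.__setattr__(self, "pr_values", tuple(self.pr_values))
        object.__setattr__(self, "variants", tuple(self.variants))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def parameter_sets(self) -> list[tuple[float, float, float]]:
        """Ordered (pa, pn, pr) combinations; index = set index for seeding."""
        return list(product(self.pa_values, self.pn_values, self.pr_values))

    @property
    def n_sets(self) -> int:
        return len(self.pa_values) * len(self.pn_values) * len(self.pr_values)


def default_grid(
    replicates: int = 100,
    base_seed: int = 0,
    variants: Sequence[str] = ("one_step", "two_step"),
) -> ExperimentGrid:
    """The full reference grid: 9 Pa x 6 Pn x 3 Pr = 162 parameter sets."""
    return ExperimentGrid(
        pa_values=tuple(np.round(np.arange(0.0, 0.81, 0.1), 10)),
        pn_values=tuple(np.round(np.arange(0.3, 0.81, 0.1), 10)),
        pr_values=(0.001, 0.01, 0.05),
        variants=tuple(variants),
        replicates=replicates,
        base_seed=base_seed,
    )


def replicate_seed(base_seed: int, set_index: int, rep_index: int) -> int:
    """Platform-stable derived seed for one replicate of one parameter set."""
    ss = np.random.SeedSequence((int(base_seed), int(set_index), int(rep_index)))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def run_experiment(
    grid: ExperimentGrid,
    params_template: Optional[ModelParams] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every replicate of every parameter set and collect final metrics.

    Returns one row per (variant, parameter set, replicate) with the
    final-step metrics.  A replicate that raises is recorded with NaN
    metrics and the error message rather than silently dropped.
    """
    template = params_template or ModelParams()
    rows = []
    sets = grid.parameter_sets
    for variant in grid.variants:
        for set_index, (pa, pn, pr) in enumerate(sets):
            params = template.with_(pa=pa, pn=pn, pr=pr, variant=variant)
            for rep in range(grid.replicates):
                seed = replicate_seed(grid.base_seed, set_index, rep)
                row = {
                    "variant": variant,
                    "pa": pa,
                    "pn": pn,
                    "pr": pr,
                    "replicate": rep,
                    "seed": seed,
                    "error": "",
                }
                try:
                    trace = run_simulation(params, seed, record="final")
                    final = trace.metrics.iloc[-1]
                    for col in METRIC_COLUMNS:
                        row[col] = final[col]
                except Exception as exc:  # pragma: no cover - defensive
                    for col in METRIC_COLUMNS:
                        row[col] = np.nan
                    row["error"] = f"{type(exc).__name__}: {exc}"
                    logger.error("replicate failed (seed=%d): %s", seed, exc)
                rows.append(row)
            if progress:
                logger.info(
                    "%s set %d/%d (pa=%.3g pn=%.3g pr=%.3g) done",
                    variant, set_index + 1, len(sets), pa, pn, pr,
                )
    return pd.DataFrame(rows)


def summarize(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter-set means and standard deviations of final metrics.

    Undefined weak-transitivity values (networks with no connected
    two-paths) are excluded from that metric's mean with the number of
    dropped replicates reported in ``n_dropped_transitivity``.
    """
    if raw.empty:
        raise ValueError("cannot summarize an empty results table")
    keys = ["variant", "pa", "pn", "pr"]
    out = []
    for key_vals, grp in raw.groupby(keys, sort=True):
        rec = dict(zip(keys, key_vals))
        rec["n_replicates"] = len(grp)
        rec["n_dropped_transitivity"] = int(grp["weak_transitivity"].isna().sum())
        for col in METRIC_COLUMNS:
            vals = grp[col].dropna()
            rec[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        out.append(rec)
    n_dropped = sum(r["n_dropped_transitivity"] for r in out)
    if n_dropped:
        logger.info("dropped %d undefined transitivity values", n_dropped)
    return pd.DataFrame(out)


def trend_report(
    summary: pd.DataFrame,
    metric: str,
    along: str,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Classify the trend of a metric along one swept parameter.

    For every fixed combination of the other parameters (and variant), the
    Spearman rank correlation between the swept parameter's values and the
    per-set mean of ``metric`` is computed; |rho| >= ``threshold`` is
    classified ``increasing``/``decreasing`` by sign, anything weaker is
    ``flat``.  Requires at least three sweep values per curve.
    """
    col = f"{metric}_mean"
    if col not in summary.columns:
        raise ValueError(f"unknown metric {metric!r}")
    others = [k for k in ("variant", "pa", "pn", "pr") if k != along]
    rows = []
    for key_vals, grp in summary.groupby(others, sort=True):
        grp = grp.sort_values(along)
        x = grp[along].to_numpy(dtype=float)
        y = grp[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3:
            raise ValueError(
                f"need >= 3 sweep values of {along!r} per curve, got {ok.sum()}"
            )
        with warnings.catch_warnings():
            # a constant curve has undefined rho; we classify it as flat
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(x[ok], y[ok]).statistic
        if np.isnan(rho) or abs(rho) < threshold:
            trend = "flat"
        else:
            trend = "increasing" if rho > 0 else "decreasing"
        row = dict(zip(others, key_vals))
        row.update(metric=metric, along=along, rho=rho, trend=trend)
        rows.append(row)
    return pd.DataFrame(rows)
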
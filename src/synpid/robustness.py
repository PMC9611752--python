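"""Stress tests of the PID pipeline: subsample-size and noise sweeps.

Small samples bias plug-in information estimates upward, inflating the
whole-minus-sum heuristic; the subsample sweep measures that bias curve
by rerunning the entire balanced-resample pipeline on random record
subsets of decreasing size.  The noise sweep instead corrupts a growing
fraction of rows by independently permuting each column among the
selected rows — destroying their associations while preserving every
marginal — and tracks how the measures respond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortConfig,
    PersonTable,
    balanced_resample_mixture,
    effective_pid,
)
from .lattice import classify_atoms

__all__ = ["SweepResult", "subsample_sweep", "noise_sweep", "log_spaced_sizes"]

logger = logging.getLogger(__name__)


@dataclass
class SweepResult:
    """Replicate-level sweep statistics in tidy long format.

    ``data`` columns: axis (subset size or noise fraction), replicate,
    whole_minus_sum, redundant_fraction, synergistic_fraction.
    """

    axis_name: str
    axis_values: tuple
    replicates: int
    data: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return (
            self.data.groupby("axis")[
                ["whole_minus_sum", "redundant_fraction", "synergistic_fraction"]
            ]
            .agg(["mean", "std"])
            .reset_index()
        )


def log_spaced_sizes(n_min: int, n_max: int, k: int) -> tuple[int, ...]:
    """k log-spaced integer sizes from n_min to n_max inclusive."""
    sizes = np.unique(
        np.round(np.geomspace(n_min, n_max, k)).astype(int)
    )
    return tuple(int(s) for s in sizes)


def _run_once(
    df: pd.DataFrame,
    triad,
    config: CohortConfig,
    seed: int,
    method: str,
) -> "dict | None":
    sources, target = triad
    table = PersonTable(df=df, year=None, provenance="sweep")
    cfg = replace(config, seed=seed)
    eff = balanced_resample_mixture(table, tuple(sources), target, cfg)
    result = effective_pid(eff, method=method)
    classes = classify_atoms(result)
    wms = result.joint_mi - sum(result.marginal_mi)
    if classes.fractions is None:
        red = syn = np.nan
    else:
        red = classes.fractions["redundant"]
        syn = classes.fractions["synergistic"]
    return {
        "whole_minus_sum": wms,
        "redundant_fraction": red,
        "synergistic_fraction": syn,
    }


def subsample_sweep(
    table: PersonTable,
    triad=(("race", "sex"), "income"),
    sizes: "Sequence[int] | None" = None,
    reps: int = 600,
    seed: int = 0,
    config: "CohortConfig | None" = None,
    method: str = "imin",
) -> SweepResult:
    """Rerun the full pipeline on random record subsets of each size.

    Default sizes are 20 log-spaced values from 250 records to the full
    table; each size is replicated ``reps`` times with independent seeded
    draws.  Sizes too small to populate every joint predictor cell are
    skipped with a warning from the pipeline.
    """
    config = config or CohortConfig(n_resamples=50)
    if sizes is None:
        sizes = log_spaced_sizes(250, len(table), 20)
    sources, _target = triad
    n_cells_min = 2 ** len(sources)  # coarse lower bound for a warning
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(sizes) * reps)
    rows = []
    si = 0
    for size in sizes:
        if size > len(table):
            raise ValueError(f"subset size {size} exceeds table size {len(table)}")
        if size < n_cells_min:
            logger.warning("subset size %d below cell count; skipped", size)
            si += reps
            continue
        for rep in range(reps):
            stream = streams[si]
            si += 1
            rng = np.random.default_rng(stream)
            idx = rng.choice(len(table), size=size, replace=False)
            sub = table.df.iloc[idx].reset_index(drop=True)
            rep_seed = int(stream.generate_state(1)[0] % (2**31))
            stats = _run_once(sub, triad, config, rep_seed, method)
            rows.append({"axis": size, "replicate": rep, **stats})
    return SweepResult(
        axis_name="subset_size",
        axis_values=tuple(sizes),
        replicates=reps,
        data=pd.DataFrame(rows),
    )


def _permute_rows(
    df: pd.DataFrame, fraction: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Shuffle each column independently among a selected row fraction.

    Column-wise within-selection shuffling preserves every marginal
    distribution exactly while severing the selected rows' associations,
    so any change in the measured information reflects association loss,
    not altered marginals.
    """
    if fraction < 0 or fraction > 1:
        raise ValueError("noise fraction must be in [0, 1]")
    out = df.copy()
    k = int(np.ceil(fraction * len(df)))
    if k <= 1:
        return out
    sel = rng.choice(len(df), size=k, replace=False)
    for col in out.columns:
        vals = out[col].to_numpy()
        vals[sel] = vals[sel][rng.permutation(k)]
        out[col] = vals
    return out


def noise_sweep(
    table: PersonTable,
    triad=(("race", "sex"), "income"),
    fractions: "Sequence[float] | None" = None,
    reps: int = 600,
    seed: int = 0,
    config: "CohortConfig | None" = None,
    method: str = "imin",
) -> SweepResult:
    """Rerun the pipeline with a growing fraction of rows scrambled.

    Default fractions are 20 log-spaced values from 0.01% to 10%.
    """
    config = config or CohortConfig(n_resamples=50)
    if fractions is None:
        fractions = tuple(np.geomspace(1e-4, 0.10, 20))
    if any(f > 1 for f in fractions):
        raise ValueError("noise fractions must not exceed 1")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(fractions) * reps)
    rows = []
    si = 0
    for frac in fractions:
        for rep in range(reps):
            stream = streams[si]
            si += 1
            rng = np.random.default_rng(stream)
            noisy = _permute_rows(table.df, frac, rng)
            rep_seed = int(stream.generate_state(1)[0] % (2**31))
            stats = _run_once(noisy, triad, config, rep_seed, method)
            rows.append({"axis": frac, "replicate": rep, **stats})
    return SweepResult(
        axis_name="noise_fraction",
        axis_values=tuple(fractions),
        replicates=reps,
        data=pd.DataFrame(rows),
    )
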
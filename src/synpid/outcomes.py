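"""Local decomposition of intersectional effects in outcome units (USD).

Where the information decomposition works in bits over whole variables,
this module asks the same whole-versus-parts question about one specific
configuration of identities, in the units of the outcome itself: how does
the expected income change for people holding *at least one* of two
identities (the disjunction — the shared, redundant shift), and how much
further does it change for people holding *both* (the conjunction — the
synergistic shift, the cost or reward specific to the intersection)?

By construction the two shifts add up exactly to the total gap between
the conjunction and the population baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import EffectiveDistribution, PersonTable

__all__ = [
    "IdentityPredicate",
    "OutcomeDecomposition",
    "expected_outcome",
    "intersection_decomposition",
]


@dataclass(frozen=True)
class IdentityPredicate:
    """A single identity condition, e.g. race == "Black"."""

    variable: str
    category: object

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        if self.variable not in df.columns:
            raise KeyError(f"unknown variable {self.variable!r}")
        return (df[self.variable] == self.category).to_numpy()

    def __repr__(self) -> str:
        return f"{self.variable}={self.category}"


@dataclass
class OutcomeDecomposition:
    """Baseline, disjunctive, and conjunctive expected outcomes.

    ``redundant_shift`` is the change from holding at least one identity
    (disjunctive − baseline); ``synergistic_shift`` is the further change
    specific to holding both (conjunctive − disjunctive).  The two shifts
    sum to conjunctive − baseline exactly.
    """

    baseline: float
    disjunctive: float
    conjunctive: float
    redundant_shift: float
    synergistic_shift: float
    pred_a: IdentityPredicate = None
    pred_b: IdentityPredicate = None
    outcome: str = ""


def _validate_predicate(df: pd.DataFrame, pred: IdentityPredicate) -> None:
    if pred.variable not in df.columns:
        raise KeyError(f"unknown variable {pred.variable!r}")
    if pred.category not in set(df[pred.variable].unique()):
        raise ValueError(
            f"category {pred.category!r} not present in {pred.variable!r}"
        )


def _condition_mask(df, condition) -> np.ndarray:
    if condition is None:
        return np.ones(len(df), dtype=bool)
    op, pred_a, pred_b = condition
    a, b = pred_a.mask(df), pred_b.mask(df)
    if op == "or":
        return a | b
    if op == "and":
        return a & b
    raise ValueError(f"unknown condition operator {op!r}")


def expected_outcome(
    data,
    outcome: str,
    condition=None,
    *,
    predictors: "Sequence[str] | None" = None,
    balanced: bool = False,
) -> float:
    """Expected outcome, optionally under an AND/OR of two predicates.

    ``data`` may be a :class:`PersonTable` or an
    :class:`EffectiveDistribution`.  ``condition`` is ``None`` (grand
    mean) or a tuple ``(op, pred_a, pred_b)`` with ``op`` in
    ``{"and", "or"}``.

    On records, the default is the plain mean over matching rows.  With
    ``balanced=True`` (requires ``predictors``), every joint predictor
    cell is reweighted equally before averaging — the exact expectation
    of the balanced-resample scheme, since equal-size per-cell draws give
    every cell the same weight and each cell's resample mean is its
    within-cell mean.  On a mixture distribution the expectation is
    probability-weighted over the (numeric) outcome support.
    """
    if isinstance(data, EffectiveDistribution):
        dist = data.dist
        df_like = None
        for pred in ([] if condition is None else list(condition[1:])):
            if pred.variable not in dist.variables:
                raise KeyError(f"unknown variable {pred.variable!r}")
            if pred.category not in dist.supports[pred.variable]:
                raise ValueError(
                    f"category {pred.category!r} not in support of {pred.variable!r}"
                )
        values = np.asarray(dist.supports[outcome], dtype=float)
        # joint array over (variables); build the condition mask on the grid
        grids = np.meshgrid(
            *[np.arange(len(dist.supports[v])) for v in dist.variables],
            indexing="ij",
        )
        axes = {v: i for i, v in enumerate(dist.variables)}
        if condition is None:
            mask = np.ones(dist.probs.shape, dtype=bool)
        else:
            op, pa, pb = condition
            ma = grids[axes[pa.variable]] == dist.supports[pa.variable].index(
                pa.category
            )
            mb = grids[axes[pb.variable]] == dist.supports[pb.variable].index(
                pb.category
            )
            mask = (ma | mb) if op == "or" else (ma & mb)
        w = np.where(mask, dist.probs, 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("conditioning event has zero probability")
        out_axis = axes[outcome]
        w_out = w.sum(axis=tuple(i for i in range(w.ndim) if i != out_axis))
        return float((w_out * values).sum() / total)

    table: PersonTable = data
    df = table.df
    if condition is not None:
        for pred in condition[1:]:
            _validate_predicate(df, pred)
    mask = _condition_mask(df, condition)
    if not mask.any():
        raise ValueError("conditioning event matches no records")
    y = df[outcome].to_numpy(dtype=float)
    if not balanced:
        return float(y[mask].mean())
    if not predictors:
        raise ValueError("balanced expectation requires the predictor columns")
    sub = df[mask]
    cell_means = sub.groupby(list(predictors), observed=True)[outcome].mean()
    return float(cell_means.mean())


def intersection_decomposition(
    data,
    outcome: str,
    pred_a: IdentityPredicate,
    pred_b: IdentityPredicate,
    *,
    predictors: "Sequence[str] | None" = None,
    balanced: bool = False,
) -> OutcomeDecomposition:
    """Baseline, disjunctive and conjunctive expectations with their shifts.

    Symmetric in the two predicates.  Works identically for marginalized
    and privileged identity pairs — the sign of the shifts carries the
    direction of the effect.
    """
    kwargs = {"predictors": predictors, "balanced": balanced}
    baseline = expected_outcome(data, outcome, None, **kwargs)
    disjunctive = expected_outcome(data, outcome, ("or", pred_a, pred_b), **kwargs)
    conjunctive = expected_outcome(data, outcome, ("and", pred_a, pred_b), **kwargs)
    return OutcomeDecomposition(
        baseline=baseline,
        disjunctive=disjunctive,
        conjunctive=conjunctive,
        redundant_shift=disjunctive - baseline,
        synergistic_shift=conjunctive - disjunctive,
        pred_a=pred_a,
        pred_b=pred_b,
        outcome=outcome,
    )
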
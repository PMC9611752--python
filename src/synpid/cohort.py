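"""Person-level cohort pipeline: ingestion, filters, coarse-graining, and
the balanced-resample mixture distribution.

The pipeline turns a person-level table (race, sex, age, nativity,
employment status, annual income in USD, 5-level self-rated health) into
the joint categorical distribution the information measures need.  Income
is coarse-grained into four brackets; the joint distribution of the
predictor variables is forced to uniform by drawing an equal number of
records from every joint predictor cell, many times, and pooling the
draws (a balanced-resample mixture).  Mutual information computed on that
mixture is an *effective* information: the dependence that remains once
the empirical over-representation of any demographic cell has been
removed by intervention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .info_core import JointDistribution, as_group, whole_minus_sum
from .lattice import PIDResult, pid_imin

__all__ = [
    "PersonRecord",
    "PersonTable",
    "CohortConfig",
    "EffectiveDistribution",
    "DecadeResult",
    "INCOME_LEVELS",
    "DEFAULT_CUTPOINTS",
    "DEFAULT_TRIADS",
    "PipelineError",
    "load_person_table",
    "apply_filters",
    "coarse_grain_income",
    "with_income_bracket",
    "plug_in_distribution",
    "balanced_resample_mixture",
    "effective_pid",
    "decade_analysis",
]

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("race", "sex", "age", "nativity", "employment", "income", "health")

INCOME_LEVELS = ("Low", "Lower-Middle", "Upper-Middle", "High")
#: Bracket edges in USD: [0, 27500), [27500, 52500), [52500, 77500), >= 77500
DEFAULT_CUTPOINTS = (27_500.0, 52_500.0, 77_500.0)

#: The three source/target combinations of the headline analysis.
DEFAULT_TRIADS = (
    (("race", "sex"), "income"),
    (("race", "income"), "health"),
    (("race", "sex", "income"), "health"),
)


class PipelineError(RuntimeError):
    """A cohort-pipeline stage produced an unusable (e.g. empty) result."""


@dataclass(frozen=True)
class PersonRecord:
    race: str
    sex: str
    age: int
    nativity: str
    employment: str
    income: float
    health: int

    def __post_init__(self):
        if self.health not in (1, 2, 3, 4, 5):
            raise ValueError(f"health must be 1..5, got {self.health}")
        if self.income < 0:
            raise ValueError("income must be non-negative")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass
class PersonTable:
    """Filtered or raw person-level records, stored as a DataFrame."""

    df: pd.DataFrame
    year: "int | None" = None
    provenance: str = ""

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing canonical column(s): {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[PersonRecord]:
        return [
            PersonRecord(
                race=r.race,
                sex=r.sex,
                age=int(r.age),
                nativity=r.nativity,
                employment=r.employment,
                income=float(r.income),
                health=int(r.health),
            )
            for r in self.df.itertuples(index=False)
        ]

    @classmethod
    def from_records(
        cls, records: Iterable[PersonRecord], year=None, provenance=""
    ) -> "PersonTable":
        df = pd.DataFrame([vars(r) for r in records])
        return cls(df=df[list(CANONICAL_COLUMNS)], year=year, provenance=provenance)

    def to_csv(self, path, delimiter: str = ",") -> None:
        self.df.to_csv(path, sep=delimiter, index=False)


@dataclass
class CohortConfig:
    """Inclusion filters, coarse-graining, and resampling parameters.

    The defaults encode the working-age, native-born, full-time employed,
    single-race (White/Black) cohort with the four standard income
    brackets and 1000 balanced resamples.
    """

    age_min: int = 25
    age_max: int = 65  # both endpoints retained
    allowed_races: tuple[str, ...] = ("White", "Black")
    nativity_required: bool = True
    nativity_value: str = "Native"
    employment_required: bool = True
    employment_value: str = "Full-time"
    income_cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    n_resamples: int = 1000
    cell_size: "int | None" = None  # default: the smallest joint predictor cell
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self):
        cps = tuple(self.income_cutpoints)
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("income_cutpoints must be strictly increasing")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be at least 1")


@dataclass
class EffectiveDistribution:
    """Balanced-resample mixture distribution over (predictors..., outcome).

    The joint predictor marginal is uniform by construction (equal draws
    from every cell); ``predictor_marginal_flatness`` records the realized
    maximum deviation, which is zero up to float rounding.
    """

    dist: JointDistribution
    predictors: tuple[str, ...]
    outcome: str
    predictor_marginal_flatness: float
    cell_size: int
    n_resamples: int
    seed: int


def load_person_table(
    path,
    column_map: Mapping[str, str],
    *,
    delimiter: str = ",",
    year: "int | None" = None,
) -> PersonTable:
    """Read a delimited person-level file into canonical form.

    ``column_map`` maps canonical field names to the file's column names.
    Rows whose required fields fail to parse (non-numeric income/age,
    health outside 1..5, negative income or age) are dropped and counted
    in the log, mirroring how survey extracts flag missing responses.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in column_map]
    if missing:
        raise ValueError(f"column_map lacks canonical field(s): {missing}")
    # extra keys (e.g. a _comment field in a JSON map) are ignored
    column_map = {c: column_map[c] for c in CANONICAL_COLUMNS}
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    absent = [src for src in column_map.values() if src not in raw.columns]
    if absent:
        raise ValueError(f"mapped column(s) not in file: {absent}")
    df = pd.DataFrame({canon: raw[src] for canon, src in column_map.items()})
    n_raw = len(df)
    for col in ("age", "income", "health"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df[list(CANONICAL_COLUMNS)].notna().all(axis=1)
        & df["health"].isin([1, 2, 3, 4, 5])
        & (df["income"] >= 0)
        & (df["age"] >= 0)
    )
    dropped = int(n_raw - ok.sum())
    if dropped:
        logger.info("load_person_table: dropped %d unparseable row(s)", dropped)
    df = df[ok].copy()
    df["age"] = df["age"].astype(int)
    df["health"] = df["health"].astype(int)
    df["income"] = df["income"].astype(float)
    table = PersonTable(
        df=df[list(CANONICAL_COLUMNS)].reset_index(drop=True),
        year=year,
        provenance=f"{path} ({dropped} rows dropped at parse)",
    )
    return table


def apply_filters(table: PersonTable, config: CohortConfig) -> PersonTable:
    """Apply the cohort inclusion filters.

    Keeps working-age records (both age endpoints inclusive), native-born
    and full-time employed respondents (when required), and the allowed
    single-race categories.  The filters commute; they are applied in a
    fixed order only so an emptying filter can be named.
    """
    df = table.df
    steps = [
        (
            f"age in [{config.age_min}, {config.age_max}]",
            (df["age"] >= config.age_min) & (df["age"] <= config.age_max),
        ),
        (
            f"race in {config.allowed_races}",
            df["race"].isin(config.allowed_races),
        ),
    ]
    if config.nativity_required:
        steps.append(
            (f"nativity == {config.nativity_value!r}", df["nativity"] == config.nativity_value)
        )
    if config.employment_required:
        steps.append(
            (
                f"employment == {config.employment_value!r}",
                df["employment"] == config.employment_value,
            )
        )
    mask = pd.Series(True, index=df.index)
    for name, step in steps:
        mask &= step
        kept = int(mask.sum())
        logger.info("filter %s: %d record(s) remain", name, kept)
        if kept == 0:
            raise PipelineError(f"filter {name} emptied the table")
    out = df[mask].reset_index(drop=True)
    return PersonTable(
        df=out,
        year=table.year,
        provenance=f"{table.provenance}; filtered {len(df)}->{len(out)}",
    )


def coarse_grain_income(
    income, cutpoints: Sequence[float] = DEFAULT_CUTPOINTS
):
    """Map income in USD to the four ordered brackets.

    Accepts a scalar or an array; bracket k covers [cut_{k-1}, cut_k).
    """
    arr = np.asarray(income, dtype=float)
    if np.any(arr < 0):
        raise ValueError("income must be non-negative")
    codes = np.searchsorted(np.asarray(cutpoints, dtype=float), arr, side="right")
    labels = np.asarray(INCOME_LEVELS, dtype=object)[codes]
    if np.isscalar(income) or arr.ndim == 0:
        return str(labels if arr.ndim == 0 else labels[0])
    return labels


def with_income_bracket(
    table: PersonTable, cutpoints: Sequence[float] = DEFAULT_CUTPOINTS
) -> PersonTable:
    """Copy of the table with an ``income_bracket`` column added."""
    df = table.df.copy()
    df["income_bracket"] = coarse_grain_income(df["income"].to_numpy(), cutpoints)
    return PersonTable(df=df, year=table.year, provenance=table.provenance)


def _analysis_frame(table: PersonTable, config: CohortConfig) -> pd.DataFrame:
    """Categorical working frame: income replaced by its bracket."""
    df = table.df.copy()
    df["income"] = coarse_grain_income(
        df["income"].to_numpy(), config.income_cutpoints
    )
    return df


def _supports_for(df: pd.DataFrame, variables: Sequence[str]) -> dict[str, tuple]:
    sup = {}
    for v in variables:
        if v == "income":
            sup[v] = INCOME_LEVELS
        elif v == "health":
            sup[v] = (1, 2, 3, 4, 5)
        else:
            sup[v] = tuple(sorted(df[v].unique()))
    return sup


def plug_in_distribution(
    table: PersonTable,
    variables: Sequence[str],
    config: "CohortConfig | None" = None,
) -> JointDistribution:
    """Raw (unbalanced) maximum-likelihood joint distribution of columns.

    Income is coarse-grained first.  Unlike the balanced mixture, this
    preserves the empirical dependence *between* the predictor variables,
    which is exactly what the uniform intervention deliberately removes —
    use this when source correlation itself is the object of study (e.g.
    detecting common-cause redundancy between identities).
    """
    config = config or CohortConfig()
    df = _analysis_frame(table, config)
    variables = tuple(variables)
    return JointDistribution.from_dataframe(
        df, variables, _supports_for(df, variables)
    )


def balanced_resample_mixture(
    table: PersonTable,
    predictors: Sequence[str],
    outcome: str,
    config: CohortConfig,
) -> EffectiveDistribution:
    """Equal-weight mixture of balanced subsampled empirical distributions.

    Each replicate draws the same number of records from every joint
    predictor cell (default: the smallest cell's count, without
    replacement) and contributes its empirical joint distribution of
    (predictors, outcome); pooling the draws gives the mixture.  Because
    every replicate is cell-balanced, the mixture's joint predictor
    marginal is exactly uniform — the maximum-entropy intervention that
    turns the measured dependence into an effective information.

    One master seed spawns independent per-replicate substreams, so
    increasing ``n_resamples`` extends rather than reshuffles the
    replicate sequence.
    """
    predictors = tuple(predictors)
    df = _analysis_frame(table, config)
    variables = predictors + (outcome,)
    supports = _supports_for(df, variables)

    cells = list(
        df.groupby(list(predictors), observed=True, sort=True).groups.items()
    )
    full_cells = [
        combo
        for combo in _all_cells(supports, predictors)
    ]
    present = {k if isinstance(k, tuple) else (k,) for k, _ in cells}
    empty = [c for c in full_cells if c not in present]
    if empty:
        raise PipelineError(f"empty joint predictor cell(s): {empty}")

    outcome_support = supports[outcome]
    out_index = {c: i for i, c in enumerate(outcome_support)}
    cell_outcomes = {}
    for key, idx in cells:
        key = key if isinstance(key, tuple) else (key,)
        cell_outcomes[key] = (
            df.loc[idx, outcome].map(out_index).to_numpy(dtype=np.int64)
        )

    m = config.cell_size
    if m is None:
        m = min(len(v) for v in cell_outcomes.values())
    if m < 1:
        raise PipelineError("per-cell draw size must be at least 1")
    if not config.with_replacement:
        short = [k for k, v in cell_outcomes.items() if len(v) < m]
        if short:
            raise PipelineError(
                f"cell(s) smaller than draw size {m} without replacement: {short}"
            )

    shape = tuple(len(supports[v]) for v in variables)
    counts = np.zeros(shape, dtype=np.float64)
    pred_index = {
        key: tuple(supports[p].index(k) for p, k in zip(predictors, key))
        for key in cell_outcomes
    }
    streams = np.random.SeedSequence(config.seed).spawn(config.n_resamples)
    for stream in streams:
        rng = np.random.default_rng(stream)
        for key, outs in cell_outcomes.items():
            if config.with_replacement:
                draw = rng.integers(0, len(outs), size=m)
            else:
                draw = rng.choice(len(outs), size=m, replace=False)
            binc = np.bincount(outs[draw], minlength=len(outcome_support))
            counts[pred_index[key]] += binc

    dist = JointDistribution.from_counts(variables, supports, counts)
    # equal per-cell draws make the predictor-cell counts identical, so the
    # uniform marginal is exact; fall back to the float deviation otherwise
    cell_counts = counts.sum(axis=-1).ravel()
    if np.all(cell_counts == cell_counts[0]):
        flatness = 0.0
    else:
        pred_marg = dist.marginal_array(as_group(predictors)).ravel()
        flatness = float(np.abs(pred_marg - 1.0 / pred_marg.size).max())
    return EffectiveDistribution(
        dist=dist,
        predictors=predictors,
        outcome=outcome,
        predictor_marginal_flatness=flatness,
        cell_size=m,
        n_resamples=config.n_resamples,
        seed=config.seed,
    )


def _all_cells(supports, predictors):
    import itertools

    return [
        tuple(combo)
        for combo in itertools.product(*(supports[p] for p in predictors))
    ]


def effective_pid(
    effdist: EffectiveDistribution,
    sources: "Sequence | None" = None,
    target: "str | None" = None,
    method: str = "imin",
) -> PIDResult:
    """Decompose the effective information in a balanced mixture."""
    sources = list(sources) if sources is not None else list(effdist.predictors)
    target = target if target is not None else effdist.outcome
    if method == "imin":
        return pid_imin(effdist.dist, sources, target)
    if method == "broja":
        from .broja import pid_broja

        return pid_broja(effdist.dist, sources, target)
    raise ValueError(f"unknown method {method!r}; expected 'imin' or 'broja'")


@dataclass
class DecadeResult:
    """Per-year decompositions plus across-year summary statistics."""

    per_year: dict  # (year, triad label) -> PIDResult
    wms: pd.DataFrame  # year, triad, whole_minus_sum bits
    tidy: pd.DataFrame  # year, triad, atom, bits, fraction
    summary: pd.DataFrame  # triad, atom, mean fraction, sd fraction


def _triad_label(sources, target) -> str:
    return f"({', '.join(sources)} -> {target})"


def decade_analysis(
    tables: Sequence[PersonTable],
    triads: "Sequence | None" = None,
    config: "CohortConfig | None" = None,
    method: str = "imin",
    prefiltered: bool = False,
) -> DecadeResult:
    """Run the balanced-resample PID for each year and summarize the decade.

    ``triads`` is a sequence of (sources, target) pairs over canonical
    column names; the default runs the three headline combinations.  The
    across-year mean and standard deviation of every atom fraction, and
    the per-year whole-minus-sum series, quantify how stable each
    information-sharing mode is over time.
    """
    if not tables:
        raise ValueError("at least one yearly table is required")
    config = config or CohortConfig()
    triads = list(triads) if triads is not None else list(DEFAULT_TRIADS)
    for sources, _t in triads:
        if method == "broja" and len(sources) > 2:
            raise ValueError(
                "the optimization-based method supports exactly two sources; "
                f"triad {tuple(sources)} has {len(sources)}"
            )

    from .lattice import node_label

    per_year: dict = {}
    wms_rows, tidy_rows = [], []
    for table in tables:
        cohort = table if prefiltered else apply_filters(table, config)
        year = table.year
        for sources, target in triads:
            sources = tuple(sources)
            label = _triad_label(sources, target)
            eff = balanced_resample_mixture(cohort, sources, target, config)
            result = effective_pid(eff, method=method)
            per_year[(year, label)] = result
            wms_rows.append(
                {
                    "year": year,
                    "triad": label,
                    "whole_minus_sum": result.joint_mi - sum(result.marginal_mi),
                }
            )
            for node, bits in result.atoms.items():
                tidy_rows.append(
                    {
                        "year": year,
                        "triad": label,
                        "atom": node_label(node),
                        "bits": bits,
                        "fraction": (
                            np.nan
                            if result.fractions is None
                            else result.fractions[node]
                        ),
                    }
                )
    wms = pd.DataFrame(wms_rows)
    tidy = pd.DataFrame(tidy_rows)
    summary = (
        tidy.groupby(["triad", "atom"])["fraction"]
        .agg(mean_fraction="mean", sd_fraction=lambda s: s.std(ddof=0))
        .reset_index()
    )
    return DecadeResult(per_year=per_year, wms=wms, tidy=tidy, summary=summary)
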
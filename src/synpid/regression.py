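"""OLS with a multiplicative interaction term, and the dummy-variable
experiment showing the interaction coefficient cannot tell redundancy
from synergy.

Two constructed columns are derived from the empirical (income, health)
pair: D_red = (1 + income) mod 4 — an invertible relabeling of the
4-level income code, so everything it says about health is exactly what
income already says (pure redundancy) — and D_syn = (income + health)
mod 2 — a generalized parity, informative about health only jointly with
income (almost pure synergy).  The information decompositions of the two
triads are maximally different; the interaction-term regressions are
qualitatively the same.  Regression fitting itself is delegated to
statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortConfig, PersonTable
from .info_core import JointDistribution
from .lattice import PIDResult, pid_imin

__all__ = [
    "RegressionFit",
    "DummyExperimentResult",
    "ols_interaction",
    "make_dred",
    "make_dsyn",
    "dummy_experiment",
    "RACE_CODES",
    "SEX_CODES",
]

#: Numeric codings used for regression designs.
RACE_CODES = {"White": 0, "Black": 1}
SEX_CODES = {"Male": 0, "Female": 1}


@dataclass
class RegressionFit:
    """Summary of an interaction-term least-squares fit.

    Coefficient order: intercept, x1, x2, x1·x2.  Standard errors are the
    classical (non-robust) ones; AIC/BIC come from the Gaussian
    likelihood, matching the conventional least-squares summary table.
    """

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    conf_int: np.ndarray  # (4, 2): 95% bounds
    r_squared: float
    f_statistic: float
    aic: float
    bic: float
    n_observations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.coefficients,
                "std_err": self.standard_errors,
                "t": self.t_statistics,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
            },
            index=list(self.names),
        )


def ols_interaction(
    y, x1, x2, names: tuple[str, str] = ("x1", "x2")
) -> RegressionFit:
    """Fit y ~ 1 + x1 + x2 + x1·x2 by ordinary least squares."""
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (len(y) == len(x1) == len(x2)):
        raise ValueError("y, x1, x2 must have equal lengths")
    if len(y) < 5:
        raise ValueError("need at least 5 observations")
    design = np.column_stack([np.ones_like(y), x1, x2, x1 * x2])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("design matrix [1, x1, x2, x1*x2] is rank deficient")
    fit = sm.OLS(y, design).fit()
    return RegressionFit(
        names=("intercept", names[0], names[1], f"{names[0]}*{names[1]}"),
        coefficients=np.asarray(fit.params),
        standard_errors=np.asarray(fit.bse),
        t_statistics=np.asarray(fit.tvalues),
        conf_int=np.asarray(fit.conf_int(alpha=0.05)),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        aic=float(fit.aic),
        bic=float(fit.bic),
        n_observations=int(fit.nobs),
    )


def make_dred(income_codes) -> np.ndarray:
    """Cyclically shifted copy of the 4-level income code: (1 + c) mod 4."""
    codes = np.asarray(income_codes)
    if not np.isin(codes, [0, 1, 2, 3]).all():
        raise ValueError("income codes must be in {0, 1, 2, 3}")
    return (1 + codes) % 4


def make_dsyn(income_codes, health_codes) -> np.ndarray:
    """Generalized parity of income and health codes: (income + health) mod 2."""
    income = np.asarray(income_codes)
    health = np.asarray(health_codes)
    if income.shape != health.shape:
        raise ValueError("income and health vectors must have equal length")
    return (income + health) % 2


@dataclass
class DummyExperimentResult:
    """Side-by-side information and regression views of the two constructs."""

    pid_red_construct: PIDResult
    pid_syn_construct: PIDResult
    fit_red: RegressionFit
    fit_syn: RegressionFit
    pid_red_broja: "PIDResult | None" = None
    pid_syn_broja: "PIDResult | None" = None

    def discrimination_summary(self) -> pd.DataFrame:
        """Does each view separate the two constructs?

        The information route reports the dominant atom per construct; the
        regression route reports the interaction t statistics, whose
        shared significance and sign is what makes the two fits
        indistinguishable.
        """
        from .lattice import node_label

        def dominant(r: PIDResult) -> str:
            return node_label(max(r.atoms, key=r.atoms.get))

        return pd.DataFrame(
            {
                "construct": ["redundant (D_red)", "synergistic (D_syn)"],
                "dominant_atom": [
                    dominant(self.pid_red_construct),
                    dominant(self.pid_syn_construct),
                ],
                "interaction_t": [
                    self.fit_red.t_statistics[3],
                    self.fit_syn.t_statistics[3],
                ],
                "interaction_beta": [
                    self.fit_red.coefficients[3],
                    self.fit_syn.coefficients[3],
                ],
                "r_squared": [self.fit_red.r_squared, self.fit_syn.r_squared],
            }
        )


def dummy_experiment(
    table: PersonTable,
    config: "CohortConfig | None" = None,
    *,
    with_broja: bool = False,
) -> DummyExperimentResult:
    """Build D_red and D_syn from a person table and compare PID with OLS.

    Income is coarse-grained to codes 0-3; health keeps its native 1-5
    codes.  The decompositions are run on the plug-in joint distribution
    of each (income, construct, health) triple; the regressions fit
    health on the same numeric codes with a multiplicative interaction.
    """
    config = config or CohortConfig()
    income_codes = np.searchsorted(
        np.asarray(config.income_cutpoints, dtype=float),
        table.df["income"].to_numpy(dtype=float),
        side="right",
    )
    health_codes = table.df["health"].to_numpy(dtype=int)
    dred = make_dred(income_codes)
    dsyn = make_dsyn(income_codes, health_codes)

    def plug_in(construct, construct_name) -> JointDistribution:
        df = pd.DataFrame(
            {
                "income": income_codes,
                construct_name: construct,
                "health": health_codes,
            }
        )
        return JointDistribution.from_dataframe(
            df, ("income", construct_name, "health")
        )

    dist_red = plug_in(dred, "dred")
    dist_syn = plug_in(dsyn, "dsyn")
    pid_red = pid_imin(dist_red, ("income", "dred"), "health")
    pid_syn = pid_imin(dist_syn, ("income", "dsyn"), "health")
    fit_red = ols_interaction(health_codes, income_codes, dred, ("income", "dred"))
    fit_syn = ols_interaction(health_codes, income_codes, dsyn, ("income", "dsyn"))

    pid_red_b = pid_syn_b = None
    if with_broja:
        from .broja import pid_broja

        pid_red_b = pid_broja(dist_red, ("income", "dred"), "health")
        pid_syn_b = pid_broja(dist_syn, ("income", "dsyn"), "health")

    return DummyExperimentResult(
        pid_red_construct=pid_red,
        pid_syn_construct=pid_syn,
        fit_red=fit_red,
        fit_syn=fit_syn,
        pid_red_broja=pid_red_b,
        pid_syn_broja=pid_syn_b,
    )
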
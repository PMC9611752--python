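"""Shannon measures on finite categorical joint distributions.

Everything downstream — the redundancy lattice, the optimization-based
unique information, the cohort pipeline — operates on a single substrate:
a joint probability mass function over a handful of named categorical
variables (race, sex, a coarse-grained income, a 5-level self-rated
health, ...).  Supports here are tiny (a few dozen to a few hundred joint
outcomes), so every measure is computed by exact summation over the full
outcome array; there is no estimation beyond the maximum-likelihood
plug-in used when a distribution is built from counts.

All information quantities are reported in bits (log base 2), with the
convention 0·log2(0) = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableGroup",
    "JointDistribution",
    "as_group",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "whole_minus_sum",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class VariableGroup:
    """A non-empty set of variable names treated as one macro-variable."""

    members: frozenset[str]

    def __init__(self, members: Iterable[str]):
        ms = frozenset(members)
        if not ms:
            raise ValueError("a VariableGroup must contain at least one variable")
        object.__setattr__(self, "members", ms)

    def __iter__(self):
        return iter(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, name: str) -> bool:
        return name in self.members

    def issubset(self, other: "VariableGroup") -> bool:
        return self.members <= other.members

    def __repr__(self) -> str:
        return "{" + ",".join(sorted(self.members)) + "}"


def as_group(spec: "str | Iterable[str] | VariableGroup") -> VariableGroup:
    """Coerce a name, an iterable of names, or a group into a VariableGroup."""
    if isinstance(spec, VariableGroup):
        return spec
    if isinstance(spec, str):
        return VariableGroup([spec])
    return VariableGroup(spec)


class JointDistribution:
    """Finite categorical joint probability table over named variables.

    Parameters
    ----------
    variables
        Ordered variable names, one per axis.
    supports
        Mapping from variable name to its ordered category labels.
    probs
        Array of shape ``tuple(len(supports[v]) for v in variables)``.
        Must be non-negative and sum to 1 within 1e-9; renormalization is
        an explicit opt-in (:meth:`normalized`), never silent.
    """

    def __init__(
        self,
        variables: Sequence[str],
        supports: Mapping[str, Sequence],
        probs: np.ndarray,
        *,
        _validate: bool = True,
    ):
        self.variables: tuple[str, ...] = tuple(variables)
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        self.supports: dict[str, tuple] = {
            v: tuple(supports[v]) for v in self.variables
        }
        arr = np.asarray(probs, dtype=float)
        expected = tuple(len(self.supports[v]) for v in self.variables)
        if arr.shape != expected:
            raise ValueError(f"probs shape {arr.shape} != support shape {expected}")
        if _validate:
            if np.any(arr < -_PROB_TOL):
                raise ValueError("negative probability")
            total = float(arr.sum())
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"probabilities sum to {total}, not 1")
        self.probs = np.clip(arr, 0.0, None)
        self._axis: dict[str, int] = {v: i for i, v in enumerate(self.variables)}

    # -- construction -------------------------------------------------

    @classmethod
    def from_pmf(
        cls,
        variables: Sequence[str],
        supports: Mapping[str, Sequence],
        pmf: Mapping[tuple, float],
    ) -> "JointDistribution":
        """Build from a mapping of full joint outcomes to probabilities."""
        variables = tuple(variables)
        shape = tuple(len(supports[v]) for v in variables)
        arr = np.zeros(shape)
        index = {
            v: {c: i for i, c in enumerate(supports[v])} for v in variables
        }
        for outcome, p in pmf.items():
            if len(outcome) != len(variables):
                raise ValueError(f"outcome {outcome!r} has wrong arity")
            try:
                idx = tuple(index[v][c] for v, c in zip(variables, outcome))
            except KeyError as exc:
                raise ValueError(f"label {exc} not in support") from exc
            arr[idx] += p
        return cls(variables, supports, arr)

    @classmethod
    def from_counts(
        cls,
        variables: Sequence[str],
        supports: Mapping[str, Sequence],
        counts: "np.ndarray | Mapping[tuple, float]",
    ) -> "JointDistribution":
        """Maximum-likelihood distribution from a table of counts."""
        variables = tuple(variables)
        if isinstance(counts, Mapping):
            shape = tuple(len(supports[v]) for v in variables)
            arr = np.zeros(shape)
            index = {
                v: {c: i for i, c in enumerate(supports[v])} for v in variables
            }
            for outcome, c in counts.items():
                arr[tuple(index[v][k] for v, k in zip(variables, outcome))] += c
        else:
            arr = np.asarray(counts, dtype=float)
        if np.any(arr < 0):
            raise ValueError("negative count")
        total = arr.sum()
        if total <= 0:
            raise ValueError("empty count table")
        return cls(variables, supports, arr / total)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        variables: Sequence[str],
        supports: "Mapping[str, Sequence] | None" = None,
    ) -> "JointDistribution":
        """Empirical (plug-in) joint distribution of the given columns."""
        variables = tuple(variables)
        if supports is None:
            supports = {v: tuple(sorted(df[v].unique())) for v in variables}
        shape = tuple(len(supports[v]) for v in variables)
        arr = np.zeros(shape)
        index = {v: {c: i for i, c in enumerate(supports[v])} for v in variables}
        cols = [df[v].to_numpy() for v in variables]
        for row in zip(*cols):
            arr[tuple(index[v][c] for v, c in zip(variables, row))] += 1
        return cls(variables, supports, arr / arr.sum())

    # -- basic queries -------------------------------------------------

    def pmf(self) -> dict[tuple, float]:
        """Mapping from joint outcome tuples to probabilities (dense)."""
        out = {}
        for idx in itertools.product(*(range(s) for s in self.probs.shape)):
            outcome = tuple(
                self.supports[v][i] for v, i in zip(self.variables, idx)
            )
            out[outcome] = float(self.probs[idx])
        return out

    def normalized(self) -> "JointDistribution":
        """Explicitly renormalized copy (for almost-valid tables)."""
        total = self.probs.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero table")
        return JointDistribution(self.variables, self.supports, self.probs / total)

    def marginal_array(self, group: VariableGroup) -> np.ndarray:
        """Marginal probability array over ``group`` (axes in variable order)."""
        missing = group.members - set(self.variables)
        if missing:
            raise KeyError(f"unknown variable(s): {sorted(missing)}")
        keep = [self._axis[v] for v in self.variables if v in group]
        drop = tuple(i for i in range(self.probs.ndim) if i not in keep)
        return self.probs.sum(axis=drop)

    def marginal(self, group: "str | Iterable[str] | VariableGroup") -> "JointDistribution":
        group = as_group(group)
        kept = [v for v in self.variables if v in group]
        arr = self.marginal_array(group)
        return JointDistribution(
            kept, {v: self.supports[v] for v in kept}, arr, _validate=False
        )

    def condition_on(self, variable: str, value) -> "JointDistribution":
        """Distribution of the remaining variables given ``variable == value``."""
        if variable not in self._axis:
            raise KeyError(variable)
        try:
            i = self.supports[variable].index(value)
        except ValueError:
            raise ValueError(f"{value!r} not in support of {variable}")
        sl = [slice(None)] * self.probs.ndim
        sl[self._axis[variable]] = i
        arr = self.probs[tuple(sl)]
        mass = arr.sum()
        if mass <= 0:
            raise ValueError(f"conditioning event {variable}={value!r} has zero mass")
        kept = [v for v in self.variables if v != variable]
        return JointDistribution(
            kept, {v: self.supports[v] for v in kept}, arr / mass
        )

    # -- serialization -------------------------------------------------

    def to_text(self, path, delimiter: str = "\t") -> None:
        """Write the two-column text form: semicolon-joined outcome, probability."""
        with open(path, "w") as fh:
            fh.write(f"# variables: {';'.join(self.variables)}\n")
            for v in self.variables:
                fh.write(
                    f"# support {v}: {';'.join(str(c) for c in self.supports[v])}\n"
                )
            for outcome, p in self.pmf().items():
                key = ";".join(str(c) for c in outcome)
                fh.write(f"{key}{delimiter}{p!r}\n")

    @classmethod
    def from_text(cls, path, delimiter: str = "\t") -> "JointDistribution":
        variables: list[str] = []
        supports: dict[str, tuple] = {}
        pmf: dict[tuple, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("# variables:"):
                    variables = line.split(":", 1)[1].strip().split(";")
                elif line.startswith("# support"):
                    head, vals = line.split(":", 1)
                    name = head[len("# support") :].strip()
                    supports[name] = tuple(vals.strip().split(";"))
                elif line.startswith("#"):
                    continue
                else:
                    key, p = line.split(delimiter)
                    pmf[tuple(key.split(";"))] = float(p)
        if not variables:
            raise ValueError("missing '# variables:' header")
        return cls.from_pmf(variables, supports, pmf)

    def __repr__(self) -> str:
        return (
            f"JointDistribution(variables={self.variables}, "
            f"shape={self.probs.shape})"
        )


# -- measures ----------------------------------------------------------


def _entropy_of_array(p: np.ndarray) -> float:
    """−Σ p·log2(p) with 0·log2(0) = 0."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _check_groups_disjoint(*groups: VariableGroup) -> None:
    seen: set[str] = set()
    for g in groups:
        if seen & g.members:
            raise ValueError(f"variable groups overlap: {sorted(seen & g.members)}")
        seen |= g.members


def entropy(dist: JointDistribution, group) -> float:
    """Shannon entropy H(group) in bits of the marginal of ``group``."""
    group = as_group(group)
    return _entropy_of_array(dist.marginal_array(group))


def conditional_entropy(dist: JointDistribution, target, given) -> float:
    """H(target | given) = H(target, given) − H(given), in bits."""
    target, given = as_group(target), as_group(given)
    _check_groups_disjoint(target, given)
    joint = VariableGroup(target.members | given.members)
    return entropy(dist, joint) - entropy(dist, given)


def mutual_information(dist: JointDistribution, a, b) -> float:
    """I(a; b) = H(a) − H(a|b), in bits.  Symmetric and non-negative."""
    a, b = as_group(a), as_group(b)
    _check_groups_disjoint(a, b)
    return entropy(dist, a) - conditional_entropy(dist, a, b)


def whole_minus_sum(dist: JointDistribution, sources, target) -> float:
    """Joint MI of all sources about the target minus the sum of marginal MIs.

    Positive values indicate synergy-dominated dependence (the whole
    carries more than the parts), negative values redundancy-dominated.
    For two sources this equals Syn − Red under any decomposition
    satisfying the standard consistency identities.
    """
    sources = [as_group(s) for s in sources]
    target = as_group(target)
    if len(sources) < 2:
        raise ValueError("whole_minus_sum needs at least 2 sources")
    _check_groups_disjoint(*sources, target)
    pooled = VariableGroup(frozenset().union(*(s.members for s in sources)))
    joint = mutual_information(dist, pooled, target)
    marginals = sum(mutual_information(dist, s, target) for s in sources)
    return joint - marginals
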
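"""Williams–Beer partial information decomposition on the redundancy lattice.

The redundancy of a collection of source groups about a target is the
expected (over target states) minimum of the target-state-specific
information each source provides.  Evaluating that redundancy on every
antichain of source subsets and Möbius-inverting over the resulting
lattice yields the partial-information "atoms": redundant, unique,
synergistic, and — for three or more sources — the mixed "exotic" terms.

Supports 2- and 3-source decompositions (4- and 18-node lattices).  The
number of antichains grows super-exponentially with source count, and the
mixed atoms rapidly lose interpretability, so larger lattices are out of
scope.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .info_core import (
    JointDistribution,
    VariableGroup,
    as_group,
    mutual_information,
)

__all__ = [
    "SourceCollection",
    "AntichainLattice",
    "PIDResult",
    "AtomClassification",
    "specific_information",
    "imin_redundancy",
    "build_lattice",
    "pid_imin",
    "classify_atoms",
    "node_label",
]

logger = logging.getLogger(__name__)

# A lattice node is a frozenset of frozensets of 1-based source indices,
# e.g. frozenset({frozenset({1}), frozenset({2})}) is the node "{1}{2}".
Node = frozenset


def node_label(node: Node) -> str:
    """Bracket notation for a lattice node, e.g. ``{1}{2}`` or ``{12}``."""
    parts = sorted(node, key=lambda g: (len(g), sorted(g)))
    return "".join("{" + "".join(str(i) for i in sorted(g)) + "}" for g in parts)


@dataclass(frozen=True)
class SourceCollection:
    """An antichain of variable groups: no group contains another."""

    groups: frozenset[VariableGroup]

    def __init__(self, groups):
        gs = frozenset(as_group(g) for g in groups)
        if not gs:
            raise ValueError("SourceCollection must be non-empty")
        for a in gs:
            for b in gs:
                if a is not b and a.members <= b.members:
                    raise ValueError(
                        f"not an antichain: {a!r} is contained in {b!r}"
                    )
        object.__setattr__(self, "groups", gs)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)


def _is_antichain(node: Node) -> bool:
    return not any(a < b for a in node for b in node)


def _node_leq(alpha: Node, beta: Node) -> bool:
    """alpha ⪯ beta iff every group in beta contains some group in alpha."""
    return all(any(a <= b for a in alpha) for b in beta)


@dataclass
class AntichainLattice:
    """The partial order of source antichains for an n-source decomposition."""

    n_sources: int
    nodes: list[Node]
    down_sets: dict[Node, list[Node]]  # strictly-lower nodes, per node
    topo_order: list[Node]  # bottom-up order compatible with ⪯

    def leq(self, alpha: Node, beta: Node) -> bool:
        return _node_leq(alpha, beta)


@lru_cache(maxsize=None)
def build_lattice(n_sources: int) -> AntichainLattice:
    """Enumerate all antichains over {1..n} and their partial order.

    Node counts are 4 for two sources and 18 for three (the free
    distributive lattice minus the empty antichain).
    """
    if n_sources not in (2, 3):
        raise ValueError(
            f"only 2- and 3-source lattices are supported, got {n_sources}"
        )
    indices = range(1, n_sources + 1)
    subsets = [
        frozenset(c)
        for r in range(1, n_sources + 1)
        for c in itertools.combinations(indices, r)
    ]
    nodes: list[Node] = []
    for r in range(1, len(subsets) + 1):
        for combo in itertools.combinations(subsets, r):
            node = frozenset(combo)
            if _is_antichain(node):
                nodes.append(node)
    nodes.sort(key=lambda nd: (sum(len(g) for g in nd), node_label(nd)))
    down_sets = {
        b: [a for a in nodes if a != b and _node_leq(a, b)] for b in nodes
    }
    topo = sorted(nodes, key=lambda nd: (len(down_sets[nd]), node_label(nd)))
    return AntichainLattice(n_sources, nodes, down_sets, topo)


@dataclass
class PIDResult:
    """Partial information decomposition of I(sources; target).

    ``atoms`` maps each lattice node to its partial-information value in
    bits; ``fractions`` holds the same values normalized by the joint
    mutual information (``None`` when the joint MI is numerically zero,
    in which case fractions are undefined rather than 0/0).
    """

    joint_mi: float
    marginal_mi: list[float]
    atoms: dict[Node, float]
    fractions: "dict[Node, float] | None"
    method_label: str
    sources: list[VariableGroup] = field(default_factory=list)
    target: "VariableGroup | None" = None

    @property
    def n_sources(self) -> int:
        return len(self.marginal_mi)

    def atom(self, label: str) -> float:
        for node, v in self.atoms.items():
            if node_label(node) == label:
                return v
        raise KeyError(label)

    def fraction(self, label: str) -> "float | None":
        if self.fractions is None:
            return None
        for node, v in self.fractions.items():
            if node_label(node) == label:
                return v
        raise KeyError(label)

    # convenience accessors for the 2-source case
    @property
    def redundancy(self) -> float:
        return self.atom("{1}{2}")

    @property
    def unique(self) -> list[float]:
        return [self.atom("{" + str(i + 1) + "}") for i in range(self.n_sources)]

    @property
    def synergy(self) -> float:
        top = "{" + "".join(str(i + 1) for i in range(self.n_sources)) + "}"
        return self.atom(top)

    def to_text(self, path) -> None:
        """Flat key-value serialization: node label, bits, fraction."""
        with open(path, "w") as fh:
            fh.write(f"# method: {self.method_label}\n")
            fh.write(f"joint_mi\t{self.joint_mi!r}\t\n")
            for i, mi in enumerate(self.marginal_mi, start=1):
                fh.write(f"marginal_mi_{i}\t{mi!r}\t\n")
            for node in sorted(self.atoms, key=node_label):
                frac = "" if self.fractions is None else repr(self.fractions[node])
                fh.write(f"{node_label(node)}\t{self.atoms[node]!r}\t{frac}\n")


@dataclass
class AtomClassification:
    """Aggregation of lattice atoms into the four interpretable categories.

    *redundant*: collections of two or more singleton sources;
    *unique*: a single singleton source; *synergistic*: a single
    multi-source group; *exotic*: everything mixed (only present for
    three or more sources).
    """

    bits: dict[str, float]
    fractions: "dict[str, float] | None"
    nodes: dict[str, list[Node]]


def _category(node: Node) -> str:
    if len(node) == 1:
        (group,) = node
        return "unique" if len(group) == 1 else "synergistic"
    if all(len(g) == 1 for g in node):
        return "redundant"
    return "exotic"


def classify_atoms(result: PIDResult) -> AtomClassification:
    """Aggregate a PIDResult's atoms into redundant/unique/synergistic/exotic."""
    bits = {"redundant": 0.0, "unique": 0.0, "synergistic": 0.0, "exotic": 0.0}
    nodes: dict[str, list[Node]] = {k: [] for k in bits}
    for node, v in result.atoms.items():
        cat = _category(node)
        bits[cat] += float(v)
        nodes[cat].append(node)
    if result.fractions is None:
        fractions = None
    else:
        fractions = {k: v / result.joint_mi for k, v in bits.items()}
    return AtomClassification(bits=bits, fractions=fractions, nodes=nodes)


# -- Imin --------------------------------------------------------------


def specific_information(
    dist: JointDistribution, source, target, target_value
) -> float:
    """Information the source provides about one particular target state.

    Σ_s P(s|y) [log2 P(y|s) − log2 P(y)].  Its expectation over target
    states recovers the mutual information exactly.
    """
    source, target = as_group(source), as_group(target)
    joint = dist.marginal(VariableGroup(source.members | target.members))
    s_vars = [v for v in joint.variables if v in source]
    t_vars = [v for v in joint.variables if v in target]
    if isinstance(target_value, tuple):
        t_vals = dict(zip(sorted(target.members), target_value))
    else:
        if len(t_vars) != 1:
            raise ValueError("tuple target_value required for a grouped target")
        t_vals = {t_vars[0]: target_value}
    p = joint.probs
    t_axes = [joint.variables.index(v) for v in t_vars]
    s_axes = [joint.variables.index(v) for v in s_vars]
    # P(y): marginalize over source axes, pick the target cell
    p_t = p.sum(axis=tuple(s_axes)) if s_axes else p
    t_idx = tuple(
        joint.supports[v].index(t_vals[v])
        for v in [w for w in joint.variables if w in target]
    )
    p_y = float(np.atleast_1d(p_t)[t_idx] if t_idx else p_t)
    if p_y <= 0:
        raise ValueError(f"target value {target_value!r} has zero probability")
    # slice the joint at the target cell -> array over source axes
    sl = [slice(None)] * p.ndim
    for v, ax in zip(t_vars, t_axes):
        sl[ax] = joint.supports[v].index(t_vals[v])
    p_sy = p[tuple(sl)]  # P(s, y) over source axes
    p_s = p.sum(axis=tuple(t_axes))  # P(s)
    total = 0.0
    it = np.nditer(p_sy, flags=["multi_index"])
    for val in it:
        psy = float(val)
        if psy <= 0:
            continue
        ps = float(p_s[it.multi_index])
        p_s_given_y = psy / p_y
        p_y_given_s = psy / ps
        total += p_s_given_y * (np.log2(p_y_given_s) - np.log2(p_y))
    return total


def imin_redundancy(dist: JointDistribution, collection, target) -> float:
    """Expected minimum specific information over the collection's groups.

    For a single-group collection this reduces to the plain mutual
    information between that group and the target.
    """
    if not isinstance(collection, SourceCollection):
        collection = SourceCollection(collection)
    target = as_group(target)
    for g in collection:
        if g.members & target.members:
            raise ValueError(
                f"target variable(s) {sorted(g.members & target.members)} "
                "appear inside a source group"
            )
    t_marg = dist.marginal(target)
    t_vars = list(t_marg.variables)
    total = 0.0
    it = np.nditer(t_marg.probs, flags=["multi_index"])
    for val in it:
        p_y = float(val)
        if p_y <= 0:
            continue
        y = tuple(t_marg.supports[v][i] for v, i in zip(t_vars, it.multi_index))
        tv = y[0] if len(t_vars) == 1 else y
        spec = min(
            specific_information(dist, g, target, tv) for g in collection
        )
        total += p_y * spec
    return total


def pid_imin(dist: JointDistribution, sources, target) -> PIDResult:
    """Full Imin decomposition via Möbius inversion over the lattice.

    Atoms are computed bottom-up: π(α) = Imin(α) − Σ_{β≺α} π(β).  Values
    within 1e-12 below zero are clamped to zero (floating-point guard);
    genuine negatives are left in place so violations are visible.
    """
    sources = [as_group(s) for s in sources]
    target = as_group(target)
    n = len(sources)
    lattice = build_lattice(n)

    def realize(subset: frozenset) -> VariableGroup:
        members: frozenset[str] = frozenset()
        for i in subset:
            members |= sources[i - 1].members
        return VariableGroup(members)

    pooled = realize(frozenset(range(1, n + 1)))
    joint_mi = mutual_information(dist, pooled, target)
    marginal_mi = [mutual_information(dist, s, target) for s in sources]

    if joint_mi < 1e-12:
        logger.warning(
            "target carries no information about the sources; all atoms are 0"
        )
        atoms = {node: 0.0 for node in lattice.nodes}
        return PIDResult(
            joint_mi=joint_mi,
            marginal_mi=marginal_mi,
            atoms=atoms,
            fractions=None,
            method_label="imin",
            sources=sources,
            target=target,
        )

    red: dict[Node, float] = {}
    for node in lattice.nodes:
        groups = [realize(sub) for sub in node]
        red[node] = imin_redundancy(dist, SourceCollection(groups), target)

    atoms: dict[Node, float] = {}
    for node in lattice.topo_order:
        below = sum(atoms[b] for b in lattice.down_sets[node])
        v = float(red[node] - below)
        if -1e-12 < v < 0.0:
            v = 0.0
        atoms[node] = v

    fractions = {node: v / joint_mi for node, v in atoms.items()}
    return PIDResult(
        joint_mi=joint_mi,
        marginal_mi=marginal_mi,
        atoms=atoms,
        fractions=fractions,
        method_label="imin",
        sources=sources,
        target=target,
    )
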
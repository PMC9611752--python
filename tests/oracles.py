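"""Independent brute-force oracles used to validate the package.

Everything here is written against the defining sums, not against the
package's own code paths: entropies enumerate the full outcome set from a
plain pmf dict, the redundancy evaluations re-derive specific
information from first principles, and the unique-information oracle
searches the feasible polytope on a dense grid.  Keeping these
implementations naive and separate is the point.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def marginal_pmf(pmf: dict, variables: tuple, keep: tuple) -> dict:
    idx = [variables.index(v) for v in keep]
    out: dict = {}
    for outcome, p in pmf.items():
        key = tuple(outcome[i] for i in idx)
        out[key] = out.get(key, 0.0) + p
    return out


def entropy_brute(pmf: dict, variables: tuple, keep: tuple) -> float:
    marg = marginal_pmf(pmf, variables, keep)
    return -sum(p * math.log2(p) for p in marg.values() if p > 0)


def conditional_entropy_brute(pmf, variables, target, given) -> float:
    return entropy_brute(pmf, variables, tuple(target) + tuple(given)) - entropy_brute(
        pmf, variables, tuple(given)
    )


def mutual_information_brute(pmf, variables, a, b) -> float:
    return entropy_brute(pmf, variables, tuple(a)) - conditional_entropy_brute(
        pmf, variables, tuple(a), tuple(b)
    )


def specific_information_brute(pmf, variables, source, target, y) -> float:
    """Direct evaluation of the target-state-specific information."""
    source, target = tuple(source), tuple(target)
    p_sy = marginal_pmf(pmf, variables, source + target)
    p_s = marginal_pmf(pmf, variables, source)
    p_t = marginal_pmf(pmf, variables, target)
    y = y if isinstance(y, tuple) else (y,)
    p_y = p_t[y]
    total = 0.0
    for s_key in p_s:
        psy = p_sy.get(s_key + y, 0.0)
        if psy <= 0:
            continue
        total += (psy / p_y) * (math.log2(psy / p_s[s_key]) - math.log2(p_y))
    return total


def imin_brute(pmf, variables, groups, target) -> float:
    """Expected minimum specific information over the source groups."""
    target = tuple(target)
    p_t = marginal_pmf(pmf, variables, target)
    total = 0.0
    for y, p_y in p_t.items():
        if p_y <= 0:
            continue
        total += p_y * min(
            specific_information_brute(pmf, variables, g, target, y)
            for g in groups
        )
    return total


def pid2_brute(pmf, variables, s1, s2, target):
    """Two-source atoms from the redundancy plus the consistency identities."""
    red = imin_brute(pmf, variables, [tuple(s1), tuple(s2)], target)
    i1 = mutual_information_brute(pmf, variables, tuple(s1), target)
    i2 = mutual_information_brute(pmf, variables, tuple(s2), target)
    i12 = mutual_information_brute(pmf, variables, tuple(s1) + tuple(s2), target)
    unq1 = i1 - red
    unq2 = i2 - red
    syn = i12 - red - unq1 - unq2
    return {"red": red, "unq1": unq1, "unq2": unq2, "syn": syn, "joint": i12}


def enumerate_antichains(n: int) -> list:
    """Exhaustive antichain enumeration over {1..n} (independent of the
    package's lattice builder)."""
    elements = list(range(1, n + 1))
    subsets = []
    for r in range(1, n + 1):
        subsets.extend(frozenset(c) for c in itertools.combinations(elements, r))
    antichains = []
    for r in range(1, len(subsets) + 1):
        for combo in itertools.combinations(subsets, r):
            if all(
                not (a < b or b < a) for a, b in itertools.combinations(combo, 2)
            ):
                antichains.append(frozenset(combo))
    return antichains


def cond_mi_bits(q: np.ndarray) -> float:
    """I(X1; Y | X2) in bits for an array over axes (x1, x2, y)."""

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    return (
        h(q.sum(axis=2)) + h(q.sum(axis=0)) - h(q) - h(q.sum(axis=(0, 2)))
    )


def broja_unique_dense(p: np.ndarray, n_coarse: int = 41, n_fine: int = 41) -> float:
    """Dense search for min I_Q(X1;Y|X2) over the marginal polytope.

    Only 2x2x|Y| supports: each target slice is a 2x2 transportation
    polytope with one free parameter, so the feasible set is a box in
    |Y| dimensions.  A coarse grid pass is refined once around the best
    corner, which resolves the optimum far beyond the 1e-4 comparison
    tolerance (the objective is smooth and convex on the box).
    """
    assert p.shape[0] == 2 and p.shape[1] == 2
    p13 = p.sum(axis=1)
    p23 = p.sum(axis=0)
    p_y = p13.sum(axis=0)
    c = p.shape[2]

    def q_of(t_vec):
        q = np.zeros_like(p)
        for k in range(c):
            if p_y[k] <= 0:
                continue
            a0, b0 = p13[0, k], p23[0, k]
            t = t_vec[k]
            q[0, 0, k] = t
            q[0, 1, k] = a0 - t
            q[1, 0, k] = b0 - t
            q[1, 1, k] = p_y[k] - a0 - b0 + t
        return q

    bounds = []
    for k in range(c):
        if p_y[k] <= 0:
            bounds.append((0.0, 0.0))
            continue
        a0, b0 = p13[0, k], p23[0, k]
        bounds.append((max(0.0, a0 + b0 - p_y[k]), min(a0, b0)))

    def search(grids):
        best_v, best_t = np.inf, None
        for t_vec in itertools.product(*grids):
            q = q_of(np.array(t_vec))
            if (q < -1e-12).any():
                continue
            v = cond_mi_bits(np.clip(q, 0, None))
            if v < best_v:
                best_v, best_t = v, np.array(t_vec)
        return best_v, best_t

    grids = [np.linspace(lo, hi, n_coarse) for lo, hi in bounds]
    best_v, best_t = search(grids)
    # refine around the coarse optimum
    fine = []
    for k, (lo, hi) in enumerate(bounds):
        span = (hi - lo) / (n_coarse - 1) if hi > lo else 0.0
        fine.append(
            np.linspace(
                max(lo, best_t[k] - span), min(hi, best_t[k] + span), n_fine
            )
        )
    v2, _ = search(fine)
    return min(best_v, v2)


def ols_normal_equations(y, x1, x2):
    """Interaction-design least squares via the normal equations."""
    X = np.column_stack([np.ones_like(y, dtype=float), x1, x2, x1 * x2])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


def random_joint(rng: np.random.Generator, shape, concentration: float = 0.7):
    """Random categorical joint distribution (Dirichlet over all cells)."""
    n = int(np.prod(shape))
    return rng.dirichlet(np.full(n, concentration)).reshape(shape)
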
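"""Redundancy lattice, specific information, and the Imin decomposition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synpid import (
    SourceCollection,
    build_lattice,
    classify_atoms,
    imin_redundancy,
    mutual_information,
    node_label,
    pid_imin,
    specific_information,
    whole_minus_sum,
)
from synpid.lattice import _node_leq

from .conftest import make_dist
from . import oracles


class TestSpecificInformation:
    def test_independent_source_is_zero_for_every_state(self):
        arr = np.einsum("i,j,k->ijk", [0.5, 0.5], [0.3, 0.7], [0.4, 0.6])
        d = make_dist(arr)
        for y in (0, 1):
            assert specific_information(d, "X1", "Y", y) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_copy_fully_disambiguates(self, gates):
        assert specific_information(
            gates["copy_x1"], "X1", "Y", 0
        ) == pytest.approx(1.0, abs=1e-12)

    def test_and_gate_matches_exhaustive_evaluation(self, gates):
        pmf = gates["and"].pmf()
        for y in (0, 1):
            expected = oracles.specific_information_brute(
                pmf, gates["and"].variables, ("X1",), ("Y",), y
            )
            assert specific_information(
                gates["and"], "X1", "Y", y
            ) == pytest.approx(expected, abs=1e-12)

    def test_expectation_recovers_mutual_information(self, rng):
        d = make_dist(oracles.random_joint(rng, (3, 2, 4)))
        total = sum(
            d.marginal("Y").probs[y] * specific_information(d, "X1", "Y", y)
            for y in range(4)
            if d.marginal("Y").probs[y] > 0
        )
        assert total == pytest.approx(mutual_information(d, "X1", "Y"), abs=1e-9)

    def test_zero_probability_state_rejected(self):
        d = make_dist(
            np.array([[[0.5, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.5, 0.0]]])
        )
        with pytest.raises(ValueError, match="zero probability"):
            specific_information(d, "X1", "Y", 1)


class TestIminRedundancy:
    def test_single_group_equals_mutual_information(self, gates):
        d = gates["and"]
        assert imin_redundancy(d, [("X1",)], "Y") == pytest.approx(
            mutual_information(d, "X1", "Y"), abs=1e-12
        )

    def test_duplicated_sources(self, gates):
        assert imin_redundancy(
            gates["redundant_copy"], [("X1",), ("X2",)], "Y"
        ) == pytest.approx(1.0, abs=1e-12)

    def test_and_gate_matches_brute_force(self, gates):
        expected = oracles.imin_brute(
            gates["and"].pmf(), gates["and"].variables, [("X1",), ("X2",)], ("Y",)
        )
        got = imin_redundancy(gates["and"], [("X1",), ("X2",)], "Y")
        assert got == pytest.approx(expected, abs=1e-12)
        assert got > 0.3  # strictly positive despite independent sources

    def test_target_inside_source_rejected(self, gates):
        with pytest.raises(ValueError, match="source group"):
            imin_redundancy(gates["and"], [("X1", "Y")], "Y")

    def test_antichain_property_enforced(self):
        with pytest.raises(ValueError, match="antichain"):
            SourceCollection([("X1",), ("X1", "X2")])


class TestLattice:
    def test_two_source_lattice(self):
        lat = build_lattice(2)
        assert len(lat.nodes) == 4
        labels = {node_label(n) for n in lat.nodes}
        assert labels == {"{1}{2}", "{1}", "{2}", "{12}"}
        bottom = next(n for n in lat.nodes if node_label(n) == "{1}{2}")
        top = next(n for n in lat.nodes if node_label(n) == "{12}")
        for n in lat.nodes:
            if n != bottom:
                assert lat.leq(bottom, n)
            if n != top:
                assert lat.leq(n, top)

    def test_three_source_lattice_has_18_nodes(self):
        lat = build_lattice(3)
        assert len(lat.nodes) == 18
        # independent exhaustive enumeration
        assert len(oracles.enumerate_antichains(3)) == 18

    def test_order_is_antisymmetric_and_transitive(self):
        lat = build_lattice(3)
        for a in lat.nodes:
            for b in lat.nodes:
                if a != b and _node_leq(a, b) and _node_leq(b, a):
                    pytest.fail("antisymmetry violated")
                for c in lat.nodes:
                    if _node_leq(a, b) and _node_leq(b, c):
                        assert _node_leq(a, c)

    def test_four_sources_unsupported(self):
        with pytest.raises(ValueError, match="supported"):
            build_lattice(4)


class TestPidImin:
    def test_xor(self, gates):
        r = pid_imin(gates["xor"], [("X1",), ("X2",)], "Y")
        assert r.synergy == pytest.approx(1.0, abs=1e-12)
        assert r.redundancy == pytest.approx(0.0, abs=1e-12)
        assert r.unique == [pytest.approx(0.0, abs=1e-12)] * 2

    def test_relabeled_source_is_pure_redundancy(self):
        # X2 an exact relabeling of X1; target = X1
        pmf = {(0, "b", 0): 0.5, (1, "a", 1): 0.5}
        sup = {"X1": (0, 1), "X2": ("a", "b"), "Y": (0, 1)}
        from synpid import JointDistribution

        d = JointDistribution.from_pmf(["X1", "X2", "Y"], sup, pmf)
        r = pid_imin(d, [("X1",), ("X2",)], "Y")
        assert r.redundancy == pytest.approx(
            mutual_information(d, "X1", "Y"), abs=1e-12
        )
        assert r.synergy == pytest.approx(0.0, abs=1e-12)
        assert max(r.unique) == pytest.approx(0.0, abs=1e-12)

    def test_and_gate_matches_oracle(self, gates):
        expected = oracles.pid2_brute(
            gates["and"].pmf(), gates["and"].variables, ("X1",), ("X2",), ("Y",)
        )
        r = pid_imin(gates["and"], [("X1",), ("X2",)], "Y")
        assert r.redundancy == pytest.approx(expected["red"], abs=1e-12)
        assert r.unique[0] == pytest.approx(expected["unq1"], abs=1e-12)
        assert r.synergy == pytest.approx(expected["syn"], abs=1e-12)

    def test_constant_target_gives_zero_atoms(self):
        arr = np.zeros((2, 2, 2))
        arr[:, :, 0] = 0.25
        d = make_dist(arr)
        r = pid_imin(d, [("X1",), ("X2",)], "Y")
        assert all(v == 0.0 for v in r.atoms.values())
        assert r.fractions is None

    def test_serialization(self, gates, tmp_path):
        r = pid_imin(gates["and"], [("X1",), ("X2",)], "Y")
        path = tmp_path / "pid.tsv"
        r.to_text(path)
        text = path.read_text()
        assert "{1}{2}" in text and "joint_mi" in text


class TestClassifyAtoms:
    def test_two_source_has_no_exotic(self, gates):
        c = classify_atoms(pid_imin(gates["and"], [("X1",), ("X2",)], "Y"))
        assert c.bits["exotic"] == 0.0
        assert not c.nodes["exotic"]

    def test_three_source_category_counts(self, gates):
        r = pid_imin(gates["parity3"], [("X1",), ("X2",), ("X3",)], "Y")
        c = classify_atoms(r)
        assert len(c.nodes["redundant"]) == 4
        assert len(c.nodes["unique"]) == 3
        assert len(c.nodes["synergistic"]) == 4
        assert len(c.nodes["exotic"]) == 7

    def test_parity3_is_pure_top_synergy(self, gates):
        r = pid_imin(gates["parity3"], [("X1",), ("X2",), ("X3",)], "Y")
        assert r.atom("{123}") == pytest.approx(r.joint_mi, abs=1e-9)
        c = classify_atoms(r)
        assert c.bits["synergistic"] == pytest.approx(1.0, abs=1e-9)
        assert c.bits["redundant"] == pytest.approx(0.0, abs=1e-9)

    def test_category_totals_sum_to_joint_mi(self, rng):
        d = make_dist(
            oracles.random_joint(rng, (2, 2, 2, 3)), names=("X1", "X2", "X3", "Y")
        )
        r = pid_imin(d, [("X1",), ("X2",), ("X3",)], "Y")
        c = classify_atoms(r)
        assert sum(c.bits.values()) == pytest.approx(r.joint_mi, abs=1e-6)


@given(st.integers(0, 2**32 - 1))
def test_imin_consistency_identities_and_nonnegativity(seed):
    """Red + Unq_i recovers each marginal MI; atoms are non-negative and sum
    to the joint MI; whole-minus-sum equals Syn - Red."""
    rng = np.random.default_rng(seed)
    shape = (
        int(rng.integers(2, 5)),
        int(rng.integers(2, 5)),
        int(rng.integers(2, 6)),
    )
    d = make_dist(oracles.random_joint(rng, shape))
    r = pid_imin(d, [("X1",), ("X2",)], "Y")
    assert r.redundancy + r.unique[0] == pytest.approx(r.marginal_mi[0], abs=1e-6)
    assert r.redundancy + r.unique[1] == pytest.approx(r.marginal_mi[1], abs=1e-6)
    assert sum(r.atoms.values()) == pytest.approx(r.joint_mi, abs=1e-6)
    assert min(r.atoms.values()) >= -1e-9
    wms = whole_minus_sum(d, [("X1",), ("X2",)], "Y")
    assert wms == pytest.approx(r.synergy - r.redundancy, abs=1e-9)


@given(st.integers(0, 2**32 - 1))
def test_mobius_route_agrees_with_algebraic_route(seed):
    """For two sources the lattice inversion must match solving the linear
    identity system from the redundancy alone."""
    rng = np.random.default_rng(seed)
    d = make_dist(oracles.random_joint(rng, (2, 3, 3)))
    r = pid_imin(d, [("X1",), ("X2",)], "Y")
    red = imin_redundancy(d, [("X1",), ("X2",)], "Y")
    i1, i2 = r.marginal_mi
    assert r.redundancy == pytest.approx(red, abs=1e-9)
    assert r.unique[0] == pytest.approx(max(i1 - red, 0.0), abs=1e-9)
    assert r.unique[1] == pytest.approx(max(i2 - red, 0.0), abs=1e-9)
    assert r.synergy == pytest.approx(
        r.joint_mi - red - (i1 - red) - (i2 - red), abs=1e-9
    )
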
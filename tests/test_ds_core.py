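"""Belief-function algebra: worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest

from evicomb.ds_core import (Frame, MassFunction, NotCombinableError, belief,
                             combine, combine_all, conflict, make_bba,
                             pignistic, plausibility, read_bba, write_bba)

from .conftest import random_mass_function
from .helpers import (brute_belief, brute_combine, brute_combine3,
                      brute_conflict, brute_pignistic, brute_plausibility,
                      powerset, random_normal_bba)


def as_focal_dict(m: MassFunction) -> dict:
    return {frozenset(members): mass for members, mass in m.items()}


class TestConstruction:
    def test_certain_and_vacuous(self, frame_ab):
        certain = make_bba(frame_ab, {("a",): 1.0})
        assert certain.mass(("a",)) == 1.0
        vac = make_bba(frame_ab, {("a", "b"): 1.0})
        assert vac.mass(("a", "b")) == 1.0

    def test_sum_violation_rejected(self, frame_ab):
        with pytest.raises(ValueError, match="sum"):
            make_bba(frame_ab, {("a",): 0.6, ("b",): 0.5})

    def test_negative_mass_and_empty_focal_rejected(self, frame_ab):
        with pytest.raises(ValueError, match="negative"):
            make_bba(frame_ab, {("a",): -0.1, ("b",): 1.1})
        with pytest.raises(ValueError, match="empty"):
            make_bba(frame_ab, {(): 0.5, ("a",): 0.5})

    def test_tiny_deviation_renormalized(self, frame_ab):
        m = make_bba(frame_ab, {("a",): 0.5, ("b",): 0.5 + 5e-7})
        assert sum(mass for _, mass in m.items()) == pytest.approx(1.0, abs=1e-12)

    def test_frame_needs_unique_classes(self):
        with pytest.raises(ValueError):
            Frame(("a", "a"))
        with pytest.raises(ValueError):
            Frame(("a",))


class TestBeliefPlausibility:
    @pytest.fixture
    def m(self, frame_abc):
        return make_bba(frame_abc, {("a",): 0.3, ("a", "b"): 0.7})

    @pytest.mark.parametrize("subset,expected", [
        (("a", "b"), 1.0), (("a",), 0.3), ((), 0.0), (("a", "b", "c"), 1.0),
    ])
    def test_belief_examples(self, m, subset, expected):
        assert belief(m, subset) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("subset,expected", [
        (("c",), 0.0), (("a",), 1.0), (("a", "b", "c"), 1.0),
    ])
    def test_plausibility_examples(self, m, subset, expected):
        assert plausibility(m, subset) == pytest.approx(expected, abs=1e-12)

    def test_vacuous_maximizes_plausibility(self, frame_ab):
        vac = MassFunction.vacuous(frame_ab)
        assert plausibility(vac, ("a",)) == 1.0
        assert belief(vac, ("a",)) == 0.0

    def test_unknown_class_rejected(self, m):
        with pytest.raises(KeyError):
            belief(m, ("z",))


class TestCombination:
    def test_conflict_example(self, frame_ab):
        m1 = make_bba(frame_ab, {("a",): 0.6, ("a", "b"): 0.4})
        m2 = make_bba(frame_ab, {("b",): 0.5, ("a", "b"): 0.5})
        assert conflict(m1, m2) == pytest.approx(0.3, abs=1e-12)

    def test_vacuous_has_no_conflict_and_is_neutral(self, frame_abc):
        rng = np.random.default_rng(7)
        m = random_mass_function(rng, frame_abc)
        vac = MassFunction.vacuous(frame_abc)
        assert conflict(m, vac) == 0.0
        combined = combine(vac, m)
        for members, mass in m.items():
            assert combined.mass(members) == pytest.approx(mass, abs=1e-12)

    def test_total_conflict_raises(self, frame_ab):
        m1 = make_bba(frame_ab, {("a",): 1.0})
        m2 = make_bba(frame_ab, {("b",): 1.0})
        assert conflict(m1, m2) == 1.0
        with pytest.raises(NotCombinableError):
            combine(m1, m2)

    def test_combine_worked_example(self, frame_ab):
        m1 = make_bba(frame_ab, {("a",): 0.6, ("a", "b"): 0.4})
        m2 = make_bba(frame_ab, {("b",): 0.5, ("a", "b"): 0.5})
        m12 = combine(m1, m2)
        assert m12.mass(("a",)) == pytest.approx(3 / 7, abs=1e-9)
        assert m12.mass(("b",)) == pytest.approx(2 / 7, abs=1e-9)
        assert m12.mass(("a", "b")) == pytest.approx(2 / 7, abs=1e-9)

    def test_mismatched_frames_rejected(self, frame_ab, frame_abc):
        with pytest.raises(ValueError):
            conflict(MassFunction.vacuous(frame_ab), MassFunction.vacuous(frame_abc))

    def test_combine_all_single_and_vacuous(self, frame_abc):
        rng = np.random.default_rng(3)
        m = random_mass_function(rng, frame_abc)
        vac = MassFunction.vacuous(frame_abc)
        assert as_focal_dict(combine_all([m])) == as_focal_dict(m)
        out = combine_all([vac, vac, m])
        for members, mass in m.items():
            assert out.mass(members) == pytest.approx(mass, abs=1e-12)

    def test_combine_all_matches_triple_enumeration(self, frame_abc):
        rng = np.random.default_rng(11)
        done = 0
        while done < 20:
            ms = [random_mass_function(rng, frame_abc) for _ in range(3)]
            try:
                result = combine_all(ms)
            except NotCombinableError:
                continue  # totally conflicting draw; not the property under test
            done += 1
            expected = brute_combine3(*[as_focal_dict(m) for m in ms])
            got = as_focal_dict(result)
            assert set(got) == set(expected)
            for key in expected:
                assert got[key] == pytest.approx(expected[key], abs=1e-9)

    def test_combine_all_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_all([])


class TestPignistic:
    def test_bayesian_identity(self, frame_abc):
        m = make_bba(frame_abc, {("a",): 0.2, ("b",): 0.5, ("c",): 0.3})
        assert pignistic(m).probs == pytest.approx([0.2, 0.5, 0.3], abs=1e-12)

    def test_worked_expansion(self, frame_abc):
        m = make_bba(frame_abc, {("a",): 0.4, ("a", "b"): 0.6})
        assert pignistic(m).probs == pytest.approx([0.7, 0.3, 0.0], abs=1e-9)

    def test_vacuous_is_uniform(self):
        frame = Frame((1, 2, 3, 4))
        assert pignistic(MassFunction.vacuous(frame)).probs == pytest.approx(
            [0.25] * 4, abs=1e-12)


class TestRandomizedOracleEquivalence:
    """The bitmask implementation against frozenset brute-force enumeration."""

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_belief_plausibility_duality_and_oracle(self, n_classes):
        rng = np.random.default_rng(100 + n_classes)
        classes = tuple(range(n_classes))
        frame = Frame(classes)
        for _ in range(1000 // n_classes):
            focal = random_normal_bba(rng, classes)
            m = MassFunction(frame, {frame.to_mask(tuple(s)): v
                                     for s, v in focal.items()})
            for A in powerset(classes):
                comp = tuple(c for c in classes if c not in A)
                b, p = belief(m, A), plausibility(m, A)
                assert b == pytest.approx(brute_belief(focal, A), abs=1e-9)
                assert p == pytest.approx(brute_plausibility(focal, A), abs=1e-9)
                assert b <= p + 1e-9
                assert p == pytest.approx(1.0 - belief(m, comp), abs=1e-9)

    def test_combination_oracle_and_algebraic_laws(self):
        rng = np.random.default_rng(2024)
        classes = ("a", "b", "c", "d")
        frame = Frame(classes)
        done = 0
        while done < 100:
            f1, f2, f3 = (random_normal_bba(rng, classes) for _ in range(3))
            if (brute_conflict(f1, f2) > 0.99 or brute_conflict(f2, f3) > 0.99
                    or brute_conflict(brute_combine(f1, f2), f3) > 0.99):
                continue  # near-total conflict is rejected by design
            done += 1
            ms = [MassFunction(frame, {frame.to_mask(tuple(s)): v
                                       for s, v in f.items()})
                  for f in (f1, f2, f3)]
            expected = brute_combine(f1, f2)
            got = as_focal_dict(combine(ms[0], ms[1]))
            for key in expected:
                assert got.get(key, 0.0) == pytest.approx(expected[key], abs=1e-9)
            # commutativity and associativity
            ab = combine(ms[0], ms[1])
            ba = combine(ms[1], ms[0])
            for members, mass in ab.items():
                assert ba.mass(members) == pytest.approx(mass, abs=1e-9)
            left = combine(combine(ms[0], ms[1]), ms[2])
            right = combine(ms[0], combine(ms[1], ms[2]))
            for members, mass in left.items():
                assert right.mass(members) == pytest.approx(mass, abs=1e-9)

    def test_pignistic_oracle_sum_and_permutation_equivariance(self):
        rng = np.random.default_rng(99)
        classes = ("a", "b", "c")
        frame = Frame(classes)
        for _ in range(200):
            focal = random_normal_bba(rng, classes)
            m = MassFunction(frame, {frame.to_mask(tuple(s)): v
                                     for s, v in focal.items()})
            betp = pignistic(m)
            assert betp.probs.sum() == pytest.approx(1.0, abs=1e-9)
            oracle = brute_pignistic(focal, classes)
            for i, c in enumerate(classes):
                assert betp.probs[i] == pytest.approx(oracle[c], abs=1e-9)
            # relabel the frame by a random permutation: probabilities follow
            perm = rng.permutation(3)
            pclasses = tuple(classes[i] for i in perm)
            pframe = Frame(pclasses)
            pm = MassFunction(pframe, {pframe.to_mask(tuple(s)): v
                                       for s, v in focal.items()})
            pbetp = pignistic(pm)
            for c in classes:
                assert pbetp.probs[pclasses.index(c)] == pytest.approx(
                    betp.probs[classes.index(c)], abs=1e-9)


class TestPropertyBased:
    """Structural invariants over arbitrary valid mass assignments."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=7))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_bounds_and_unit_sums_for_arbitrary_bbas(self, raw):
        frame = Frame(("a", "b", "c"))
        subsets = [s for s in powerset(frame.classes) if s][: len(raw)]
        total = sum(raw)
        m = make_bba(frame, {s: v / total for s, v in zip(subsets, raw)})
        betp = pignistic(m)
        assert betp.probs.sum() == pytest.approx(1.0, abs=1e-9)
        for A in powerset(frame.classes):
            b, p = belief(m, A), plausibility(m, A)
            assert -1e-12 <= b <= p + 1e-9 <= 1 + 2e-9
        assert belief(m, frame.classes) == pytest.approx(1.0, abs=1e-9)


def test_bba_text_round_trip(tmp_path, frame_abc):
    rng = np.random.default_rng(5)
    m = random_mass_function(rng, frame_abc)
    path = tmp_path / "bba.tsv"
    write_bba(m, path)
    back = read_bba(path)
    assert back.frame.classes == frame_abc.classes
    for members, mass in m.items():
        assert back.mass(members) == mass  # repr round trip is exact
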
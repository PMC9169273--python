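import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemdepict.param_space import (
    FeatureFingerprint,
    FingerprintScheme,
    ParameterDecision,
    assignment_to_fingerprint,
    binary,
    building_blocks,
    categorical,
    count_valid_fingerprints,
    enumerate_valid_fingerprints,
    fingerprint_at_index,
    fingerprint_to_assignment,
    int_range,
    ranged_subranges,
    real_range,
    register_decision,
    sample_assignment,
    scheme_from_json,
    scheme_to_json,
)

WORKED_EXAMPLE_FPS = {
    (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1),
    (1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 1),
}


class TestRegisterDecision:
    def test_binary_on_empty_scheme(self):
        scheme = register_decision(FingerprintScheme(), binary("kekulised"))
        assert scheme.total_length == 1
        assert scheme.layout == ((0, 1),)

    def test_categorical_span_positions(self, worked_example_scheme):
        # bond width occupies positions 1-3 after the binary at position 0
        assert worked_example_scheme.layout == ((0, 1), (1, 4))
        assert worked_example_scheme.total_length == 4

    def test_duplicate_name_rejected(self):
        scheme = register_decision(FingerprintScheme(), binary("x"))
        with pytest.raises(ValueError, match="already registered"):
            register_decision(scheme, binary("x"))

    def test_categorical_single_option_rejected(self):
        with pytest.raises(ValueError, match=">= 2 options"):
            categorical("width", ["only"])

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="low < high"):
            int_range("r", 5, 5)

    def test_order_stable_layout(self):
        decisions = [binary("a"), categorical("b", [1, 2, 3]), int_range("c", 1, 9)]
        s1 = FingerprintScheme()
        s2 = FingerprintScheme()
        for d in decisions:
            s1 = register_decision(s1, d)
            s2 = register_decision(s2, d)
        assert s1.layout == s2.layout
        assert s1 == s2


class TestBuildingBlocks:
    def test_binary(self):
        assert building_blocks(binary("k")) == [(0,), (1,)]

    def test_categorical_three(self):
        blocks = building_blocks(categorical("w", ["thin", "medium", "bold"]))
        assert blocks == [(1, 0, 0), (0, 1, 0), (0, 0, 1)]

    def test_ranged_one_to_six_subranges(self):
        d = int_range("bw", 1, 6)
        assert building_blocks(d) == [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        assert ranged_subranges(d) == [(1, 2), (3, 4), (5, 6)]

    def test_ranged_remainder_goes_to_last(self):
        assert ranged_subranges(int_range("r", 0, 7)) == [(0, 1), (2, 3), (4, 7)]

    def test_real_range_thirds(self):
        subs = ranged_subranges(real_range("p", 0.0, 3.0))
        assert subs == [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)]


class TestCounting:
    def test_worked_example_count(self, worked_example_scheme):
        assert count_valid_fingerprints(worked_example_scheme) == 6

    def test_empty_scheme(self):
        assert count_valid_fingerprints(FingerprintScheme()) == 1

    def test_style_a_count(self, profiles):
        assert count_valid_fingerprints(profiles["STYLE_A"].scheme) == 2_799_360


class TestEnumeration:
    def test_worked_example_exact_set(self, worked_example_scheme):
        fps = {f.bits for f in enumerate_valid_fingerprints(worked_example_scheme)}
        assert fps == WORKED_EXAMPLE_FPS

    def test_single_binary(self):
        scheme = register_decision(FingerprintScheme(), binary("x"))
        assert {f.bits for f in enumerate_valid_fingerprints(scheme)} == {(0,), (1,)}

    def test_two_categoricals_match_nested_loop_oracle(self):
        scheme = FingerprintScheme()
        scheme = register_decision(scheme, categorical("a", ["x", "y", "z"]))
        scheme = register_decision(scheme, categorical("b", ["u", "v", "w"]))
        got = [f.bits for f in enumerate_valid_fingerprints(scheme)]

        onehots = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        expected = []
        for first in onehots:  # independent nested-loop oracle
            for second in onehots:
                expected.append(first + second)
        assert got == expected
        assert len(got) == 9

    def test_guard_refuses_large_schemes(self, profiles):
        with pytest.raises(ValueError, match="guard"):
            enumerate_valid_fingerprints(profiles["STYLE_A"].scheme, guard=1000)

    def test_count_matches_enumeration(self, profiles):
        scheme = profiles["STYLE_C"].scheme
        fps = enumerate_valid_fingerprints(scheme)
        assert len(fps) == count_valid_fingerprints(scheme) == 864
        assert len({f.bits for f in fps}) == 864

    def test_index_decode_matches_enumeration(self, profiles):
        scheme = profiles["STYLE_C"].scheme
        fps = enumerate_valid_fingerprints(scheme)
        for i in [0, 1, 17, 100, 863]:
            assert fingerprint_at_index(scheme, i).bits == fps[i].bits
        with pytest.raises(IndexError):
            fingerprint_at_index(scheme, 864)


class TestSampleAssignment:
    def test_same_seed_identical(self, worked_example_scheme):
        a1 = sample_assignment(worked_example_scheme, np.random.default_rng(7))
        a2 = sample_assignment(worked_example_scheme, np.random.default_rng(7))
        assert a1 == a2

    def test_ranged_domain_containment(self):
        scheme = register_decision(FingerprintScheme(), int_range("bw", 1, 6))
        rng = np.random.default_rng(3)
        for _ in range(200):
            assert sample_assignment(scheme, rng)["bw"] in {1, 2, 3, 4, 5, 6}

    def test_categorical_uniformity_5_sigma(self):
        # 6000 draws of a 3-way choice: each count within 5 sigma of 2000
        scheme = register_decision(
            FingerprintScheme(), categorical("w", ["a", "b", "c"])
        )
        rng = np.random.default_rng(11)
        counts = {"a": 0, "b": 0, "c": 0}
        for _ in range(6000):
            counts[sample_assignment(scheme, rng)["w"]] += 1
        sigma = (6000 * (1 / 3) * (2 / 3)) ** 0.5
        for v in counts.values():
            assert abs(v - 2000) < 5 * sigma


class TestFingerprintToAssignment:
    def test_worked_example_mapping(self, worked_example_scheme):
        fp = FeatureFingerprint((1, 1, 0, 0), "example")
        a = fingerprint_to_assignment(worked_example_scheme, fp, np.random.default_rng(0))
        assert a == {"kekulised": 1, "bond_width": "thin"}

    def test_multi_hot_span_rejected(self, worked_example_scheme):
        fp = FeatureFingerprint((0, 1, 0, 1), "example")
        with pytest.raises(ValueError, match="bond_width"):
            fingerprint_to_assignment(worked_example_scheme, fp, np.random.default_rng(0))

    def test_all_zero_span_rejected(self, worked_example_scheme):
        fp = FeatureFingerprint((1, 0, 0, 0), "example")
        with pytest.raises(ValueError, match="bond_width"):
            fingerprint_to_assignment(worked_example_scheme, fp, np.random.default_rng(0))

    def test_ranged_draw_stays_in_hot_subrange(self):
        scheme = register_decision(FingerprintScheme(), int_range("bw", 1, 6))
        fp = FeatureFingerprint((0, 1, 0))  # middle block -> [3, 4]
        seen = set()
        for seed in range(1000):
            a = fingerprint_to_assignment(scheme, fp, np.random.default_rng(seed))
            seen.add(a["bw"])
        assert seen == {3, 4}

    def test_every_enumerated_fingerprint_is_valid(self, profiles):
        scheme = profiles["STYLE_C"].scheme
        rng = np.random.default_rng(0)
        for fp in enumerate_valid_fingerprints(scheme):
            a = fingerprint_to_assignment(scheme, fp, rng)
            assert set(a) == {d.name for d in scheme.decisions}

    def test_one_bit_perturbations_rejected(self, worked_example_scheme):
        # flipping any single bit of a one-hot span breaks validity
        base = (1, 0, 1, 0)
        for pos in (1, 2, 3):
            bits = list(base)
            bits[pos] ^= 1
            with pytest.raises(ValueError):
                fingerprint_to_assignment(
                    worked_example_scheme,
                    FeatureFingerprint(tuple(bits)),
                    np.random.default_rng(0),
                )


class TestAssignmentToFingerprint:
    def test_binary_one(self):
        scheme = register_decision(FingerprintScheme(), binary("k"))
        assert assignment_to_fingerprint(scheme, {"k": 1}).bits == (1,)

    def test_ranged_middle_block(self):
        scheme = register_decision(FingerprintScheme(), int_range("bw", 1, 6))
        assert assignment_to_fingerprint(scheme, {"bw": 4}).bits == (0, 1, 0)

    def test_out_of_domain_rejected(self):
        scheme = register_decision(FingerprintScheme(), int_range("bw", 1, 6))
        with pytest.raises(ValueError, match="outside"):
            assignment_to_fingerprint(scheme, {"bw": 9})

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_preserves_discrete_values(self, seed, profiles):
        scheme = profiles["STYLE_A"].scheme
        rng = np.random.default_rng(seed)
        for _ in range(20):  # 25 x 20 = 500 random assignments
            a = sample_assignment(scheme, rng)
            fp = assignment_to_fingerprint(scheme, a)
            back = fingerprint_to_assignment(scheme, fp, rng)
            for d in scheme.decisions:
                if d.kind in ("binary", "categorical"):
                    assert back[d.name] == a[d.name]
                else:
                    subs = ranged_subranges(d)
                    block = next(
                        i for i, (lo, hi) in enumerate(subs) if lo <= a[d.name] <= hi
                    )
                    lo, hi = subs[block]
                    assert lo <= back[d.name] <= hi


class TestSerialization:
    def test_json_round_trip(self, profiles):
        for p in profiles.values():
            restored = scheme_from_json(scheme_to_json(p.scheme))
            assert restored == p.scheme
            assert restored.layout == p.scheme.layout


class TestReferenceProfiles:
    @pytest.mark.parametrize(
        "style,n_decisions,n_fingerprints",
        [("STYLE_A", 15, 2_799_360), ("STYLE_B", 10, 18_432), ("STYLE_C", 8, 864)],
    )
    def test_decision_and_fingerprint_counts(
        self, profiles, style, n_decisions, n_fingerprints
    ):
        scheme = profiles[style].scheme
        assert len(scheme) == n_decisions
        assert count_valid_fingerprints(scheme) == n_fingerprints
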
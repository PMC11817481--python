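import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wdpscan import constants as C
from wdpscan.io import ProteinRecord
from wdpscan.physchem import (aliphatic_index, gravy, instability_index,
                              isoelectric_point, net_charge, physchem_profile,
                              PhyschemProfile)
from conftest import random_sequence

SEQ = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=60)


# ---- independent naive oracles (plain loops over the constant tables) ----

def naive_gravy(seq):
    total = 0.0
    for aa in seq:
        total += C.KYTE_DOOLITTLE.get(aa, 0.0)
    return total / len(seq)


def naive_ii(seq):
    total = 0.0
    for i in range(len(seq) - 1):
        pair = C.DIWV.get(seq[i], {})
        total += pair.get(seq[i + 1], C.DIWV_DEFAULT)
    return 10.0 / len(seq) * total


def naive_ai(seq):
    counts = {"A": 0, "V": 0, "I": 0, "L": 0}
    for aa in seq:
        if aa in counts:
            counts[aa] += 1
    n = len(seq)
    return (100.0 * counts["A"] / n + 2.9 * 100.0 * counts["V"] / n
            + 3.9 * 100.0 * (counts["I"] + counts["L"]) / n)


def grid_scan_pi(seq, step=1e-3):
    """Densely scan pH for the sign change of the same charge function."""
    ph = 0.0
    prev = net_charge(seq, ph)
    while ph < 14.0:
        ph += step
        q = net_charge(seq, ph)
        if q <= 0 <= prev:
            return ph - step / 2
        prev = q
    raise AssertionError("no sign change found")


class TestGravy:
    @pytest.mark.parametrize("seq,expected", [
        ("GGGG", -0.4),          # uniform Gly
        ("KK", -3.9),            # uniform Lys
        ("AIV", (1.8 + 4.5 + 4.2) / 3),
    ])
    def test_hand_computed_values(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gravy("")

    @given(seq=SEQ)
    @settings(max_examples=60, deadline=None)
    def test_permutation_and_reversal_invariant(self, seq):
        assert gravy(seq[::-1]) == pytest.approx(gravy(seq), abs=1e-12)
        assert gravy("".join(sorted(seq))) == pytest.approx(gravy(seq), abs=1e-12)


class TestInstabilityIndex:
    def test_dipeptide_table_lookup(self):
        # II("AA") = (10/2) * DIWV(A, A); the pair is unlisted -> default 1.0
        assert instability_index("AA") == pytest.approx(5 * C.diwv("A", "A"))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            instability_index("A")

    def test_not_permutation_invariant(self):
        # same composition, different dipeptides
        assert instability_index("ACDP") != pytest.approx(instability_index("PDCA"))

    @given(seq=SEQ)
    @settings(max_examples=60, deadline=None)
    def test_self_concatenation_matches_oracle(self, seq):
        double = seq + seq
        assert instability_index(double) == pytest.approx(naive_ii(double),
                                                          abs=1e-9)


class TestAliphaticIndex:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAA", 100.0),
        ("VVVV", 290.0),
        ("AVIL", 25 + 2.9 * 25 + 3.9 * 50),
    ])
    def test_hand_computed_values(self, seq, expected):
        assert aliphatic_index(seq) == pytest.approx(expected, abs=1e-12)

    @given(seq=SEQ, k=st.integers(2, 4))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_self_concatenation(self, seq, k):
        # mole percents are unchanged by repeating the chain
        assert aliphatic_index(seq * k) == pytest.approx(aliphatic_index(seq),
                                                         abs=1e-9)


class TestIsoelectricPoint:
    def test_acidic_neutral_basic_ordering(self):
        assert isoelectric_point("DDDD") < isoelectric_point("GGGG") \
            < isoelectric_point("KKKK")

    @given(seq=SEQ)
    @settings(max_examples=40, deadline=None)
    def test_returned_root_has_near_zero_charge(self, seq):
        pi = isoelectric_point(seq)
        assert abs(net_charge(seq, pi)) < 1e-4

    def test_matches_dense_grid_scan(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert isoelectric_point(seq) == pytest.approx(grid_scan_pi(seq),
                                                       abs=2e-3)

    @given(seq=SEQ)
    @settings(max_examples=30, deadline=None)
    def test_net_charge_strictly_decreasing_in_ph(self, seq):
        phs = np.linspace(0.5, 13.5, 27)
        charges = [net_charge(seq, ph) for ph in phs]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    @given(seq=SEQ)
    @settings(max_examples=30, deadline=None)
    def test_inserting_charged_residue_moves_pi_monotonically(self, seq):
        # insert mid-chain so both termini (and their residue-specific
        # pKas) stay fixed and only the side-chain contribution changes
        pi = isoelectric_point(seq)
        basic = seq[:1] + "K" + seq[1:]
        acidic = seq[:1] + "D" + seq[1:]
        assert isoelectric_point(basic) >= pi - 1e-3
        assert isoelectric_point(acidic) <= pi + 1e-3


class TestProfile:
    def test_profile_equals_standalone_operations(self, rng):
        seq = random_sequence(rng, 80)
        profile = physchem_profile(ProteinRecord("P", seq))
        assert profile.gravy == pytest.approx(gravy(seq))
        assert profile.ii == pytest.approx(instability_index(seq))
        assert profile.ai == pytest.approx(aliphatic_index(seq))
        assert profile.pi == pytest.approx(isoelectric_point(seq))

    @pytest.mark.parametrize("ii,expected", [
        (40.0, "stable"),     # the threshold itself is not exceeded
        (40.1, "unstable"),
        (-0.99, "stable"),
    ])
    def test_stability_boundary(self, ii, expected):
        profile = PhyschemProfile("P", 100, 7.0, -1.0, ii, 50.0)
        assert profile.stability_class == expected


class TestOracleAgreement:
    def test_all_indices_match_naive_oracles_on_random_sequences(self, rng):
        for _ in range(200):
            seq = random_sequence(rng, int(rng.integers(2, 400)))
            assert gravy(seq) == pytest.approx(naive_gravy(seq), abs=1e-9)
            assert instability_index(seq) == pytest.approx(naive_ii(seq), abs=1e-9)
            assert aliphatic_index(seq) == pytest.approx(naive_ai(seq), abs=1e-9)

    def test_agreement_with_independent_protparam_implementation(self, rng):
        # Biopython's ProtParam implements the same published definitions
        # and serves as an external cross-check of the constant tables.
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        for _ in range(25):
            seq = random_sequence(rng, int(rng.integers(10, 200)))
            pa = ProteinAnalysis(seq)
            assert gravy(seq) == pytest.approx(pa.gravy(), abs=1e-9)
            assert instability_index(seq) == pytest.approx(
                pa.instability_index(), abs=1e-6)
            assert isoelectric_point(seq) == pytest.approx(
                pa.isoelectric_point(), abs=0.02)
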
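"""Base and expanded phase-separation potentials."""

import math
import random

import numpy as np
import pytest

from parse2.potential import (
    PRESETS,
    PotentialParams,
    expanded_potential,
    ncpr,
    ps_potential,
    scd,
    u_pi,
    u_q,
    window_contributions,
)
from parse2.windows import WindowProperties, window_table

from conftest import random_protein


def make_window(label, distance, u_pi_val=0.0, u_q_val=0.0):
    return WindowProperties(
        start=1, phi=0.0, alpha=0.0, f_ppii=0.5, q_net=0, r_h=10.0,
        v_model=0.5, label=label, distance=distance, scd=0.0, ncpr=0.0,
        u_pi=u_pi_val, u_q=u_q_val,
    )


def brute_scd(window: str) -> float:
    charge = {"K": 1, "R": 1, "D": -1, "E": -1}
    q = [charge.get(aa, 0) for aa in window]
    total = 0.0
    for i in range(len(q)):
        for j in range(i + 1, len(q)):
            total += q[i] * q[j] * math.sqrt(j - i)
    return total / len(q)


class TestBasePotential:
    def test_no_p_windows_gives_zero(self):
        wins = [make_window("F", 2.0), make_window("D", 1.0)]
        assert ps_potential(wins) == 0.0
        assert ps_potential([]) == 0.0

    def test_sums_p_distances(self):
        wins = [
            make_window("P", 0.5),
            make_window("P", 1.2),
            make_window("D", 9.0),
            make_window("P", 0.3),
        ]
        assert ps_potential(wins) == pytest.approx(2.0)

    def test_appending_p_window_adds_exactly_its_distance(self):
        wins = [make_window("P", 0.7), make_window("F", 1.0)]
        before = ps_potential(wins)
        assert ps_potential(wins + [make_window("P", 0.25)]) == pytest.approx(
            before + 0.25
        )

    def test_matches_filter_and_sum_on_real_sequences(self, rng):
        for _ in range(5):
            table = window_table(random_protein(rng, 150))
            brute = sum(
                d for lab, d in zip(table.label, table.distance) if lab == "P"
            )
            assert ps_potential(table) == pytest.approx(brute, abs=1e-12)


class TestUPi:
    def test_zero_without_aromatic_or_basic_residues(self):
        assert u_pi("G" * 25) == 0.0

    def test_hand_value_unbalanced_pair(self):
        # #Y=2, #R=1: a * 3 * (2*1)/|2-1| = 0.28 * 6
        assert u_pi("YYR" + "G" * 22, a=0.28) == pytest.approx(1.68, abs=1e-9)

    def test_hand_value_zero_divisor_forced_to_one(self):
        assert u_pi("YR" + "G" * 23, a=0.28) == pytest.approx(0.84, abs=1e-9)

    def test_composition_only_permutation_invariant(self, rng):
        win = list("YYRKF" + "G" * 20)
        base = u_pi("".join(win))
        for _ in range(5):
            rng.shuffle(win)
            assert u_pi("".join(win)) == pytest.approx(base, abs=1e-12)

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(ValueError, match="position 3"):
            u_pi("GGBGG" + "G" * 20)


class TestScdNcpr:
    def test_uncharged_window_has_zero_scd(self):
        assert scd("G" * 25) == 0.0

    def test_two_charge_hand_value(self):
        # K at 1, E at 6: (+1)(-1) sqrt(5) / 25
        win = "K" + "G" * 4 + "E" + "G" * 19
        assert scd(win) == pytest.approx(-math.sqrt(5) / 25, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            win = random_protein(rng, 25)
            assert scd(win) == pytest.approx(brute_scd(win), abs=1e-12)

    def test_alternating_charges_closer_to_zero_than_diblock(self):
        alternating = "KE" * 12 + "G"
        diblock = "K" * 12 + "E" * 12 + "G"
        assert abs(brute_scd(alternating)) < abs(brute_scd(diblock))
        assert abs(scd(alternating)) < abs(scd(diblock))

    def test_scd_is_position_dependent(self):
        assert scd("KE" * 12 + "G") != scd("K" * 12 + "E" * 12 + "G")

    def test_ncpr_values(self):
        assert ncpr("K" * 25) == 1.0
        assert ncpr("K" + "E" + "G" * 23) == 0.0
        assert ncpr("RRR" + "D" + "S" * 21) == pytest.approx(2 / 25)


class TestUq:
    def test_zero_inputs_zero_everywhere(self):
        for preset in PRESETS.values():
            assert u_q(0.0, 0.0, preset) == 0.0

    def test_csat_hand_value(self):
        val = u_q(-math.sqrt(5) / 25, 0.0, PRESETS["csat"])
        assert val == pytest.approx(16.0 * math.sqrt(5) / 25, abs=1e-9)
        assert val == pytest.approx(1.431, abs=1e-3)

    def test_symmetric_in_ncpr_sign(self):
        preset = PRESETS["delta_g"]
        assert u_q(0.1, -0.08, preset) == u_q(0.1, 0.08, preset)

    def test_published_presets(self):
        assert PRESETS["delta_h"] == PotentialParams(0.14, 8.4, 5.6, "delta_h")
        assert PRESETS["delta_s"] == PotentialParams(0.08, 4.6, 7.0, "delta_s")
        assert PRESETS["delta_g"] == PotentialParams(0.11, 5.2, 5.4, "delta_g")
        assert PRESETS["csat"] == PotentialParams(0.28, -16.0, 33.0, "csat")


class TestExpandedPotential:
    def test_flags_off_reduces_to_base(self, rng):
        for _ in range(5):
            table = window_table(random_protein(rng, 120))
            assert expanded_potential(
                table, include_pi=False, include_q=False
            ) == ps_potential(table)

    def test_zero_weights_reduce_to_base(self, rng):
        zero = PotentialParams(0.0, 0.0, 0.0, "null")
        for _ in range(5):
            table = window_table(random_protein(rng, 120), params=zero)
            assert expanded_potential(table) == ps_potential(table)

    def test_p_window_gains_interaction_energy(self):
        wins = [make_window("P", 0.5, u_pi_val=0.3, u_q_val=0.1)]
        assert expanded_potential(wins) == pytest.approx(0.9)

    def test_d_window_promoted_when_u_exceeds_distance(self):
        wins = [make_window("D", 0.4, u_pi_val=1.0)]
        assert expanded_potential(wins) == pytest.approx(0.6)
        _, promoted = window_contributions(wins)
        assert promoted.tolist() == [True]

    def test_d_window_not_promoted_when_u_small(self):
        wins = [make_window("D", 0.4, u_pi_val=0.3)]
        assert expanded_potential(wins) == 0.0
        _, promoted = window_contributions(wins)
        assert promoted.tolist() == [False]

    def test_f_windows_never_contribute(self):
        wins = [make_window("F", 3.0, u_pi_val=10.0, u_q_val=10.0)]
        assert expanded_potential(wins) == 0.0

    def test_joint_promotion_uses_combined_energy(self):
        # neither term alone exceeds the distance; together they do
        wins = [make_window("D", 0.5, u_pi_val=0.3, u_q_val=0.3)]
        assert expanded_potential(wins, include_q=False) == 0.0
        assert expanded_potential(wins, include_pi=False) == 0.0
        assert expanded_potential(wins) == pytest.approx(0.1)

    def test_explicit_params_reweight_from_raw_fields(self, rng):
        seq = random_protein(rng, 100)
        table = window_table(seq, params=PRESETS["csat"])
        direct = window_table(seq, params=PRESETS["delta_h"])
        assert expanded_potential(
            table, params=PRESETS["delta_h"]
        ) == pytest.approx(expanded_potential(direct), abs=1e-10)
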
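"""Composition traits: residue frequencies, IVYWREL/OGT, charge and pI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from revecol.proteome import CANONICAL_AA
from revecol.synthetic import gen_bimodal_proteome
from revecol.traits import (EMBOSS, IPC_PROTEIN, composition_traits,
                            group_fraction, ivywrel_fraction, net_charge,
                            ogt_from_ivywrel, pi_bias, pi_profile, pi_trough,
                            protein_pi, proteome_pi, residue_frequencies)

from .conftest import grid_scan_pi, make_proteome, random_protein


class TestResidueFrequencies:
    def test_single_residue(self):
        assert residue_frequencies(make_proteome("GGGG")) == pytest.approx(
            {aa: (1.0 if aa == "G" else 0.0) for aa in CANONICAL_AA})

    def test_symmetric_two_residues(self):
        freqs = residue_frequencies(make_proteome("GA", "AG"))
        assert freqs["G"] == pytest.approx(0.5)
        assert freqs["A"] == pytest.approx(0.5)

    def test_ambiguous_dropped_from_both_sides(self):
        with pytest.warns(UserWarning, match="non-canonical"):
            freqs = residue_frequencies(make_proteome("GAXG"))
        assert freqs["G"] == pytest.approx(2 / 3)
        assert freqs["A"] == pytest.approx(1 / 3)

    def test_frequencies_sum_to_one(self, rng):
        prot = make_proteome(*[random_protein(rng) for _ in range(10)])
        assert sum(residue_frequencies(prot).values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError):
            residue_frequencies(make_proteome("XXXX"))


class TestIvywrelAndOgt:
    @pytest.mark.parametrize("seqs,expected", [
        (("IVYWREL",), 1.0),
        (("GGGG",), 0.0),
        (("IVYWRELGGGG",), 7 / 11),
    ])
    def test_ivywrel_fraction(self, seqs, expected):
        assert ivywrel_fraction(make_proteome(*seqs)) == pytest.approx(expected)

    def test_order_and_concatenation_invariance(self, rng):
        seqs = [random_protein(rng) for _ in range(6)]
        f1 = ivywrel_fraction(make_proteome(*seqs))
        f2 = ivywrel_fraction(make_proteome(*reversed(seqs)))
        f3 = ivywrel_fraction(make_proteome("".join(seqs)))
        assert f1 == pytest.approx(f2) == pytest.approx(f3)

    @pytest.mark.parametrize("f,expected", [
        (0.0, -335.0), (1.0, 602.0), (0.443, 80.091),
    ])
    def test_ogt_linear_map(self, f, expected):
        assert ogt_from_ivywrel(f) == pytest.approx(expected, abs=1e-9)

    def test_ogt_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ogt_from_ivywrel(1.2)

    def test_ogt_is_affine(self, rng):
        f1, f2, alpha = rng.random(3)
        mix = alpha * f1 + (1 - alpha) * f2
        assert ogt_from_ivywrel(mix) == pytest.approx(
            alpha * ogt_from_ivywrel(f1) + (1 - alpha) * ogt_from_ivywrel(f2))


class TestGroupFraction:
    @pytest.mark.parametrize("seq,residues,expected", [
        ("RERE", {"R", "E"}, 1.0),
        ("GPGP", {"P"}, 0.5),
        ("RGEGG", {"R", "E"}, 0.4),
    ])
    def test_examples(self, seq, residues, expected):
        assert group_fraction(make_proteome(seq), residues) == pytest.approx(expected)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            group_fraction(make_proteome("GG"), set())


class TestNetCharge:
    def test_limits_with_termini(self, rng):
        for _ in range(5):
            seq = random_protein(rng)
            assert net_charge(seq, 0.0) > 0
            assert net_charge(seq, 14.0) < 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet=CANONICAL_AA, min_size=1, max_size=60))
    def test_strictly_decreasing_in_ph(self, seq):
        phs = np.linspace(0.5, 13.5, 27)
        charges = [net_charge(seq, ph) for ph in phs]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_adding_lysine_raises_charge_everywhere(self, rng):
        seq = random_protein(rng)
        for ph in (2.0, 7.0, 12.0):
            assert net_charge(seq + "K", ph) > net_charge(seq, ph)


class TestProteinPi:
    def test_acidic_below_basic_above_neutral(self):
        assert protein_pi("DDDD") < 7 < protein_pi("KKKK")

    def test_glycine_dipeptide_at_terminal_midpoint(self):
        # only the two termini titrate: by symmetry pI = (pKa_N + pKa_C)/2
        mid = (IPC_PROTEIN.n_term + IPC_PROTEIN.c_term) / 2
        assert protein_pi("GG") == pytest.approx(mid, abs=1e-4)

    def test_appending_lysine_increases_pi(self):
        assert protein_pi("DDDDK") > protein_pi("DDDD")

    @pytest.mark.parametrize("pka", [IPC_PROTEIN, EMBOSS], ids=lambda p: p.name)
    def test_matches_grid_scan_oracle(self, rng, pka):
        for _ in range(50):
            seq = random_protein(rng)
            assert protein_pi(seq, pka) == pytest.approx(
                grid_scan_pi(seq, pka), abs=2e-4)

    def test_no_ionizable_groups_errors(self):
        with pytest.raises(ValueError):
            protein_pi("GGGG", count_termini=False)


class TestProteomePi:
    def test_average_is_mean_of_pis(self):
        prot = make_proteome("DDDDDDDD", "KKKKKKKK")
        pis, avg = proteome_pi(prot)
        assert avg == pytest.approx(np.mean(pis))
        assert len(pis) == 2

    def test_single_protein(self):
        prot = make_proteome("MKRDE")
        pis, avg = proteome_pi(prot)
        assert avg == pytest.approx(pis[0])

    def test_all_acidic_proteome_below_neutral(self):
        prot, labels = gen_bimodal_proteome(60, frac_acidic=1.0, seed=5)
        assert set(labels) == {"acidic"}
        pis, avg = proteome_pi(prot)
        assert avg < 7
        assert np.all(pis < 7)


class TestTrough:
    def test_breakpoint_between_two_modes(self, rng):
        pis = np.concatenate([rng.normal(5, 0.4, 1000), rng.normal(10, 0.4, 1000)])
        res = pi_trough(pis)
        assert not res.unimodal
        assert 6.5 <= res.breakpoint <= 8.5

    def test_unimodal_falls_back(self, rng):
        res = pi_trough(rng.normal(6, 0.3, 500))
        assert res.unimodal
        assert res.breakpoint == 7.0

    def test_small_sample_falls_back(self):
        assert pi_trough([5.0, 9.0]).breakpoint == 7.0

    def test_symmetric_mixture_breakpoint_near_centre(self, rng):
        for d in (1.5, 2.5):
            pis = np.concatenate([rng.normal(7 - d, 0.4, 1500),
                                  rng.normal(7 + d, 0.4, 1500)])
            res = pi_trough(pis)
            assert abs(res.breakpoint - 7.0) <= 0.25

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pi_trough([])


class TestPiBias:
    @pytest.mark.parametrize("pis,bp,expected", [
        ([8.0, 9.0, 10.0], 7.0, 1.0),
        ([5.0, 6.0, 8.0, 9.0], 7.0, 0.0),
        ([4.0] * 30 + [9.0] * 70, 7.0, 0.4),
    ])
    def test_examples(self, pis, bp, expected):
        bias, n_acidic, n_basic = pi_bias(pis, bp)
        assert bias == pytest.approx(expected)
        assert n_acidic + n_basic == len(pis)

    def test_ties_count_acidic(self):
        bias, n_acidic, n_basic = pi_bias([7.0, 9.0], 7.0)
        assert (n_acidic, n_basic) == (1, 1)
        assert bias == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=13.99), min_size=1,
                    max_size=50), st.floats(min_value=1.0, max_value=13.0))
    def test_antisymmetry_under_reflection(self, pis, bp):
        pis = [p for p in pis if abs(p - bp) > 1e-6
               and 0 < 2 * bp - p < 14]
        if not pis:
            return
        bias, _, _ = pi_bias(pis, bp)
        mirrored = [2 * bp - p for p in pis]
        mirrored_bias, _, _ = pi_bias(mirrored, bp)
        assert mirrored_bias == pytest.approx(-bias)


def test_composition_and_profile_roundup(rng):
    prot, _ = gen_bimodal_proteome(200, frac_acidic=0.3, seed=1)
    comp = composition_traits(prot)
    assert comp.f_ivywrel == pytest.approx(
        sum(comp.frequencies[aa] for aa in "IVYWREL"))
    prof = pi_profile(prot)
    assert prof.n_acidic + prof.n_basic == len(prof.pi_values)
    # 30% acidic-class proteins -> basic majority -> positive bias
    assert prof.pi_bias > 0
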
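"""Sequence-descriptor tests: charged fractions, kappa, diagram of states,
charge-hydropathy plot, hydropathy and composition deviation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpkit.descriptors import (
    _charges,
    _delta,
    _delta_max,
    analyze_sequence,
    charge_hydropathy,
    charged_fractions,
    composition_deviation,
    delta_max_bruteforce,
    hydropathy_mean,
    isoelectric_point,
    kappa,
    ncpr_fcr,
    phase_diagram_region,
)
from idpkit.exceptions import InputError, UndefinedKappaError
from idpkit.sequence import ProteinSequence

from conftest import make_seq

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_strategy = st.text(alphabet=AA, min_size=10, max_size=60)


class TestChargedFractions:
    @pytest.mark.parametrize(
        "residues, expected",
        [
            ("G" * 20, (0.0, 0.0)),
            ("E" * 10, (0.0, 1.0)),
            ("KRKR" + "A" * 6, (0.4, 0.0)),
        ],
    )
    def test_examples(self, residues, expected):
        assert charged_fractions(make_seq(residues)) == pytest.approx(expected)

    def test_histidine_neutral_by_default_charged_on_request(self):
        seq = make_seq("HHHHKKDD" + "A" * 12)
        assert charged_fractions(seq) == pytest.approx((0.1, 0.1))
        assert charged_fractions(seq, his_charged=True) == pytest.approx((0.3, 0.1))

    @given(seq_strategy)
    @settings(max_examples=50, derandomize=True)
    def test_matches_direct_count(self, residues):
        fp, fm = charged_fractions(make_seq(residues))
        n = len(residues)
        assert fp == sum(residues.count(c) for c in "KR") / n
        assert fm == sum(residues.count(c) for c in "DE") / n


class TestNcprFcr:
    def test_table_style_fractions(self, hv_like):
        ncpr, fcr = ncpr_fcr(*hv_like)
        assert round(ncpr, 3) == -0.065
        assert round(fcr, 2) == 0.34

    @pytest.mark.parametrize(
        "fp, fm, expected", [((0.0), 0.0, (0.0, 0.0)), (0.5, 0.5, (0.0, 1.0))]
    )
    def test_trivial(self, fp, fm, expected):
        assert ncpr_fcr(fp, fm) == pytest.approx(expected)

    @pytest.mark.parametrize("fp, fm", [(-0.1, 0.2), (0.2, 1.3), (0.7, 0.6)])
    def test_invalid_fractions_rejected(self, fp, fm):
        with pytest.raises(InputError):
            ncpr_fcr(fp, fm)

    @given(st.floats(0, 0.5), st.floats(0, 0.5))
    @settings(max_examples=50, derandomize=True)
    def test_ncpr_bounded_by_fcr(self, fp, fm):
        ncpr, fcr = ncpr_fcr(fp, fm)
        assert abs(ncpr) <= fcr + 1e-12


class TestKappa:
    def test_block_sequence_is_maximally_segregated(self):
        assert kappa(make_seq("E" * 25 + "K" * 25)) == pytest.approx(1.0)

    def test_alternating_sequence_is_well_mixed(self):
        k_alt = kappa(make_seq("EK" * 25))
        assert k_alt < 0.05
        # the alternating arrangement minimizes kappa among random
        # permutations of the same composition
        rng = np.random.default_rng(0)
        residues = list("EK" * 25)
        for _ in range(2000):
            rng.shuffle(residues)
            assert kappa("".join(residues)) >= k_alt - 1e-12

    def test_no_charges_raises(self):
        with pytest.raises(UndefinedKappaError):
            kappa(make_seq("G" * 30))

    def test_too_short_raises(self):
        with pytest.raises(InputError):
            kappa(make_seq("EKG"))

    @given(seq_strategy.filter(lambda s: any(c in "KRDE" for c in s)))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_invariances(self, residues):
        k0 = kappa(residues)
        assert 0.0 <= k0 <= 1.0
        # reversal symmetry
        assert kappa(residues[::-1]) == pytest.approx(k0, abs=1e-12)
        # only the charge sign matters: K<->R and D<->E swaps are neutral
        table = str.maketrans("KRDE", "RKED")
        assert kappa(residues.translate(table)) == pytest.approx(k0, abs=1e-12)

    @pytest.mark.parametrize(
        "residues", ["KKEE", "KKKEEE", "KEKEKE", "DKDKRE", "KKEEEE"]
    )
    def test_delta_max_construction_attains_exhaustive_max_without_neutrals(
        self, residues
    ):
        """For fully charged compositions and blobs well below the chain
        length, the canonical segregated arrangement attains the
        exhaustive permutation maximum of delta."""
        charges = _charges(residues, his_charged=False)
        blob = 3
        assert _delta_max(charges, blob) == pytest.approx(
            delta_max_bruteforce(charges, blob), abs=1e-12
        )
        assert _delta(charges, blob) <= _delta_max(charges, blob) + 1e-12

    def test_delta_max_near_chain_length_blob_counterexample(self):
        """When the blob approaches the chain length the few windows
        underweight terminal residues and an end-split arrangement
        (KEEEEK) can beat the contiguous blocks; the construction is then
        only a lower bound on the exhaustive maximum."""
        charges = _charges("KKEEEE", his_charged=False)
        assert _delta_max(charges, 5) <= delta_max_bruteforce(charges, 5)

    @pytest.mark.parametrize("residues", ["KKEEAAAA", "KEEEGGGG", "KKEAAAAA"])
    def test_delta_max_construction_is_bounded_by_exhaustive_max(self, residues):
        """With neutral residues the canonical construction places charge
        blocks at the termini, where full-window blob decomposition
        underweights them, so the exhaustive permutation maximum can
        exceed it (e.g. AKKAAEEA beats KKAAAAEE for blob 3).  The
        construction is the conventional normalization; kappa is clipped
        to [0, 1] to absorb this finite-size effect."""
        charges = _charges(residues, his_charged=False)
        for blob in (3, 5):
            assert _delta_max(charges, blob) <= delta_max_bruteforce(
                charges, blob
            ) + 1e-12


class TestPhaseDiagram:
    @pytest.mark.parametrize(
        "fp, fm, region",
        [
            (0.136, 0.201, 2),   # HvASR1 printed fractions
            (0.131, 0.204, 2),   # TtASR1 printed fractions
            (0.05, 0.05, 1),
            (0.30, 0.30, 3),
            (0.02, 0.45, 4),
            (0.45, 0.02, 5),
        ],
    )
    def test_region_assignment(self, fp, fm, region):
        assert phase_diagram_region(fp, fm) == region


class TestChargeHydropathy:
    def test_max_hydropathy_homopolymer_is_folded(self):
        point = charge_hydropathy(make_seq("I" * 30))
        assert not point.is_disordered
        assert point.distance < 0

    def test_hydrophilic_charged_sequence_is_disordered(self):
        point = charge_hydropathy(make_seq("EKDS" * 10))
        assert point.is_disordered
        assert point.distance > 0

    def test_distance_is_boundary_minus_h(self):
        p = charge_hydropathy(make_seq("EKGASTHQ" * 5))
        assert p.distance == pytest.approx(p.boundary - p.H)
        assert p.boundary == pytest.approx((p.R + 1.151) / 2.785)

    def test_too_short_raises(self):
        with pytest.raises(InputError):
            charge_hydropathy(make_seq("EKG"))


class TestHydropathyMean:
    @pytest.mark.parametrize(
        "residues, expected", [("G" * 20, 4.1), ("I" * 15, 9.0), ("R" * 10, 0.0)]
    )
    def test_homopolymers(self, residues, expected):
        assert hydropathy_mean(make_seq(residues)) == pytest.approx(expected)


class TestCompositionDeviation:
    def test_deviation_formula_and_flags(self):
        seq = make_seq("E" * 10 + "A" * 10)
        ref = {aa: 0.05 for aa in AA}  # uniform reference
        df = composition_deviation(seq, ref)
        # CP_E = 0.5, CSP_E = 0.05 -> D = 9; absent residues -> D = -1
        assert df.loc["E", "deviation"] == pytest.approx(9.0)
        assert df.loc["W", "deviation"] == pytest.approx(-1.0)
        assert df.loc["E", "category"] == "disorder-promoting"
        assert df.loc["W", "category"] == "order-promoting"

    def test_doubled_fraction_gives_plus_one(self):
        ref = {aa: 0.05 for aa in AA}
        # 20 residues with E present twice (W dropped): CP_E = 0.10 = 2*CSP_E
        seq = make_seq("EE" + "".join(a for a in AA if a not in "EW"))
        df = composition_deviation(seq, ref)
        assert df.loc["E", "deviation"] == pytest.approx(1.0)
        assert df.loc["W", "deviation"] == pytest.approx(-1.0)

    @given(seq_strategy)
    @settings(max_examples=30, derandomize=True)
    def test_reconstruction_identity(self, residues):
        """sum CSP_X (1 + D_X) recovers sum CP_X = 1."""
        df = composition_deviation(make_seq(residues))
        total = (df["reference"] * (1.0 + df["deviation"])).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_reference_with_presence_raises(self):
        ref = {aa: (0.0 if aa == "E" else 1 / 19) for aa in AA}
        with pytest.raises(InputError):
            composition_deviation(make_seq("EAAAA"), ref)


class TestReportAndPi:
    def test_full_report_consistency(self):
        seq = make_seq("MKEEHAGKST" * 10, "demo")
        rep = analyze_sequence(seq)
        assert rep.FCR == pytest.approx(rep.f_plus + rep.f_minus)
        assert rep.NCPR == pytest.approx(rep.f_plus - rep.f_minus)
        assert rep.N == 100
        assert rep.PDR in (1, 2, 3, 4, 5)
        assert 0 <= rep.kappa <= 1

    def test_isoelectric_point_ordering(self):
        acidic = isoelectric_point(make_seq("EEEEDDDDAA"))
        basic = isoelectric_point(make_seq("KKKKRRRRAA"))
        assert acidic < 5 < basic
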
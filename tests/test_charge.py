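"""Titration model: sites, fractional charges, net charge, pI, mass, labels."""

import numpy as np
import pytest

from pepassembly import (
    BJELLQVIST,
    PeptideSpec,
    charge_state_model,
    ionizable_sites,
    isoelectric_point,
    molecular_weight,
    net_charge,
    titration_curve,
)
from pepassembly.charge import (
    IonizableSite,
    NoIsoelectricPointError,
    fractional_charge,
)
from pepassembly.peptide import (
    AVERAGE_RESIDUE_MASS,
    WATER_MASS_AVERAGE,
    PeptideValidationError,
)


class TestIonizableSites:
    def test_uncapped_a6k_has_three_sites_in_nc_order(self, a6k):
        sites = ionizable_sites(a6k, BJELLQVIST)
        assert [(s.site_kind, s.residue_index, s.polarity) for s in sites] == [
            ("n_terminus", 1, "base"),
            ("side_chain", 7, "base"),
            ("c_terminus", 7, "acid"),
        ]
        by_kind = {s.site_kind: s.pKa for s in sites}
        assert by_kind["n_terminus"] == pytest.approx(7.59)
        assert by_kind["c_terminus"] == pytest.approx(3.55)
        assert sites[1].pKa == pytest.approx(10.00)

    def test_capped_peptide_keeps_only_side_chain(self):
        capped = PeptideSpec("AAAAAAK", n_term_free=False, c_term_free=False)
        sites = ionizable_sites(capped)
        assert [(s.site_kind, s.residue_index) for s in sites] == [("side_chain", 7)]

    def test_poly_ala_free_termini_has_exactly_two_sites(self):
        sites = ionizable_sites(PeptideSpec("AAAA"))
        assert [s.site_kind for s in sites] == ["n_terminus", "c_terminus"]

    def test_unknown_residue_names_position(self):
        with pytest.raises(PeptideValidationError, match="position 3"):
            PeptideSpec("AAXA")


class TestFractionalCharge:
    @pytest.mark.parametrize(
        "polarity,pka,ph,expected",
        [
            ("base", 10.0, 10.0, 0.5),
            ("acid", 3.55, 3.55, -0.5),
            ("acid", 3.55, 2.0, -1.0 / (1.0 + 10.0 ** (3.55 - 2.0))),  # -0.0274
        ],
    )
    def test_closed_form(self, polarity, pka, ph, expected):
        site = IonizableSite("c_terminus" if polarity == "acid" else "n_terminus",
                             1, pka, polarity)
        assert fractional_charge(site, ph) == pytest.approx(expected, abs=1e-6)

    def test_ph_out_of_range_rejected(self):
        site = IonizableSite("n_terminus", 1, 7.59, "base")
        with pytest.raises(ValueError):
            fractional_charge(site, -0.5)
        with pytest.raises(ValueError):
            fractional_charge(site, 14.5)

    def test_strictly_decreasing_in_ph_for_both_polarities(self):
        grid = np.linspace(0, 14, 141)
        for polarity in ("acid", "base"):
            site = IonizableSite("side_chain", 1, 7.0, polarity)
            vals = [fractional_charge(site, p) for p in grid]
            assert np.all(np.diff(vals) < 0)


class TestNetCharge:
    @pytest.mark.parametrize(
        "ph,expected_q,expected_round",
        [(2.0, 1.972, 2), (7.0, 0.795, 1), (8.0, 0.270, 0), (11.0, -0.909, -1)],
    )
    def test_a6k_printed_charges(self, a6k, ph, expected_q, expected_round):
        tp = net_charge(a6k, ph)
        assert tp.net_charge == pytest.approx(expected_q, abs=2e-3)
        assert tp.rounded_net_charge == expected_round

    def test_monotone_and_bounded(self, a6k):
        grid = np.linspace(0, 14, 281)
        qs = [net_charge(a6k, p).net_charge for p in grid]
        assert np.all(np.diff(qs) < 0)
        # 2 base sites, 1 acid site
        assert all(-1.0 <= q <= 2.0 for q in qs)

    def test_titration_curve_matches_pointwise_and_preserves_order(self, a6k):
        pts = titration_curve(a6k, [11.0, 2.0, 7.0])
        assert [p.pH for p in pts] == [11.0, 2.0, 7.0]
        assert [p.rounded_net_charge for p in pts] == [-1, 2, 1]
        assert titration_curve(a6k, []) == []


class TestIsoelectricPoint:
    def test_a6k_pi_is_8_8(self, a6k):
        assert isoelectric_point(a6k, BJELLQVIST) == pytest.approx(8.8)

    def test_net_charge_at_pi_is_zero(self, a6k):
        root = isoelectric_point(a6k, tol=1e-6, decimals=None)
        assert abs(net_charge(a6k, root).net_charge) < 1e-6

    def test_two_site_zwitterion_is_mean_of_pkas(self):
        # single free Ala: base pKa 7.59 and acid pKa 3.55; two-site pI is
        # the mean of the two pKa values
        ala = PeptideSpec("A")
        root = isoelectric_point(ala, tol=1e-8, decimals=None)
        assert root == pytest.approx((7.59 + 3.55) / 2.0, abs=1e-3)
        assert isoelectric_point(ala) == pytest.approx(5.6)  # 5.57 to 1 dp

    def test_base_only_peptide_has_no_pi(self):
        capped = PeptideSpec("AAAAAAK", n_term_free=False, c_term_free=False)
        with pytest.raises(NoIsoelectricPointError, match="no isoelectric point"):
            isoelectric_point(capped)

    def test_bisection_agrees_with_brute_force_scan(self, a6k):
        """Oracle: dense scan of the net-charge function at pH step 1e-4."""
        grid = np.arange(7.5, 10.0, 1e-4)
        qs = np.array([net_charge(a6k, p).net_charge for p in grid])
        scan_root = grid[np.argmin(np.abs(qs))]
        bisect_root = isoelectric_point(a6k, tol=1e-8, decimals=None)
        assert abs(bisect_root - scan_root) < 1e-3

    def test_pi_invariant_under_appending_non_ionizable_residues(self):
        base = isoelectric_point(PeptideSpec("AAK"), tol=1e-8, decimals=None)
        longer = isoelectric_point(PeptideSpec("AAKGGGG"), tol=1e-8, decimals=None)
        # same site kinds; only the C-terminal residue letter stays non-special
        assert longer == pytest.approx(base, abs=1e-6)


class TestMolecularWeight:
    def test_a6k_average_mass_rounds_to_573(self, a6k):
        mw = molecular_weight(a6k, "average")
        assert mw == pytest.approx(572.66, abs=0.01)
        assert round(mw) == 573

    def test_single_gly(self):
        assert molecular_weight(PeptideSpec("G"), "average") == pytest.approx(
            75.07, abs=0.01
        )

    def test_monoisotopic_not_larger_than_average(self, a6k):
        assert molecular_weight(a6k, "monoisotopic") <= molecular_weight(a6k, "average")

    def test_mass_additivity(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        expected = sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS_AVERAGE
        assert molecular_weight(PeptideSpec(seq)) == pytest.approx(expected, abs=1e-9)


class TestChargeStateModel:
    def test_ph8_narrative_labels(self, a6k):
        cm = charge_state_model(a6k, 8.0)
        labels = dict(zip((s.site_kind for s, _ in cm.site_charges), cm.site_labels))
        assert labels["n_terminus"] == "mostly_neutral"
        assert labels["side_chain"] == "charged"
        assert labels["c_terminus"] == "charged"
        assert cm.rounded_net_charge == 0

    def test_ph2_carboxyl_neutral(self, a6k):
        cm = charge_state_model(a6k, 2.0)
        labels = dict(zip((s.site_kind for s, _ in cm.site_charges), cm.site_labels))
        assert labels["c_terminus"] == "neutral"
        assert labels["n_terminus"] == "charged"
        assert labels["side_chain"] == "charged"
        assert cm.rounded_net_charge == 2

    def test_site_at_its_pka_is_mixed(self):
        cm = charge_state_model(PeptideSpec("A"), 7.59)
        labels = dict(zip((s.site_kind for s, _ in cm.site_charges), cm.site_labels))
        assert labels["n_terminus"] == "mixed"

    def test_net_charge_equals_sum_of_sites(self, a6k):
        cm = charge_state_model(a6k, 6.3)
        assert cm.net_charge == pytest.approx(sum(q for _, q in cm.site_charges))
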
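"""Secondary-structure labels, hydrogen bonds, and β-turn detection."""

import numpy as np
import pytest

from pepassembly import (
    DihedralSet,
    PeptideSpec,
    TurnCriteria,
    backbone_dihedrals,
    build_chain,
    classify_ss,
    detect_beta_turns,
    find_hbonds,
    make_motif,
    make_system,
    sample_coil,
    turn_content,
)


def brute_force_turns(conf, criteria):
    """Independent oracle: both β-turn criteria recomputed from raw atom
    coordinates for every i..i+3 window (no reuse of the detector's code)."""
    hits = []
    n = len(conf.residues)
    for i in range(n - 3):
        ri, rj = conf.residues[i], conf.residues[i + 3]
        ca_d = float(np.linalg.norm(ri.coords_of("CA") - rj.coords_of("CA")))
        hit_b = ca_d < criteria.ca_dist_max
        hit_a = False
        O, N, H = ri.coords_of("O"), rj.coords_of("N"), rj.coords_of("H")
        if O is not None and N is not None and H is not None:
            if np.linalg.norm(O - N) <= criteria.hbond_ON_max:
                u, v = N - H, O - H
                cosang = float(
                    np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                )
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= criteria.hbond_angle_min:
                    hit_a = True
        ok = (hit_a and hit_b) if criteria.combine == "both" else (hit_a or hit_b)
        if ok:
            hits.append(i + 1)
    return hits


class TestBackboneDihedrals:
    def test_termini_undefined(self, extended_chain):
        d = backbone_dihedrals(extended_chain)
        assert np.isnan(d.phi[0]) and np.isnan(d.omega[0]) and np.isnan(d.psi[-1])
        assert not np.any(np.isnan(d.phi[1:]))

    def test_two_residue_chain(self):
        pep = PeptideSpec("AA")
        conf = build_chain(pep, DihedralSet.from_phi_psi([(-139.0, 135.0)] * 2))
        d = backbone_dihedrals(conf)
        assert np.isnan(d.phi[0]) and not np.isnan(d.phi[1])
        assert not np.isnan(d.psi[0]) and np.isnan(d.psi[1])


class TestClassifySS:
    def test_ideal_helix_interior(self, helix_chain):
        ss = classify_ss(backbone_dihedrals(helix_chain), helix_chain)
        assert ss[1:6] == ["helix"] * 5
        assert ss[0] == "coil" and ss[6] == "coil"  # undefined termini

    def test_extended_chain_is_sheet_without_turns(self, extended_chain):
        ss = classify_ss(backbone_dihedrals(extended_chain), extended_chain)
        assert "turn" not in ss
        assert ss[1:6] == ["sheet"] * 5

    def test_turn_motif_centers_labeled_turn(self, turn2_chain):
        ss = classify_ss(backbone_dihedrals(turn2_chain), turn2_chain)
        assert ss[3] == "turn" and ss[4] == "turn"  # residues i+1, i+2 of window 3


class TestHBonds:
    def test_helix_i_to_i4_contacts(self, helix_chain):
        hbonds = find_hbonds(helix_chain)
        pairs = {(hb.donor, hb.acceptor) for hb in hbonds}
        assert {(5, 1), (6, 2), (7, 3)} <= pairs
        for hb in hbonds:
            assert 2.8 <= hb.distance_ON <= 3.2

    def test_distant_residues_no_bond(self, extended_chain):
        assert find_hbonds(extended_chain) == []

    def test_proline_not_a_donor(self):
        pep = PeptideSpec("AAAPAAA")
        conf = make_motif(pep, "alpha_helix")
        assert all(hb.donor != 4 for hb in find_hbonds(conf))


class TestDetectBetaTurns:
    @pytest.mark.parametrize("motif", ["beta_turn_I", "beta_turn_II"])
    def test_planted_motif_yields_one_record(self, a6k, motif):
        conf = make_motif(a6k, motif, turn_position=3)
        records = detect_beta_turns(conf)
        assert [r.start for r in records] == [3]
        assert records[0].evidence in ("both", "ca_distance", "hbond")
        oracle = brute_force_turns(conf, TurnCriteria())
        assert [r.start for r in records] == oracle

    def test_helix_rejected_with_exclusion(self, helix_chain):
        assert detect_beta_turns(helix_chain) == []
        # without exclusion the same windows qualify geometrically
        relaxed = TurnCriteria(exclude_helix=False)
        assert len(detect_beta_turns(helix_chain, relaxed)) == 4

    def test_extended_chain_no_records(self, extended_chain):
        assert detect_beta_turns(extended_chain) == []

    def test_short_chain_empty(self):
        pep = PeptideSpec("AAA")
        conf = build_chain(pep, DihedralSet.from_phi_psi([(-139.0, 135.0)] * 3))
        assert detect_beta_turns(conf) == []

    def test_agrees_with_brute_force_on_random_chains(self, a6k):
        """Oracle equivalence over random coil conformations, both combine
        modes, helix exclusion off (the oracle is purely geometric)."""
        for seed in range(100):
            conf = sample_coil(a6k, seed=seed)
            for combine in ("either", "both"):
                crit = TurnCriteria(combine=combine, exclude_helix=False)
                got = [r.start for r in detect_beta_turns(conf, crit)]
                assert got == brute_force_turns(conf, crit), f"seed {seed}"

    def test_threshold_sharpness_strict_less_than(self, turn2_chain):
        # isolate criterion B by making the hydrogen-bond criterion unsatisfiable
        base = TurnCriteria(hbond_angle_min=179.99, exclude_helix=False)
        [rec] = detect_beta_turns(turn2_chain, base)
        d = rec.ca_dist
        at = TurnCriteria(ca_dist_max=d, hbond_angle_min=179.99, exclude_helix=False)
        above = TurnCriteria(ca_dist_max=d + 1e-9, hbond_angle_min=179.99,
                             exclude_helix=False)
        assert detect_beta_turns(turn2_chain, at) == []  # strict <
        assert [r.start for r in detect_beta_turns(turn2_chain, above)] == [3]

    def test_monotone_in_ca_cutoff(self, a6k):
        for seed in range(10):
            conf = sample_coil(a6k, seed=seed)
            counts = [
                len(detect_beta_turns(conf, TurnCriteria(ca_dist_max=c, exclude_helix=False)))
                for c in (5.0, 6.0, 7.0, 8.0, 10.0)
            ]
            assert counts == sorted(counts)


class TestTurnContent:
    def test_planted_fraction_constant_across_frames(self, a6k):
        conf = make_motif(a6k, "beta_turn_II", turn_position=3)
        covered = set()
        for start in brute_force_turns(conf, TurnCriteria()):
            covered.update(range(start, start + 4))
        expected = 100.0 * len(covered) / 7.0

        system = make_system(a6k, 8, box_nm=10.0, seed=4, n_frames=10,
                             per_chain_motif="beta_turn_II")
        tc = turn_content(system)
        assert len(set(tc.per_frame_beta_turn)) == 1  # rigid placement: exact
        assert tc.beta_turn_percent == pytest.approx(expected)
        assert tc.beta_turn_percent_sd == pytest.approx(0.0)

    def test_all_helix_system_zero_beta(self, a6k):
        system = make_system(a6k, 4, box_nm=10.0, seed=1, per_chain_motif="alpha_helix")
        tc = turn_content(system)
        assert tc.beta_turn_percent == 0.0

    def test_mixture_linearity(self, a6k):
        pure = make_system(a6k, 4, box_nm=12.0, seed=2, per_chain_motif="beta_turn_II")
        half = make_system(a6k, 4, box_nm=12.0, seed=2,
                           per_chain_motif=["beta_turn_II", "extended",
                                            "beta_turn_II", "extended"])
        assert turn_content(half).beta_turn_percent == pytest.approx(
            turn_content(pure).beta_turn_percent / 2.0
        )

    def test_percentages_bounded_and_order_independent(self, a6k):
        system = make_system(a6k, 6, box_nm=9.0, seed=8)
        tc = turn_content(system)
        assert 0.0 <= tc.turn_percent <= 100.0
        assert 0.0 <= tc.beta_turn_percent <= 100.0
        from pepassembly.model import PeptideSystem

        shuffled = PeptideSystem(
            frames=[list(reversed(system.frames[0]))], box_nm=system.box_nm
        )
        tc2 = turn_content(shuffled)
        assert tc2.per_frame_turn[0] == pytest.approx(tc.per_frame_turn[0])
        assert tc2.per_frame_beta_turn[0] == pytest.approx(tc.per_frame_beta_turn[0])

    def test_empty_system_rejected(self):
        from pepassembly.model import PeptideSystem

        with pytest.raises(ValueError, match="empty"):
            turn_content(PeptideSystem(frames=[]))

    def test_window_denominator_mode(self, a6k):
        system = make_system(a6k, 4, box_nm=10.0, seed=3, per_chain_motif="beta_turn_II")
        tc = turn_content(system, denominator="windows")
        # exactly one qualifying window of four per 7-residue chain
        assert tc.beta_turn_percent == pytest.approx(25.0)
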
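import numpy as np
import pytest

from qensemble.rama_regions import (ALPHA_L, ALPHA_R, BETA, PPII,
                                    RegionLabelMatrix, alpha_tilde_mask,
                                    assign_regions_hard)
from qensemble.ss_motifs import (HBond, MotifInstance, assign_ss,
                                 assign_ss_single, classify_turns,
                                 detect_hairpins, detect_strands, find_hbonds,
                                 helix_segment_stats, kabsch_sander_energy,
                                 motif_prevalence, place_backbone_hydrogen)
from qensemble.synthetic import (alpha_tilde_strand, beta_hairpin,
                                 extended_beta, ideal_helix, ppii_helix,
                                 type_i_beta_turn)


class TestHydrogenPlacement:
    def test_nh_distance_is_one_angstrom(self, helix):
        H = place_backbone_hydrogen(helix.coords[0], helix.residue_names)
        N = helix.coords[0, :, 0]
        d = np.linalg.norm(H[1:] - N[1:], axis=1)
        assert np.allclose(d, 1.0, atol=1e-12)

    def test_first_residue_and_proline_have_no_h(self, helix):
        names = list(helix.residue_names)
        names[3] = "PRO"
        H = place_backbone_hydrogen(helix.coords[0], names)
        assert np.isnan(H[0]).all()
        assert np.isnan(H[3]).all()

    def test_helix_h_points_toward_acceptor_oxygen(self, helix):
        """In an ideal alpha-helix the N-H of residue i points at O(i-4)."""
        coords = helix.coords[0]
        H = place_backbone_hydrogen(coords, helix.residue_names)
        for i in range(5, 10):
            N, O = coords[i, 0], coords[i - 4, 3]
            nh = H[i] - N
            no = O - N
            # N-H...O angle
            ho = O - H[i]
            cosang = np.dot(-nh, -ho) / (np.linalg.norm(nh) * np.linalg.norm(ho))
            angle = np.degrees(np.arccos(np.clip(np.dot(nh, ho) /
                     (np.linalg.norm(nh) * np.linalg.norm(ho)), -1, 1)))
            assert angle < 40.0  # i.e. N-H...O nearly linear (>140 deg)


class TestKabschSander:
    def test_symmetric_distances_give_zero(self):
        # N and H on the x axis, C and O on its perpendicular bisector:
        # r_ON = r_CH = r_OH = r_CN, so the energy cancels exactly
        e, capped = kabsch_sander_energy(
            np.array([0.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]),
            np.array([0.5, -1.0, 0.0]), np.array([0.5, 1.0, 0.0]))
        assert e == pytest.approx(0.0, abs=1e-9)
        assert not capped

    def test_canonical_linear_hbond_below_cutoff(self):
        # collinear N-H...O=C, r_ON = 2.9 A
        N = np.array([0.0, 0.0, 0.0])
        H = np.array([1.0, 0.0, 0.0])
        O = np.array([2.9, 0.0, 0.0])
        C = np.array([4.131, 0.0, 0.0])
        e, capped = kabsch_sander_energy(N, H, C, O)
        assert e < -0.5
        assert not capped

    def test_distant_pair_negligible(self):
        N = np.array([0.0, 0.0, 0.0])
        H = np.array([1.0, 0.0, 0.0])
        O = np.array([15.0, 0.0, 0.0])
        C = np.array([16.2, 0.0, 0.0])
        e, _ = kabsch_sander_energy(N, H, C, O)
        assert abs(e) < 0.05

    def test_capped_pair_flagged(self):
        N = np.array([0.0, 0.0, 0.0])
        H = np.array([0.1, 0.0, 0.0])
        O = np.array([0.2, 0.0, 0.0])
        C = np.array([0.3, 0.0, 0.0])
        _, capped = kabsch_sander_energy(N, H, C, O)
        assert capped


class TestAssignSS:
    def test_ideal_helix_interior_is_h(self, helix):
        ss, bonds = assign_ss_single(helix.coords[0], helix.residue_names)
        assert ss == "CHHHHHHHHHHC"
        accept_donor = {(b.acceptor, b.donor) for b in bonds}
        # the canonical i -> i+4 ladder
        for i in range(0, 8):
            assert (i, i + 4) in accept_donor

    def test_extended_chain_no_bonds(self):
        ens = extended_beta(10)
        ss, bonds = assign_ss_single(ens.coords[0], ens.residue_names)
        assert bonds == []
        assert set(ss) <= {"C", "S"}

    def test_hairpin_has_e_codes_and_loop_turn(self):
        ens = beta_hairpin()
        ss, bonds = assign_ss_single(ens.coords[0], ens.residue_names)
        assert "E" in ss
        loop = ss[4:7]
        assert any(c in "TS" for c in loop)

    def test_helix_run_lengths(self, q40_small):
        """H runs are >= 4 and G runs >= 3 by the two-turn rule."""
        from qensemble.synthetic import build_backbone

        _, _, ens = q40_small
        small = build_backbone(ens.subset(range(40)))
        ss_strings, _ = assign_ss(small)
        for s in ss_strings:
            for code, min_len in (("H", 4), ("G", 3), ("I", 5)):
                run = 0
                for ch in s + "C":
                    if ch == code:
                        run += 1
                    else:
                        if run:
                            assert run >= min_len
                        run = 0


class TestHelixStats:
    def test_no_helix_anywhere(self):
        stats = helix_segment_stats(["CCCC"] * 5, ["GLN"] * 4)
        assert stats["alpha_content"] == 0.0
        assert stats["segment_count_distribution"] == {0: 100.0}

    def test_single_run_arithmetic(self):
        s = "C" * 10 + "H" * 10 + "C" * 20
        stats = helix_segment_stats([s] * 7, ["GLN"] * 40)
        assert stats["alpha_content"] == pytest.approx(25.0)
        assert stats["segment_count_distribution"] == {1: 100.0}
        assert stats["long_segment_percent"][7] == 100.0
        assert stats["long_segment_percent"][9] == 100.0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(2)
        codes = np.array(list("HGITSBEC"))
        strings = ["".join(rng.choice(codes, 30)) for _ in range(50)]
        stats = helix_segment_stats(strings, ["GLN"] * 30)
        # brute force run-length scan
        import re

        counts = [len(re.findall(r"[HGI]+", s)) for s in strings]
        dist = {c: 100.0 * counts.count(c) / len(counts) for c in set(counts)}
        assert stats["segment_count_distribution"] == pytest.approx(dist)


class TestTurns:
    def test_type_i_beta_turn_fixture(self):
        ens = type_i_beta_turn()
        labels = assign_regions_hard(ens)
        ss, bonds = assign_ss(ens)
        table = classify_turns(ss, bonds, labels)
        kinds = [t["kind"] for t in table["turns"]]
        assert kinds.count("I-beta") == 1
        assert kinds.count("gamma") == 0

    def test_gamma_turn_from_i_to_i_plus_2_bond(self):
        labels = RegionLabelMatrix(
            np.full((1, 5), ALPHA_R, dtype=np.int8), "hard", ["GLN"] * 5)
        bonds = [[HBond(donor=3, acceptor=1, energy=-1.0)]]
        table = classify_turns(["CCCCC"], bonds, labels)
        assert table["gamma_percent"] == 100.0
        assert table["i_beta_percent"] == 0.0

    def test_bend_without_hbond_counts_in_bend_column(self):
        labels = RegionLabelMatrix(
            np.full((1, 5), ALPHA_R, dtype=np.int8), "hard", ["GLN"] * 5)
        table = classify_turns(["CCSCC"], [[]], labels)
        assert table["bend_content"] == pytest.approx(20.0)
        assert table["hbonded_turn_content"] == 0.0


def _labels_from_rows(rows, names=None):
    arr = np.asarray(rows, dtype=np.int8)
    return RegionLabelMatrix(arr, "hard", names or ["GLN"] * arr.shape[1])


class TestStrands:
    def test_beta_run_of_three(self):
        labels = _labels_from_rows([[ALPHA_R, BETA, BETA, BETA, ALPHA_R]])
        out3 = detect_strands(labels, [[]], "beta", 3)
        out4 = detect_strands(labels, [[]], "beta", 4)
        assert len(out3) == 1 and out3[0].isolated is True
        assert out3[0].start == 1 and out3[0].end == 3
        assert out4 == []

    def test_alpha_tilde_alternation_both_phases(self):
        labels = _labels_from_rows([[ALPHA_R, ALPHA_L, ALPHA_R, ALPHA_L, ALPHA_R]])
        out = detect_strands(labels, None, "alpha_tilde", 3)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (0, 4)
        assert out[0].isolated is None

    def test_broken_alternation_rejected(self):
        labels = _labels_from_rows([[ALPHA_R, ALPHA_R, ALPHA_L]])
        assert detect_strands(labels, [[]], "alpha_tilde", 3) == []

    def test_min_len_4_subset_of_3(self, q40_small):
        _, labels, _ = q40_small
        for kind in ("beta", "alpha_tilde", "ppii"):
            s3 = {(m.conformation, m.start, m.end)
                  for m in detect_strands(labels, None, kind, 3)}
            s4 = {(m.conformation, m.start, m.end)
                  for m in detect_strands(labels, None, kind, 4)}
            assert s4 <= s3

    def test_strand_residues_have_alpha_tilde_mask(self, q40_small):
        _, labels, _ = q40_small
        mask = alpha_tilde_mask(labels)
        for m in detect_strands(labels, None, "alpha_tilde", 3):
            assert mask[m.conformation, m.start:m.end + 1].all()

    def test_unknown_kind_rejected(self, q40_small):
        _, labels, _ = q40_small
        with pytest.raises(ValueError):
            detect_strands(labels, None, "gamma", 3)


class TestHairpins:
    def test_engineered_beta_hairpin_found(self):
        ens = beta_hairpin()
        labels = assign_regions_hard(ens)
        ss, bonds = assign_ss(ens)
        out = detect_hairpins(labels, ss, bonds, "beta")
        assert len(out) == 1
        assert out[0].type == "beta_hairpin"

    def test_no_cross_strand_bonds_no_hairpin(self):
        ens = beta_hairpin()
        labels = assign_regions_hard(ens)
        ss, _ = assign_ss(ens)
        out = detect_hairpins(labels, ss, [[]], "beta")
        assert out == []
        strands = detect_strands(labels, [[]], "beta", 3)
        assert len(strands) == 2 and all(s.isolated for s in strands)

    def test_loop_without_turn_geometry_rejected(self):
        ens = beta_hairpin()
        labels = assign_regions_hard(ens)
        ss, bonds = assign_ss(ens)
        flat_ss = ["C" * ens.n_residues]
        assert detect_hairpins(labels, flat_ss, bonds, "beta") == []

    def test_helix_fixture_has_no_strands_or_hairpins(self, helix):
        labels = assign_regions_hard(helix)
        ss, bonds = assign_ss(helix)
        for kind in ("beta", "ppii"):
            assert detect_strands(labels, bonds, kind, 3) == []
        assert detect_hairpins(labels, ss, bonds, "beta") == []


class TestPrevalence:
    def test_every_conformation_hit(self, q40_small):
        _, _, ens = q40_small
        instances = [MotifInstance("beta_strand", c, 2, 5)
                     for c in range(ens.n_conformations)]
        out = motif_prevalence(instances, ens)
        assert out[("beta_strand", 3)] == 100.0

    def test_fraction_arithmetic(self, q40_small):
        _, _, ens = q40_small
        instances = [MotifInstance("beta_hairpin", c, 0, 6) for c in (1, 5, 9)]
        out = motif_prevalence(instances, ens)
        assert out[("beta_hairpin", 3)] == pytest.approx(
            100.0 * 3 / ens.n_conformations)

    def test_matches_brute_force_any_scan(self):
        rng = np.random.default_rng(4)
        from conftest import random_ensemble

        ens = random_ensemble(n_conf=200, n_res=10, seed=4)
        instances = [
            MotifInstance("ppii_run", int(c), 1, 4)
            for c in rng.integers(0, 200, 57)
        ]
        out = motif_prevalence(instances, ens)
        brute = 100.0 * len({m.conformation for m in instances}) / 200
        assert out[("ppii_run", 3)] == pytest.approx(brute)

    def test_proline_span_excluded(self):
        from conftest import random_ensemble

        ens = random_ensemble(n_conf=10, n_res=8, seed=5,
                              names=["GLN"] * 6 + ["PRO"] * 2)
        inside = [MotifInstance("beta_strand", 0, 1, 4)]
        overlapping = [MotifInstance("beta_strand", 0, 4, 7)]
        assert motif_prevalence(inside, ens)[("beta_strand", 3)] == 10.0
        assert motif_prevalence(overlapping, ens) == {}
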
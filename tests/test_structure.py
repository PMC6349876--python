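"""Secondary-structure assignment, PPII overlay, SASA, radius of gyration
and the windowed report."""
import numpy as np
import pytest

from idpbem.backbone import build_backbone_from_torsions, uniform_profile
from idpbem.model import Conformation, PeptideSequence, TorsionProfile, compute_torsions
from idpbem.structure import (
    SASAProfile,
    assign_ppii,
    assign_ss,
    golden_spiral_points,
    label_conformation,
    radius_of_gyration,
    sasa,
    sasa_points,
    window_report,
)
from idpbem.synthetic import BlockSpec, SSSpec, sample_ensemble


class TestAssignSS:
    def test_ideal_helix_labels_2_to_26(self, ala_helix):
        labels = assign_ss(ala_helix)
        assert "".join(labels) == "C" + "H" * 25 + "C"

    def test_extended_single_chain_has_no_strand(self, ala_sequence):
        ext = build_backbone_from_torsions(ala_sequence, uniform_profile(27, -140.0, 135.0))
        assert not (assign_ss(ext) == "E").any()

    def test_antiparallel_hairpin_strands_labeled_e(self):
        seq = PeptideSequence("GKSWVSAAERYAVVADETGLTDGSSKG", 397)
        traj, gt = sample_ensemble(
            seq, SSSpec(27, [BlockSpec(8, 18, "E", 1.0)], noise_sd=0.0), 1, seed=1
        )
        labels = assign_ss(traj.frames[0])
        assert (labels[[9, 10, 11]] == "E").all()
        assert (labels[[14, 15, 16]] == "E").all()

    def test_missing_atoms_fall_back_to_coil(self, ala_helix):
        broken = Conformation(
            sequence=ala_helix.sequence,
            coords={k: v.copy() for k, v in ala_helix.coords.items()},
        )
        broken.coords["O"][10:15] = np.nan
        labels = assign_ss(broken)
        assert len(labels) == 27  # degraded but total


class TestAssignPPII:
    def _coil_labels(self, n):
        return np.full(n, "C", dtype="U1")

    def test_two_consecutive_in_box_become_p(self):
        phi = np.full(10, -150.0)
        psi = np.full(10, 60.0)
        phi[4:6] = -75.0
        psi[4:6] = 145.0
        t = TorsionProfile(phi=phi, psi=psi)
        out = assign_ppii(t, self._coil_labels(10))
        assert "".join(out) == "CCCCPPCCCC"

    def test_isolated_residue_stays_coil(self):
        phi = np.full(10, -150.0)
        psi = np.full(10, 60.0)
        phi[4] = -75.0
        psi[4] = 145.0
        out = assign_ppii(TorsionProfile(phi=phi, psi=psi), self._coil_labels(10))
        assert (out == "C").all()

    def test_helix_label_takes_precedence(self):
        phi = np.full(10, -75.0)
        psi = np.full(10, 145.0)
        labels = self._coil_labels(10)
        labels[4] = "H"
        out = assign_ppii(TorsionProfile(phi=phi, psi=psi), labels)
        assert out[4] == "H"
        assert out[3] == "P" and out[5] == "P"

    def test_box_boundaries_inclusive(self):
        phi = np.full(4, -104.0)  # exactly -75 - 29
        psi = np.full(4, 174.0)  # exactly 145 + 29
        out = assign_ppii(TorsionProfile(phi=phi, psi=psi), self._coil_labels(4))
        assert (out == "P").all()

    def test_undefined_termini_never_p(self, ppii_chain):
        labels = label_conformation(ppii_chain)
        assert labels[0] == "C" and labels[-1] == "C"
        assert (labels[1:-1] == "P").all()


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        r = 0.17
        probe = 0.14
        area = sasa_points(np.zeros((1, 3)), np.array([r]), probe, 960)[0]
        exact = 4.0 * np.pi * (r + probe) ** 2
        assert area == pytest.approx(exact, rel=0.005)

    def test_far_separated_atoms_additive(self):
        pts = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        radii = np.array([0.17, 0.155])
        areas = sasa_points(pts, radii, 0.14, 960)
        for a, r in zip(areas, radii):
            assert a == pytest.approx(4.0 * np.pi * (r + 0.14) ** 2, rel=0.005)

    def test_buried_atom_in_cage_is_zero(self):
        # central atom enclosed by a tight icosahedral-ish cage
        cage = golden_spiral_points(30) * 0.25
        pts = np.vstack([[0.0, 0.0, 0.0], cage])
        radii = np.full(len(pts), 0.17)
        areas = sasa_points(pts, radii, 0.14, 960)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            sasa_points(np.empty((0, 3)), np.empty(0))

    def test_profile_total_is_sum(self, helix):
        prof = sasa(helix)
        assert isinstance(prof, SASAProfile)
        assert prof.total == pytest.approx(prof.per_residue.sum())
        assert (prof.per_residue >= 0).all()

    def test_deterministic_no_rng(self, helix):
        a = sasa(helix).per_residue
        b = sasa(helix).per_residue
        np.testing.assert_array_equal(a, b)

    def test_against_bruteforce_occlusion_oracle(self, random_frames):
        """Independent oracle: dense random surface points, plain loops."""
        rng = np.random.default_rng(8)
        for conf in random_frames[:5]:
            pts, elements = conf.heavy_atoms()
            from idpbem.structure import ATOM_RADII

            radii = np.array([ATOM_RADII[e] for e in elements])
            got = sasa_points(pts, radii, 0.14, 960).sum()
            want = 0.0
            n_mc = 3000
            for i in range(len(pts)):
                ri = radii[i] + 0.14
                v = rng.normal(size=(n_mc, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                test = pts[i] + ri * v
                free = np.ones(n_mc, dtype=bool)
                for j in range(len(pts)):
                    if j == i:
                        continue
                    rj = radii[j] + 0.14
                    free &= np.sum((test - pts[j]) ** 2, axis=1) >= rj * rj
                want += 4.0 * np.pi * ri * ri * free.mean()
            assert got == pytest.approx(want, rel=0.02)

    def test_against_mdtraj_cross_check(self, tmp_path, ala_helix, ala_sequence):
        import mdtraj

        from idpbem.model import Trajectory
        from idpbem.pdbio import write_pdb

        no_h = Conformation(
            sequence=ala_sequence,
            coords={k: v for k, v in ala_helix.coords.items() if k != "H"},
        )
        path = tmp_path / "helix.pdb"
        write_pdb(Trajectory(sequence=ala_sequence, frames=[no_h]), path)
        t = mdtraj.load(str(path))
        ours = sasa(no_h).total
        theirs = float(mdtraj.shrake_rupley(t, n_sphere_points=960).sum())
        assert ours == pytest.approx(theirs, rel=0.02)


class TestRadiusOfGyration:
    def _conf_from_points(self, pts):
        n = len(pts)
        seq = PeptideSequence("A" * max(n, 7))
        coords = {k: np.full((len(seq), 3), np.nan) for k in ("N", "CA", "C", "O", "CB")}
        coords["CA"][:n] = pts
        return Conformation(sequence=seq, coords=coords)

    def test_coincident_points_give_zero(self):
        conf = self._conf_from_points(np.zeros((7, 3)))
        assert radius_of_gyration(conf) == 0.0

    def test_two_points_at_distance_d(self):
        d = 1.4
        conf = self._conf_from_points(
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]] + [[0.0, 0.0, 0.0]] * 5)
        )
        # 5 extra coincident unit masses shift the closed form accordingly
        pts = conf.coords["CA"][:7]
        com = pts.mean(axis=0)
        expect = np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1)))
        assert radius_of_gyration(conf) == pytest.approx(expect, abs=1e-12)

    def test_ring_radius(self):
        ang = np.linspace(0.0, 2 * np.pi, 8, endpoint=False)
        ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(8)]) * 0.9
        conf = self._conf_from_points(ring)
        assert radius_of_gyration(conf) == pytest.approx(0.9, abs=1e-12)

    def test_helix_more_compact_than_extended(self, helix, extended):
        assert radius_of_gyration(helix) < radius_of_gyration(extended)


class TestWindowReport:
    def test_all_frames_window0_zero_delta_sasa(self):
        labels = np.full((10, 5), "C", dtype="U1")
        sas = np.random.default_rng(0).uniform(0.5, 1.0, size=(10, 5))
        rep = window_report(labels, np.zeros(10, dtype=int), sas, np.ones(10))
        np.testing.assert_allclose(rep.delta_sasa, 0.0, atol=1e-12)

    def test_fraction_modes(self):
        labels = np.full((10, 3), "C", dtype="U1")
        labels[:2, 1] = "H"  # 2 helix frames at residue 1, all in window 1
        wa = np.array([1, 1] + [0] * 8)
        total = window_report(labels, wa, mode="total")
        within = window_report(labels, wa, mode="within")
        w1_t = np.where(total.windows == 1)[0][0]
        assert total.fractions["H"][w1_t, 1] == pytest.approx(0.2)
        assert within.fractions["H"][w1_t, 1] == pytest.approx(1.0)

    def test_recovers_constructed_20_percent_helix(self, wt_sequence):
        """Window with exactly 20% helical frames at residues 15-18 reports
        an H fraction of 0.20 there (within-window mode)."""
        spec = SSSpec(27, [BlockSpec(14, 18, "H", 1.0)], noise_sd=4.0)
        helix_traj, _ = sample_ensemble(wt_sequence, spec, 20, seed=9)
        coil_traj, _ = sample_ensemble(wt_sequence, SSSpec(27, [], 4.0), 80, seed=10)
        frames = helix_traj.frames + coil_traj.frames
        labels = np.array([label_conformation(c) for c in frames])
        wa = np.ones(100, dtype=int)  # one populated window
        rep = window_report(labels, wa, mode="within")
        for r in range(14, 18):
            assert rep.fractions["H"][0, r] == pytest.approx(0.20, abs=0.05)

    def test_fractions_partition_bound(self, wt_sequence):
        spec = SSSpec(
            27,
            [BlockSpec(14, 18, "H", 0.5), BlockSpec(4, 6, "P", 0.5)],
            noise_sd=8.0,
        )
        traj, _ = sample_ensemble(wt_sequence, spec, 50, seed=11)
        labels = np.array([label_conformation(c) for c in traj.frames])
        rep = window_report(labels, np.zeros(50, dtype=int), mode="within")
        total = rep.fractions["H"] + rep.fractions["E"] + rep.fractions["P"]
        assert (total <= 1.0 + 1e-12).all()

    def test_out_of_range_frames_dropped(self):
        labels = np.full((4, 3), "C", dtype="U1")
        wa = np.array([0, 0, -1, 1])
        rep = window_report(labels, wa)
        assert rep.frame_counts.sum() == 3

    def test_compaction_trend_fixture(self, wt_sequence):
        """Windows constructed with increasing structure are increasingly
        compact: mean Rg and mean total SASA strictly decrease."""
        frames, wa = [], []
        for w in range(5):
            for k in range(3):
                n_hel = 4 + 5 * w
                phi = np.full(27, -140.0 - k)  # slight within-window variety
                psi = np.full(27, 135.0 + k)
                phi[2 : 2 + n_hel] = -57.8
                psi[2 : 2 + n_hel] = -47.0
                frames.append(
                    build_backbone_from_torsions(
                        wt_sequence, TorsionProfile(phi=phi, psi=psi)
                    )
                )
                wa.append(w)
        labels = np.array([label_conformation(c) for c in frames])
        sas = np.array([sasa(c, n_sphere_points=480).per_residue for c in frames])
        rg = np.array([radius_of_gyration(c) for c in frames])
        rep = window_report(labels, np.array(wa), sas, rg)
        assert (np.diff(rep.mean_rg) < 0).all()
        assert (np.diff(rep.mean_sasa) < 0).all()

    def test_long_format_row_count(self):
        labels = np.full((6, 4), "C", dtype="U1")
        sas = np.ones((6, 4))
        rep = window_report(labels, np.array([0, 0, 1, 1, 2, 2]), sas, np.ones(6))
        df = rep.to_frame()
        # residues x populated windows x (3 fractions + delta_sasa)
        assert len(df) == 4 * 3 * 4
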
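"""The seven collective variables: switching-function analytics, fragment
counts on structural fixtures, contact numbers, side-chain similarity, and
agreement with naive loop re-implementations."""
import importlib.resources

import numpy as np
import pytest
from hypothesis import given, strategies as st

from idpbem.colvars import (
    CHI_REFERENCE,
    ContactSet,
    CVConfig,
    HYDROPHOBIC_SWITCH,
    RMSD_SWITCH,
    SwitchingSpec,
    _TEMPLATE_ATOMS,
    alphabeta_cv,
    compute_all_cvs,
    compute_cvs,
    contact_cv,
    get_template,
    hydrophobic_contact_set,
    n_contributing_angles,
    n_fragment_windows,
    salt_bridge_contact_set,
    ss_rmsd_cv,
    switching,
    uvr8_cv_config,
)
from idpbem.geometry import kabsch_rmsd, random_rotation
from idpbem.model import Trajectory, compute_torsions
from tests.conftest import random_conformations


class TestSwitching:
    def test_value_one_at_zero(self):
        assert switching(0.0, RMSD_SWITCH) == pytest.approx(1.0)

    def test_analytic_limit_at_r0(self):
        assert switching(RMSD_SWITCH.r0, RMSD_SWITCH) == pytest.approx(2.0 / 3.0)

    def test_direct_arithmetic(self):
        spec = SwitchingSpec(r0=1.0, n_exp=6, m_exp=12)
        assert switching(2.0, spec) == pytest.approx(63.0 / 4095.0, rel=1e-12)

    def test_continuity_across_singularity(self):
        for eps in (1e-6, 1e-7, 1e-8):
            lo = switching(RMSD_SWITCH.r0 * (1 - eps), RMSD_SWITCH)
            hi = switching(RMSD_SWITCH.r0 * (1 + eps), RMSD_SWITCH)
            mid = 2.0 / 3.0
            assert abs(0.5 * (lo + hi) - mid) < 1e-8
            assert abs(lo - mid) < 3.0 * eps and abs(hi - mid) < 3.0 * eps

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_monotone_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert switching(hi, RMSD_SWITCH) <= switching(lo, RMSD_SWITCH) + 1e-12

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SwitchingSpec(r0=-1.0, n_exp=8, m_exp=12)
        with pytest.raises(ValueError):
            SwitchingSpec(r0=0.08, n_exp=12, m_exp=8)


class TestFragmentCVs:
    def test_helix_counts_all_windows(self, helix):
        assert 21.5 <= ss_rmsd_cv(helix, "alpha") <= 22.0

    def test_helix_scores_no_sheet(self, helix):
        assert ss_rmsd_cv(helix, "para_beta") < 0.5
        assert ss_rmsd_cv(helix, "anti_beta") < 0.5

    def test_extended_scores_no_helix(self, extended):
        assert ss_rmsd_cv(extended, "alpha") < 0.5

    def test_rigid_invariance(self, helix):
        rng = np.random.default_rng(4)
        rot = random_rotation(rng)
        shift = rng.normal(size=3)
        moved = type(helix)(
            sequence=helix.sequence,
            coords={k: v @ rot.T + shift for k, v in helix.coords.items()},
            chi=helix.chi,
        )
        for kind in ("alpha", "para_beta", "anti_beta"):
            assert ss_rmsd_cv(moved, kind) == pytest.approx(
                ss_rmsd_cv(helix, kind), abs=1e-9
            )

    def test_bounded_by_window_count(self, random_frames):
        for conf in random_frames[:5]:
            n = len(conf)
            assert 0.0 <= ss_rmsd_cv(conf, "alpha") <= n_fragment_windows(n, "alpha")

    def test_templates_have_ideal_geometry(self):
        for kind in ("alpha", "para_beta", "anti_beta"):
            t = get_template(kind)
            assert t.coordinates.shape == (30, 3)
            # N-CA bond lengths within 1% of ideal in every residue
            for res in range(6):
                n_at = t.coordinates[res * 5 + 0]
                ca = t.coordinates[res * 5 + 1]
                assert np.linalg.norm(ca - n_at) == pytest.approx(0.1458, rel=0.01)

    def test_template_fixture_files_match_built(self):
        data = importlib.resources.files("idpbem") / "data" / "templates"
        for kind in ("alpha", "para_beta", "anti_beta"):
            pts = []
            for line in (data / f"{kind}.pdb").read_text().splitlines():
                if line.startswith("ATOM"):
                    pts.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
            fixture_nm = np.array(pts) * 0.1
            assert np.allclose(fixture_nm, get_template(kind).coordinates, atol=5.1e-5)


class TestContactCVs:
    def test_far_apart_sites_give_zero(self, helix, extended, wt_sequence):
        cset = hydrophobic_contact_set(wt_sequence, uvr8_cv_config().hydrophobic_residues)
        # strict: all sites more than 3 r0 apart by construction
        conf = type(helix)(
            sequence=helix.sequence,
            coords={k: v.copy() for k, v in helix.coords.items()},
        )
        conf.coords["CB"][:] = np.arange(27)[:, None] * np.array([10.0, 0.0, 0.0])
        assert contact_cv(conf, cset) < 1e-6
        # the extended chain keeps the hydrophobic core open too
        assert contact_cv(extended, cset) < 0.2

    def test_single_pair_at_r0_gives_n_over_m(self, helix, wt_sequence):
        # put exactly two sites at r0, everything else far away
        conf = type(helix)(
            sequence=helix.sequence,
            coords={k: v.copy() for k, v in helix.coords.items()},
        )
        sites = conf.coords["CB"]
        for i in range(27):
            sites[i] = np.array([10.0 * i, 0.0, 0.0])
        i, j = wt_sequence.index_of(401), wt_sequence.index_of(409)
        sites[j] = sites[i] + np.array([HYDROPHOBIC_SWITCH.r0, 0.0, 0.0])
        cset = hydrophobic_contact_set(wt_sequence, uvr8_cv_config().hydrophobic_residues)
        expected = HYDROPHOBIC_SWITCH.n_exp / HYDROPHOBIC_SWITCH.m_exp
        assert contact_cv(conf, cset) == pytest.approx(expected, abs=1e-6)

    def test_matches_bruteforce_oracle(self, wt_sequence):
        cset4 = hydrophobic_contact_set(wt_sequence, uvr8_cv_config().hydrophobic_residues)
        cset5 = salt_bridge_contact_set(wt_sequence)
        for conf in random_conformations(wt_sequence, 5, seed=3, compact=True):
            for cset in (cset4, cset5):
                sites = conf.sidechain_sites()
                expected = 0.0
                for i, j in cset.pairs:
                    expected += switching(
                        float(np.linalg.norm(sites[i] - sites[j])), cset.switching
                    )
                assert contact_cv(conf, cset) == pytest.approx(expected, abs=1e-10)

    def test_uvr8_pair_set_composition(self, wt_sequence):
        cset = hydrophobic_contact_set(wt_sequence, uvr8_cv_config().hydrophobic_residues)
        # C(7,2) = 21 minus the four sequence-adjacent pairs
        # (P403-A404, A408-V409, V409-V410, V410-P411)
        assert len(cset.pairs) == 17
        sset = salt_bridge_contact_set(wt_sequence)
        acid = {i for i, aa in enumerate(wt_sequence.residues) if aa in "DE"}
        base = {i for i, aa in enumerate(wt_sequence.residues) if aa in "RK"}
        for i, j in sset.pairs:
            assert (i in acid and j in base)

    def test_contact_set_rejects_self_and_duplicate_pairs(self):
        with pytest.raises(ValueError):
            ContactSet(pairs=((3, 3),), switching=HYDROPHOBIC_SWITCH)
        with pytest.raises(ValueError):
            ContactSet(pairs=((3, 5), (5, 3)), switching=HYDROPHOBIC_SWITCH)

    def test_empty_pair_set_returns_zero(self, helix):
        cset = ContactSet(pairs=(), switching=HYDROPHOBIC_SWITCH)
        assert contact_cv(helix, cset) == 0.0


class TestAlphaBetaCVs:
    def test_all_at_reference_counts_contributors(self, wt_sequence, helix):
        n = len(wt_sequence)
        chi = np.full((n, 2), np.nan)
        for i, aa in enumerate(wt_sequence.residues):
            if aa in CHI_REFERENCE["chi1"]:
                chi[i, 0] = CHI_REFERENCE["chi1"][aa]
        conf = type(helix)(sequence=wt_sequence, coords=helix.coords, chi=chi)
        t = compute_torsions(conf)
        expected = n_contributing_angles(wt_sequence, "chi1")
        assert expected > 0
        assert alphabeta_cv(t, wt_sequence, "chi1") == pytest.approx(expected)

    def test_antiperiodic_offset_gives_zero(self, wt_sequence, helix):
        n = len(wt_sequence)
        chi = np.full((n, 2), np.nan)
        for i, aa in enumerate(wt_sequence.residues):
            if aa in CHI_REFERENCE["chi1"]:
                chi[i, 0] = CHI_REFERENCE["chi1"][aa] + 180.0
        conf = type(helix)(sequence=wt_sequence, coords=helix.coords, chi=chi)
        t = compute_torsions(conf)
        assert alphabeta_cv(t, wt_sequence, "chi1") == pytest.approx(0.0, abs=1e-9)

    def test_mixed_offsets_direct_arithmetic(self, wt_sequence, helix):
        # three contributing residues offset by 0, 90 and 180 degrees
        n = len(wt_sequence)
        chi = np.full((n, 2), np.nan)
        picked = [i for i, aa in enumerate(wt_sequence.residues) if aa in CHI_REFERENCE["chi1"]][:3]
        for k, i in enumerate(picked):
            aa = wt_sequence.residues[i]
            chi[i, 0] = CHI_REFERENCE["chi1"][aa] + (0.0, 90.0, 180.0)[k]
        conf = type(helix)(sequence=wt_sequence, coords=helix.coords, chi=chi)
        t = compute_torsions(conf)
        assert alphabeta_cv(t, wt_sequence, "chi1") == pytest.approx(1.5, abs=1e-9)

    def test_residues_lacking_angle_contribute_zero(self, wt_sequence, helix):
        t = compute_torsions(helix)  # no chi stored at all
        assert alphabeta_cv(t, wt_sequence, "chi1") == 0.0
        assert alphabeta_cv(t, wt_sequence, "chi2") == 0.0


class TestComputeAllCVs:
    def test_empty_trajectory(self, wt_sequence):
        traj = Trajectory(sequence=wt_sequence, frames=[], times=np.array([]))
        assert compute_all_cvs(traj) == []

    def test_helix_frame_values(self, helix, wt_sequence):
        traj = Trajectory(sequence=wt_sequence, frames=[helix])
        rec = compute_all_cvs(traj, uvr8_cv_config())[0]
        assert 21.5 <= rec.values[0] <= 22.0
        assert rec.values[1] < 0.5 and rec.values[2] < 0.5

    def test_identical_frames_identical_records(self, helix, wt_sequence):
        traj = Trajectory(sequence=wt_sequence, frames=[helix, helix])
        r1, r2 = compute_all_cvs(traj, uvr8_cv_config())
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_agreement_with_naive_loops(self, random_frames, wt_sequence):
        """All seven CVs match plain-loop re-implementations to 1e-10."""
        cfg = uvr8_cv_config()
        cset4 = hydrophobic_contact_set(wt_sequence, cfg.hydrophobic_residues)
        cset5 = salt_bridge_contact_set(wt_sequence)
        for conf in random_frames:
            got = compute_cvs(conf, cfg)
            want = np.empty(7)
            for k, kind in enumerate(("alpha", "para_beta", "anti_beta")):
                want[k] = _naive_fragment_cv(conf, kind)
            sites = conf.sidechain_sites()
            for k, cset in ((3, cset4), (4, cset5)):
                tot = 0.0
                for i, j in cset.pairs:
                    tot += switching(
                        float(np.linalg.norm(sites[i] - sites[j])), cset.switching
                    )
                want[k] = tot
            t = compute_torsions(conf)
            for k, angle in ((5, "chi1"), (6, "chi2")):
                tot = 0.0
                chis = t.chi1 if angle == "chi1" else t.chi2
                for i, aa in enumerate(wt_sequence.residues):
                    if aa in CHI_REFERENCE[angle] and np.isfinite(chis[i]):
                        tot += 0.5 * (
                            1.0 + np.cos(np.radians(chis[i] - CHI_REFERENCE[angle][aa]))
                        )
                want[k] = tot
            np.testing.assert_allclose(got, want, atol=1e-10)


def _naive_fragment_cv(conf, kind, cutoff=1.0):
    tmpl = get_template(kind).coordinates
    n = len(conf)
    total = 0.0
    if kind == "alpha":
        for a in range(n - 5):
            pts = np.array(
                [conf.coords[nm][i] for i in range(a, a + 6) for nm in _TEMPLATE_ATOMS]
            )
            total += switching(kabsch_rmsd(pts, tmpl), RMSD_SWITCH)
        return total
    ca = conf.coords["CA"]
    cent = np.array([ca[i : i + 3].mean(axis=0) for i in range(n - 2)])
    for i in range(n - 2):
        for j in range(i + 4, n - 2):
            if np.linalg.norm(cent[i] - cent[j]) > cutoff:
                continue
            pts = np.array(
                [
                    conf.coords[nm][k]
                    for k in list(range(i, i + 3)) + list(range(j, j + 3))
                    for nm in _TEMPLATE_ATOMS
                ]
            )
            total += switching(kabsch_rmsd(pts, tmpl), RMSD_SWITCH)
    return total
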
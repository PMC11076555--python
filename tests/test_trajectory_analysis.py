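"""RMSF, interaction propensity, secondary-structure propensity and
residue-wise conformer deviation."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import pdzcoupling as pz
from pdzcoupling import synthetic_data as sd
from pdzcoupling.structure_io import Selection
from pdzcoupling.trajectory_analysis import dihedral


def random_rigid(rng):
    q = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(q)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(scale=10.0, size=3)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        m = sd.build_chain_structure("GSTFSLW")
        traj = pz.Trajectory(m, np.tile(m.coords, (4, 1, 1)))
        prof = pz.rmsf(traj)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_two_frame_closed_form_without_fit(self):
        m = sd.build_chain_structure("GSTFSLW")
        d = 0.7
        frames = np.stack([m.coords + [d, 0, 0], m.coords - [d, 0, 0]])
        prof = pz.rmsf(pz.Trajectory(m, frames), fit=False)
        np.testing.assert_allclose(prof.values, d, atol=1e-12)

    def test_isotropic_gaussian_matches_sigma_sqrt3(self):
        sigma = 0.5
        m = sd.build_chain_structure("A" * 20)
        traj = sd.gen_trajectory(sigma ** 2 * np.eye(20), 5000, 11, m)
        prof = pz.rmsf(traj, fit=False)
        np.testing.assert_allclose(prof.values, sigma * np.sqrt(3), rtol=0.05)

    def test_fit_removes_per_frame_rigid_noise(self):
        rng = np.random.default_rng(4)
        m = sd.build_chain_structure("GSTFSLWQDIP")
        frames = []
        for _ in range(6):
            R, t = random_rigid(rng)
            frames.append(m.coords @ R.T + t)
        prof = pz.rmsf(pz.Trajectory(m, np.stack(frames)), fit=True)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-6)

    def test_empty_selection_raises(self):
        m = sd.build_chain_structure("GSTF")
        traj = pz.Trajectory(m, np.tile(m.coords, (3, 1, 1)))
        with pytest.raises(ValueError):
            pz.rmsf(traj, Selection(chain_id="Z"))


class TestInteractionPropensity:
    @pytest.fixture()
    def scripted(self):
        schedule = {(7, 3): 0.3, (9, 1): 1.0, (2, 4): 0.0}
        traj, gt = sd.gen_complex_trajectory("GSTFSLWQDIP", domain_size=5,
                                             contact_schedule=schedule,
                                             cutoff=4.0, n_frames=10, seed=5)
        return traj, gt

    def test_scripted_fractions_exact(self, scripted):
        traj, _ = scripted
        pm = pz.interaction_propensity(traj, Selection(chain_id="B"),
                                       Selection(chain_id="A"), cutoff=4.0)
        assert pm.values[6, 2] == pytest.approx(0.3)
        assert pm.values[8, 0] == pytest.approx(1.0)
        assert pm.values[1, 3] == pytest.approx(0.0)

    def test_matches_brute_force_distance_oracle(self, scripted):
        traj, _ = scripted
        pm = pz.interaction_propensity(traj, Selection(chain_id="B"),
                                       Selection(chain_id="A"), cutoff=4.0)
        topo = traj.topology
        pep_res = sorted({a.residue_index for a in topo.atoms if a.chain_id == "B"})
        dom_res = sorted({a.residue_index for a in topo.atoms if a.chain_id == "A"})
        for i, pr in enumerate(pep_res):
            pep_idx = [k for k, a in enumerate(topo.atoms)
                       if a.chain_id == "B" and a.residue_index == pr
                       and (a.name not in ("N", "CA", "C", "O", "OXT")
                            or a.residue_name == "GLY")]
            for j, dr in enumerate(dom_res):
                dom_idx = [k for k, a in enumerate(topo.atoms)
                           if a.chain_id == "A" and a.residue_index == dr]
                count = sum(
                    cdist(traj.frames[f][pep_idx], traj.frames[f][dom_idx]).min() < 4.0
                    for f in range(traj.n_frames))
                assert pm.values[i, j] == pytest.approx(count / traj.n_frames)

    def test_frame_permutation_and_rigid_invariance(self, scripted, rng):
        traj, _ = scripted
        ref = pz.interaction_propensity(traj, Selection(chain_id="B"),
                                        Selection(chain_id="A")).values
        perm = pz.Trajectory(traj.topology, traj.frames[rng.permutation(traj.n_frames)])
        assert np.array_equal(
            pz.interaction_propensity(perm, Selection(chain_id="B"),
                                      Selection(chain_id="A")).values, ref)
        moved = traj.frames.copy()
        for f in range(traj.n_frames):
            R, t = random_rigid(rng)
            moved[f] = moved[f] @ R.T + t
        got = pz.interaction_propensity(pz.Trajectory(traj.topology, moved),
                                        Selection(chain_id="B"),
                                        Selection(chain_id="A")).values
        assert np.array_equal(got, ref)

    def test_monotone_non_increasing_in_cutoff(self, scripted):
        traj, _ = scripted
        vals = [pz.interaction_propensity(traj, Selection(chain_id="B"),
                                          Selection(chain_id="A"), cutoff=c).values
                for c in (2.0, 4.0, 8.0, 20.0)]
        for lo, hi in zip(vals, vals[1:]):
            assert np.all(lo <= hi)

    def test_boundary_distance_is_not_a_contact(self):
        # a pair at exactly the cutoff must not count (strict inequality)
        from pdzcoupling.structure_io import Atom, StructureModel

        topo = StructureModel([
            Atom("CA", "C", 1, "ALA", "A", np.array([0.0, 0.0, 0.0])),
            Atom("CB", "C", 1, "ALA", "B", np.array([4.0, 0.0, 0.0])),
            Atom("CA", "C", 1, "ALA", "B", np.array([4.0, 2.0, 0.0])),
        ])
        traj = pz.Trajectory(topo, np.tile(topo.coords, (3, 1, 1)))
        pm = pz.interaction_propensity(traj, Selection(chain_id="B"),
                                       Selection(chain_id="A"), cutoff=4.0)
        assert pm.values[0, 0] == 0.0
        assert pz.interaction_propensity(traj, Selection(chain_id="B"),
                                         Selection(chain_id="A"),
                                         cutoff=4.0 + 1e-9).values[0, 0] == 1.0


class TestSsPropensity:
    def test_extended_strand_is_all_beta(self):
        m = sd.build_backbone_model("ASTFS", phi=-120.0, psi=130.0)
        traj = pz.Trajectory(m, np.tile(m.coords, (3, 1, 1)))
        prof = pz.ss_propensity(traj)
        inner = prof.values[1:-1]
        np.testing.assert_allclose(inner, 1.0)
        assert np.isnan(prof.values[0]) and np.isnan(prof.values[-1])

    def test_alpha_helix_is_never_beta(self):
        m = sd.build_backbone_model("ASTFS", phi=-57.0, psi=-47.0)
        traj = pz.Trajectory(m, np.tile(m.coords, (3, 1, 1)))
        np.testing.assert_allclose(pz.ss_propensity(traj).values[1:-1], 0.0)

    def test_mixed_frames_count_exactly(self):
        strand = sd.build_backbone_model("ASTFS", phi=-120.0, psi=130.0)
        helix = sd.build_backbone_model("ASTFS", phi=-57.0, psi=-47.0)
        frames = np.concatenate([np.tile(strand.coords, (4, 1, 1)),
                                 np.tile(helix.coords, (6, 1, 1))])
        prof = pz.ss_propensity(pz.Trajectory(strand, frames))
        np.testing.assert_allclose(prof.values[1:-1], 0.4)

    def test_halves_average_to_full(self):
        strand = sd.build_backbone_model("ASTFS", phi=-120.0, psi=130.0)
        helix = sd.build_backbone_model("ASTFS", phi=-57.0, psi=-47.0)
        frames = np.concatenate([np.tile(strand.coords, (3, 1, 1)),
                                 np.tile(helix.coords, (3, 1, 1))])
        full = pz.ss_propensity(pz.Trajectory(strand, frames)).values
        h1 = pz.ss_propensity(pz.Trajectory(strand, frames[:3])).values
        h2 = pz.ss_propensity(pz.Trajectory(strand, frames[3:])).values
        np.testing.assert_allclose((h1[1:-1] + h2[1:-1]) / 2, full[1:-1])

    def test_backbone_builder_reproduces_prescribed_dihedrals(self):
        m = sd.build_backbone_model("AAAAA", phi=-120.0, psi=130.0)
        c = m.coords.reshape(5, 3, 3)   # (res, [N, CA, C], xyz)
        for i in range(1, 4):
            phi = dihedral(c[i - 1, 2], c[i, 0], c[i, 1], c[i, 2])
            psi = dihedral(c[i, 0], c[i, 1], c[i, 2], c[i + 1, 0])
            assert phi == pytest.approx(-120.0, abs=1e-6)
            assert psi == pytest.approx(130.0, abs=1e-6)

    def test_missing_backbone_atom_raises(self):
        m = sd.build_chain_structure("ASTF")   # Ca trace only
        traj = pz.Trajectory(m, np.tile(m.coords, (2, 1, 1)))
        with pytest.raises(ValueError, match="backbone"):
            pz.ss_propensity(traj)


class TestResidueDeviation:
    def test_identical_models_zero(self):
        m = sd.build_chain_structure("GSTFSLWQDIP")
        prof = pz.residue_deviation(m, m)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_rigidly_rotated_copy_zero(self, rng):
        m = sd.build_chain_structure("GSTFSLWQDIP")
        R, t = random_rigid(rng)
        moved = m.with_coords(m.coords @ R.T + t)
        prof = pz.residue_deviation(m, moved)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-8)

    def test_single_displaced_residue_detected(self):
        m = sd.build_chain_structure("A" * 50)
        coords = m.coords.copy()
        coords[24] += [0.0, 2.0, 0.0]
        prof = pz.residue_deviation(m, m.with_coords(coords))
        assert prof.values[24] == pytest.approx(2.0, rel=0.05)
        others = np.delete(prof.values, 24)
        assert np.all(others < 0.15)

    def test_empty_pairing_raises(self):
        a = sd.build_chain_structure("GSTF", start_index=1)
        b = sd.build_chain_structure("GSTF", start_index=100)
        with pytest.raises(ValueError):
            pz.residue_deviation(a, b)
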
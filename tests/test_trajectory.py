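import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynallo import trajectory as tj
from dynallo.synthetic import place_fourth_atom


def linear_topology(n_atoms, resids=None, elements=None):
    return tj.Topology(
        names=np.array([f"C{i}" for i in range(n_atoms)]),
        resids=np.array(resids if resids is not None else range(n_atoms)),
        resnames=np.array(["GLY"] * n_atoms),
        elements=np.array(elements if elements is not None else ["C"] * n_atoms),
    )


def make_ensemble(coords, dt_ns=0.1, topo=None, condition="test"):
    coords = np.asarray(coords, dtype=float)
    topo = topo or linear_topology(coords.shape[1])
    return tj.TrajectoryEnsemble(
        topology=topo,
        replicas=[tj.Replica(coords=coords, dt_ns=dt_ns, label="r0")],
        condition=condition,
    )


class TestSelection:
    def setup_method(self):
        self.topo = tj.Topology(
            names=np.array(["CA", "CB", "HA", "N"]),
            resids=np.array([757, 760, 760, 783]),
            resnames=np.array(["ALA"] * 4),
            elements=np.array(["C", "C", "H", "N"]),
        )

    def test_resid_range_and_heavy(self):
        mask = tj.select(self.topo, "resid 757-770 and heavy")
        assert mask.tolist() == [True, True, False, False]

    def test_name_and_element(self):
        assert tj.select(self.topo, "name CA").tolist() == [True, False, False, False]
        assert tj.select(self.topo, "element N").tolist() == [False, False, False, True]

    def test_resid_list(self):
        assert tj.select(self.topo, "resid 757 783").tolist() == [True, False, False, True]

    def test_unknown_keyword_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            tj.select(self.topo, "backbone")


class TestContactProbability:
    def test_alternating_distances_give_half(self):
        """Distances alternating 2/3 Å with a 10-frame window → all 0.5."""
        n = 100
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = np.where(np.arange(n) % 2 == 0, 2.0, 3.0)
        ens = make_ensemble(coords, dt_ns=0.1, topo=linear_topology(2, resids=[1, 2]))
        prof = tj.contact_probability(ens, "resid 1", "resid 2", window_ns=1.0)[0]
        assert prof.window_frames == 10
        assert np.allclose(prof.window_series, 0.5)
        assert len(prof.window_series) == n - 10 + 1

    def test_far_apart_never_in_contact(self):
        coords = np.zeros((50, 2, 3))
        coords[:, 1, 0] = 5.0
        ens = make_ensemble(coords, topo=linear_topology(2, resids=[1, 2]))
        prof = tj.contact_probability(ens, "resid 1", "resid 2")[0]
        assert prof.indicator.sum() == 0
        assert np.all(prof.window_series == 0.0)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.uniform(0, 6, size=(40, 6, 3))
        topo = linear_topology(6, resids=[1, 1, 1, 2, 2, 2])
        ens = make_ensemble(coords, topo=topo)
        prof = tj.contact_probability(ens, "resid 1", "resid 2", cutoff=2.5)[0]
        for f in range(40):
            expected = 0.0
            for i in range(3):
                for j in range(3, 6):
                    d = np.linalg.norm(coords[f, i] - coords[f, j])
                    if d < 2.5:
                        expected = 1.0
            assert prof.indicator[f] == expected

    def test_selection_swap_invariance(self, rng):
        coords = rng.uniform(0, 5, size=(30, 4, 3))
        topo = linear_topology(4, resids=[1, 1, 2, 2])
        ens = make_ensemble(coords, topo=topo)
        a = tj.contact_probability(ens, "resid 1", "resid 2")[0]
        b = tj.contact_probability(ens, "resid 2", "resid 1")[0]
        assert np.array_equal(a.indicator, b.indicator)

    def test_hydrogens_excluded_by_default(self):
        coords = np.zeros((5, 3, 3))
        coords[:, 1, 0] = 2.0   # H atom of residue 1, within cutoff
        coords[:, 2, 0] = 4.0   # heavy atom of residue 2, outside cutoff
        topo = linear_topology(3, resids=[1, 1, 2], elements=["C", "H", "C"])
        ens = make_ensemble(coords, topo=topo)
        heavy = tj.contact_probability(ens, "resid 1", "resid 2")[0]
        assert heavy.indicator.sum() == 0
        withh = tj.contact_probability(
            ens, "resid 1", "resid 2", include_hydrogens=True
        )[0]
        assert withh.indicator.sum() == 5

    def test_window_probabilities_match_brute_force_mean(self, rng):
        coords = rng.uniform(0, 4, size=(50, 2, 3))
        ens = make_ensemble(coords, dt_ns=0.2, topo=linear_topology(2, resids=[1, 2]))
        prof = tj.contact_probability(ens, "resid 1", "resid 2", window_ns=1.0)[0]
        w = prof.window_frames
        for s in range(len(prof.window_series)):
            assert prof.window_series[s] == pytest.approx(
                prof.indicator[s:s + w].mean(), abs=1e-12
            )

    def test_errors(self):
        coords = np.zeros((10, 2, 3))
        ens = make_ensemble(coords, topo=linear_topology(2, resids=[1, 2]))
        with pytest.raises(ValueError, match="empty"):
            tj.contact_probability(ens, "resid 9", "resid 2")
        with pytest.raises(ValueError, match="disjoint"):
            tj.contact_probability(ens, "resid 1 2", "resid 2")
        with pytest.raises(ValueError, match="window"):
            tj.contact_probability(ens, "resid 1", "resid 2", window_ns=0.01)


def stretch_frames(n_frames, rng, amplitude=1.0):
    """Symmetric stretch of two atoms inside a rigid scaffold.

    The net translation and torque of the displacement are zero, so
    least-squares superposition is the identity and the planted eigenvalue
    has the closed form Var(s)/2.
    """
    base = np.array([
        [3.0, 0.0, 0.0], [-3.0, 0.0, 0.0],
        [0.0, 5.0, 0.0], [0.0, -5.0, 0.0],
        [0.0, 0.0, 5.0], [0.0, 0.0, -5.0],
    ])
    s = rng.normal(0, amplitude, size=n_frames)
    coords = np.repeat(base[None], n_frames, axis=0)
    coords[:, 0, 0] += s / 2
    coords[:, 1, 0] -= s / 2
    return coords, s


class TestPCA:
    def test_planted_mode_eigenvalue_closed_form(self, rng):
        coords, s = stretch_frames(400, rng)
        ens = make_ensemble(coords)
        model = tj.fit_pca([ens], "all")
        expected = np.var(s, ddof=1) / 2.0
        assert model.eigenvalues[0] == pytest.approx(expected, rel=1e-6)
        # mode is supported only on the two stretch atoms' x coordinates
        v = model.eigenvectors[:, 0].reshape(-1, 3)
        support = np.abs(v).max(axis=1) > 1e-8
        assert support.tolist() == [True, True, False, False, False, False]

    def test_replica_order_invariance(self, rng):
        c1, _ = stretch_frames(100, rng)
        c2 = c1 + rng.normal(0, 0.05, size=c1.shape)
        topo = linear_topology(6)
        e12 = tj.TrajectoryEnsemble(topo, [
            tj.Replica(c1, 0.1, "a"), tj.Replica(c2, 0.1, "b")])
        e21 = tj.TrajectoryEnsemble(topo, [
            tj.Replica(c2, 0.1, "b"), tj.Replica(c1, 0.1, "a")])
        m12 = tj.fit_pca([e12], "all")
        m21 = tj.fit_pca([e21], "all")
        assert np.allclose(m12.eigenvalues, m21.eigenvalues, atol=1e-8)

    def test_trace_identity(self, rng):
        coords = rng.normal(0, 0.3, size=(200, 5, 3)) + np.arange(5)[None, :, None]
        ens = make_ensemble(coords, topo=linear_topology(5))
        model = tj.fit_pca([ens], "all")
        sup = tj._superpose_stack(coords, coords[0])
        dev = (sup - sup.mean(axis=0)).reshape(200, -1)
        assert model.eigenvalues.sum() == pytest.approx(
            dev.var(axis=0, ddof=1).sum(), rel=1e-9
        )

    def test_rigid_body_motion_invariance(self, rng):
        """Global rotation+translation of all frames leaves eigenvalues alone."""
        coords, _ = stretch_frames(150, rng)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        moved = coords @ rot.T + np.array([10.0, -4.0, 2.5])
        m0 = tj.fit_pca([make_ensemble(coords)], "all")
        m1 = tj.fit_pca([make_ensemble(moved)], "all")
        assert np.allclose(m0.eigenvalues, m1.eigenvalues, atol=1e-8)

    def test_static_frames_flagged_degenerate(self):
        coords = np.repeat(np.arange(12).reshape(1, 4, 3).astype(float), 10, axis=0)
        model = tj.fit_pca([make_ensemble(coords, topo=linear_topology(4))], "all")
        assert model.degenerate
        assert np.all(model.eigenvalues < 1e-12)

    def test_orthonormal_eigenvectors(self, rng):
        coords = rng.normal(0, 0.2, size=(100, 4, 3))
        model = tj.fit_pca([make_ensemble(coords, topo=linear_topology(4))], "all")
        gram = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


class TestProjectionOverlap:
    def test_identical_series_overlap_one(self):
        s = np.array([0.0, 1.0, -1.0, 0.5])
        assert tj.overlap(s, s) == 1.0

    def test_disjoint_ranges_overlap_zero(self):
        assert tj.overlap(np.array([0.0, 1.0]), np.array([2.0, 3.0])) == 0.0

    def test_partial_overlap_is_interval_jaccard(self):
        assert tj.overlap(np.array([0.0, 2.0]), np.array([1.0, 3.0])) == pytest.approx(1 / 3)

    def test_condition_specific_mode_has_low_overlap(self, rng):
        ca, _ = stretch_frames(300, rng, amplitude=1.0)
        cb, _ = stretch_frames(300, rng, amplitude=0.0)
        cb += rng.normal(0, 0.02, size=cb.shape)
        ca += rng.normal(0, 0.02, size=ca.shape)
        topo = linear_topology(6)
        ea, eb = make_ensemble(ca, topo=topo), make_ensemble(cb, topo=topo)
        model = tj.fit_pca([ea, eb], "all")
        pa = tj.project(ea.replicas[0], model, 0)
        pb = tj.project(eb.replicas[0], model, 0)
        assert tj.overlap(pa, pb) < 0.5
        p2a = tj.project(ea.replicas[0], model, 1)
        p2b = tj.project(eb.replicas[0], model, 1)
        assert tj.overlap(p2a, p2b) > 0.5

    def test_out_of_range_eigenvector_rejected(self, rng):
        coords = rng.normal(0, 0.1, size=(20, 3, 3))
        ens = make_ensemble(coords, topo=linear_topology(3))
        model = tj.fit_pca([ens], "all")
        with pytest.raises(IndexError):
            tj.project(ens.replicas[0], model, 99)


class TestEigenvectorRMSF:
    def test_support_and_normalization(self, rng):
        coords, _ = stretch_frames(300, rng)
        topo = linear_topology(6, resids=[10, 11, 12, 12, 13, 13])
        model = tj.fit_pca([make_ensemble(coords, topo=topo)], "all")
        rmsf = tj.eigenvector_rmsf(model, 0).set_index("resid")
        # mode lives on residues 10 and 11 only
        assert rmsf.loc[10, "rmsf"] > 1e-3 and rmsf.loc[11, "rmsf"] > 1e-3
        assert rmsf.loc[13, "rmsf"] < 1e-6
        # sum over residues of RMSF^2 equals the eigenvalue
        assert (rmsf["rmsf"] ** 2).sum() == pytest.approx(
            model.eigenvalues[0], rel=1e-12
        )

    def test_matches_rank_one_reconstruction(self, rng):
        """RMSF agrees with direct fluctuation of the rank-1 reconstruction."""
        coords = rng.normal(0, 0.3, size=(500, 4, 3))
        topo = linear_topology(4, resids=[1, 1, 2, 2])
        ens = make_ensemble(coords, topo=topo)
        model = tj.fit_pca([ens], "all")
        k = 0
        proj = tj.project(ens.replicas[0], model, k)
        recon = proj[:, None] * model.eigenvectors[:, k][None, :]
        recon = recon.reshape(len(proj), -1, 3)
        per_atom_msf = (recon ** 2).sum(axis=2).mean(axis=0)
        expected = {
            r: np.sqrt(per_atom_msf[model.resids == r].sum())
            for r in (1, 2)
        }
        rmsf = tj.eigenvector_rmsf(model, k).set_index("resid")
        for r in (1, 2):
            # reconstruction uses 1/M variance; the model uses 1/(M-1)
            ratio = np.sqrt(len(proj) / (len(proj) - 1))
            assert rmsf.loc[r, "rmsf"] == pytest.approx(
                expected[r] * ratio, rel=0.01
            )


class TestDihedralMI:
    @given(phi=st.floats(-179.0, 180.0))
    @settings(max_examples=40, deadline=None)
    def test_torsion_placement_round_trip(self, phi):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.5, 0.0, 0.0])
        c = np.array([2.0, 1.4, 0.0])
        d = place_fourth_atom(a, b, c, 1.5, 109.5, np.array([phi]))
        coords = np.stack([a, b, c, d[0]])[None]
        measured = tj.dihedral_angles(coords, np.array([0, 1, 2, 3]))[0]
        assert measured == pytest.approx(phi, abs=1e-6)

    def test_identical_series_mi_is_log_bins(self, rng):
        """A series visiting b bins uniformly has self-MI ln(b)."""
        n_bins, n = 24, 120000
        angles = (np.arange(n) % n_bins) * (360.0 / n_bins) - 170.0
        mi = tj.histogram_mi(angles, angles, n_bins=n_bins)
        # plugin value is exactly ln(b); Miller-Madow adds (b-1)/2N
        assert mi == pytest.approx(np.log(n_bins) + (n_bins - 1) / (2 * n), abs=1e-9)

    def test_independent_angles_near_zero(self, rng):
        n = 100_000
        a = rng.uniform(-180, 180, n)
        b = rng.uniform(-180, 180, n)
        mi = tj.histogram_mi(a, b)
        assert abs(mi) <= 3 * tj.mi_bias_bound(n)

    def test_gaussian_correlation_closed_form(self, rng):
        rho, n = 0.8, 100_000
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        mi = tj.histogram_mi(z[:, 0] * 45.0, z[:, 1] * 45.0)
        expected = -0.5 * np.log(1 - rho**2)
        assert mi == pytest.approx(expected, rel=0.10)

    def test_matrix_symmetric_with_excluded_diagonal(self, toy_ensembles):
        from dynallo.synthetic import dihedral_map

        ens_a, _ = toy_ensembles
        mats = tj.dihedral_mi(ens_a, dihedral_map(ens_a.topology))
        for m in mats:
            assert np.array_equal(m.matrix, m.matrix.T)
            assert np.all(np.diag(m.matrix) == 0.0)

    def test_residues_without_dihedrals_excluded(self, toy_ensembles):
        ens_a, _ = toy_ensembles
        from dynallo.synthetic import dihedral_map

        dmap = dict(dihedral_map(ens_a.topology))
        dmap[999] = []
        mats = tj.dihedral_mi(ens_a, dmap)
        assert 999 not in mats[0].residues


class TestMIDifference:
    def _mats(self, values, residues=(1, 2, 3)):
        residues = np.array(residues)
        out = []
        for v in values:
            m = np.zeros((3, 3))
            m[0, 1] = m[1, 0] = v
            out.append(tj.MIMatrix(residues=residues, matrix=m, n_bins=24))
        return out

    def test_identical_replica_sets_give_empty_mask(self, rng):
        vals = rng.normal(0.5, 0.01, size=4)
        diff = tj.mi_difference(self._mats(vals), self._mats(vals))
        assert not diff.mask.any()

    def test_planted_difference_detected_with_sign(self, toy_ensembles):
        from dynallo.synthetic import DIHEDRAL_RESIDUES, dihedral_map

        ens_a, ens_b = toy_ensembles  # apo rho=0, phospho rho=0.8
        dmap = dihedral_map(ens_a.topology)
        mi_a = tj.dihedral_mi(ens_a, dmap)
        mi_b = tj.dihedral_mi(ens_b, dmap)
        diff = tj.mi_difference(mi_b, mi_a)
        res = list(diff.residues)
        i = res.index(DIHEDRAL_RESIDUES[0])
        j = res.index(DIHEDRAL_RESIDUES[1])
        assert diff.mask[i, j]
        assert diff.filtered[i, j] > 0.3  # MI gained on phosphorylation

    def test_too_few_replicas_rejected(self):
        with pytest.raises(ValueError, match="replicas"):
            tj.mi_difference(self._mats([0.1]), self._mats([0.1, 0.2]))

    def test_shape_mismatch_rejected(self):
        a = self._mats([0.1, 0.2])
        b = self._mats([0.1, 0.2], residues=(7, 8, 9))
        with pytest.raises(ValueError, match="share"):
            tj.mi_difference(a, b)
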
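"""Least-squares fitting, weighted fitting and symmetric side-chain remap."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from oligosuper import (
    RigidTransform,
    build_atom_mapping,
    global_align,
    lsq_fit,
    remap_symmetric_sidechains,
    rmsd_value,
    standard_fit,
    weighted_fit,
)
from oligosuper.fixtures import (
    FixtureSpec,
    apply_hinge,
    make_cyclic_assembly,
    make_protomer,
    make_sidechain_chain,
)
from oligosuper.superpose import deviations
from oligosuper.structure import Assembly


def rotation_oracle_rmsd(ref, tgt, rng, n_starts=400):
    """Independent optimum: random-quaternion sampling refined by local
    optimisation over rotation vectors, translation solved analytically."""
    ref = np.asarray(ref)
    tgt = np.asarray(tgt)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        moved = tgt @ R.T
        moved = moved - moved.mean(axis=0) + ref.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((ref - moved) ** 2, axis=1))))

    quats = rng.normal(size=(n_starts, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rotvecs = Rotation.from_quat(quats).as_rotvec()
    scores = [rmsd_of(rv) for rv in rotvecs]
    best = np.inf
    for idx in np.argsort(scores)[:5]:
        res = minimize(rmsd_of, rotvecs[idx], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def rz(deg):
    a = np.radians(deg)
    return np.array([
        [np.cos(a), -np.sin(a), 0.0],
        [np.sin(a), np.cos(a), 0.0],
        [0.0, 0.0, 1.0],
    ])


class TestLsqFit:
    def test_identical_sets_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(size=(8, 3))
        tf, r = lsq_fit(pts, pts)
        assert r < 1e-12
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-10)

    def test_exact_rigid_motion_recovered(self, rng):
        A = rng.normal(size=(10, 3))
        R, t = rz(37.0), np.array([1.0, -2.0, 3.0])
        B = (A - t) @ R  # so that R @ B + t == A... constructed inversely
        B = (R.T @ (A - t).T).T
        tf, r = lsq_fit(A, B)
        assert r < 1e-8
        assert np.allclose(tf.rotation, R, atol=1e-8)

    def test_matches_rotation_space_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(4, 7)
            A = rng.normal(size=(n, 3)) * 5
            B = A + rng.normal(size=(n, 3)) * 1.5
            _, r = lsq_fit(A, B)
            assert abs(r - rotation_oracle_rmsd(A, B, rng)) < 1e-4

    def test_invariant_under_rigid_premotion_of_target(self, rng):
        A = rng.normal(size=(12, 3)) * 4
        B = A + rng.normal(size=(12, 3))
        _, r0 = lsq_fit(A, B)
        R = Rotation.random(random_state=7).as_matrix()
        _, r1 = lsq_fit(A, B @ R.T + np.array([3.0, -1.0, 8.0]))
        assert r1 == pytest.approx(r0, abs=1e-8)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            lsq_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_raise(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            lsq_fit(line, line + [0.0, 1.0, 0.0])

    def test_proper_rotation_even_for_reflected_cloud(self, rng):
        A = rng.normal(size=(6, 3))
        B = A * np.array([-1.0, 1.0, 1.0])  # mirror image
        tf, _ = lsq_fit(A, B)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)


class TestRmsd:
    def test_self_is_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        assert rmsd_value(pts, pts, RigidTransform.identity()) == 0.0

    def test_single_pair_distance(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[0.0, 0.0, 2.0]])
        assert rmsd_value(a, b, RigidTransform.identity()) == pytest.approx(2.0)

    def test_two_pairs_closed_form(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [1.0, 2.0, 0]])
        assert rmsd_value(a, b, RigidTransform.identity()) == pytest.approx(np.sqrt(2.0))


class TestAtomMapping:
    def _map(self, ref, tgt, level):
        aln = global_align(ref.sequence, tgt.sequence)
        return build_atom_mapping(ref, tgt, aln, level)

    def test_identical_chains_heavy(self):
        c = make_sidechain_chain(4, seed=1)
        m = self._map(c, make_sidechain_chain(4, seed=1), "heavy")
        n_atoms = sum(len(r.atoms) for r in c.residues)
        assert len(m) == n_atoms

    def test_mismatched_types_share_backbone_only(self, two_residue_pdb):
        from oligosuper import read_pdb

        a = read_pdb(two_residue_pdb)  # Ala-Gly
        ref, tgt = a.chains[0], a.chains[0]
        aln = global_align(ref.sequence, tgt.sequence)
        m = build_atom_mapping(ref, tgt, aln, "heavy")
        assert len(m) == 9  # Ala 5 + Gly 4

    def test_ca_level_one_per_residue(self):
        p = make_protomer(5, seed=2)
        m = self._map(p, p, "ca")
        assert len(m) == 5
        assert all(pair.atom_name == "CA" for pair in m.pairs)


def _ca_mapping(ref_chain, tgt_chain):
    aln = global_align(ref_chain.sequence, tgt_chain.sequence)
    return build_atom_mapping(ref_chain, tgt_chain, aln, "ca")


class TestWeightedFit:
    def test_rigid_pair_matches_standard(self, rng):
        p = make_protomer(30, seed=4)
        moved = Assembly(chains=[p], id="m").transformed(
            rz(25.0), np.array([4.0, 0.0, -2.0])
        ).chains[0]
        m = _ca_mapping(p, moved)
        std = standard_fit(m)
        wtd = weighted_fit(m)
        assert wtd.rmsd == pytest.approx(std.rmsd, abs=1e-10)
        assert wtd.core_count == len(m)
        assert wtd.converged

    def test_hinge_fixture_finds_rigid_core(self):
        # domain swing large enough that every mobile atom beyond the
        # pivot leaves the 2 A core band
        p = make_protomer(50, seed=6)
        bent = apply_hinge(p, 30, 50, 100.0)  # 60% fixed, 40% hinged
        m = _ca_mapping(p, bent)
        std = standard_fit(m)
        wtd = weighted_fit(m)
        assert std.rmsd > 1.0
        assert wtd.core_rmsd < 0.1
        assert wtd.core_count >= 0.6 * len(m)
        # core is the fixed domain plus the stationary pivot residue
        core_idx = np.nonzero(wtd.deviations < 2.0)[0]
        assert np.all(core_idx <= 30)

    def test_moderate_hinge_core_excludes_far_domain(self):
        # a 30-degree bend: the core still covers the fixed domain and the
        # far part of the mobile domain is excluded, though atoms adjacent
        # to the pivot stay inside the 2 A band
        p = make_protomer(50, seed=6)
        bent = apply_hinge(p, 30, 50, 30.0)
        wtd = weighted_fit(_ca_mapping(p, bent))
        assert standard_fit(_ca_mapping(p, bent)).rmsd > 1.0
        assert wtd.core_count >= 0.6 * 50
        assert np.all(np.nonzero(wtd.deviations < 2.0)[0] <= 32)
        # fixed-domain atoms fit tightly despite the mobile domain
        assert np.sqrt(np.mean(wtd.deviations[:30] ** 2)) < 0.1

    def test_core_deviations_below_cutoff(self):
        p = make_protomer(40, seed=8)
        bent = apply_hinge(p, 25, 40, 45.0)
        wtd = weighted_fit(_ca_mapping(p, bent))
        assert np.all(wtd.deviations[wtd.deviations < 2.0] < 2.0)
        assert wtd.core_rmsd <= 2.0


class TestSymmetricRemap:
    def test_flipped_phe_ring_swapped_back(self):
        ref = make_sidechain_chain(6, seed=10)
        tgt = make_sidechain_chain(6, seed=10, flip_fraction=1.0)
        aln = global_align(ref.sequence, tgt.sequence)
        m = build_atom_mapping(ref, tgt, aln, "heavy")
        fit = standard_fit(m)
        remapped, n_swapped = remap_symmetric_sidechains(m, fit.transform)
        assert n_swapped > 0
        refit = standard_fit(remapped)
        assert refit.rmsd < 1e-8

    def test_consistent_labels_unchanged(self):
        ref = make_sidechain_chain(6, seed=11)
        tgt = make_sidechain_chain(6, seed=11)
        aln = global_align(ref.sequence, tgt.sequence)
        m = build_atom_mapping(ref, tgt, aln, "heavy")
        fit = standard_fit(m)
        remapped, n_swapped = remap_symmetric_sidechains(m, fit.transform)
        assert n_swapped == 0
        assert [p.tgt_atom.name for p in remapped.pairs] == [
            p.tgt_atom.name for p in m.pairs
        ]

    @pytest.mark.parametrize("seed", range(100))
    def test_remap_never_increases_squared_deviation(self, seed):
        ref = make_sidechain_chain(5, seed=seed)
        tgt = make_sidechain_chain(5, seed=seed, noise=0.4, flip_fraction=0.5)
        aln = global_align(ref.sequence, tgt.sequence)
        m = build_atom_mapping(ref, tgt, aln, "heavy")
        fit = standard_fit(m)
        R, T = m.coords()
        before = np.sum(deviations(R, T, fit.transform) ** 2)
        remapped, _ = remap_symmetric_sidechains(m, fit.transform)
        R2, T2 = remapped.coords()
        after = np.sum(deviations(R2, T2, fit.transform) ** 2)
        assert after <= before + 1e-9
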
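"""Torsion-profile metrics, geometry comparison, MD error statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mlpforge.benchmarks import (
    TorsionProfile,
    barrier_metrics,
    frame_force_magnitude,
    internal_coord_maes,
    kabsch_rmsd,
    profile_metrics,
    relative_energies,
    traj_error_stats,
)
from mlpforge.moltopo import Conformation, build_molecule
from mlpforge.oracle import (
    ForceFieldEvaluator,
    LabeledFrame,
    perturb_params,
)
from mlpforge.sampler import torsion_scan


def _profile(mol_id, energies, label="ml", angles=None):
    e = np.asarray(energies, dtype=float)
    return TorsionProfile(
        molecule_id=mol_id,
        dihedral=(0, 1, 2, 3),
        angles=angles if angles is not None else np.arange(len(e)) * 10.0,
        energies={label: e},
    )


class TestRelativeEnergies:
    def test_first_point_zeroes_first(self):
        out = relative_energies([5.0, 7.0, 4.0], "first_point")
        assert out[0] == 0.0
        assert np.allclose(out, [0, 2, -1])

    def test_minimum_convention(self):
        assert np.allclose(relative_energies([3, 1, 4], "minimum"), [2, 0, 3])

    def test_first_frame_alias(self):
        a = relative_energies([2.0, 3.0], "first_frame")
        b = relative_energies([2.0, 3.0], "first_point")
        assert np.array_equal(a, b)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            relative_energies([1.0], "median")


class TestProfileMetrics:
    def test_identical_sets_zero(self):
        ml = [_profile("m", [0, 1, 2], "ml")]
        ref = [_profile("m", [0, 1, 2], "ref")]
        mae, rmse = profile_metrics(ml, ref)
        assert mae == 0.0 and rmse == 0.0

    def test_hand_summation_example(self):
        """One molecule with relative-energy errors {0, 2}: MAE 1, RMSE sqrt(2)."""
        ml = [_profile("m", [0.0, 0.0], "ml", angles=np.array([0.0, 10.0]))]
        ref = [_profile("m", [0.0, 2.0], "ref", angles=np.array([0.0, 10.0]))]
        mae, rmse = profile_metrics(ml, ref)
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(2.0))

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=12)
        ml = [_profile("m", e, "ml")]
        ref = [_profile("m", e + 0.3 * rng.normal(size=12), "ref")]
        m1 = profile_metrics(ml, ref)
        ml_shift = [_profile("m", e + 57.0, "ml")]
        m2 = profile_metrics(ml_shift, ref)
        assert m1 == pytest.approx(m2)

    def test_molecule_nesting_not_pooled(self):
        """RMSE roots per molecule before averaging, exactly as written."""
        ml = [
            _profile("a", [0.0, 0.0, 0.0], "ml"),
            _profile("b", [0.0, 0.0, 0.0], "ml"),
        ]
        ref = [
            _profile("a", [0.0, 3.0, 3.0], "ref"),
            _profile("b", [0.0, 0.0, 0.0], "ref"),
        ]
        _, rmse = profile_metrics(ml, ref)
        expected = 0.5 * (np.sqrt((0 + 9 + 9) / 3) + 0.0)
        assert rmse == pytest.approx(expected)
        # a pooled RMSE over all bins would differ
        pooled = np.sqrt((0 + 9 + 9 + 0 + 0 + 0) / 6)
        assert rmse != pytest.approx(pooled)

    def test_grid_mismatch_names_molecule(self):
        ml = [_profile("badmol", [0, 1], "ml", angles=np.array([0.0, 10.0]))]
        ref = [_profile("badmol", [0, 1, 2], "ref")]
        with pytest.raises(ValueError, match="badmol"):
            profile_metrics(ml, ref)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_rmse_at_least_mae(self, seed):
        rng = np.random.default_rng(seed)
        n_mol = rng.integers(1, 5)
        n_bins = rng.integers(2, 20)
        angles = np.arange(n_bins) * (360.0 / n_bins)
        ml, ref = [], []
        for j in range(n_mol):
            e = rng.normal(size=n_bins)
            ml.append(_profile(f"m{j}", e, "ml", angles=angles))
            ref.append(_profile(f"m{j}", e + rng.normal(size=n_bins), "ref", angles=angles))
        mae, rmse = profile_metrics(ml, ref)
        assert rmse >= mae - 1e-12


class TestBarrierMetrics:
    def test_uniform_half_kcal_shift(self):
        ml = [_profile(f"m{j}", [0.0, 2.0 + j], "ml", angles=np.array([0.0, 10.0]))
              for j in range(3)]
        ref = [_profile(f"m{j}", [0.0, 2.5 + j], "ref", angles=np.array([0.0, 10.0]))
               for j in range(3)]
        rep = barrier_metrics(ml, ref)
        assert rep.maeb == pytest.approx(0.5)
        assert rep.nabh == 0

    def test_direct_count_and_mean(self):
        errors = [0.2, 1.2, 3.0]
        ml = [_profile(f"m{j}", [0.0, 1.0], "ml", angles=np.array([0.0, 10.0]))
              for j in range(3)]
        ref = [_profile(f"m{j}", [0.0, 1.0 + err], "ref", angles=np.array([0.0, 10.0]))
               for j, err in enumerate(errors)]
        rep = barrier_metrics(ml, ref)
        assert rep.maeb == pytest.approx(4.4 / 3)
        assert rep.nabh == 2

    def test_threshold_strictly_greater(self):
        ml = [_profile("m", [0.0, 1.0], "ml", angles=np.array([0.0, 10.0]))]
        ref = [_profile("m", [0.0, 2.0], "ref", angles=np.array([0.0, 10.0]))]
        assert barrier_metrics(ml, ref).nabh == 0  # error exactly 1.0
        ref2 = [_profile("m", [0.0, 2.0001], "ref", angles=np.array([0.0, 10.0]))]
        assert barrier_metrics(ml, ref2).nabh == 1

    def test_degraded_oracle_known_barrier_scaling(self, chain4, chain4_relaxed):
        """Scaling the only torsion term scales the scanned barrier by the
        same factor, so MAEB equals the barrier difference in closed form."""
        from dataclasses import replace

        cv = next(iter(chain4.params.dihedral))
        v2, n, gamma = chain4.params.dihedral[cv][0]
        scaled = replace(
            chain4.params, dihedral={cv: ((1.5 * v2, n, gamma),)}
        )
        ev_ref = ForceFieldEvaluator(chain4.molecule, chain4.params)
        ev_ml = ForceFieldEvaluator(chain4.molecule, scaled)
        p_ref, _ = torsion_scan(ev_ref, chain4.molecule, cv, 30.0,
                                conf0=chain4_relaxed, fmax_tol=1e-2,
                                method_label="ref")
        p_ml, _ = torsion_scan(ev_ml, chain4.molecule, cv, 30.0,
                               conf0=chain4_relaxed, fmax_tol=1e-2,
                               method_label="ml")
        rep = barrier_metrics([p_ml], [p_ref], label_ml="ml", label_ref="ref")
        assert rep.maeb == pytest.approx(0.5 * 2 * v2, rel=1e-3)


class TestKabschRMSD:
    def test_identical_zero(self):
        coords = np.random.default_rng(0).normal(size=(6, 3))
        assert kabsch_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_zero(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(8, 3))
        R = Rotation.random(random_state=3).as_matrix()
        moved = coords @ R.T + np.array([3.0, -1.0, 2.0])
        assert kabsch_rmsd(coords, moved) < 1e-8

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(5, 3))
        b = a + rng.normal(scale=0.2, size=(5, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-10)

    def test_matches_rotation_grid_search(self):
        """3-point planar sets: exhaustive in-plane rotation search oracle."""
        a = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]])
        b = np.array([[1.1, 0, 0], [-0.9, 0, 0], [0, 1.3, 0]])
        best = np.inf
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        for theta in np.linspace(0, 2 * np.pi, 200_000, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            best = min(best, np.sqrt(np.mean(np.sum((ac - bc @ R.T) ** 2, axis=1))))
        assert kabsch_rmsd(a, b) == pytest.approx(best, abs=1e-4)

    def test_mask_selects_subset(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[5] += 10.0  # only the unmasked atom differs
        mask = np.array([True] * 5 + [False])
        assert kabsch_rmsd(a, b, mask) < 1e-10
        with pytest.raises(ValueError):
            kabsch_rmsd(a, b, np.array([True] * 4))


class TestInternalCoordMaes:
    def test_identical_zero(self, chain4):
        c = chain4.start.coordinates
        rep = internal_coord_maes(chain4.molecule, c, c)
        assert rep.bond_mae == 0.0 and rep.angle_mae == 0.0 and rep.torsion_mae == 0.0

    def test_torsion_wrap_rule(self):
        """179 vs -179 degrees is a 2-degree difference, not 358."""
        mol = build_molecule(["C"] * 4, [(0, 1), (1, 2), (2, 3)])

        # atoms 1,2 on the x-axis; atoms 0 and 3 offset to set the dihedral
        def coords(phi_deg):
            phi = np.radians(phi_deg)
            a = np.array([1.5 + np.cos(np.radians(110.0)), np.sin(np.radians(110.0)), 0.0])
            d = np.array([
                -np.cos(np.radians(110.0)),
                np.sin(np.radians(110.0)) * np.cos(phi),
                np.sin(np.radians(110.0)) * np.sin(phi),
            ])
            return np.array([a, [1.5, 0, 0], [0, 0, 0], d])

        from mlpforge.moltopo import dihedral_angle

        ca, cb = coords(179.0), coords(-179.0)
        assert abs(dihedral_angle(ca, 0, 1, 2, 3)) == pytest.approx(179.0, abs=1e-6)
        assert abs(dihedral_angle(cb, 0, 1, 2, 3)) == pytest.approx(179.0, abs=1e-6)
        rep = internal_coord_maes(mol, ca, cb)
        assert rep.torsion_mae == pytest.approx(2.0, abs=1e-6)

    def test_hand_set_perturbations_enumerated(self, chain4):
        from mlpforge.moltopo import (
            bond_angle,
            bond_length,
            dihedral_angle,
            enumerate_internal_coords,
        )

        rng = np.random.default_rng(5)
        a = chain4.start.coordinates
        b = a + rng.normal(scale=0.05, size=a.shape)
        rep = internal_coord_maes(chain4.molecule, a, b)
        ic = enumerate_internal_coords(chain4.molecule)
        bond_d = [abs(bond_length(a, *t) - bond_length(b, *t)) for t in ic.bonds]
        ang_d = [abs(bond_angle(a, *t) - bond_angle(b, *t)) for t in ic.angles]
        tor_d = []
        for t in ic.dihedrals:
            da, db = dihedral_angle(a, *t), dihedral_angle(b, *t)
            diff = abs(da - db) % 360
            tor_d.append(min(diff, 360 - diff))
        assert rep.bond_mae == pytest.approx(np.mean(bond_d))
        assert rep.angle_mae == pytest.approx(np.mean(ang_d))
        assert rep.torsion_mae == pytest.approx(np.mean(tor_d))


class TestTrajErrorStats:
    def _frames(self, mol, energies, forces):
        coords = np.zeros((mol.n_atoms, 3))
        return [
            LabeledFrame(Conformation(mol, coords), e, f)
            for e, f in zip(energies, forces)
        ]

    def test_identical_sets_zero(self):
        mol = build_molecule(["C", "C"], [(0, 1)])
        rng = np.random.default_rng(0)
        f = [rng.normal(size=(2, 3)) for _ in range(4)]
        frames = self._frames(mol, [1.0, 2.0, 3.0, 4.0], f)
        rep = traj_error_stats(frames, frames)
        assert rep.energy_mae == 0.0 and rep.force_component_rmse == 0.0
        assert np.allclose(rep.force_magnitude_series, 0.0)

    def test_345_triangle_frame_magnitude(self):
        assert frame_force_magnitude(np.array([[3.0, 4.0, 0.0]])) == pytest.approx(5.0)

    def test_two_frame_hand_summation(self):
        mol = build_molecule(["C"], [])
        ref = self._frames(mol, [0.0, 1.0], [np.array([[1.0, 0, 0]]), np.array([[0.0, 2, 0]])])
        ml = self._frames(mol, [0.0, 1.5], [np.array([[0.0, 0, 0]]), np.array([[0.0, 0, 0]])])
        rep = traj_error_stats(ref, ml)
        # relative energies: ref [0,1], ml [0,1.5] -> de = [0, -0.5]
        assert rep.energy_mae == pytest.approx(0.25)
        assert rep.energy_rmse == pytest.approx(np.sqrt(0.125))
        comps = np.array([1, 0, 0, 0, 2, 0], dtype=float)
        assert rep.force_component_mae == pytest.approx(np.abs(comps).mean())
        assert rep.force_component_rmse == pytest.approx(np.sqrt((comps**2).mean()))
        assert np.allclose(rep.force_magnitude_series, [1.0, 2.0])
        assert rep.force_magnitude_mae == pytest.approx(1.5)
        assert rep.force_magnitude_rmse == pytest.approx(np.sqrt(2.5))

    def test_per_method_offset_cancels(self):
        mol = build_molecule(["C"], [])
        rng = np.random.default_rng(1)
        f = [rng.normal(size=(1, 3)) for _ in range(5)]
        e = list(rng.normal(size=5))
        ref = self._frames(mol, e, f)
        ml = self._frames(mol, [x + 100.0 for x in e], f)
        rep = traj_error_stats(ref, ml)
        assert rep.energy_mae == pytest.approx(0.0, abs=1e-12)

    def test_misaligned_rejected(self):
        mol = build_molecule(["C"], [])
        a = self._frames(mol, [0.0], [np.zeros((1, 3))])
        with pytest.raises(ValueError):
            traj_error_stats(a, [])

    def test_rmse_at_least_mae_on_oracle_comparator(self, chain4, chain4_relaxed):
        """Degraded-oracle comparator on real MD frames."""
        from mlpforge.sampler import SamplerConfig, run_md

        ev = ForceFieldEvaluator(chain4.molecule, chain4.params)
        degraded = ForceFieldEvaluator(
            chain4.molecule, perturb_params(chain4.params, 0.05, seed=3)
        )
        traj = run_md(ev, chain4.molecule, chain4_relaxed,
                      SamplerConfig(300, 0.5, 0.05, 500, seed=4, record_stride=25))
        ref, ml = [], []
        for conf in traj.conformations():
            e1, f1 = ev.energy_forces(conf.coordinates)
            e2, f2 = degraded.energy_forces(conf.coordinates)
            ref.append(LabeledFrame(conf, e1, f1))
            ml.append(LabeledFrame(conf, e2, f2, source="degraded-oracle"))
        rep = traj_error_stats(ref, ml)
        assert rep.energy_rmse >= rep.energy_mae
        assert rep.force_component_rmse >= rep.force_component_mae
        assert rep.force_magnitude_rmse >= rep.force_magnitude_mae
        assert rep.force_component_mae > 0.0
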
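import numpy as np
import pytest

from idrflex.membranemd import (
    KJ_PER_MOL_NM_TO_PN,
    ForceCurve,
    ForceCurvePoint,
    RestraintRecord,
    TrajectorySlice,
    axial_rmsf,
    effective_force_constant,
    force_constant_ratio,
    force_displacement_curve,
    read_frame_table,
    residue_membrane_contacts,
    restraint_forces,
)
from idrflex.synthetic import synth_contact_traj


def record(z_values, target=5.0, k=1000.0, rep=0, cond="c"):
    z = np.asarray(z_values, dtype=float)
    return RestraintRecord(
        target_height=target, force_constant=k,
        times=np.linspace(0, 1, len(z)), z=z, replicate_id=rep, condition=cond,
    )


class TestRestraintForces:
    def test_hookes_law_with_unit_conversion(self):
        r = record(np.full(200, 4.99))
        f, h = restraint_forces(r)
        assert f == pytest.approx(10.0 * KJ_PER_MOL_NM_TO_PN, rel=1e-9)  # 16.6 pN
        assert h == pytest.approx(4.99)

    def test_bead_at_target_zero_force(self):
        f, _ = restraint_forces(record(np.full(150, 5.0)))
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_fluctuations_average_to_zero(self):
        """Ornstein-Uhlenbeck-like symmetric motion about the target."""
        rng = np.random.default_rng(0)
        z = 5.0 + 0.05 * rng.standard_normal(20000)
        f, _ = restraint_forces(record(z))
        sem = 1000 * 0.05 * KJ_PER_MOL_NM_TO_PN / np.sqrt(20000)
        assert abs(f) < 4 * sem

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            restraint_forces(record(np.full(50, 5.0)))

    def test_equilibration_cut_applied(self):
        z = np.concatenate([np.full(100, 4.0), np.full(200, 5.0)])
        r = record(z)
        f, _ = restraint_forces(r, equilibration_cut=r.times[100])
        assert f == pytest.approx(0.0, abs=1e-12)


class TestForceCurve:
    def test_identical_replicates_zero_sem(self):
        recs = [record(np.full(200, 4.99), rep=i) for i in range(4)]
        curve = force_displacement_curve(recs)
        assert curve.points[0].sem_force == pytest.approx(0.0, abs=1e-12)

    def test_sem_matches_bessel_oracle(self):
        # replicate means 1, 2, 3, 4 pN -> mean 2.5, SEM = sd/sqrt(4)
        recs = [
            record(np.full(200, 5.0 - m / (1000 * KJ_PER_MOL_NM_TO_PN)), rep=i)
            for i, m in enumerate([1.0, 2.0, 3.0, 4.0])
        ]
        curve = force_displacement_curve(recs)
        p = curve.points[0]
        assert p.mean_force == pytest.approx(2.5, rel=1e-9)
        assert p.sem_force == pytest.approx(
            np.std([1, 2, 3, 4], ddof=1) / 2.0, rel=1e-9
        )
        assert p.sem_force == pytest.approx(0.6455, abs=2e-4)

    def test_single_replicate_sem_flagged_nan(self):
        curve = force_displacement_curve([record(np.full(200, 4.9))])
        assert np.isnan(curve.points[0].sem_force)
        assert curve.points[0].n_replicates == 1

    def test_planted_linear_law_reproduced_pointwise(self):
        recs = []
        for h in (5.0, 6.0, 7.0, 8.0, 9.0):
            F = 4.0 * h - 20.0  # pN
            z = h - F / (1000 * KJ_PER_MOL_NM_TO_PN)
            recs.extend(record(np.full(200, z), target=h, rep=i) for i in range(2))
        curve = force_displacement_curve(recs)
        for p in curve.points:
            assert p.mean_force == pytest.approx(4.0 * p.target_height - 20.0,
                                                 rel=1e-9)


class TestEffectiveForceConstant:
    def _line_curve(self, slope, intercept, heights, sem=0.1, cond="c"):
        return ForceCurve([
            ForceCurvePoint(cond, h, h, slope * h + intercept, sem, 4)
            for h in heights
        ])

    def test_exact_line(self):
        c = self._line_curve(4.0, -20.0, [7.0, 8.0, 9.0])
        slope, intercept, ci = effective_force_constant(c, 6.5)
        assert slope == pytest.approx(4.0)
        assert intercept == pytest.approx(-20.0)

    def test_planted_four_fold_ratio(self):
        a = self._line_curve(4.0, -20.0, [7.0, 8.0, 9.0], cond="a")
        b = self._line_curve(1.0, -2.0, [7.0, 8.0, 9.0], cond="b")
        assert force_constant_ratio(a, b, 6.5) == pytest.approx(4.0)

    def test_weighted_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        heights = np.array([6.6, 7.2, 8.0, 8.8, 9.5])
        sems = rng.uniform(0.05, 0.3, 5)
        forces = 3.0 * heights - 10.0 + rng.normal(scale=sems)
        curve = ForceCurve([
            ForceCurvePoint("c", h, h, f, s, 4)
            for h, f, s in zip(heights, forces, sems)
        ])
        slope, intercept, _ = effective_force_constant(curve, 6.5)
        w = 1.0 / sems**2
        A = np.vstack([heights, np.ones(5)]).T
        coef = np.linalg.solve(A.T @ (w[:, None] * A), A.T @ (w * forces))
        assert slope == pytest.approx(coef[0])
        assert intercept == pytest.approx(coef[1])

    def test_needs_two_points_beyond_min_height(self):
        c = self._line_curve(4.0, 0.0, [5.0, 9.0])
        with pytest.raises(ValueError):
            effective_force_constant(c, 6.5)

    def test_noisy_planted_slope_within_ci(self):
        rng = np.random.default_rng(2)
        heights = np.linspace(6.6, 9.4, 8)
        forces = 4.0 * heights - 20.0 + rng.normal(scale=0.05 * heights)
        curve = ForceCurve([
            ForceCurvePoint("c", h, h, f, 0.05 * h, 4)
            for h, f in zip(heights, forces)
        ])
        slope, _, ci = effective_force_constant(curve, 6.5)
        assert ci[0] <= 4.0 <= ci[1]


class TestContacts:
    def test_far_bead_never_contacts(self):
        traj, _ = synth_contact_traj(0.0, n_frames=50)
        out = residue_membrane_contacts(traj, cutoff=0.6)
        assert all(v == 0.0 for v in out.values())

    def test_planted_thirty_percent_fraction(self):
        traj, truth = synth_contact_traj(0.3, n_frames=100)
        out = residue_membrane_contacts(traj, cutoff=0.6, lipid_filter="PIP2")
        assert out[truth["contact_residue"]] == pytest.approx(0.3)

    def test_lipid_filter_matches_brute_force(self):
        rng = np.random.default_rng(3)
        T, nb, nl = 20, 4, 12
        coords = rng.uniform(0, 3, (T, nb, 3))
        lipids = rng.uniform(0, 3, (T, nl, 3))
        types = np.array(["PIP2", "POPC"] * 6)
        traj = TrajectorySlice(
            times=np.arange(T, dtype=float), coords=coords,
            bead_residues=np.arange(1, nb + 1),
            lipid_coords=lipids, lipid_types=types,
        )
        got = residue_membrane_contacts(traj, cutoff=1.0, lipid_filter="PIP2")
        for ri in range(nb):
            counts = []
            for t in range(T):
                c = 0
                for li in range(nl):
                    if types[li] != "PIP2":
                        continue
                    d = np.linalg.norm(coords[t, ri] - lipids[t, li])
                    if d <= 1.0:
                        c += 1
                counts.append(c)
            assert got[ri + 1] == pytest.approx(np.mean(counts))

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        traj = TrajectorySlice(
            times=np.arange(10, dtype=float),
            coords=rng.uniform(0, 2, (10, 3, 3)),
            bead_residues=np.array([1, 2, 3]),
            lipid_coords=rng.uniform(0, 2, (10, 8, 3)),
            lipid_types=np.array(["POPC"] * 8),
        )
        prev = None
        for cutoff in (0.3, 0.6, 1.2, 2.5):
            tot = sum(residue_membrane_contacts(traj, cutoff).values())
            if prev is not None:
                assert tot >= prev
            prev = tot

    def test_no_frames_after_cut_rejected(self):
        traj, _ = synth_contact_traj(0.5, n_frames=10)
        with pytest.raises(ValueError):
            residue_membrane_contacts(traj, equilibration_cut=1e9)


def four_subunit_traj(n_frames, extra):
    """Axis scaffold: residue 10 on chains A-D at fixed cross positions;
    extra beads appended as (chain, residue, (T,3) coords) tuples."""
    times = np.arange(n_frames, dtype=float)
    nb = 4 + len(extra)
    coords = np.zeros((n_frames, nb, 3))
    coords[:, 0] = [1, 0, 0]
    coords[:, 1] = [-1, 0, 0]
    coords[:, 2] = [0, 1, 0]
    coords[:, 3] = [0, -1, 0]
    chains = ["A", "C", "B", "D"]
    residues = [10, 10, 10, 10]
    for i, (ch, res, xyz) in enumerate(extra):
        coords[:, 4 + i] = xyz
        chains.append(ch)
        residues.append(res)
    return TrajectorySlice(
        times=times, coords=coords,
        bead_residues=np.array(residues), bead_chains=np.array(chains),
    )


AXIS_PAIRS = [(("A", 10), ("C", 10)), (("B", 10), ("D", 10))]


class TestAxialRmsf:
    def test_static_coordinates_zero_rmsf(self):
        traj = four_subunit_traj(50, [("A", 20, np.tile([0.3, 0.4, 1.0], (50, 1)))])
        out = axial_rmsf(traj, AXIS_PAIRS, align_selection=np.arange(4))
        assert np.allclose(out["mean"][list(out["residues"]).index(20)], 0.0)

    def test_sinusoid_amplitude_over_sqrt2(self):
        T, A = 2000, 0.7
        phase = 2 * np.pi * np.arange(T) / T
        xyz = np.column_stack([np.zeros(T), np.zeros(T), A * np.sin(phase)])
        traj = four_subunit_traj(T, [("A", 20, xyz)])
        out = axial_rmsf(traj, AXIS_PAIRS, align_selection=np.arange(4))
        got = out["mean"][list(out["residues"]).index(20)]
        assert got == pytest.approx(A / np.sqrt(2), rel=0.01)

    def test_perpendicular_motion_projects_to_zero(self):
        T = 200
        xyz = np.column_stack([
            0.5 * np.sin(np.arange(T)), np.zeros(T), np.zeros(T)
        ])
        traj = four_subunit_traj(T, [("A", 20, xyz)])
        out = axial_rmsf(traj, AXIS_PAIRS, align_selection=np.arange(4))
        assert out["mean"][list(out["residues"]).index(20)] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rigid_motion_invariance(self):
        T, A = 500, 0.4
        phase = 2 * np.pi * np.arange(T) / T
        xyz = np.column_stack([np.zeros(T), np.zeros(T), A * np.sin(phase)])
        traj = four_subunit_traj(T, [("A", 20, xyz)])
        ref = axial_rmsf(traj, AXIS_PAIRS, align_selection=np.arange(4))
        # rotate + translate every frame identically per frame index
        rng = np.random.default_rng(5)
        theta = rng.uniform(0, 2 * np.pi, T)
        shift = rng.uniform(-3, 3, (T, 3))
        coords = traj.coords.copy()
        for f in range(T):
            c, s = np.cos(theta[f]), np.sin(theta[f])
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            coords[f] = coords[f] @ R.T + shift[f]
        moved = TrajectorySlice(
            times=traj.times, coords=coords,
            bead_residues=traj.bead_residues, bead_chains=traj.bead_chains,
        )
        got = axial_rmsf(moved, AXIS_PAIRS, align_selection=np.arange(4))
        assert np.allclose(got["mean"], ref["mean"], atol=1e-8)

    def test_subunit_average_and_sem(self):
        T = 100
        phase = 2 * np.pi * np.arange(T) / T
        extras = []
        amps = [0.2, 0.4, 0.6, 0.8]
        for ch, A in zip("ABCD", amps):
            xyz = np.column_stack([np.zeros(T), np.zeros(T), A * np.sin(phase)])
            extras.append((ch, 20, xyz))
        traj = four_subunit_traj(T, extras)
        out = axial_rmsf(traj, AXIS_PAIRS, align_selection=np.arange(4))
        i20 = list(out["residues"]).index(20)
        per = np.array(amps) / np.sqrt(2)
        assert out["mean"][i20] == pytest.approx(per.mean(), rel=1e-6)
        assert out["sem"][i20] == pytest.approx(per.std(ddof=1) / 2.0, rel=1e-6)

    def test_degenerate_axis_frames_dropped(self):
        traj = four_subunit_traj(20, [])
        # collapse one axis pair onto the other in 5 frames
        traj.coords[:5, 2] = traj.coords[:5, 0]
        traj.coords[:5, 3] = traj.coords[:5, 1]
        out = axial_rmsf(traj, AXIS_PAIRS, align_selection=np.arange(4))
        assert out["n_frames_dropped"] == 5


def test_frame_table_roundtrip(tmp_path):
    import pandas as pd

    rows = []
    for t in (0.0, 1.0):
        for ch, res in (("A", 1), ("A", 2), ("B", 1)):
            rows.append(dict(time=t, chain=ch, residue=res, bead=0,
                             x=t + res, y=0.0, z=float(res)))
    pd.DataFrame(rows).to_csv(tmp_path / "frames.csv", index=False)
    traj = read_frame_table(tmp_path / "frames.csv")
    assert traj.coords.shape == (2, 3, 3)
    assert list(traj.bead_residues) == [1, 2, 1]
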
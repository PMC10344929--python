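import numpy as np
import pytest

from idrflex.chains import Conformer, Ensemble, conformer_metrics
from idrflex.saxs import (
    ScatteringProfile,
    chi2_reduced,
    cormap_test,
    debye_profile,
    guinier_fit,
    kratky_dimensionless,
    longest_run_pvalue,
    pr_transform,
    profile_from_pr,
    read_dat,
)

from conftest import sphere_pr, sphere_profile


def brute_force_longest_run_pvalue(longest: int, n: int) -> float:
    """Exhaustive enumeration over all 2^n sign sequences (oracle)."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    changes = np.diff(bits, axis=1) != 0
    # run lengths: longest stretch without a change
    max_run = np.ones(len(bits), dtype=int)
    run = np.ones(len(bits), dtype=int)
    for j in range(changes.shape[1]):
        run = np.where(changes[:, j], 1, run + 1)
        max_run = np.maximum(max_run, run)
    return float(np.mean(max_run >= longest))


class TestDebye:
    def test_single_bead_flat_unity(self):
        c = Conformer(residue_numbers=[1], coordinates=[[0.0, 0.0, 0.0]])
        q = np.linspace(0.1, 3, 30)
        assert np.allclose(debye_profile(c, q).I, 1.0)

    def test_two_beads_closed_form(self):
        r = 0.7
        c = Conformer(residue_numbers=[1, 2], coordinates=[[0, 0, 0], [r, 0, 0]])
        q = np.linspace(0.05, 4, 100)
        expect = 2.0 * (1.0 + np.sin(q * r) / (q * r))
        assert np.allclose(debye_profile(c, q).I, expect)

    def test_forward_intensity_at_origin_limit(self, coil_conformers):
        c = coil_conformers[0]
        q = np.array([1e-4])
        assert debye_profile(c, q).I[0] == pytest.approx(len(c) ** 2, rel=1e-6)

    def test_ensemble_profile_is_weight_average(self, coil_conformers):
        q = np.linspace(0.1, 2, 40)
        a, b = coil_conformers[:2]
        e = Ensemble([a, b], weights=[0.3, 0.7])
        expect = 0.3 * debye_profile(a, q).I + 0.7 * debye_profile(b, q).I
        assert np.allclose(debye_profile(e, q).I, expect)

    def test_guinier_limit_slope_matches_rg(self, coil_conformers):
        c = coil_conformers[1]
        rg = conformer_metrics(c)[0]
        q = np.linspace(0.01, 0.5 / rg, 50)
        prof = debye_profile(c, q)
        slope = np.polyfit(q**2, np.log(prof.I), 1)[0]
        assert np.sqrt(-3 * slope) == pytest.approx(rg, rel=0.02)


class TestGuinier:
    def test_exact_gaussian_profile_recovered(self):
        q = np.linspace(0.01, 1.0, 200)
        rg, i0 = 3.4, 100.0
        p = ScatteringProfile(q, i0 * np.exp(-(q**2) * rg**2 / 3.0))
        res = guinier_fit(p)
        assert res.Rg == pytest.approx(rg, rel=1e-9)
        assert res.I0 == pytest.approx(i0, rel=1e-9)
        assert res.fit_window[1] * res.Rg <= 1.3 + 1e-9

    def test_noisy_mean_within_two_percent(self):
        rng = np.random.default_rng(0)
        q = np.linspace(0.01, 1.0, 200)
        rg, i0 = 3.4, 100.0
        truth = i0 * np.exp(-(q**2) * rg**2 / 3.0)
        estimates = []
        for _ in range(50):
            sig = 0.01 * truth
            p = ScatteringProfile(q, truth + rng.normal(scale=sig), sig)
            estimates.append(guinier_fit(p).Rg)
        assert np.mean(estimates) == pytest.approx(rg, rel=0.02)

    def test_flat_profile_fails(self):
        q = np.linspace(0.01, 1.0, 50)
        with pytest.raises(ValueError):
            guinier_fit(ScatteringProfile(q, np.ones_like(q)))


class TestPrTransform:
    def test_sphere_recovers_analytic_distribution(self):
        R = 3.0
        q = np.linspace(0.05, 2.5, 120)
        prof = sphere_profile(R, q, I0=100.0)
        res = pr_transform(prof, (4.0, 9.0))
        assert res.Dmax == pytest.approx(2 * R, rel=0.05)
        assert res.Rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.05)
        pa = sphere_pr(R, res.r)
        pa *= np.trapezoid(res.p, res.r) / np.trapezoid(pa, res.r)
        assert np.linalg.norm(res.p - pa) / np.linalg.norm(pa) < 0.05

    def test_round_trip_within_regularization_tolerance(self):
        r = np.linspace(0, 6, 200)
        pr = r**2 * np.exp(-(((r - 2.5) / 1.2) ** 2))
        pr[-1] = 0.0
        prof = profile_from_pr(r, pr, np.linspace(0.05, 3, 150))
        res = pr_transform(prof, (4.5, 8.0))
        pa = np.interp(res.r, r, pr)
        pa *= np.trapezoid(res.p, res.r) / np.trapezoid(pa, res.r)
        assert np.linalg.norm(res.p - pa) / np.linalg.norm(pa) < 0.05

    def test_guinier_and_pr_rg_agree_on_sphere_and_coil(self, coil_conformers):
        # globular case
        q = np.linspace(0.05, 2.5, 120)
        prof = sphere_profile(3.0, q)
        g = guinier_fit(prof)
        res = pr_transform(prof, (4.0, 9.0))
        assert res.Rg == pytest.approx(g.Rg, rel=0.05)
        # coil case: ensemble-average profile of self-avoiding chains
        q = np.geomspace(0.02, 2.5, 160)
        e = Ensemble(coil_conformers)
        p0 = debye_profile(e, q)
        prof = ScatteringProfile(p0.q, p0.I, 0.01 * p0.I)
        g = guinier_fit(prof)
        res = pr_transform(prof, (3.0, 10.0))
        assert res.Rg == pytest.approx(g.Rg, rel=0.05)

    def test_requires_errors(self):
        q = np.linspace(0.05, 2, 50)
        with pytest.raises(ValueError):
            pr_transform(ScatteringProfile(q, np.exp(-(q**2))), (2, 8))

    def test_pr_moment_invariants(self):
        """Rg and I0 follow from the p(r) moments."""
        prof = sphere_profile(2.5, np.linspace(0.05, 2.5, 100), I0=40.0)
        res = pr_transform(prof, (3.5, 8.0))
        total = np.trapezoid(res.p, res.r)
        assert res.I0 == pytest.approx(4 * np.pi * total)
        assert res.Rg == pytest.approx(
            np.sqrt(np.trapezoid(res.r**2 * res.p, res.r) / (2 * total))
        )
        assert res.p[0] == pytest.approx(0.0, abs=1e-9)
        assert res.p[-1] == pytest.approx(0.0, abs=1e-9)


class TestKratky:
    def test_ordinate_vanishes_at_low_q(self):
        prof = sphere_profile(3.0, np.linspace(1e-3, 1.0, 50))
        x, y = kratky_dimensionless(prof, 3.0 * np.sqrt(3 / 5), 1.0)
        assert y[0] < 1e-4

    def test_sphere_peak_location_and_height(self):
        """Computed from the analytic sphere form factor: the
        dimensionless Kratky peak sits at qRg = 1.612 with height 1.027
        (close to the sqrt(3) ~ 1.1 globular landmark)."""
        R = 3.0
        rg = np.sqrt(3 / 5) * R
        q = np.linspace(0.01, 3.0, 2000)
        prof = sphere_profile(R, q)
        x, y = kratky_dimensionless(prof, rg, 1.0)
        pk = np.argmax(y[x < 3.0])
        assert x[pk] == pytest.approx(1.6124, abs=0.01)
        assert y[pk] == pytest.approx(1.0274, abs=0.005)
        assert x[pk] == pytest.approx(np.sqrt(3.0), rel=0.10)

    def test_gaussian_chain_plateau_near_two(self):
        rg = 3.4
        x = np.linspace(0.01, 8, 500)  # qRg
        u = x**2
        debye_fn = 2 * (np.exp(-u) + u - 1) / u**2
        _, y = kratky_dimensionless(ScatteringProfile(x / rg, debye_fn), rg, 1.0)
        assert y[-1] == pytest.approx(2.0, rel=0.03)
        assert np.all(np.diff(y[x > 2]) >= -1e-9)  # monotone approach


class TestChi2:
    def test_identical_profiles_zero(self):
        q = np.linspace(0.1, 2, 50)
        I = np.exp(-(q**2))
        m = ScatteringProfile(q, I)
        d = ScatteringProfile(q, I, 0.01 * I)
        assert chi2_reduced(m, d) == pytest.approx(0.0, abs=1e-20)

    def test_noise_only_distribution_centred_on_one(self):
        rng = np.random.default_rng(1)
        q = np.linspace(0.1, 3, 200)
        I = 100 * np.exp(-(q**2))
        chis = []
        for _ in range(100):
            sig = 0.05 * I
            d = ScatteringProfile(q, I + rng.normal(scale=sig), sig)
            chis.append(chi2_reduced(ScatteringProfile(q, I), d))
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)

    def test_doubled_sigma_quarters_chi2(self):
        rng = np.random.default_rng(2)
        q = np.linspace(0.1, 3, 100)
        I = np.exp(-(q**2))
        noisy = I + rng.normal(scale=0.05, size=len(q))
        d1 = ScatteringProfile(q, noisy, np.full(len(q), 0.05))
        d2 = ScatteringProfile(q, noisy, np.full(len(q), 0.10))
        m = ScatteringProfile(q, I)
        assert chi2_reduced(m, d1) == pytest.approx(4 * chi2_reduced(m, d2))

    def test_nonpositive_dof_rejected(self):
        q = np.linspace(0.1, 1, 3)
        d = ScatteringProfile(q, np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            chi2_reduced(ScatteringProfile(q, np.ones(3)), d, n_params=3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        q = np.linspace(0.1, 3, 80)
        I = np.exp(-(q**2))
        d = ScatteringProfile(q, I + rng.normal(scale=0.02, size=80),
                              np.full(80, 0.02))
        m = ScatteringProfile(q, I)
        assert chi2_reduced(m, d) == pytest.approx(
            chi2_reduced(m.scaled(7.3), d.scaled(123.0))
        )


class TestCorMap:
    def test_alternating_signs_give_p_one(self):
        q = np.linspace(0.1, 2, 100)
        I = np.ones(100)
        resid = 0.01 * (-1.0) ** np.arange(100)
        d = ScatteringProfile(q, I + resid, np.full(100, 0.01))
        out = cormap_test(ScatteringProfile(q, I), d)
        assert out.cormap_longest_run == 1
        assert out.cormap_p == 1.0

    @pytest.mark.parametrize("n", [5, 10, 14])
    def test_exact_pvalues_match_enumeration(self, n):
        for longest in range(1, n + 1):
            assert longest_run_pvalue(longest, n) == pytest.approx(
                brute_force_longest_run_pvalue(longest, n), abs=1e-12
            )

    def test_all_same_sign_is_vanishingly_unlikely(self):
        assert longest_run_pvalue(50, 50) < 1e-9

    def test_monotone_nonincreasing_in_longest_run(self):
        ps = [longest_run_pvalue(k, 80) for k in range(1, 81)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_all_zero_residuals_flagged(self):
        q = np.linspace(0.1, 2, 20)
        I = np.exp(-q)
        out = cormap_test(ScatteringProfile(q, I), ScatteringProfile(q, I, 0.1 * I))
        assert out.all_zero and out.cormap_p == 1.0

    def test_ties_inherit_previous_sign(self):
        q = np.linspace(0.1, 2, 12)
        I = np.ones(12)
        # zero-mean residuals keep the fitted scale at exactly 1, so the
        # planted zeros survive; sign sequence + + + + - + - + - + - -
        resid = np.array([0.2, 0.0, 0.0, 0.2, -0.2, 0.2, -0.2, 0.2, -0.2, 0.2,
                          -0.2, -0.2])
        assert resid.sum() == 0.0
        d = ScatteringProfile(q, I + resid)
        m = ScatteringProfile(q, I)
        out = cormap_test(m, d)
        assert out.cormap_longest_run == 4  # leading + run spans the zeros


def test_read_dat_with_header_and_angstrom_heuristic(tmp_path):
    path = tmp_path / "saxs.dat"
    path.write_text(
        "# sample: IDR-like\nq I err\n0.010 100.0 1.0\n0.050 80.0 0.9\n"
        "0.100 50.0 0.8\n0.200 20.0 0.5\n"
    )
    p = read_dat(path)  # q_max < 1 -> Angstrom^-1, converted
    assert p.q[0] == pytest.approx(0.10)
    assert p.sigma is not None
    p2 = read_dat(path, assume_nm=True)
    assert p2.q[0] == pytest.approx(0.01)
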
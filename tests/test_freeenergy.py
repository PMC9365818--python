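"""Estimator oracles: MBAR vs analytic/BAR, TI vs closed form, blocking
vs i.i.d. SEM, analytic restraint release vs numerical quadrature, and
the multi-pose Boltzmann combination against the published worked rows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from abfescreen.constants import Constants
from abfescreen.errors import ValidationError
from abfescreen.freeenergy import (
    analytic_release,
    analytic_release_translational,
    blocking_sigma,
    combine_poses,
    mbar_delta_g,
    mbar_solve,
    pose_free_energy,
    select_best_run,
    ti_integrate,
)
from abfescreen.models import (
    ComponentResult,
    PoseFreeEnergy,
    RestraintParams,
    RunResult,
    WindowSet,
)
from abfescreen.synthetic import HarmonicWindowConfig, simulate_harmonic_windows

C = Constants()
RT = C.RT


def two_state_harmonic(k1, k2, n, seed):
    """Exact Gaussian samples of two harmonic states (reduced units)."""
    rng = np.random.default_rng(seed)
    x = np.concatenate(
        [rng.normal(0, 1 / math.sqrt(k1), n), rng.normal(0, 1 / math.sqrt(k2), n)]
    )
    u = 0.5 * np.array([k1, k2])[:, None] * x[None, :] ** 2
    return WindowSet("sdr_lj", "MBAR", u=u, N_k=np.array([n, n]))


def bar_oracle(u, N_k):
    """Bennett acceptance ratio for two states, solved independently by
    root-finding on the implicit self-consistency equation."""
    n1, n2 = int(N_k[0]), int(N_k[1])
    w_f = u[1, :n1] - u[0, :n1]  # forward work from state-1 samples
    w_r = u[0, n1:] - u[1, n1:]  # reverse work from state-2 samples
    M = math.log(n1 / n2)

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))

    def g(df):
        return float(fermi(M + w_f - df).sum() - fermi(-M + w_r + df).sum())

    return brentq(g, -100, 100, xtol=1e-14)


class TestMbar:
    def test_single_state_gauge(self):
        ws = WindowSet("sdr_lj", "MBAR", u=np.zeros((1, 5)), N_k=np.array([5]))
        assert mbar_solve(ws).tolist() == [0.0]

    def test_identical_states_give_zero(self):
        rng = np.random.default_rng(0)
        row = rng.normal(1.0, 0.5, 200)
        ws = WindowSet(
            "sdr_lj", "MBAR", u=np.vstack([row, row]), N_k=np.array([100, 100])
        )
        f = mbar_solve(ws)
        assert abs(f[1] - f[0]) < 1e-10

    def test_harmonic_pair_recovers_analytic_within_3se(self):
        # Δf = ½ ln(k2/k1) = ln 2 for k1=1, k2=4; SE from independent replicates
        estimates = [
            mbar_solve(two_state_harmonic(1.0, 4.0, 5000, seed))[1]
            for seed in range(7, 18)
        ]
        target = 0.5 * math.log(4.0)
        se = float(np.std(estimates, ddof=1))
        assert abs(estimates[0] - target) < 3 * se

    def test_k2_reduces_to_bennett_acceptance_ratio(self):
        ws = two_state_harmonic(1.0, 4.0, 2000, seed=7)
        f = mbar_solve(ws)
        assert f[1] - f[0] == pytest.approx(bar_oracle(ws.u, ws.N_k), abs=1e-8)

    def test_multiwindow_harmonic_schedule(self):
        cfg = HarmonicWindowConfig(
            k_schedule=tuple(np.geomspace(1.0, 4.0, 11)), n_per_window=2000, seed=11
        )
        ws, dg_true = simulate_harmonic_windows(cfg)
        reps = [
            mbar_delta_g(simulate_harmonic_windows(
                HarmonicWindowConfig(
                    k_schedule=cfg.k_schedule, n_per_window=2000, seed=100 + i
                )
            )[0])
            for i in range(8)
        ]
        se = float(np.std(reps, ddof=1))
        assert abs(mbar_delta_g(ws) - dg_true) < 3 * max(se, 1e-6)

    def test_nan_in_reduced_potentials_rejected(self):
        u = np.zeros((2, 4))
        u[0, 0] = np.nan
        with pytest.raises(ValidationError):
            WindowSet("sdr_lj", "MBAR", u=u, N_k=np.array([2, 2]))


class TestTi:
    def test_constant_integrand(self):
        assert ti_integrate([0.0, 0.3, 1.0], [2.5, 2.5, 2.5]) == pytest.approx(2.5)

    def test_exact_for_linear_integrand(self):
        assert ti_integrate([0.0, 0.5, 1.0], [0.0, 0.5, 1.0]) == pytest.approx(0.5)

    def test_harmonic_interpolation_within_trapezoid_bound(self):
        # U(λ) = ½(k0 + λΔk)x² ⇒ ⟨dU/dλ⟩ = RT Δk / (2(k0 + λΔk))
        k0, k1 = 1.0, 4.0
        dk = k1 - k0
        lam = np.linspace(0.0, 1.0, 33)
        means = RT * dk / (2.0 * (k0 + lam * dk))
        exact = 0.5 * RT * math.log(k1 / k0)
        h = lam[1] - lam[0]
        max_f2 = RT * dk**3 / k0**3  # |f''| max at λ=0
        bound = h**2 * max_f2 / 12.0
        assert abs(ti_integrate(lam, means) - exact) <= bound

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            ti_integrate([0.5], [1.0])


class TestBlocking:
    def test_constant_series_zero(self):
        assert blocking_sigma(np.full(100, 3.2)) == 0.0

    def test_iid_normal_matches_sem(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10_000)
        sigma = blocking_sigma(x, n_blocks=5)
        sem = 1.0 / math.sqrt(10_000)
        assert 0.5 * sem < sigma < 2.0 * sem  # χ² spread of 5-block variance

    def test_autocorrelation_inflates_blocking_sigma(self):
        rng = np.random.default_rng(8)
        rho, n = 0.9, 50_000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + math.sqrt(1 - rho**2) * eps[t]
        naive = float(np.std(x, ddof=1)) / math.sqrt(n)
        assert blocking_sigma(x) > 2.0 * naive

    def test_remainder_dropped_from_tail(self):
        # length 12 with 5 blocks: only the first 10 samples enter
        x = np.arange(12, dtype=float)
        x_trunc = x[:10]
        assert blocking_sigma(x) == pytest.approx(blocking_sigma(x_trunc))

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            blocking_sigma([1.0, 2.0, 3.0], n_blocks=5)


def quadrature_release(r: RestraintParams, c: Constants) -> float:
    """Exact free energy of release via separable 1-D quadratures of the
    restrained configuration integral (full Jacobian r² sinθA sinθB)."""
    b = c.beta
    z_r = quad(lambda x: x * x * math.exp(-b * r.k_r * (x - r.r0) ** 2 / 2), 0, r.r0 + 25)[0]
    z_a = quad(
        lambda t: math.sin(t) * math.exp(-b * r.k_thA * (t - r.thetaA0) ** 2 / 2),
        0,
        math.pi,
    )[0]
    z_b = quad(
        lambda t: math.sin(t) * math.exp(-b * r.k_thB * (t - r.thetaB0) ** 2 / 2),
        0,
        math.pi,
    )[0]
    z_phi = 1.0
    for k in (r.k_phA, r.k_phB, r.k_phC):
        z_phi *= quad(lambda p, k=k: math.exp(-b * k * p * p / 2), -math.pi, math.pi)[0]
    z = z_r * z_a * z_b * z_phi
    return -c.RT * math.log(8 * math.pi**2 * c.V_std / z)


def uniform_restraints(k: float) -> RestraintParams:
    return RestraintParams(
        r0=5.0,
        thetaA0=math.pi / 2,
        thetaB0=math.pi / 2,
        k_r=k,
        k_thA=k,
        k_thB=k,
        k_phA=k,
        k_phB=k,
        k_phC=k,
    )


class TestAnalyticRelease:
    def test_zero_when_restrained_integral_equals_free_volume(self):
        # choose equal force constants so the closed-form argument is 1
        r0, s = 5.0, 1.0  # sin(π/2)
        k_star = (r0**2 * s * s * (2 * math.pi * RT) ** 3 / (8 * math.pi**2 * C.V_std)) ** (1 / 3)
        r = uniform_restraints(k_star)
        assert analytic_release(r, C) == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_within_stiff_error_bound(self):
        # stiff-approximation error is dominated by the sinθ Jacobi factor:
        # ΔG_exact − ΔG_stiff ≈ −RT·(σ²_θA + σ²_θB)/2 = −RT·RT/k at θ0=π/2
        for k in (10.0, 40.0, 100.0):
            r = uniform_restraints(k)
            dev = abs(analytic_release(r, C) - quadrature_release(r, C))
            bound = 2.0 * RT * RT / k  # safety factor 2 over the leading term
            assert dev < bound, f"k={k}: dev={dev:.4f} bound={bound:.4f}"

    def test_quadrature_agreement_tightens_with_stiffness(self):
        devs = [
            abs(analytic_release(uniform_restraints(k), C) - quadrature_release(uniform_restraints(k), C))
            for k in (10.0, 100.0)
        ]
        assert devs[1] < devs[0]
        assert devs[1] < 0.01

    def test_force_constant_scaling_is_exact(self):
        r1 = uniform_restraints(10.0)
        r4 = uniform_restraints(40.0)
        assert analytic_release(r4, C) - analytic_release(r1, C) == pytest.approx(
            -3.0 * RT * math.log(4.0), rel=1e-12
        )
        # direction confirmed against the numeric oracle
        assert quadrature_release(r4, C) < quadrature_release(r1, C)

    def test_singular_geometry_rejected(self):
        r = RestraintParams(
            r0=5.0, thetaA0=1e-9, thetaB0=math.pi / 2,
            k_r=10, k_thA=10, k_thB=10, k_phA=10, k_phB=10, k_phC=10,
        )
        with pytest.raises(ValidationError):
            analytic_release(r, C)

    def test_translational_release_closed_form(self):
        k = 10.0
        expected = -RT * math.log(C.V_std * (k / (2 * math.pi * RT)) ** 1.5)
        assert analytic_release_translational(k, C) == pytest.approx(expected, rel=1e-12)


class TestPoseFreeEnergy:
    def test_quadrature_sum(self):
        comps = [
            ComponentResult("attach_receptor_conf", 2.0, 0.1, "MBAR"),
            ComponentResult("sdr_charge", -5.0, 0.2, "MBAR"),
            ComponentResult("sdr_lj", 1.0, 0.2, "TI"),
        ]
        p = pose_free_energy(comps, "p1")
        assert p.dg == pytest.approx(-2.0)
        assert p.sigma == pytest.approx(0.3)

    def test_single_analytic_component_passthrough(self):
        comps = [ComponentResult("release_ligand_tr", -7.1, 0.0, "analytic")]
        p = pose_free_energy(comps)
        assert p.dg == -7.1 and p.sigma == 0.0

    def test_eight_randomized_components_match_elementwise_oracle(self):
        from abfescreen.models import CYCLE_COMPONENTS

        rng = np.random.default_rng(17)
        dgs = rng.normal(0, 5, 8)
        sigs = rng.uniform(0, 1, 8)
        comps = [
            ComponentResult(name, float(dgs[i]), float(sigs[i]), "MBAR")
            for i, name in enumerate(CYCLE_COMPONENTS)
        ]
        p = pose_free_energy(comps)
        assert p.dg == pytest.approx(sum(float(g) for g in dgs))
        assert p.sigma == pytest.approx(math.sqrt(sum(float(s) ** 2 for s in sigs)))

    def test_duplicate_component_rejected(self):
        comps = [
            ComponentResult("sdr_lj", 1.0, 0.1, "TI"),
            ComponentResult("sdr_lj", 2.0, 0.1, "TI"),
        ]
        with pytest.raises(ValidationError):
            pose_free_energy(comps)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pose_free_energy([])


def poses_from(dgs, sigmas=None):
    sigmas = sigmas or [0.0] * len(dgs)
    return [PoseFreeEnergy(f"p{i}", g, s) for i, (g, s) in enumerate(zip(dgs, sigmas))]


class TestCombinePoses:
    def test_published_row_chembl502289(self):
        res = combine_poses(poses_from([-22.2, 0.4, -9.0, -1.4, -22.2]), C)
        assert res.dg_overall == pytest.approx(-22.6, abs=0.05)

    def test_published_row_chembl1092788(self):
        res = combine_poses(poses_from([-4.9, -6.0, -5.8, -1.8, -4.8]), C)
        assert res.dg_overall == pytest.approx(-6.4, abs=0.05)

    def test_single_pose_passthrough(self):
        res = combine_poses(poses_from([-9.3], [0.7]), C)
        assert res.dg_overall == pytest.approx(-9.3)
        assert res.sigma_overall == pytest.approx(0.7)

    def test_two_identical_poses_shift_by_rt_ln2(self):
        res = combine_poses(poses_from([-8.0, -8.0]), C)
        assert res.dg_overall == pytest.approx(-8.0 - RT * math.log(2), rel=1e-12)

    def test_stable_for_extreme_magnitudes(self):
        res = combine_poses(poses_from([-1000.0, -999.0, 5.0]), C)
        assert math.isfinite(res.dg_overall)
        assert res.dg_overall <= -1000.0

    @given(
        st.lists(st.floats(-30, 10, allow_nan=False), min_size=1, max_size=10),
        st.floats(-30, 10, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=100)
    def test_adding_a_pose_never_hurts_and_usually_strictly_improves(self, dgs, extra):
        before = combine_poses(poses_from(dgs), C).dg_overall
        after = combine_poses(poses_from(dgs + [extra]), C).dg_overall
        assert after <= before
        # strict improvement whenever the new pose's Boltzmann factor is
        # representable next to the existing sum (≈ 36 RT dynamic range)
        if extra < min(dgs) + 15.0:
            assert after < before

    @given(st.lists(st.floats(-30, 10, allow_nan=False), min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=100)
    def test_bounded_by_best_pose_and_degeneracy(self, dgs):
        res = combine_poses(poses_from(dgs), C).dg_overall
        lo = min(dgs) - RT * math.log(len(dgs))
        assert lo - 1e-9 <= res <= min(dgs) + 1e-9

    def test_sigma_matches_monte_carlo_propagation(self):
        rng = np.random.default_rng(23)
        dgs = [-9.0, -8.4, -7.9, -8.8, -10.1]
        sigmas = [0.4, 0.5, 0.3, 0.45, 0.5]
        res = combine_poses(poses_from(dgs, sigmas), C)
        draws = rng.normal(dgs, sigmas, size=(100_000, 5))
        mc = -RT * np.log(np.exp(-np.asarray(draws) / RT).sum(axis=1))
        mc_sigma = float(np.std(mc, ddof=1))
        assert res.sigma_overall == pytest.approx(mc_sigma, rel=0.15)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            combine_poses([], C)
        with pytest.raises(ValidationError):
            PoseFreeEnergy("p", float("inf"), 0.0)


def run_of(dg, index=1):
    return RunResult(
        run_index=index,
        poses=[PoseFreeEnergy("p1", dg, 0.0)],
        dg_overall=dg,
        sigma_overall=0.0,
    )


class TestSelectBestRun:
    def test_published_extreme_pair(self):
        sel = select_best_run(run_of(-19.8, 1), run_of(-10.9, 2))
        assert sel.chosen_dg == -19.8
        assert sel.diff == pytest.approx(8.9)

    def test_identical_runs_zero_diff(self):
        sel = select_best_run(run_of(-18.1, 1), run_of(-18.1, 2))
        assert sel.diff == 0.0

    def test_tie_goes_to_run_one(self):
        r1, r2 = run_of(-5.0, 1), run_of(-5.0, 2)
        assert select_best_run(r1, r2).run_more is r1

    def test_missing_run_rejected(self):
        with pytest.raises(ValidationError):
            select_best_run(run_of(-5.0), None)


class TestFullCycle:
    def test_harmonic_site_binding_free_energy(self):
        """Composed path (restrain by MBAR → decouple site by MBAR →
        analytic translational release) vs the exactly integrable
        standard binding free energy of a 3-D harmonic site."""
        k_site, k_rest = 2.0, 20.0  # kcal/(mol Å²)

        def cycle(seed):
            # reduced spring constants κ = k/RT; samples are exact Gaussians
            leg1 = HarmonicWindowConfig(
                k_schedule=tuple(np.linspace(k_site, k_site + k_rest, 12) / RT),
                n_per_window=1500, ndim=3, seed=seed,
            )
            leg2 = HarmonicWindowConfig(
                k_schedule=tuple(np.linspace(k_site + k_rest, k_rest, 12) / RT),
                n_per_window=1500, ndim=3, seed=seed + 5000,
            )
            dg1 = mbar_delta_g(simulate_harmonic_windows(leg1)[0], C)
            dg2 = mbar_delta_g(simulate_harmonic_windows(leg2)[0], C)
            dg3 = analytic_release_translational(k_rest, C)
            return -(dg1 + dg2 + dg3)

        exact = -RT * math.log((2 * math.pi * RT / k_site) ** 1.5 / C.V_std)
        reps = [cycle(seed) for seed in range(31, 39)]
        se = float(np.std(reps, ddof=1))
        assert abs(reps[0] - exact) < 3 * max(se, 1e-6)
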
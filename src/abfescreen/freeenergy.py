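"""Free-energy estimation primitives and the per-compound aggregation chain.

The chain mirrors one ABFE calculation of the screening workflow:

1. each thermodynamic-cycle component is estimated from its alchemical
   windows by MBAR or thermodynamic integration (the release of the
   ligand translational/rotational restraints is analytic);
2. component free energies sum to the pose ABFE, with blocking-analysis
   uncertainties added in quadrature;
3. the pose ABFEs of a run combine into the compound's overall binding
   free energy by a Boltzmann sum,

       ΔG°_overall = −RT ln Σᵢ exp(−β ΔG°ᵢ),

   with first-order (linearized) uncertainty propagation through the
   Boltzmann weights;
4. of the two independent runs, the more favorable overall value is kept.
"""

from __future__ import annotations

import math
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import Constants, DEFAULT
from .errors import ConvergenceError, ValidationError
from .models import (
    ComponentResult,
    PoseFreeEnergy,
    RestraintParams,
    RunResult,
    WindowSet,
)

__all__ = [
    "mbar_solve",
    "mbar_delta_g",
    "ti_integrate",
    "blocking_sigma",
    "analytic_release",
    "analytic_release_translational",
    "pose_free_energy",
    "combine_poses",
    "make_run_result",
    "select_best_run",
]


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _mbar_objective(f_free: np.ndarray, u: np.ndarray, N_k: np.ndarray):
    """Convex MBAR objective and gradient in the K−1 free parameters
    (f_1 is gauge-fixed to 0)."""
    K, N = u.shape
    f = np.concatenate(([0.0], f_free))
    logN_k = np.log(N_k)
    # log denom_n = logsumexp_k (ln N_k + f_k − u_kn)
    log_denom = logsumexp(logN_k[:, None] + f[:, None] - u, axis=0)
    obj = log_denom.sum() - float(N_k @ f)
    # ∂obj/∂f_k = N_k (Σ_n W_kn − 1), W_kn = exp(f_k − u_kn − log denom_n)
    w_sum = np.exp(f[:, None] - u - log_denom[None, :]).sum(axis=1)
    grad = N_k * (w_sum - 1.0)
    return obj, grad[1:]


def mbar_solve(
    w: WindowSet,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> np.ndarray:
    """Dimensionless per-state free energies from a reduced-potential matrix.

    Solves the multistate reweighting (MBAR) self-consistency equations

        f_k = −ln Σ_n exp(−u_kn) / Σ_j N_j exp(f_j − u_jn)

    by minimizing the equivalent convex objective (quasi-Newton), then
    polishing with self-consistent iteration until the per-iteration
    update is below ``tol`` in max |Δf|.  Gauge: f_1 = 0.

    Returns the array ``f`` of shape (K,); the endpoint free-energy
    difference in kcal/mol is ``RT * (f[-1] - f[0])``.
    """
    if w.method != "MBAR":
        raise ValidationError("mbar_solve requires an MBAR WindowSet")
    u = w.u
    N_k = w.N_k.astype(float)
    K = u.shape[0]
    if K == 1:
        return np.zeros(1)

    res = minimize(
        _mbar_objective,
        x0=np.zeros(K - 1),
        args=(u, N_k),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
    )
    f = np.concatenate(([0.0], res.x))

    logN_k = np.log(N_k)
    for _ in range(max_iter):
        log_denom = logsumexp(logN_k[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            return f

    # Convergence failure: report per-neighbor overlap diagnostics.
    log_denom = logsumexp(logN_k[:, None] + f[:, None] - u, axis=0)
    W = np.exp(f[:, None] - u - log_denom[None, :])  # weight of sample n in state k
    ess = 1.0 / np.maximum((W**2).sum(axis=1), 1e-300)
    raise ConvergenceError(
        f"MBAR did not converge to {tol} in {max_iter} iterations "
        f"(last update {delta:.3e}); near-zero effective sample sizes "
        "indicate non-overlapping states",
        diagnostics={"f": f.tolist(), "ess_per_state": ess.tolist(), "last_delta": delta},
    )


def mbar_delta_g(w: WindowSet, constants: Constants = DEFAULT) -> float:
    """Endpoint free-energy difference (kcal/mol) of an MBAR window set."""
    f = mbar_solve(w)
    return constants.RT * float(f[-1] - f[0])


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------

def ti_integrate(lambdas: Sequence[float], mean_dudl: Sequence[float]) -> float:
    """Trapezoidal quadrature of ⟨∂U/∂λ⟩ over the λ grid (kcal/mol).

    The grid must be strictly increasing with at least two points; no
    spline smoothing is applied, so the estimate is exact for integrands
    linear in λ between grid points.
    """
    lam = np.asarray(lambdas, dtype=float)
    du = np.asarray(mean_dudl, dtype=float)
    if lam.size < 2:
        raise ValidationError("TI requires at least 2 λ points")
    if lam.shape != du.shape:
        raise ValidationError("lambdas and mean_dudl must have equal length")
    if np.any(np.diff(lam) <= 0):
        raise ValidationError("lambdas must be strictly increasing")
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(du))):
        raise ValidationError("TI inputs must be finite")
    return float(np.trapezoid(du, lam))


def ti_delta_g(w: WindowSet) -> float:
    """TI estimate (kcal/mol) from a TI WindowSet's per-λ series means."""
    if w.method != "TI":
        raise ValidationError("ti_delta_g requires a TI WindowSet")
    means = [float(np.mean(s)) for s in w.dudl_series]
    return ti_integrate(w.lambdas, means)


# ---------------------------------------------------------------------------
# Blocking analysis
# ---------------------------------------------------------------------------

def blocking_sigma(
    series: Sequence[float],
    n_blocks: int = 5,
    estimator: Callable[[np.ndarray], float] = np.mean,
) -> float:
    """Blocking-analysis uncertainty of an estimator over a time series.

    The series is split into ``n_blocks`` contiguous equal blocks (any
    remainder is dropped from the end), the estimator is applied per
    block, and the returned σ is the standard deviation of the block
    estimates (ddof=1) divided by √n_blocks.  Contiguous blocks make the
    estimate robust to the autocorrelation of MD time series, which a
    naive σ/√n would underestimate.
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValidationError("n_blocks must be at least 2")
    if x.size < n_blocks:
        raise ValidationError(
            f"series of length {x.size} cannot form {n_blocks} blocks"
        )
    block = x.size // n_blocks
    trimmed = x[: block * n_blocks].reshape(n_blocks, block)
    estimates = np.array([float(estimator(b)) for b in trimmed])
    return float(np.std(estimates, ddof=1) / math.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# Analytic restraint release
# ---------------------------------------------------------------------------

def analytic_release(r: RestraintParams, c: Constants = DEFAULT) -> float:
    """Free energy (kcal/mol) of releasing the six harmonic anchor
    restraints (one distance, two angles, three dihedrals) on a bound
    ligand into the standard-state volume and free orientation.

    Stiff-restraint closed form:

        ΔG = −RT ln[ 8π² V° √(k_r k_θA k_θB k_φA k_φB k_φC)
                      / (r0² sinθA0 sinθB0 (2πRT)³) ]

    The approximation replaces the Jacobian factors r² sinθA sinθB by
    their values at the restraint minima; its relative error is O(RT/k)
    per coordinate, negligible for stiff production restraints.
    """
    sinA, sinB = math.sin(r.thetaA0), math.sin(r.thetaB0)
    if min(sinA, sinB) < 1e-6:
        raise ValidationError(
            "restraint reference angle too close to 0 or π (singular geometry)"
        )
    RT = c.RT
    prod_k = math.prod(r.force_constants)
    arg = (
        8.0
        * math.pi**2
        * c.V_std
        * math.sqrt(prod_k)
        / (r.r0**2 * sinA * sinB * (2.0 * math.pi * RT) ** 3)
    )
    return -RT * math.log(arg)


def analytic_release_translational(k: float, c: Constants = DEFAULT) -> float:
    """Free energy (kcal/mol) of releasing a single 3-D isotropic harmonic
    translational restraint (spring constant ``k``, kcal/(mol Å²)) into the
    standard-state volume: ΔG = −RT ln[ V° (k / 2πRT)^{3/2} ]."""
    if not k > 0:
        raise ValidationError("spring constant must be positive")
    RT = c.RT
    return -RT * math.log(c.V_std * (k / (2.0 * math.pi * RT)) ** 1.5)


# ---------------------------------------------------------------------------
# Aggregation chain
# ---------------------------------------------------------------------------

def pose_free_energy(
    components: Sequence[ComponentResult], pose_id: str = ""
) -> PoseFreeEnergy:
    """Sum the cycle components of one pose: ΔG = Σ ΔGᵢ, σ = √(Σ σᵢ²)."""
    if not components:
        raise ValidationError("pose has no components")
    names = [comp.component_name for comp in components]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate component(s): {dupes}")
    dg = float(sum(comp.dg for comp in components))
    sigma = float(math.sqrt(sum(comp.sigma**2 for comp in components)))
    return PoseFreeEnergy(
        pose_id=pose_id, dg=dg, sigma=sigma, components=list(components)
    )


class CombinedResult(NamedTuple):
    dg_overall: float
    sigma_overall: float
    weights: np.ndarray  # Boltzmann weight of each pose


def combine_poses(
    poses: Sequence[PoseFreeEnergy], c: Constants = DEFAULT
) -> CombinedResult:
    """Boltzmann-combine per-pose ABFEs into the compound's overall value.

        ΔG°_overall = −RT ln Σᵢ exp(−β ΔG°ᵢ)

    The pose with the most favorable ΔG dominates the sum.  Uncertainty
    is propagated to first order: σ² = Σᵢ wᵢ² σᵢ² with Boltzmann weights
    wᵢ = exp(−β ΔGᵢ)/Σⱼ exp(−β ΔGⱼ) (wᵢ = ∂ΔG_overall/∂ΔGᵢ).  Computed
    with log-sum-exp, stable for |ΔG| up to ~10³ kcal/mol.
    """
    if not poses:
        raise ValidationError("combine_poses requires at least one pose")
    dg = np.array([p.dg for p in poses], dtype=float)
    sig = np.array([p.sigma for p in poses], dtype=float)
    if not np.all(np.isfinite(dg)):
        raise ValidationError("pose free energies must be finite")
    beta = c.beta
    a = -beta * dg
    lse = float(logsumexp(a))
    weights = np.exp(a - lse)
    dg_overall = -c.RT * lse
    sigma_overall = float(np.sqrt(np.sum(weights**2 * sig**2)))
    return CombinedResult(dg_overall, sigma_overall, weights)


def make_run_result(
    run_index: int, poses: Sequence[PoseFreeEnergy], c: Constants = DEFAULT
) -> RunResult:
    """Package one run's poses with their Boltzmann-combined overall ΔG."""
    combined = combine_poses(poses, c)
    return RunResult(
        run_index=run_index,
        poses=list(poses),
        dg_overall=combined.dg_overall,
        sigma_overall=combined.sigma_overall,
    )


class BestRunSelection(NamedTuple):
    run_more: RunResult  # the more favorable run
    run_less: RunResult
    chosen_dg: float
    diff: float


def select_best_run(run1: RunResult, run2: RunResult) -> BestRunSelection:
    """Keep the more favorable of two independent runs (ties go to run 1).

    The rationale: the tighter-binding post-equilibration conformation is
    the more stable, hence presumably the more realistic one.  ``diff``
    records the run-to-run spread |ΔG₁ − ΔG₂|.
    """
    if run1 is None or run2 is None:
        raise ValidationError("both runs are required")
    diff = abs(run1.dg_overall - run2.dg_overall)
    if run1.dg_overall <= run2.dg_overall:
        return BestRunSelection(run1, run2, run1.dg_overall, diff)
    return BestRunSelection(run2, run1, run2.dg_overall, diff)
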
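"""Seeded generators emulating the statistical structure of a screen.

These generators stand in for the expensive upstream machinery (docking
engine, MD, alchemical sampling) so every pipeline stage is testable:

* class-shifted docking-score distributions for actives and decoys;
* per-pose ABFE observations with an exponential pose-quality penalty,
  run-level equilibration drift (0–9 kcal/mol), blocking-scale noise
  (0.5–3 kcal/mol), and Bernoulli pose-stability flags;
* exact Gaussian samples from λ-interpolated harmonic states, for which
  the free energy is known in closed form;
* geometric point-cloud poses for the diversity/stability rules.

All generators are bit-reproducible under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import Constants, DEFAULT
from .errors import ValidationError
from .models import (
    CompoundRecord,
    PoseCoordinates,
    PoseFreeEnergy,
    ScreenTable,
    WindowSet,
)

#: Free-energy equivalent of the 1 μM activity cutoff at 298 K:
#: RT ln(1e-6) ≈ −8.18 kcal/mol.  Actives are at least this favorable.
DG_1UM = DEFAULT.RT * np.log(1e-6)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of a simulated screen.

    Docking scores are class-conditional normals (actives shifted toward
    better scores); the true binding free energy of each compound is
    uniform over its class range.  Default active range ends at the 1 μM
    equivalent (≈ −8.2 kcal/mol); the decoy range overlaps nothing of it
    but sits 4 kcal/mol less favorable on average, while the docking
    class separation is half a score standard deviation — weakly
    informative docking over a strong underlying affinity signal.
    """

    n_active: int = 15
    n_decoy: int = 15
    dock_mu_active: float = -9.0
    dock_mu_decoy: float = -8.5
    dock_sigma: float = 1.0
    dg_active_range: tuple[float, float] = (-12.18, -8.18)
    dg_decoy_range: tuple[float, float] = (-8.18, -4.18)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_decoy < 0:
            raise ValidationError("counts must be non-negative")
        if not self.dock_mu_active < self.dock_mu_decoy:
            raise ValidationError("actives must dock better on average")
        if not self.dock_sigma > 0:
            raise ValidationError("dock_sigma must be positive")
        for name in ("dg_active_range", "dg_decoy_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValidationError(f"{name} must be ordered")


def simulate_screen(cfg: ScreenSimConfig) -> tuple[ScreenTable, dict[str, float]]:
    """Draw a labeled screening table plus the latent true ΔG per compound."""
    rng = np.random.default_rng(cfg.seed)
    rows: list[CompoundRecord] = []
    truth: dict[str, float] = {}
    for label, n, mu, dg_range, prefix in (
        ("active", cfg.n_active, cfg.dock_mu_active, cfg.dg_active_range, "A"),
        ("decoy", cfg.n_decoy, cfg.dock_mu_decoy, cfg.dg_decoy_range, "D"),
    ):
        scores = rng.normal(mu, cfg.dock_sigma, size=n)
        dgs = rng.uniform(dg_range[0], dg_range[1], size=n)
        for i in range(n):
            cid = f"{prefix}{i:05d}"
            rows.append(
                CompoundRecord(
                    compound_id=cid, label=label, final_score=float(scores[i])
                )
            )
            truth[cid] = float(dgs[i])
    return ScreenTable(rows=rows, provenance="simulated screen"), truth


@dataclass(frozen=True)
class AbfeObsConfig:
    """Noise model of the simulated ABFE observations.

    ``pose_penalty_scale`` is the mean of the exponential pose-quality
    penalty (worse poses bind less favorably; the best of several poses
    has penalty near zero).  ``drift_prob``/``drift_range`` model
    equilibration drift: with that probability a run's MD equilibration
    relaxes the ligand away from its docked pose and every pose of that
    run inherits a shared uniform penalty — the mechanism behind
    run-to-run differences of up to ~9 kcal/mol.  ``sigma_block_range``
    spans the blocking uncertainties of production runs (0.5–3 kcal/mol);
    each pose's observed ΔG gets Normal(0, σ) noise of its own σ.
    """

    n_poses: int = 10
    pose_penalty_scale: float = 2.0
    drift_prob: float = 0.3
    drift_range: tuple[float, float] = (0.0, 9.0)
    sigma_block_range: tuple[float, float] = (0.5, 3.0)
    stable_prob: float = 0.9
    n_runs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1 or self.n_runs < 1:
            raise ValidationError("n_poses and n_runs must be >= 1")
        for name in ("drift_prob", "stable_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.pose_penalty_scale < 0:
            raise ValidationError("pose_penalty_scale must be non-negative")
        for name in ("drift_range", "sigma_block_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValidationError(f"{name} must be non-negative and ordered")


@dataclass
class SimulatedRun:
    """One simulated ABFE run: per-pose observations and stability flags."""

    poses: list[PoseFreeEnergy]
    stable: list[bool]
    drifted: bool


def simulate_abfe_observations(
    truth: dict[str, float], cfg: AbfeObsConfig
) -> dict[str, list[SimulatedRun]]:
    """Per-compound, per-run pose observations around the true ΔG."""
    if not truth:
        raise ValidationError("truth map is empty")
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, list[SimulatedRun]] = {}
    for cid in truth:
        dg_true = truth[cid]
        runs: list[SimulatedRun] = []
        for r in range(cfg.n_runs):
            if cfg.pose_penalty_scale > 0:
                penalties = rng.exponential(cfg.pose_penalty_scale, size=cfg.n_poses)
            else:
                penalties = np.zeros(cfg.n_poses)
            drifted = bool(rng.random() < cfg.drift_prob)
            drift = (
                float(rng.uniform(*cfg.drift_range)) if drifted else 0.0
            )
            lo, hi = cfg.sigma_block_range
            sigmas = rng.uniform(lo, hi, size=cfg.n_poses) if hi > 0 else np.zeros(cfg.n_poses)
            noise = np.where(sigmas > 0, rng.normal(0.0, 1.0, size=cfg.n_poses) * sigmas, 0.0)
            dgs = dg_true + penalties + drift + noise
            stable = rng.random(cfg.n_poses) < cfg.stable_prob
            poses = [
                PoseFreeEnergy(
                    pose_id=f"{cid}/r{r + 1}/p{i + 1}",
                    dg=float(dgs[i]),
                    sigma=float(sigmas[i]),
                )
                for i in range(cfg.n_poses)
            ]
            runs.append(SimulatedRun(poses=poses, stable=stable.tolist(), drifted=drifted))
        out[cid] = runs
    return out


@dataclass(frozen=True)
class HarmonicWindowConfig:
    """λ-schedule of harmonic states with exactly sampleable distributions.

    State k has reduced potential u_k(x) = ½ κ_k |x|² (κ in units of
    1/[x]², energies in RT), so its samples are Gaussian with variance
    1/κ_k per dimension and the free-energy difference between states is
    known exactly: Δf = (d/2) ln(κ_K/κ_1).  With ``correlation_rho`` > 0
    each window's series is a stationary AR(1) chain — same marginal,
    autocorrelated in time — for exercising blocking analysis.
    """

    k_schedule: tuple[float, ...]
    n_per_window: int = 2000
    correlation_rho: float = 0.0
    ndim: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.k_schedule) < 2:
            raise ValidationError("need at least 2 windows")
        if any(k <= 0 for k in self.k_schedule):
            raise ValidationError("spring constants must be positive")
        if not 0.0 <= self.correlation_rho < 1.0:
            raise ValidationError("correlation_rho must lie in [0, 1)")
        if self.n_per_window < 1 or self.ndim < 1:
            raise ValidationError("n_per_window and ndim must be >= 1")

    @property
    def K(self) -> int:
        return len(self.k_schedule)


def _ar1(rng: np.random.Generator, n: int, ndim: int, rho: float) -> np.ndarray:
    """Stationary AR(1) chain with standard-normal marginals, shape (n, ndim)."""
    eps = rng.standard_normal((n, ndim))
    if rho == 0.0:
        return eps
    x = np.empty_like(eps)
    x[0] = eps[0]
    c = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + c * eps[t]
    return x


def simulate_harmonic_windows(
    cfg: HarmonicWindowConfig,
    component_name: str = "sdr_lj",
    constants: Constants = DEFAULT,
) -> tuple[WindowSet, float]:
    """Exact samples from each harmonic window plus the analytic ΔG.

    Returns a complete MBAR reduced-potential matrix (every sample
    evaluated in every state) and the closed-form endpoint free energy
    in kcal/mol: (d/2) RT ln(κ_K/κ_1).
    """
    rng = np.random.default_rng(cfg.seed)
    ks = np.asarray(cfg.k_schedule, dtype=float)
    samples = []
    for k in ks:
        z = _ar1(rng, cfg.n_per_window, cfg.ndim, cfg.correlation_rho)
        samples.append(z / np.sqrt(k))  # variance 1/k per dimension
    x = np.concatenate(samples, axis=0)  # (N_tot, ndim)
    sq = np.sum(x * x, axis=1)  # |x|² per sample
    u = 0.5 * ks[:, None] * sq[None, :]
    N_k = np.full(cfg.K, cfg.n_per_window, dtype=int)
    ws = WindowSet(component_name=component_name, method="MBAR", u=u, N_k=N_k)
    dg_analytic = constants.RT * 0.5 * cfg.ndim * float(np.log(ks[-1] / ks[0]))
    return ws, dg_analytic


def harmonic_ti_windows(
    cfg: HarmonicWindowConfig,
    component_name: str = "sdr_lj",
    constants: Constants = DEFAULT,
) -> tuple[WindowSet, float]:
    """TI window set for the λ-interpolated harmonic spring.

    Interprets the schedule as U(λ_j) = ½ k_j x² (kcal/mol) on a uniform
    λ grid and emits per-λ dU/dλ = (dk/dλ)·x²/2 series from exact
    samples at each window (x ~ N(0, RT/k_j)).  The analytic endpoint
    value is (RT/2) ln(k_K/k_1) per dimension.
    """
    rng = np.random.default_rng(cfg.seed)
    ks = np.asarray(cfg.k_schedule, dtype=float)
    K = cfg.K
    lambdas = np.linspace(0.0, 1.0, K)
    # d k / d λ on the uniform grid via finite differences of the schedule
    dk_dlam = np.gradient(ks, lambdas)
    series = []
    RT = constants.RT
    for j, k in enumerate(ks):
        z = _ar1(rng, cfg.n_per_window, cfg.ndim, cfg.correlation_rho)
        x = z * np.sqrt(RT / k)
        series.append(0.5 * dk_dlam[j] * np.sum(x * x, axis=1))
    ws = WindowSet(
        component_name=component_name, method="TI", lambdas=lambdas, dudl_series=series
    )
    dg_analytic = RT * 0.5 * cfg.ndim * float(np.log(ks[-1] / ks[0]))
    return ws, dg_analytic


def simulate_pose_cloud(
    n_atoms: int,
    base_seed: int,
    transforms: Sequence[tuple[Sequence[float], float]] = (),
    box: float = 10.0,
) -> list[PoseCoordinates]:
    """A base point-cloud pose plus one derived pose per transform.

    Each transform is ``(translation, jitter_sigma)``: the derived pose is
    the base cloud rigidly shifted by the translation with i.i.d. Gaussian
    jitter of the given σ on every coordinate.
    """
    if n_atoms < 1:
        raise ValidationError("n_atoms must be >= 1")
    rng = np.random.default_rng(base_seed)
    base = rng.uniform(0.0, box, size=(n_atoms, 3))
    poses = [PoseCoordinates(pose_id="base", atoms=base)]
    for i, (shift, jitter) in enumerate(transforms):
        shift = np.asarray(shift, dtype=float)
        if shift.shape != (3,):
            raise ValidationError("translation must be a 3-vector")
        if jitter < 0:
            raise ValidationError("jitter must be non-negative")
        coords = base + shift
        if jitter > 0:
            coords = coords + rng.normal(0.0, jitter, size=coords.shape)
        poses.append(PoseCoordinates(pose_id=f"t{i + 1}", atoms=coords))
    return poses
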
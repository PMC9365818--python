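# Methods

This note records the models, conventions, and numerical choices behind the
package, and what the synthetic generators do and do not emulate.

## Thermodynamic state and conventions

All free energies are in kcal/mol, lengths in Å. `Constants` fixes
T = 298.0 K (the production temperature of the equilibration and
free-energy simulations) and R = 1.987204 × 10⁻³ kcal/(mol K), giving
RT = 0.59219 kcal/mol; results reported to 0.1 kcal/mol are insensitive to
298 vs 298.15 K. The standard state is 1 M, i.e. one molecule per
V° = 10²⁷/N_A ≈ 1660.5 Å³. Everywhere in the package, more negative =
better: docking scores and ΔG are both ranked ascending.

## Score aggregation over chemical forms

A compound may dock in several chemical forms (protonation states,
tautomers, stereoisomers). Each form carries a non-negative state penalty —
the free-energy cost of putting the free ligand in that form at assay pH —
which is *added* to its docking score; the compound's final score is the
minimum penalized score, ties going to the first-listed form. Addition is
the only scale-consistent way to fold a free-energy penalty into a
free-energy-like score.

## Pose diversity and stability rules

Diversity selection is a greedy scan over a best-score-first candidate
stream: a candidate is kept iff, against **every** kept pose, its RMSD
exceeds 2 Å **or** some atom is displaced by more than 5 Å. Reading the
displacement clause per kept pose (rather than jointly over all kept poses)
guarantees pairwise distinctness; the alternative reading would admit
near-duplicates. Both metrics are computed **without superposition**:
docked poses of one compound share the rigid receptor frame, and aligning
them would mask exactly the translational diversity the rule captures.
Inequalities are strict, so a pose at exactly the threshold is rejected.

Stability is judged on the final equilibration snapshot: a pose is stable
iff at least one ligand atom lies strictly within 4.5 Å of a
target-specific key atom (a literal coordinate, because identifying that
atom from a structure is upstream of this package). The boundary is
measure-zero, so the strict convention only matters for reproducibility.
The best-scoring five stable poses advance; fewer than five is reported,
not an error, and a compound with zero stable poses is excluded from the
ABFE ranking with its count surfaced in the report (how such compounds
should enter enrichment statistics is genuinely underdetermined, so
exclusion-with-count is the transparent choice).

## Free-energy estimators

**MBAR.** Given a complete reduced-potential matrix u[k, n] and per-state
sample counts N_k, the per-state dimensionless free energies solve

  f_k = −ln Σ_n exp(−u_kn) / Σ_j N_j exp(f_j − u_jn),  gauge f₁ = 0.

The solver minimizes the equivalent convex objective with L-BFGS (analytic
gradient), then polishes by self-consistent iteration until the update is
below 10⁻¹⁰ in max |Δf| — far below the 0.1 kcal/mol reporting precision.
All exponentials go through log-sum-exp. Non-convergence raises an error
carrying per-state effective sample sizes, the symptom of non-overlapping
neighbor states. For K = 2, MBAR coincides with the Bennett acceptance
ratio; the test suite verifies agreement to 10⁻⁸ against an independent
root-finding BAR solve.

**TI.** Trapezoidal quadrature of ⟨∂U/∂λ⟩ over the given strictly
increasing λ grid. No spline smoothing: the trapezoid is the conservative
default, exact for integrands linear between grid points, and its error is
bounded by h²·max|f″|/12 (asserted in tests against the λ-interpolated
harmonic spring, whose ΔG is (RT/2)·ln(k₁/k₀) in closed form).

**Blocking analysis.** A time series is split into five contiguous equal
blocks (the remainder is dropped from the end, keeping blocks equal-sized
and contiguous); σ = std(block estimates, ddof = 1)/√5. Contiguous blocks
make the estimate robust to autocorrelation, which a naive σ/√n
underestimates — the AR(1) test demonstrates the inflation. The estimator
applied per block is a callback (default: the mean), so blocking can wrap
either a window mean or an assembled component estimate.

**Analytic restraint release.** Releasing the six harmonic anchor
restraints (one distance r, two angles θ_A, θ_B, three dihedrals) on a
bound ligand into V° and free orientation 8π², in the stiff-restraint
approximation:

  ΔG = −RT ln[ 8π² V° √(k_r k_θA k_θB k_φA k_φB k_φC)
               / (r₀² sin θA₀ sin θB₀ (2πRT)³) ].

The approximation evaluates the Jacobian factors r² sin θ_A sin θ_B at the
restraint minima; its leading error is RT·(RT/k) per angular coordinate
(≈ 0.035 kcal/mol at k = 10 kcal/(mol rad²), ≈ 0.003 at k = 100). The tests
validate the formula against exact separable Gaussian quadrature of the
restrained configuration integral, assert the error shrinks with stiffness,
and check the exact √-product scaling (all k ×4 ⇒ ΔG shifts by −3RT ln 4).
A translational-only variant, ΔG = −RT ln[V°(k/2πRT)^{3/2}], supports the
composed-cycle oracle below.

## Aggregation chain and uncertainty

A pose's ΔG is the sum of its eight cycle components with uncertainties
added in quadrature; duplicate component names are rejected. Poses combine
by the Boltzmann sum ΔG°_overall = −RT ln Σᵢ exp(−βΔG°ᵢ), computed with
log-sum-exp (stable to |ΔG| ~ 10³). Since ∂ΔG_overall/∂ΔGᵢ is exactly the
Boltzmann weight wᵢ, first-order propagation gives σ² = Σ wᵢ²σᵢ². The
Monte-Carlo oracle in the tests shows linearization is accurate (within
15 %) when all σᵢ ≤ 0.5 kcal/mol; it degrades for large σ on
near-degenerate poses, which is a known property of linearized propagation,
not a defect of the implementation. The combiner accepts 1–10 poses even
though production uses five, because the stability filter can pass fewer.
Of the two independent runs per compound, the more favorable overall value
is chosen (ties to run 1); the run count is a config default, not
hard-coded.

## Enrichment metrics

AUC follows the Mann–Whitney convention — P(active outranks decoy) + ½
P(tie) — computed via mid-ranks; the ROC sweep traverses a tied score
group as a single diagonal segment, so the trapezoidal area under the
returned points equals the Mann–Whitney value to machine precision (an
internal consistency test). The enrichment factor at fraction x uses
m = max(1, round(xN)) top compounds, ties at the cutoff broken stably by
compound ID. Tier 1 takes the `size` best final scores after seeded random
downsampling of actives (the mechanism behind the published sets'
near-balanced composition; random-without-replacement is a documented
choice, as the selection mechanism is not otherwise determined). Tier 2
draws n_active + n_decoy compounds uniformly from a less favorable
docking-score window, with an explicit shortfall error naming the available
counts. Tier windows are applied to final (penalized) scores.

## Synthetic generators

`simulate_screen` draws class-conditional normal docking scores and a
latent true ΔG per compound, uniform over its class range. Defaults encode
the study conditions: actives' ΔG at least as favorable as the 1 μM
equivalent RT ln 10⁻⁶ ≈ −8.2 kcal/mol at 298 K, decoys 4 kcal/mol less
favorable on average with an overlapping-range construction (overlap, not a
separate mechanism, reproduces occasional very favorable decoys), and a
docking class separation of 0.5 σ — weakly informative docking over a
strong affinity signal.

`simulate_abfe_observations` adds, per pose, an exponential pose-quality
penalty (mean 2 kcal/mol; the best of several poses has penalty near zero);
per run, with probability 0.3, a uniform 0–9 kcal/mol drift penalty shared
by all of that run's poses (equilibration moves the ligand; every
subsequent window inherits the shifted conformation — the mechanism behind
large run-to-run differences); per pose, a blocking-scale σ uniform on
0.5–3 kcal/mol with Normal(0, σ) observation noise; and Bernoulli(0.9)
stability flags. The exponential pose-penalty law and the 0.9 survival
probability are declared modeling assumptions — instability is the
exception, correlated with worse scores, but no quantitative law for either
is available.

`simulate_harmonic_windows` emits exact Gaussian samples (optionally
AR(1)-correlated in time, same marginals) from a ladder of harmonic states
with the closed-form Δf = (d/2) ln(κ_K/κ_1), giving MBAR and blocking a
ground truth with no sampling bias. What the generators do **not** emulate:
molecular geometry beyond point clouds, force-field error, finite-sampling
bias of real alchemical windows, or any correlation between docking score
and pose stability. Passing tests therefore demonstrate the *statistical
machinery* is correct under the assumed noise structure, not that real
screens will show the same effect sizes.

## Problem sizes and determinism

The statistical tests use 10–16 windows at 1 500–2 000 samples each, 10⁴
points for i.i.d. SEM checks, 5 × 10⁴ for AR(1), 10⁵ draws for the
Monte-Carlo propagation oracle, and 100 pipeline replicates of 15 + 15
compounds for the end-to-end enrichment analog — sizes at which every
oracle comparison resolves well inside its tolerance while the whole suite
runs in seconds. Stochastic assertions use replicate-based standard errors
(typically 8 independent seeds) and 3-SE bands. Every random draw flows
from an explicit `numpy` `default_rng` seed; pipeline reports embed the
config hash and seeds and are byte-identical under identical configuration.

## Known limitations

- The eight-component cycle's component values are inputs here; computing
  reduced potentials from trajectories is out of scope by design.
- The stiff-restraint release formula is only as good as its O(RT²/k)
  error; for soft restraints (k ≲ 10) the quadrature route should be
  preferred.
- First-order uncertainty propagation understates σ_overall when large
  uncertainties sit on nearly degenerate poses.
- The published table's values are printed to 0.1 kcal/mol; recombining
  printed pose values can therefore deviate from the printed overall by up
  to ~0.06 kcal/mol (observed maximum), which is why reproduction is
  asserted at 0.15 kcal/mol slack.
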
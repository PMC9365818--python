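# abfescreen

Absolute binding free energy (ABFE) refinement of structure-based virtual
compound screens.

## The problem

Docking can screen tens of thousands of candidate ligands against a protein
target, but its scoring functions are approximate: actives and decoys overlap
substantially in docking score. ABFE calculations — which estimate the
standard binding free energy ΔG° from the reversible work of alchemically
decoupling the ligand from the binding site — are far more detailed, and can
re-rank the top docking hits to enrich true actives further. This package
implements everything in that refinement layer that is *not* the docking or
MD engine itself:

- aggregation of docking scores over a compound's chemical forms
  (protonation states, tautomers, stereoisomers), including the
  protonation-state free-energy penalty;
- geometric pose-diversity selection (RMSD > 2 Å or any-atom displacement
  > 5 Å, greedy over a best-score-first stream, up to 10 poses);
- post-equilibration pose stability filtering (a pose is unstable when no
  ligand atom remains within 4.5 Å of a target-specific key atom) and
  best-5 selection;
- free-energy estimation primitives: MBAR (multistate Bennett acceptance
  ratio), thermodynamic integration, five-block blocking-analysis
  uncertainties, and the analytic (stiff-restraint) free energy of
  releasing Boresch-style anchor restraints into the standard state;
- multi-pose Boltzmann combination with first-order uncertainty
  propagation, and best-of-two-run selection;
- enrichment evaluation: ROC/AUC (Mann–Whitney convention), enrichment
  factors, Tier 1/Tier 2 compound-set construction, and the
  docking-versus-ABFE comparison;
- seeded synthetic generators emulating the statistical structure of a
  screen (class-shifted score distributions, pose-quality penalties,
  run-level equilibration drift of 0–9 kcal/mol, blocking noise of
  0.5–3 kcal/mol), so the full pipeline runs with no engine and no
  downloads.

## The core model

Each of a compound's (up to) five surviving poses gets an independent ABFE
estimate ΔG°ᵢ, the sum of eight thermodynamic-cycle components (restraint
attachment, charge and Lennard-Jones decoupling/recoupling, restraint
release). The compound's overall binding free energy combines the poses as
a Boltzmann sum:

    ΔG°_overall = −RT ln Σᵢ exp(−ΔG°ᵢ / RT)

so the most favorable pose dominates. Pose uncertainties σᵢ (from blocking
analysis) propagate to first order with Boltzmann weights
wᵢ = exp(−βΔG°ᵢ)/Σⱼ exp(−βΔG°ⱼ):  σ²_overall = Σᵢ wᵢ²σᵢ². Each compound is
run twice independently; the more favorable overall value is kept, since the
tighter-binding post-equilibration conformation is the more realistic one.

## Worked example

The packaged dataset (`abfescreen.load_bace1_tier1()`) carries the BACE1
Tier 1 compound set: 15 actives and 15 decoys with docking scores, two
overall BFEs per compound, and the five per-pose BFEs of the more favorable
run. Combining the poses of the top-ranked active CHEMBL502289:

```python
from abfescreen import Constants, PoseFreeEnergy, select_best_run
from abfescreen.freeenergy import make_run_result

c = Constants()                       # T = 298 K, RT = 0.59219 kcal/mol
pose_dgs = [-22.2, 0.4, -9.0, -1.4, -22.2]
poses = [PoseFreeEnergy(f"p{i+1}", g, 1.2) for i, g in enumerate(pose_dgs)]
run1 = make_run_result(1, poses, c)
print(f"dg_overall = {run1.dg_overall:.2f}  sigma = {run1.sigma_overall:.2f}")
```

prints

```
dg_overall = -22.61  sigma = 0.85
```

The two degenerate −22.2 kcal/mol poses split the Boltzmann weight 0.50/0.50
(every other pose contributes < 10⁻⁶), so the overall value is
−22.2 − RT ln 2 ≈ −22.6 kcal/mol — the published value for this compound —
and the propagated σ is 1.2/√2 ≈ 0.85. Pairing with this compound's second
independent run (−22.3 kcal/mol) and keeping the more favorable:

```python
run2 = make_run_result(2, [PoseFreeEnergy("p1", -22.3, 1.0)], c)
sel = select_best_run(run1, run2)
print(f"chosen = {sel.chosen_dg:.2f}  diff = {sel.diff:.2f}")
# chosen = -22.61  diff = 0.31
```

The same chain over the whole table, plus the enrichment comparison, is one
call: `run_pipeline(PipelineConfig(mode="precomputed"))`, or from the shell
`abfescreen run --mode precomputed`.

## Command line

`abfescreen` exposes the stages as subcommands: `simulate screen`,
`poses select`, `poses filter`, `fe estimate`, `fe combine`, `enrich`,
`tiers`, and `run`. Every command is a thin wrapper over the library; see
`abfescreen --help`.

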
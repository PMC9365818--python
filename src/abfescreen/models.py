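"""Core domain types of the screening pipeline.

The sign convention throughout is "more negative = better": docking
scores and binding free energies are both ranked ascending, best first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError

#: The eight free-energy components of the simultaneous
#: decoupling-and-recoupling (SDR) thermodynamic cycle, in path order:
#: restrain the receptor conformation with the ligand bound, restrain the
#: bound ligand conformation, restrain the bound ligand's translation and
#: rotation, decouple/recouple the ligand charges, decouple/recouple the
#: ligand Lennard-Jones interactions, release the translational and
#: rotational restraints in bulk (analytic, defines the standard state),
#: release the ligand conformational restraints in bulk, and release the
#: receptor conformational restraints of the apo receptor.
CYCLE_COMPONENTS: tuple[str, ...] = (
    "attach_receptor_conf",
    "attach_ligand_conf",
    "attach_ligand_tr",
    "sdr_charge",
    "sdr_lj",
    "release_ligand_tr",
    "release_ligand_conf",
    "release_receptor_conf",
)

Label = Literal["active", "decoy"]
_VALID_LABELS = {"active", "decoy"}


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ChemicalFormScore:
    """Docking score of one chemical form (protonation state, tautomer,
    stereoisomer) of a compound, with its state free-energy penalty.

    The penalty is the free-energy cost of putting the free ligand in this
    form at assay pH; it is added to the raw docking score when forms are
    compared.
    """

    form_id: str
    glide_score: float
    state_penalty: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("glide_score", self.glide_score)
        _require_finite("state_penalty", self.state_penalty)
        if self.state_penalty < 0:
            raise ValidationError(
                f"state_penalty must be non-negative, got {self.state_penalty}"
            )

    @property
    def penalized_score(self) -> float:
        return self.glide_score + self.state_penalty


@dataclass
class CompoundRecord:
    """One compound in a screening table."""

    compound_id: str
    label: str
    forms: list[ChemicalFormScore] = field(default_factory=list)
    final_score: float | None = None
    tier: str | None = None

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValidationError(
                f"label must be 'active' or 'decoy', got {self.label!r}"
            )
        if self.final_score is not None:
            _require_finite("final_score", self.final_score)


@dataclass
class ScreenTable:
    """A collection of compound records with unique IDs."""

    rows: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate compound_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def n_active(self) -> int:
        return sum(1 for r in self.rows if r.label == "active")

    @property
    def n_decoy(self) -> int:
        return sum(1 for r in self.rows if r.label == "decoy")

    def subset(self, compound_ids: Sequence[str], provenance: str = "") -> "ScreenTable":
        wanted = set(compound_ids)
        return ScreenTable(
            rows=[r for r in self.rows if r.compound_id in wanted],
            provenance=provenance or self.provenance,
        )


@dataclass
class PoseCoordinates:
    """Ordered 3-D atom positions (Å) of one docked or equilibrated pose.

    Poses of the same compound must share atom count and ordering so that
    per-atom deviations are meaningful; both poses live in the rigid
    receptor frame, so no superposition is ever applied.
    """

    pose_id: str
    atoms: np.ndarray  # shape (n_atoms, 3), Å
    score: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.atoms, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise ValidationError(
                f"atoms must be a non-empty (n, 3) array, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("atom coordinates must be finite")
        object.__setattr__(self, "atoms", arr)

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]


@dataclass
class WindowSet:
    """Samples from the alchemical windows of one cycle component.

    For MBAR the data are a complete reduced-potential matrix
    ``u[k, n]`` — the dimensionless energy of sample ``n`` evaluated in
    state ``k`` — together with the per-state sample counts ``N_k``
    (samples are concatenated state-by-state along the second axis).
    For TI the data are a strictly increasing λ grid on [0, 1] and one
    dU/dλ time series (kcal/mol) per λ.
    """

    component_name: str
    method: Literal["MBAR", "TI"]
    u: np.ndarray | None = None
    N_k: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    dudl_series: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("MBAR", "TI"):
            raise ValidationError(f"method must be 'MBAR' or 'TI', got {self.method!r}")
        if self.method == "MBAR":
            if self.u is None or self.N_k is None:
                raise ValidationError("MBAR WindowSet requires u and N_k")
            u = np.asarray(self.u, dtype=float)
            N_k = np.asarray(self.N_k, dtype=int)
            if u.ndim != 2:
                raise ValidationError(f"u must be 2-D (K, N), got shape {u.shape}")
            if not np.all(np.isfinite(u)):
                raise ValidationError("reduced potentials must be finite")
            if N_k.ndim != 1 or N_k.shape[0] != u.shape[0]:
                raise ValidationError("N_k must have one entry per state")
            if np.any(N_k < 1):
                raise ValidationError("every state must contribute at least one sample")
            if int(N_k.sum()) != u.shape[1]:
                raise ValidationError(
                    f"sum(N_k)={int(N_k.sum())} does not match u columns {u.shape[1]}"
                )
            self.u, self.N_k = u, N_k
        else:
            if self.lambdas is None or self.dudl_series is None:
                raise ValidationError("TI WindowSet requires lambdas and dudl_series")
            lam = np.asarray(self.lambdas, dtype=float)
            if lam.ndim != 1 or lam.size < 2 or np.any(np.diff(lam) <= 0):
                raise ValidationError("lambdas must be strictly increasing, length >= 2")
            series = [np.asarray(s, dtype=float) for s in self.dudl_series]
            if len(series) != lam.size:
                raise ValidationError("one dU/dλ series required per λ")
            for s in series:
                if s.size < 1 or not np.all(np.isfinite(s)):
                    raise ValidationError("dU/dλ series must be non-empty and finite")
            self.lambdas, self.dudl_series = lam, series

    @property
    def n_states(self) -> int:
        if self.method == "MBAR":
            return int(self.u.shape[0])
        return int(self.lambdas.size)


@dataclass(frozen=True)
class RestraintParams:
    """Parameters of the six ligand anchor restraints: one anchor distance,
    two angles, three dihedrals (Boresch-style geometry).

    Units: r0 in Å, angles in rad, k_r in kcal/(mol Å²), angular force
    constants in kcal/(mol rad²).
    """

    r0: float
    thetaA0: float
    thetaB0: float
    k_r: float
    k_thA: float
    k_thB: float
    k_phA: float
    k_phB: float
    k_phC: float

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValidationError(f"r0 must be positive, got {self.r0}")
        for name in ("thetaA0", "thetaB0"):
            th = getattr(self, name)
            if not (0.0 < th < math.pi):
                raise ValidationError(f"{name} must lie in (0, π), got {th}")
        for name in ("k_r", "k_thA", "k_thB", "k_phA", "k_phB", "k_phC"):
            k = getattr(self, name)
            if not k > 0:
                raise ValidationError(f"{name} must be positive, got {k}")

    @property
    def force_constants(self) -> tuple[float, ...]:
        return (self.k_r, self.k_thA, self.k_thB, self.k_phA, self.k_phB, self.k_phC)


@dataclass(frozen=True)
class ComponentResult:
    """Free energy (kcal/mol) of one cycle component with its uncertainty."""

    component_name: str
    dg: float
    sigma: float
    method: Literal["MBAR", "TI", "analytic"]

    def __post_init__(self) -> None:
        if self.component_name not in CYCLE_COMPONENTS:
            raise ValidationError(
                f"unknown component {self.component_name!r}; "
                f"expected one of {CYCLE_COMPONENTS}"
            )
        _require_finite("dg", self.dg)
        _require_finite("sigma", self.sigma)
        if self.sigma < 0:
            raise ValidationError(f"sigma must be non-negative, got {self.sigma}")
        if self.method not in ("MBAR", "TI", "analytic"):
            raise ValidationError(f"bad method {self.method!r}")


@dataclass
class PoseFreeEnergy:
    """ABFE of one pose: ΔG°ᵢ with its blocking uncertainty."""

    pose_id: str
    dg: float
    sigma: float
    components: list[ComponentResult] | None = None

    def __post_init__(self) -> None:
        _require_finite("dg", self.dg)
        _require_finite("sigma", self.sigma)
        if self.sigma < 0:
            raise ValidationError(f"sigma must be non-negative, got {self.sigma}")
        if self.components:
            total = sum(c.dg for c in self.components)
            if abs(total - self.dg) > 1e-9:
                raise ValidationError(
                    f"dg={self.dg} does not equal component sum {total}"
                )


@dataclass
class RunResult:
    """One independent ABFE run of a compound: its per-pose free energies
    and the Boltzmann-combined overall value."""

    run_index: int
    poses: list[PoseFreeEnergy]
    dg_overall: float
    sigma_overall: float

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValidationError("RunResult requires at least one pose")
        _require_finite("dg_overall", self.dg_overall)
        if self.sigma_overall < 0:
            raise ValidationError("sigma_overall must be non-negative")
        best = min(p.dg for p in self.poses)
        # The multi-pose Boltzmann sum is at least as favorable as the best
        # pose; allow 0.05 kcal/mol slack for values rebuilt from rounded text.
        if self.dg_overall > best + 0.05:
            raise ValidationError(
                f"dg_overall={self.dg_overall} less favorable than best pose {best}"
            )


@dataclass
class CompoundResult:
    """Final per-compound record: both runs, the chosen (more favorable)
    overall BFE, and the run-to-run difference."""

    compound_id: str
    label: str
    docking_score: float
    run_more: RunResult
    run_less: RunResult
    chosen_dg: float
    diff: float

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValidationError(f"label must be 'active' or 'decoy', got {self.label!r}")
        if self.diff < 0:
            raise ValidationError("diff must be non-negative")
        expected = min(self.run_more.dg_overall, self.run_less.dg_overall)
        if abs(self.chosen_dg - expected) > 1e-9:
            raise ValidationError(
                f"chosen_dg={self.chosen_dg} is not the more favorable run ({expected})"
            )
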
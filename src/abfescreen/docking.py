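"""Docking-score aggregation over chemical forms and geometric pose
diversity selection.

Docked poses of one compound all live in the rigid receptor frame, so the
geometric metrics are computed without superposition: aligning poses
first would mask exactly the translational diversity the selection rule
exists to capture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ValidationError
from .models import ChemicalFormScore, PoseCoordinates


@dataclass(frozen=True)
class DiversityRule:
    """Thresholds of the pose-diversity acceptance rule.

    A candidate is accepted when, against *every* already-accepted pose,
    its RMSD exceeds ``rmsd_threshold`` or some atom is displaced by more
    than ``displacement_threshold``.  Both comparisons are strict, so a
    pose at exactly the threshold is rejected.
    """

    rmsd_threshold: float = 2.0
    displacement_threshold: float = 5.0
    max_poses: int = 10

    def __post_init__(self) -> None:
        if not (self.rmsd_threshold > 0 and self.displacement_threshold > 0):
            raise ValidationError("diversity thresholds must be positive")
        if self.max_poses < 1:
            raise ValidationError("max_poses must be at least 1")


class FinalScore(NamedTuple):
    score: float
    form_id: str


def compound_final_score(forms: Sequence[ChemicalFormScore]) -> FinalScore:
    """Best penalized docking score over the chemical forms of a compound.

    Each form's protonation-state penalty is added to its raw docking
    score; the minimum (most favorable) penalized score wins.  Ties go to
    the first-listed form.
    """
    if not forms:
        raise ValidationError("compound has no chemical forms")
    best = min(forms, key=lambda f: f.penalized_score)  # min is stable: first wins
    return FinalScore(score=best.penalized_score, form_id=best.form_id)


def _check_comparable(a: PoseCoordinates, b: PoseCoordinates) -> None:
    if a.n_atoms != b.n_atoms:
        raise ValidationError(
            f"poses {a.pose_id!r} and {b.pose_id!r} have different atom counts "
            f"({a.n_atoms} vs {b.n_atoms})"
        )


def pose_rmsd(a: PoseCoordinates, b: PoseCoordinates) -> float:
    """RMSD (Å) between corresponding atoms, without superposition."""
    _check_comparable(a, b)
    d = a.atoms - b.atoms
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def max_atom_displacement(a: PoseCoordinates, b: PoseCoordinates) -> float:
    """Largest per-atom displacement (Å) between corresponding atoms."""
    _check_comparable(a, b)
    d = a.atoms - b.atoms
    return float(np.max(np.linalg.norm(d, axis=1)))


class AcceptDecision(NamedTuple):
    accepted: bool
    reason: str


def accept_pose(
    candidate: PoseCoordinates,
    accepted: Sequence[PoseCoordinates],
    rule: DiversityRule = DiversityRule(),
) -> AcceptDecision:
    """Decide whether a candidate pose is distinct from all accepted poses.

    Accept iff for every accepted pose the candidate's RMSD is above the
    RMSD threshold or some atom is displaced beyond the displacement
    threshold.  An empty accepted list accepts vacuously.
    """
    for other in accepted:
        rmsd = pose_rmsd(candidate, other)
        disp = max_atom_displacement(candidate, other)
        if not (rmsd > rule.rmsd_threshold or disp > rule.displacement_threshold):
            return AcceptDecision(
                False,
                f"too close to {other.pose_id!r}: rmsd={rmsd:.3f} Å "
                f"(<= {rule.rmsd_threshold}), max_disp={disp:.3f} Å "
                f"(<= {rule.displacement_threshold})",
            )
    return AcceptDecision(True, "distinct from all accepted poses")


def select_diverse_poses(
    candidates: Sequence[PoseCoordinates],
    rule: DiversityRule = DiversityRule(),
    audit: list[dict] | None = None,
) -> list[PoseCoordinates]:
    """Greedy diversity selection over a best-score-first candidate stream.

    Scans candidates in order, keeping each that passes :func:`accept_pose`
    against the poses already kept, until ``rule.max_poses`` are kept.  The
    best-scored candidate (first in the stream) is always kept.  When
    ``audit`` is given, one record per rejection is appended to it.
    """
    kept: list[PoseCoordinates] = []
    for cand in candidates:
        if len(kept) >= rule.max_poses:
            break
        decision = accept_pose(cand, kept, rule)
        if decision.accepted:
            kept.append(cand)
        elif audit is not None:
            audit.append({"pose_id": cand.pose_id, "reason": decision.reason})
    return kept
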
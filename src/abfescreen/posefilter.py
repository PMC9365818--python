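"""Post-equilibration pose stability screening.

After the short equilibration MD, a pose whose ligand has drifted out of
the binding site is discarded.  The criterion is geometric: the pose is
stable when at least one ligand atom remains within a cutoff of a
target-specific key atom (e.g. a catalytic-site nitrogen).  "Within" is
strict, so a minimum distance exactly at the cutoff counts as unstable.
The best-scoring stable poses (five in production) advance to the
free-energy stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ValidationError
from .models import PoseCoordinates


@dataclass(frozen=True)
class StabilityRule:
    """Key-atom position (Å) and contact cutoff for the stability check."""

    key_atom: tuple[float, float, float]
    cutoff: float = 4.5

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValidationError("cutoff must be positive")


class StabilityResult(NamedTuple):
    stable: bool
    min_distance: float


def stability_check(final_pose: PoseCoordinates, rule: StabilityRule) -> StabilityResult:
    """Stable iff some ligand atom lies strictly within the cutoff of the
    key atom; the minimum distance is returned for audit."""
    key = np.asarray(rule.key_atom, dtype=float)
    dmin = float(np.min(np.linalg.norm(final_pose.atoms - key, axis=1)))
    return StabilityResult(stable=dmin < rule.cutoff, min_distance=dmin)


class TopStableSelection(NamedTuple):
    poses: list[PoseCoordinates]
    n_stable: int
    shortfall: int  # how many short of k the stable pool fell


def select_top_stable(
    poses: Sequence[tuple[PoseCoordinates, bool]], k: int = 5
) -> TopStableSelection:
    """Keep the ``k`` best-scoring stable poses.

    Fewer than ``k`` stable poses is not an error; the shortfall is
    reported so a compound with zero stable poses can be flagged and
    excluded downstream.
    """
    if k < 1:
        raise ValidationError("k must be at least 1")
    stable = [p for p, flag in poses if flag]
    for p in stable:
        if p.score is None:
            raise ValidationError(f"pose {p.pose_id!r} carries no docking score")
    stable.sort(key=lambda p: p.score)  # ascending: more negative = better
    chosen = stable[:k]
    return TopStableSelection(
        poses=chosen, n_stable=len(stable), shortfall=max(0, k - len(stable))
    )
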
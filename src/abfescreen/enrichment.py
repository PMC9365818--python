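"""Screening evaluation: ROC/AUC, enrichment factors, tier construction,
and the docking-versus-ABFE comparison.

Scores are ranked ascending (more negative = better) everywhere.  The
AUC follows the Mann–Whitney convention: the probability that a random
active outranks a random decoy, with ties counted half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError, ValidationError
from .models import CompoundRecord, ScreenTable


@dataclass(frozen=True)
class TierConfig:
    """Selection rule for one ABFE compound tier.

    Tier 1 takes the ``size`` best-scoring compounds after downsampling
    the actives by ``downsample_factor`` (downsampling balances the
    active/decoy counts and so lowers the AUC's statistical error).
    Tier 2 draws ``n_active`` actives and ``n_decoy`` decoys at random
    from the slightly less favorable ``score_window``.
    """

    tier: int
    size: int = 30
    downsample_factor: int = 1
    score_window: tuple[float, float] | None = None
    n_active: int = 15
    n_decoy: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tier not in (1, 2):
            raise ValidationError("tier must be 1 or 2")
        if self.size < 1:
            raise ValidationError("size must be positive")
        if self.downsample_factor < 1:
            raise ValidationError("downsample_factor must be >= 1")
        if self.tier == 2:
            if self.score_window is None:
                raise ValidationError("Tier 2 requires a score_window")
            lo, hi = self.score_window
            if not lo < hi:
                raise ValidationError("score_window must satisfy lo < hi")
            if self.n_active + self.n_decoy != self.size:
                raise ValidationError("Tier 2 size must equal n_active + n_decoy")


@dataclass
class EnrichmentReport:
    """ROC curve, AUC, enrichment factors, and score histograms."""

    auc: float
    roc_points: list[tuple[float, float]]
    ef: dict[float, float]
    histograms: dict[str, dict]
    n_active: int
    n_decoy: int
    n_excluded: int = 0


def _as_arrays(scores: Sequence[float], labels: Sequence[str]):
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if s.shape[0] != lab.shape[0]:
        raise ValidationError("scores and labels must have equal length")
    is_active = lab == "active"
    is_decoy = lab == "decoy"
    if not np.all(is_active | is_decoy):
        bad = sorted(set(lab[~(is_active | is_decoy)]))
        raise ValidationError(f"labels must be 'active'/'decoy'; got {bad}")
    return s, is_active


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC and ROC points for ascending-better scores.

    AUC = P(score_active < score_decoy) + ½ P(tie), computed via
    mid-ranks.  The ROC curve sweeps the threshold over the sorted unique
    scores; a group of tied scores is traversed as one diagonal segment,
    so the trapezoidal area under the returned points equals the
    Mann–Whitney AUC exactly.
    """
    s, is_active = _as_arrays(scores, labels)
    n_a = int(is_active.sum())
    n_d = int(s.size - n_a)
    if n_a == 0 or n_d == 0:
        raise UndefinedMetricError(
            f"ROC requires both classes (n_active={n_a}, n_decoy={n_d})"
        )
    ranks = rankdata(s)  # ascending, mid-ranks for ties
    # pairs where active score > decoy score (+ half ties)
    u_worse = float(ranks[is_active].sum()) - n_a * (n_a + 1) / 2.0
    auc = 1.0 - u_worse / (n_a * n_d)

    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    order = np.argsort(s, kind="stable")
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[order[j]] == s[order[i]]:
            j += 1
        group = order[i:j]
        tp += int(is_active[group].sum())
        fp += int(group.size - is_active[group].sum())
        points.append((fp / n_d, tp / n_a))
        i = j
    return float(auc), points


def enrichment_factor(
    scores: Sequence[float],
    labels: Sequence[str],
    fraction: float = 0.01,
    compound_ids: Sequence[str] | None = None,
) -> float:
    """Enrichment factor at the given top fraction.

    With N compounds of which N_A are active and n_A of the top
    m = max(1, round(fraction N)) are active, EF = (n_A/m)/(N_A/N).
    Ties at the cutoff are broken by compound ID (stable) when IDs are
    supplied, otherwise by input order.
    """
    if not (0.0 < fraction < 1.0 or fraction == 1.0):
        raise ValidationError("fraction must lie in (0, 1]")
    s, is_active = _as_arrays(scores, labels)
    n = s.size
    n_act = int(is_active.sum())
    if n_act == 0:
        raise UndefinedMetricError("enrichment factor undefined without actives")
    m = max(1, int(math.floor(fraction * n + 0.5)))
    m = min(m, n)
    if compound_ids is not None:
        order = sorted(range(n), key=lambda i: (s[i], str(compound_ids[i])))
    else:
        order = np.argsort(s, kind="stable").tolist()
    top = order[:m]
    n_a_top = int(is_active[top].sum())
    return (n_a_top / m) / (n_act / n)


def score_histograms(
    scores: Sequence[float], labels: Sequence[str], bin_width: float = 2.0
) -> dict[str, dict]:
    """Per-label histograms on shared fixed-width bins over the observed range."""
    s, is_active = _as_arrays(scores, labels)
    lo = bin_width * math.floor(float(s.min()) / bin_width)
    hi = bin_width * math.ceil(float(s.max()) / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    out = {}
    for name, mask in (("active", is_active), ("decoy", ~is_active)):
        counts, _ = np.histogram(s[mask], bins=edges)
        out[name] = {"edges": edges.tolist(), "counts": counts.tolist()}
    return out


def evaluate_screen(
    scores: Sequence[float],
    labels: Sequence[str],
    ef_fractions: Sequence[float] = (0.01,),
    compound_ids: Sequence[str] | None = None,
    n_excluded: int = 0,
) -> EnrichmentReport:
    """Full enrichment report for one score vector."""
    auc, points = roc_auc(scores, labels)
    ef = {
        float(f): enrichment_factor(scores, labels, f, compound_ids)
        for f in ef_fractions
    }
    s, is_active = _as_arrays(scores, labels)
    return EnrichmentReport(
        auc=auc,
        roc_points=points,
        ef=ef,
        histograms=score_histograms(scores, labels),
        n_active=int(is_active.sum()),
        n_decoy=int(s.size - is_active.sum()),
        n_excluded=n_excluded,
    )


def downsample_actives(table: ScreenTable, factor: int, seed: int) -> ScreenTable:
    """Keep ⌈N_A/factor⌉ actives drawn uniformly without replacement
    (seeded); all decoys are retained.  Row order is preserved."""
    if factor < 1:
        raise ValidationError("downsample factor must be >= 1")
    if factor == 1:
        return ScreenTable(rows=list(table.rows), provenance=table.provenance)
    active_idx = [i for i, r in enumerate(table.rows) if r.label == "active"]
    n_keep = math.ceil(len(active_idx) / factor)
    rng = np.random.default_rng(seed)
    kept = set(rng.choice(active_idx, size=n_keep, replace=False).tolist())
    rows = [
        r
        for i, r in enumerate(table.rows)
        if r.label == "decoy" or i in kept
    ]
    return ScreenTable(rows=rows, provenance=table.provenance)


def _require_scored(table: ScreenTable) -> None:
    missing = [r.compound_id for r in table.rows if r.final_score is None]
    if missing:
        raise ValidationError(f"unscored compounds: {missing[:5]}")


def tier1_select(table: ScreenTable, cfg: TierConfig) -> ScreenTable:
    """Tier 1: the best-scoring ``cfg.size`` compounds after downsampling
    the actives (stable tie-break by compound ID)."""
    _require_scored(table)
    pool = downsample_actives(table, cfg.downsample_factor, cfg.seed)
    if len(pool) < cfg.size:
        raise ValidationError(
            f"only {len(pool)} compounds available for a Tier 1 set of {cfg.size}"
        )
    ranked = sorted(pool.rows, key=lambda r: (r.final_score, r.compound_id))
    rows = [
        CompoundRecord(
            compound_id=r.compound_id,
            label=r.label,
            forms=list(r.forms),
            final_score=r.final_score,
            tier="1",
        )
        for r in ranked[: cfg.size]
    ]
    return ScreenTable(rows=rows, provenance=f"{table.provenance} [tier 1]")


def tier2_select(table: ScreenTable, cfg: TierConfig) -> ScreenTable:
    """Tier 2: a seeded draw of ``n_active`` actives and ``n_decoy``
    decoys whose final scores lie in the configured window."""
    _require_scored(table)
    if cfg.score_window is None:
        raise ValidationError("Tier 2 requires a score_window")
    lo, hi = cfg.score_window
    in_window = [r for r in table.rows if lo <= r.final_score <= hi]
    actives = [r for r in in_window if r.label == "active"]
    decoys = [r for r in in_window if r.label == "decoy"]
    if len(actives) < cfg.n_active or len(decoys) < cfg.n_decoy:
        raise ValidationError(
            f"score window [{lo}, {hi}] holds {len(actives)} actives and "
            f"{len(decoys)} decoys; need {cfg.n_active} and {cfg.n_decoy}"
        )
    rng = np.random.default_rng(cfg.seed)
    pick_a = rng.choice(len(actives), size=cfg.n_active, replace=False)
    pick_d = rng.choice(len(decoys), size=cfg.n_decoy, replace=False)
    chosen = [actives[i] for i in sorted(pick_a)] + [decoys[i] for i in sorted(pick_d)]
    rows = [
        CompoundRecord(
            compound_id=r.compound_id,
            label=r.label,
            forms=list(r.forms),
            final_score=r.final_score,
            tier="2",
        )
        for r in chosen
    ]
    return ScreenTable(rows=rows, provenance=f"{table.provenance} [tier 2]")


@dataclass
class MethodComparison:
    """Paired enrichment reports for docking and ABFE on one compound set."""

    docking: EnrichmentReport
    abfe: EnrichmentReport
    delta_auc: float
    n_excluded_from_abfe: int


def compare_methods(
    docking_scores: Sequence[float],
    abfe_dgs: Sequence[float | None],
    labels: Sequence[str],
    compound_ids: Sequence[str] | None = None,
    ef_fractions: Sequence[float] = (0.01,),
) -> MethodComparison:
    """Compare docking and ABFE ranking of the same compound set.

    Compounds without an ABFE value (``None``/NaN — e.g. no stable pose)
    are excluded from the ABFE report only, with their count recorded.
    """
    n = len(labels)
    if len(docking_scores) != n or len(abfe_dgs) != n:
        raise ValidationError("docking, ABFE, and label vectors must align")
    dock_report = evaluate_screen(docking_scores, labels, ef_fractions, compound_ids)
    keep = [
        i
        for i, g in enumerate(abfe_dgs)
        if g is not None and math.isfinite(float(g))
    ]
    excluded = n - len(keep)
    abfe_report = evaluate_screen(
        [float(abfe_dgs[i]) for i in keep],
        [labels[i] for i in keep],
        ef_fractions,
        None if compound_ids is None else [compound_ids[i] for i in keep],
        n_excluded=excluded,
    )
    return MethodComparison(
        docking=dock_report,
        abfe=abfe_report,
        delta_auc=abfe_report.auc - dock_report.auc,
        n_excluded_from_abfe=excluded,
    )
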
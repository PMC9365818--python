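"""Packaged worked-example dataset: BACE1 Tier 1 ABFE results.

The table carries, per compound: the active/decoy label (actives are
CHEMBL-prefixed), the docking score, the overall binding free energies of
the two independent ABFE runs (kcal/mol), the five per-pose ABFE values
and the blocking uncertainty of the more favorable run, and the
run-to-run difference.  All published values are rounded to 0.1 kcal/mol.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    CompoundRecord,
    CompoundResult,
    PoseFreeEnergy,
    RunResult,
    ScreenTable,
)

_FIXTURE = "bace1_tier1.csv"


def _fixture_path() -> Path:
    return Path(str(files("abfescreen") / "data" / _FIXTURE))


def load_bace1_tier1() -> pd.DataFrame:
    """Load the BACE1 Tier 1 table as a DataFrame.

    Columns: ``compound_id``, ``label``, ``docking``, ``dg_more``,
    ``sigma_more``, ``pose_bfes`` (list of 5 floats), ``dg_less``, ``diff``.
    """
    df = pd.read_csv(_fixture_path(), dtype={"compound_id": str})
    df["pose_bfes"] = df["pose_bfes"].map(
        lambda s: [float(x) for x in s.split(";")]
    )
    return df


def bace1_tier1_screen_table() -> ScreenTable:
    """The Tier 1 set as a docking-score ScreenTable."""
    df = load_bace1_tier1()
    rows = [
        CompoundRecord(
            compound_id=r.compound_id,
            label=r.label,
            final_score=float(r.docking),
            tier="1",
        )
        for r in df.itertuples()
    ]
    return ScreenTable(rows=rows, provenance="BACE1 Tier 1")


def bace1_tier1_results() -> list[CompoundResult]:
    """The Tier 1 set as full per-compound ABFE results.

    The less favorable run's pose decomposition is not published; it is
    represented as a single pose carrying the run's overall value so the
    record validates, with zero uncertainty.
    """
    df = load_bace1_tier1()
    out: list[CompoundResult] = []
    for r in df.itertuples():
        poses = [
            PoseFreeEnergy(pose_id=f"{r.compound_id}/p{i + 1}", dg=g, sigma=0.0)
            for i, g in enumerate(r.pose_bfes)
        ]
        run_more = RunResult(
            run_index=1,
            poses=poses,
            dg_overall=float(r.dg_more),
            sigma_overall=float(r.sigma_more),
        )
        run_less = RunResult(
            run_index=2,
            poses=[
                PoseFreeEnergy(
                    pose_id=f"{r.compound_id}/overall", dg=float(r.dg_less), sigma=0.0
                )
            ],
            dg_overall=float(r.dg_less),
            sigma_overall=0.0,
        )
        out.append(
            CompoundResult(
                compound_id=r.compound_id,
                label=r.label,
                docking_score=float(r.docking),
                run_more=run_more,
                run_less=run_less,
                chosen_dg=min(float(r.dg_more), float(r.dg_less)),
                diff=float(r.diff),
            )
        )
    return out
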
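"""Readers and writers for pipeline artifacts.

Screen tables travel as UTF-8 CSV with a header row; pose coordinates as
standard XYZ; run results and window sets as JSON.  All pairs round-trip
losslessly to the stated precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError
from .models import (
    ComponentResult,
    CompoundRecord,
    PoseCoordinates,
    PoseFreeEnergy,
    RunResult,
    ScreenTable,
    WindowSet,
)


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a delimited screening table.

    ``label_prefixes`` is an opt-in rule mapping compound-ID prefixes to
    labels (longest prefix wins); it is only consulted when the table has
    no label column.  The BACE1 Tier 1 convention is
    ``{"CHEMBL": "active", "C": "decoy"}``.
    """

    compound_col: str = "compound_id"
    label_col: str | None = "label"
    score_col: str | None = "score"
    tier_col: str | None = None
    label_prefixes: dict[str, str] | None = None


def _infer_label(compound_id: str, prefixes: dict[str, str]) -> str:
    for prefix, label in sorted(prefixes.items(), key=lambda kv: -len(kv[0])):
        if compound_id.startswith(prefix):
            return label
    raise ValidationError(f"no label prefix matches compound {compound_id!r}")


def read_screen_table(path: str | Path, dialect: TableDialect = TableDialect()) -> ScreenTable:
    """Read a CSV screening table into a validated :class:`ScreenTable`."""
    path = Path(path)
    df = pd.read_csv(path, dtype={dialect.compound_col: str})
    required = [dialect.compound_col]
    if dialect.label_col is not None and dialect.label_prefixes is None:
        required.append(dialect.label_col)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if dialect.score_col is not None and dialect.score_col not in df.columns:
        raise SchemaError(f"missing score column {dialect.score_col!r} in {path}")

    rows: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=2):  # line 1 is the header
        cid = str(rec[dialect.compound_col])
        if cid in seen:
            raise ValidationError(f"duplicate compound_id {cid!r} at line {i} of {path}")
        seen.add(cid)
        if dialect.label_col is not None and dialect.label_col in df.columns:
            label = str(rec[dialect.label_col])
        elif dialect.label_prefixes is not None:
            label = _infer_label(cid, dialect.label_prefixes)
        else:
            raise SchemaError("dialect provides neither a label column nor prefixes")
        score = None
        if dialect.score_col is not None:
            raw = rec[dialect.score_col]
            try:
                score = float(raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"unparseable score {raw!r} at line {i} of {path}"
                ) from exc
            if not math.isfinite(score):
                raise ValidationError(f"non-finite score at line {i} of {path}")
        tier = None
        if dialect.tier_col is not None and dialect.tier_col in df.columns:
            tier = str(rec[dialect.tier_col])
        rows.append(
            CompoundRecord(compound_id=cid, label=label, final_score=score, tier=tier)
        )
    return ScreenTable(rows=rows, provenance=str(path))


def write_screen_table(
    table: ScreenTable, path: str | Path, dialect: TableDialect = TableDialect()
) -> None:
    """Write a :class:`ScreenTable` as CSV; inverse of :func:`read_screen_table`."""
    for r in table.rows:
        if r.final_score is not None and not math.isfinite(r.final_score):
            raise ValidationError(f"non-finite score for compound {r.compound_id!r}")
    cols: dict[str, list] = {dialect.compound_col: [r.compound_id for r in table.rows]}
    if dialect.label_col is not None:
        cols[dialect.label_col] = [r.label for r in table.rows]
    if dialect.score_col is not None:
        cols[dialect.score_col] = [r.final_score for r in table.rows]
    if dialect.tier_col is not None:
        cols[dialect.tier_col] = [r.tier for r in table.rows]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# XYZ pose coordinates
# ---------------------------------------------------------------------------

def read_pose_xyz(path: str | Path) -> PoseCoordinates:
    """Read one pose from a standard XYZ file.

    The comment line is parsed for ``pose_id=... score=...`` tokens when
    present; otherwise the file stem is used as the pose ID.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"empty XYZ file {path}")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise FormatError(f"bad atom-count line in {path}: {lines[0]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) != n:
        raise FormatError(
            f"{path}: header declares {n} atoms but {len(records)} records found"
        )
    coords = np.empty((n, 3))
    for i, ln in enumerate(records):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom record {ln!r}")
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric coordinate in {ln!r}") from exc
    pose_id, score = path.stem, None
    for tok in comment.split():
        if tok.startswith("pose_id="):
            pose_id = tok.split("=", 1)[1]
        elif tok.startswith("score="):
            try:
                score = float(tok.split("=", 1)[1])
            except ValueError as exc:
                raise FormatError(f"{path}: bad score token {tok!r}") from exc
    return PoseCoordinates(pose_id=pose_id, atoms=coords, score=score)


def write_pose_xyz(pose: PoseCoordinates, path: str | Path, element: str = "C") -> None:
    """Write a pose as XYZ (coordinates at 1e-6 Å precision)."""
    comment = f"pose_id={pose.pose_id}"
    if pose.score is not None:
        comment += f" score={pose.score:.6f}"
    lines = [str(pose.n_atoms), comment]
    for x, y, z in pose.atoms:
        lines.append(f"{element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON serialization of free-energy artifacts
# ---------------------------------------------------------------------------

def run_result_to_dict(run: RunResult) -> dict:
    return {
        "run_index": run.run_index,
        "dg_overall": run.dg_overall,
        "sigma_overall": run.sigma_overall,
        "poses": [
            {
                "pose_id": p.pose_id,
                "dg": p.dg,
                "sigma": p.sigma,
                "components": None
                if p.components is None
                else [
                    {
                        "component_name": c.component_name,
                        "dg": c.dg,
                        "sigma": c.sigma,
                        "method": c.method,
                    }
                    for c in p.components
                ],
            }
            for p in run.poses
        ],
    }


def run_result_from_dict(d: dict) -> RunResult:
    poses = [
        PoseFreeEnergy(
            pose_id=p["pose_id"],
            dg=p["dg"],
            sigma=p["sigma"],
            components=None
            if p.get("components") is None
            else [ComponentResult(**c) for c in p["components"]],
        )
        for p in d["poses"]
    ]
    return RunResult(
        run_index=d["run_index"],
        poses=poses,
        dg_overall=d["dg_overall"],
        sigma_overall=d["sigma_overall"],
    )


def write_run_result(run: RunResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(run_result_to_dict(run), indent=2) + "\n")


def read_run_result(path: str | Path) -> RunResult:
    return run_result_from_dict(json.loads(Path(path).read_text()))


def window_set_to_dict(w: WindowSet) -> dict:
    d: dict = {"component_name": w.component_name, "method": w.method}
    if w.method == "MBAR":
        d["u"] = w.u.tolist()
        d["N_k"] = w.N_k.tolist()
    else:
        d["lambdas"] = w.lambdas.tolist()
        d["dudl_series"] = [s.tolist() for s in w.dudl_series]
    return d


def window_set_from_dict(d: dict) -> WindowSet:
    if d["method"] == "MBAR":
        return WindowSet(
            component_name=d["component_name"],
            method="MBAR",
            u=np.asarray(d["u"], dtype=float),
            N_k=np.asarray(d["N_k"], dtype=int),
        )
    return WindowSet(
        component_name=d["component_name"],
        method="TI",
        lambdas=np.asarray(d["lambdas"], dtype=float),
        dudl_series=[np.asarray(s, dtype=float) for s in d["dudl_series"]],
    )


def write_window_set(w: WindowSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(window_set_to_dict(w)) + "\n")


def read_window_set(path: str | Path) -> WindowSet:
    return window_set_from_dict(json.loads(Path(path).read_text()))
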
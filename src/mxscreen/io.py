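"""Readers, writers and the reproducible pipeline runner.

All tabular exchange uses long (tidy) CSV with units in column names
(``_uM``, ``_h``, ``rfu_norm``); designs travel as a long
``well_id,compound_id`` CSV plus a JSON sidecar carrying the parameters
and the ordered compound list, so a design round-trips losslessly
including library order.  A convenience importer converts 8x12 plate-grid
exports (A1-style coordinates) into the long layout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import analysis, design as design_mod, simulate as sim_mod
from .analysis import DeconvolutionPlan
from .design import CompoundLibrary, ScreenDesign, WellAssignment
from .errors import InvalidInputError, SchemaError

__all__ = [
    "read_library",
    "write_design",
    "read_design",
    "read_readings",
    "write_report",
    "write_deconvolution_plan",
    "grid_to_long",
    "RunConfig",
    "run_pipeline",
]

SCHEMA_VERSION = 1

DESIGN_CSV = "design.csv"
DESIGN_JSON = "design.json"


def read_library(path: str | Path) -> CompoundLibrary:
    """Load a compound library CSV with header ``compound_id,name``.

    Extra columns are ignored for the library object (they stay in the
    file); duplicate or missing identifiers raise a schema error naming
    the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "compound_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'compound_id'")
    ids = df["compound_id"].tolist()
    seen: dict[str, int] = {}
    for line, cid in enumerate(ids, start=2):  # line 1 is the header
        if cid is None or pd.isna(cid) or str(cid).strip() == "":
            raise SchemaError(f"{path}:{line}: empty compound_id")
        if cid in seen:
            raise SchemaError(
                f"{path}:{line}: duplicate compound_id {cid!r} (first seen line {seen[cid]})"
            )
        seen[cid] = line
    return CompoundLibrary(ids)


def write_design(design: ScreenDesign, out_dir: str | Path) -> Path:
    """Write a design as ``design.csv`` (long) + ``design.json`` (sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"well_id": w.well_id, "compound_id": c}
        for w in design.wells
        for c in w.members
    ]
    pd.DataFrame(rows).to_csv(out_dir / DESIGN_CSV, index=False)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "N": design.library.size,
        "n_per_well": design.n_per_well,
        "m": design.m,
        "seed": design.seed,
        "restarts": design.restarts,
        "trials": design.trials,
        "redundancy": design.redundancy,
        "compounds": list(design.library.compounds),
    }
    (out_dir / DESIGN_JSON).write_text(json.dumps(sidecar, indent=2) + "\n")
    return out_dir


def read_design(in_dir: str | Path) -> ScreenDesign:
    """Load a design written by :func:`write_design` (lossless round-trip)."""
    in_dir = Path(in_dir)
    sidecar_path = in_dir / DESIGN_JSON
    csv_path = in_dir / DESIGN_CSV
    if not sidecar_path.exists() or not csv_path.exists():
        raise SchemaError(f"{in_dir}: expected {DESIGN_CSV} and {DESIGN_JSON}")
    meta = json.loads(sidecar_path.read_text())
    library = CompoundLibrary(meta["compounds"])
    df = pd.read_csv(csv_path, dtype={"well_id": int, "compound_id": str})
    for col in ("well_id", "compound_id"):
        if col not in df.columns:
            raise SchemaError(f"{csv_path}: missing required column {col!r}")
    wells = []
    for well_id, grp in df.groupby("well_id", sort=True):
        members = grp["compound_id"].tolist()
        for c in members:
            if c not in library:
                raise SchemaError(f"{csv_path}: well {well_id} references unknown compound {c!r}")
        ordered = tuple(sorted(members, key=library.index))
        wells.append(WellAssignment(int(well_id), ordered))
    out = ScreenDesign(
        library=library,
        n_per_well=int(meta["n_per_well"]),
        wells=wells,
        seed=int(meta["seed"]),
        restarts=int(meta["restarts"]),
        trials=int(meta["trials"]),
    )
    if out.m != int(meta["m"]):
        raise SchemaError(
            f"{in_dir}: sidecar says m={meta['m']} but {DESIGN_CSV} holds {out.m} wells"
        )
    return out


def read_readings(path: str | Path) -> pd.DataFrame:
    """Load and validate a long plate-readings CSV.

    Requires columns ``plate_id, well_id, cell_line, time_h, rfu, role``;
    malformed rows are reported with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in analysis.READING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad_lines = []
    rfu = pd.to_numeric(df["rfu"], errors="coerce")
    for i in df.index[rfu.isna() | (rfu < 0)]:
        bad_lines.append(int(i) + 2)
    for i in df.index[~df["role"].isin(analysis.ROLES)]:
        bad_lines.append(int(i) + 2)
    if bad_lines:
        raise SchemaError(
            f"{path}: malformed rows at line(s) {sorted(set(bad_lines))[:20]} "
            "(non-numeric/negative rfu or unknown role)"
        )
    df["rfu"] = rfu
    df["time_h"] = pd.to_numeric(df["time_h"], errors="raise")
    return df


def write_report(df: pd.DataFrame, path: str | Path) -> Path:
    """Write an analysis table as CSV (deterministic row/column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_deconvolution_plan(plan: DeconvolutionPlan, path: str | Path) -> Path:
    """Deconvolution plan in the same long dialect as a design CSV."""
    rows = [
        {
            "well_id": k,
            "compound_a": p.first,
            "compound_b": p.second,
            "dose_uM": plan.dose_uM,
            "source_well": plan.source_well,
        }
        for k, p in enumerate(plan.pairs)
    ]
    return write_report(pd.DataFrame(rows), path)


GRID_ROWS = "ABCDEFGH"


def grid_to_long(
    path: str | Path,
    plate_id: str,
    cell_line: str,
    time_h: float,
    role: str = "treatment",
) -> pd.DataFrame:
    """Convert an 8x12 plate-grid CSV (rows A-H, columns 1-12) to long form.

    The grid holds raw RFU values; well positions become A1-style labels
    in ``well_pos`` and sequential integers (A1 -> 0, A2 -> 1, ...) in
    ``well_id``.
    """
    grid = pd.read_csv(path, index_col=0)
    if list(grid.index) != list(GRID_ROWS) or len(grid.columns) != 12:
        raise SchemaError(
            f"{path}: expected an 8x12 grid with row labels A-H and 12 columns"
        )
    rows = []
    for r, row_label in enumerate(GRID_ROWS):
        for c in range(12):
            rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": r * 12 + c,
                    "well_pos": f"{row_label}{c + 1}",
                    "cell_line": cell_line,
                    "time_h": float(time_h),
                    "rfu": float(grid.iloc[r, c]),
                    "role": role,
                }
            )
    return pd.DataFrame(rows)


class RunConfig(BaseModel):
    """Parameters of one end-to-end pipeline run (fully serializable)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    scenario: str = "well155_like"
    n_per_well: int = Field(default=10, ge=2)
    restarts: int = Field(default=50, ge=1)
    trials: int = Field(default=1000, ge=1)
    seed: int = 0
    time_h: float = 72.0
    k_sd: float = 3.0
    single_agent_threshold: float = 2.0
    alpha: float = 0.8
    tau: float = 0.2
    dose_uM: float = 0.1
    noise_sd: float | None = None  # None: use the scenario's own noise


def _stage_seed(master: int, stage: int) -> int:
    import numpy as np

    child = np.random.SeedSequence(master, spawn_key=(stage,))
    return int(child.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Design -> simulate -> analyze -> deconvolve -> attribute, reproducibly.

    Writes every stage output plus ``provenance.json`` (config, seeds,
    version, sha256 of each artifact) into ``out_dir`` and returns a
    result summary.  Rerunning with the same config reproduces every
    artifact bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = sim_mod.get_scenario(config.scenario)
    truth = scenario.truth
    if config.noise_sd is not None:
        truth.noise_sd = config.noise_sd

    n = min(config.n_per_well, scenario.pool_size, scenario.library.size)
    screen_design = design_mod.design_screen(
        scenario.library,
        n,
        restarts=config.restarts,
        trials=config.trials,
        seed=_stage_seed(config.seed, 0),
    )
    write_design(screen_design, out / "design")

    combo = sim_mod.simulate_combination_screen(
        truth, screen_design, seed=_stage_seed(config.seed, 1)
    )
    write_report(combo.readings, out / "combo_readings.csv")
    combo_norm = analysis.normalize_to_vehicle(combo.readings)
    combo_hits = analysis.call_combination_hits(combo_norm, time_h=config.time_h, k_sd=config.k_sd)
    write_report(combo_hits, out / "combo_hits.csv")
    overlap = analysis.overlap_summary(combo_hits)
    (out / "overlap.json").write_text(json.dumps(overlap, indent=2) + "\n")

    singles = sim_mod.simulate_single_agent(
        truth, scenario.library, seed=_stage_seed(config.seed, 2)
    )
    singles_norm = analysis.normalize_to_vehicle(singles.readings)
    singles_at = singles_norm[
        (singles_norm["role"] == "treatment")
        & (singles_norm["time_h"] == config.time_h)
        & (singles_norm["conc_uM"] == config.dose_uM)
    ]
    single_hits = analysis.call_single_agent_hits(
        singles_at, threshold=config.single_agent_threshold
    )
    write_report(single_hits, out / "single_agent_hits.csv")

    attribution = analysis.attribute_wells(
        combo_hits, singles_at, screen_design, alpha=config.alpha, tau=config.tau
    )
    write_report(attribution, out / "attribution.csv")

    summary: dict[str, Any] = {
        "design_m": screen_design.m,
        "design_redundancy": screen_design.redundancy,
        "n_combination_hits": int(combo_hits["hit"].sum()),
        "overlap": overlap,
        "attribution_counts": attribution["classification"].value_counts().to_dict(),
    }

    hits_only = combo_hits[combo_hits["hit"]]
    if not hits_only.empty:
        top_row = hits_only.sort_values(
            ["rfu_norm", "well_id"], ascending=[False, True]
        ).iloc[0]
        top_well = int(top_row["well_id"])
        plan = analysis.plan_deconvolution(screen_design, top_well, dose_uM=config.dose_uM)
        write_deconvolution_plan(plan, out / "deconvolution_plan.csv")
        decon = sim_mod.simulate_deconvolution(
            truth, plan, time_points=(config.time_h,), seed=_stage_seed(config.seed, 3)
        )
        write_report(decon.readings, out / "deconvolution_readings.csv")
        decon_norm = analysis.normalize_to_vehicle(decon.readings)
        ranked = (
            decon_norm[decon_norm["role"] == "treatment"]
            .groupby(["compound_a", "compound_b"], as_index=False)["rfu_norm"]
            .mean()
            .sort_values(["rfu_norm", "compound_a"], ascending=[False, True])
            .reset_index(drop=True)
        )
        write_report(ranked, out / "deconvolution_ranking.csv")
        top_pair = (str(ranked.iloc[0]["compound_a"]), str(ranked.iloc[0]["compound_b"]))
        summary["deconvolved_well"] = top_well
        summary["top_pair"] = top_pair

    from . import __version__

    artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "provenance.json")
    provenance = {
        "schema_version": SCHEMA_VERSION,
        "version": __version__,
        "config": config.model_dump(),
        "stage_seeds": {
            "design": _stage_seed(config.seed, 0),
            "combination_screen": _stage_seed(config.seed, 1),
            "single_agent_screen": _stage_seed(config.seed, 2),
            "deconvolution": _stage_seed(config.seed, 3),
        },
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    summary["checksums"] = provenance["checksums"]
    return summary
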
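"""Analysis of pooled cytotoxicity screens.

Operates on long-format plate-reader tables (one row per measured well)
with columns ``plate_id, well_id, cell_line, time_h, rfu, role`` where the
readout is a CellTox-style cytotoxicity signal: fluorescence rises with
cell death, so a vehicle-normalized value near 1 means an inert well and
values above 1 mean killing.  The stages mirror a standard pooled-screen
workflow: vehicle normalization, single-agent hit calling at a fixed
fold-change, combination-well hit calling at mean + k.SD per cell line,
cross-cell-line overlap, pairwise deconvolution planning for hit pools,
and attribution of a pool's effect to single-agent / additive /
candidate-synergy causes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import CompoundPair, ScreenDesign, well_pairs
from .errors import (
    IncompleteInputError,
    InsufficientDataError,
    InvalidInputError,
    MissingControlError,
)

__all__ = [
    "READING_COLUMNS",
    "STRATUM_KEYS",
    "normalize_to_vehicle",
    "call_single_agent_hits",
    "call_combination_hits",
    "overlap_summary",
    "DeconvolutionPlan",
    "plan_deconvolution",
    "AttributionEntry",
    "attribute_effect",
    "attribute_wells",
]

#: required columns of a plate-reading table
READING_COLUMNS = ["plate_id", "well_id", "cell_line", "time_h", "rfu", "role"]

#: normalization strata: vehicle means are computed within these groups
STRATUM_KEYS = ["plate_id", "cell_line", "time_h"]

ROLES = {"treatment", "vehicle", "cytotoxic-control"}

DECISION_TIME_H = 72.0


def _check_readings(readings: pd.DataFrame) -> None:
    missing = [c for c in READING_COLUMNS if c not in readings.columns]
    if missing:
        raise InvalidInputError(f"readings table is missing column(s): {missing}")
    bad_roles = set(readings["role"].unique()) - ROLES
    if bad_roles:
        raise InvalidInputError(f"unknown well roles: {sorted(bad_roles)}; expected {sorted(ROLES)}")
    if (readings["rfu"] < 0).any():
        raise InvalidInputError("raw RFU values must be non-negative")


def normalize_to_vehicle(readings: pd.DataFrame, aggregate: str = "mean") -> pd.DataFrame:
    """Divide every reading by its stratum's vehicle-control level.

    Strata are (plate, cell line, time point); the vehicle level is the
    mean (or ``aggregate='median'``) of the vehicle wells in the stratum.
    Returns a copy with an ``rfu_norm`` column; vehicle wells average to
    exactly 1 within their stratum under the mean aggregate.
    """
    _check_readings(readings)
    if aggregate not in ("mean", "median"):
        raise InvalidInputError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    out = readings.copy()
    vehicle = readings[readings["role"] == "vehicle"]
    levels = vehicle.groupby(STRATUM_KEYS)["rfu"].agg(aggregate)
    strata = pd.MultiIndex.from_frame(out[STRATUM_KEYS])
    missing = [s for s in strata.unique() if s not in levels.index]
    if missing:
        raise MissingControlError(
            f"no vehicle-control wells in stratum (plate, cell_line, time_h) = {missing[0]}"
        )
    denom = levels.reindex(strata).to_numpy(dtype=float)
    if (denom <= 0).any():
        bad = strata[int(np.flatnonzero(denom <= 0)[0])]
        raise MissingControlError(
            f"vehicle {aggregate} is not positive in stratum (plate, cell_line, time_h) = {bad}"
        )
    out["rfu_norm"] = out["rfu"].to_numpy(dtype=float) / denom
    return out


def _require_norm(screen: pd.DataFrame) -> None:
    if "rfu_norm" not in screen.columns:
        raise InvalidInputError("screen lacks an 'rfu_norm' column; run normalize_to_vehicle first")


def call_single_agent_hits(
    screen: pd.DataFrame,
    threshold: float = 2.0,
    time_h: float | None = None,
) -> pd.DataFrame:
    """Flag single-agent treatments whose normalized signal is >= threshold.

    The 2x-vehicle cut-off (inclusive) is the conventional "cell death has
    occurred" call for a cytotoxicity readout.  Evaluated per (compound,
    cell line, concentration, time point); rows must carry ``compound_id``
    and, if present, ``conc_uM``.  An empty screen yields an empty table.
    """
    if threshold < 0:
        raise InvalidInputError(f"threshold must be non-negative, got {threshold}")
    _require_norm(screen)
    if "compound_id" not in screen.columns:
        raise InvalidInputError("single-agent screen needs a 'compound_id' column")
    df = screen[screen["role"] == "treatment"].copy()
    if time_h is not None:
        df = df[df["time_h"] == time_h]
    keys = ["compound_id", "cell_line", "time_h"]
    if "conc_uM" in df.columns:
        keys.insert(1, "conc_uM")
    hits = df.groupby(keys, as_index=False)["rfu_norm"].mean()
    hits["threshold"] = threshold
    hits["rule"] = "single-agent-2x"
    hits["hit"] = hits["rfu_norm"] >= threshold
    return hits


def call_combination_hits(
    screen: pd.DataFrame,
    time_h: float = DECISION_TIME_H,
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """Flag combination wells exceeding mean + k_sd * SD of their cell line.

    The reference population is all treatment (combination) wells of the
    cell line at the chosen time point — vehicle and cytotoxic-control
    wells are excluded — and the comparison is strict (> mean + k.SD).
    """
    _require_norm(screen)
    df = screen[(screen["role"] == "treatment") & (screen["time_h"] == time_h)].copy()
    if df.empty:
        raise InsufficientDataError(f"no treatment wells at time_h={time_h}")
    rows = []
    for cell_line, grp in df.groupby("cell_line"):
        vals = grp.groupby("well_id")["rfu_norm"].mean()
        if len(vals) < 2:
            raise InsufficientDataError(
                f"cell line {cell_line!r} has {len(vals)} well(s) at {time_h} h; "
                "need >= 2 to estimate the SD"
            )
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cut = mu + k_sd * sd
        for well_id, v in vals.items():
            rows.append(
                {
                    "well_id": well_id,
                    "cell_line": cell_line,
                    "time_h": time_h,
                    "rfu_norm": float(v),
                    "mean": mu,
                    "sd": sd,
                    "threshold": cut,
                    "rule": "mean-plus-3sd" if k_sd == 3.0 else f"mean-plus-{k_sd:g}sd",
                    "hit": bool(v > cut),
                }
            )
    return pd.DataFrame(rows)


def overlap_summary(hits: pd.DataFrame) -> dict[str, int]:
    """Venn partition of hit wells across cell lines.

    Expects a hit table covering the same well universe in every cell
    line (as ``call_combination_hits`` produces).  Returns counts keyed by
    the '&'-joined sorted subset of cell lines sharing each hit well;
    counts over all keys sum to the number of distinct hit wells.
    """
    required = {"well_id", "cell_line", "hit"}
    if not required <= set(hits.columns):
        raise InvalidInputError(f"hit table needs columns {sorted(required)}")
    universes = hits.groupby("cell_line")["well_id"].apply(set)
    base = None
    for cell_line, wells in universes.items():
        if base is None:
            base = wells
        elif wells != base:
            raise InvalidInputError(
                f"cell line {cell_line!r} covers a different well universe than the others"
            )
    hit_rows = hits[hits["hit"]]
    if hit_rows.empty:
        return {}
    membership = hit_rows.groupby("well_id")["cell_line"].apply(
        lambda s: "&".join(sorted(set(s)))
    )
    counts = membership.value_counts().to_dict()
    return {k: int(v) for k, v in sorted(counts.items())}


@dataclass(frozen=True)
class DeconvolutionPlan:
    """Pairwise follow-up wells for one hit pool."""

    source_well: int
    dose_uM: float
    pairs: tuple[CompoundPair, ...]

    @property
    def size(self) -> int:
        return len(self.pairs)


def plan_deconvolution(
    design: ScreenDesign, well_id: int, dose_uM: float = 0.1
) -> DeconvolutionPlan:
    """All k(k-1)/2 pairwise combinations of a hit well's k members.

    Pairs are emitted in canonical library order so plans are
    deterministic; each is dosed at ``dose_uM`` (default 0.1 µM, the
    single common concentration carried over from the pooled screen).
    """
    if dose_uM <= 0:
        raise InvalidInputError(f"dose must be positive, got {dose_uM}")
    by_id = {w.well_id: w for w in design.wells}
    if well_id not in by_id:
        raise InvalidInputError(f"well {well_id} is not part of the design")
    pairs = tuple(well_pairs(by_id[well_id], design.library))
    return DeconvolutionPlan(source_well=well_id, dose_uM=dose_uM, pairs=pairs)


@dataclass(frozen=True)
class AttributionEntry:
    """Why one hit well responded: dominant single agent, additivity, or neither."""

    classification: str  # single-agent-driven | additive | candidate-synergy
    contributing: tuple[str, ...]
    combo_value: float
    combo_excess: float
    max_single_excess: float
    sum_single_excess: float


def _excess(value: float) -> float:
    """Effect above the vehicle level, floored at zero."""
    return max(float(value) - 1.0, 0.0)


def attribute_effect(
    combo_value: float,
    single_values: Mapping[str, float],
    members: Iterable[str] | None = None,
    alpha: float = 0.8,
    tau: float = 0.2,
) -> AttributionEntry:
    """Classify a hit pool's effect from its members' single-agent values.

    Works on the excess scale e(x) = max(x - 1, 0), where x is the
    vehicle-normalized signal.  Rules, applied in order:

    1. single-agent-driven: one member's excess alone reaches at least
       ``alpha`` of the pool excess;
    2. additive: the members' summed excesses reach the pool excess
       within slack ``tau``;
    3. candidate-synergy: otherwise — the pool did something its members
       cannot account for.
    """
    if combo_value <= 0 or any(v <= 0 for v in single_values.values()):
        raise InvalidInputError("normalized values must be positive")
    if members is not None:
        missing = sorted(set(members) - set(single_values))
        if missing:
            raise IncompleteInputError(
                f"no single-agent values for well member(s): {missing}"
            )
        single_values = {c: single_values[c] for c in members}
    if not single_values:
        raise IncompleteInputError("no single-agent values supplied")
    combo_e = _excess(combo_value)
    excesses = {c: _excess(v) for c, v in single_values.items()}
    max_e = max(excesses.values())
    sum_e = sum(excesses.values())
    positive = tuple(
        sorted((c for c, e in excesses.items() if e > 0), key=lambda c: -excesses[c])
    )
    if max_e >= alpha * combo_e:
        top = max(excesses, key=lambda c: excesses[c])
        cls, contributing = "single-agent-driven", (top,)
    elif sum_e >= combo_e - tau:
        cls, contributing = "additive", positive
    else:
        cls, contributing = "candidate-synergy", tuple(sorted(single_values))
    return AttributionEntry(
        classification=cls,
        contributing=contributing,
        combo_value=float(combo_value),
        combo_excess=combo_e,
        max_single_excess=max_e,
        sum_single_excess=sum_e,
    )


def attribute_wells(
    combo_hits: pd.DataFrame,
    singles: pd.DataFrame,
    design: ScreenDesign,
    alpha: float = 0.8,
    tau: float = 0.2,
) -> pd.DataFrame:
    """Attribute every flagged well in a combination hit table.

    ``singles`` maps (compound_id, cell_line) to a normalized single-agent
    value (column ``rfu_norm``).  Returns one row per (hit well, cell line)
    with the classification and the contributing compounds.
    """
    if not {"compound_id", "cell_line", "rfu_norm"} <= set(singles.columns):
        raise InvalidInputError("singles table needs compound_id, cell_line, rfu_norm")
    lookup = singles.groupby(["compound_id", "cell_line"])["rfu_norm"].mean()
    by_id = {w.well_id: w for w in design.wells}
    rows = []
    for _, row in combo_hits[combo_hits["hit"]].iterrows():
        well = by_id.get(row["well_id"])
        if well is None:
            raise InvalidInputError(f"hit well {row['well_id']} is not in the design")
        cell = row["cell_line"]
        try:
            values = {c: float(lookup[(c, cell)]) for c in well.members}
        except KeyError as e:
            raise IncompleteInputError(
                f"missing single-agent value for {e.args[0]} in well {well.well_id}"
            ) from None
        entry = attribute_effect(row["rfu_norm"], values, alpha=alpha, tau=tau)
        rows.append(
            {
                "well_id": well.well_id,
                "cell_line": cell,
                "classification": entry.classification,
                "contributing": ";".join(entry.contributing),
                "combo_rfu_norm": entry.combo_value,
                "combo_excess": entry.combo_excess,
                "max_single_excess": entry.max_single_excess,
                "sum_single_excess": entry.sum_single_excess,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "well_id",
            "cell_line",
            "classification",
            "contributing",
            "combo_rfu_norm",
            "combo_excess",
            "max_single_excess",
            "sum_single_excess",
        ],
    )
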
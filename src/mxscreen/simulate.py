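"""Synthetic plate-reader screens with planted ground truth.

Generates CellTox-style cytotoxicity readouts (fluorescence rises with
cell death) for every stage of the pipeline: single-agent screens, pooled
combination screens over a :class:`~mxscreen.design.ScreenDesign`,
pairwise deconvolution plates, and checkerboard dose matrices.  The
generative model composes effects additively on the excess scale — a
well's expected vehicle-normalized value is

    1 + sum(toxic-single excesses of its members)
      + sum(synergy boosts of planted pairs fully contained in the well)

— and multiplies in log-normal noise: raw = baseline * expected *
exp(Normal(0, noise_sd)).  At zero noise every analysis stage recovers
the planted truth exactly, which is what makes the simulator usable as a
round-trip oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .analysis import DeconvolutionPlan
from .design import CompoundLibrary, ScreenDesign, verify_coverage
from .errors import InvalidInputError
from .synergy import DoseResponseCurve

__all__ = [
    "GroundTruth",
    "SimulatedScreen",
    "Scenario",
    "simulate_single_agent",
    "simulate_combination_screen",
    "simulate_deconvolution",
    "simulate_dose_matrix",
    "scenario_library",
    "get_scenario",
]

#: default assay schedule (hours) and screening concentrations (µM)
TIME_POINTS_H = (24.0, 48.0, 72.0)
SINGLE_AGENT_CONCS_UM = (0.01, 0.1, 1.0)

VEHICLE_WELLS_PER_STRATUM = 6
VEHICLE_BASELINE_RFU = 1000.0

#: normalized signal of a fully killed control well, by cell-line character:
#: high-signal lines saturate near 7, low-signal lines near 1.5
CONTROL_LEVEL_HIGH = 7.0
CONTROL_LEVEL_LOW = 1.5

# integer well-id blocks for control rows so they never collide with treatments
_VEHICLE_ID_BASE = 9000
_CONTROL_ID_BASE = 9900


def _canonical(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class GroundTruth:
    """Planted effects of a simulated screen.

    ``toxic_singles``: cell line -> compound -> effect multiplier (>= 1);
    a compound's excess is multiplier - 1.  ``synergistic_pairs``: cell
    line -> unordered pair -> boost added to the expected normalized value
    when both members share a well.  Additive pairs are implicit: any two
    toxic singles co-occurring in a well compose additively.
    """

    cell_lines: tuple[str, ...]
    toxic_singles: dict[str, dict[str, float]] = field(default_factory=dict)
    synergistic_pairs: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    vehicle_baseline_rfu: float = VEHICLE_BASELINE_RFU
    noise_sd: float = 0.1
    control_levels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.cell_lines:
            raise InvalidInputError("ground truth needs at least one cell line")
        if self.noise_sd < 0:
            raise InvalidInputError("noise SD must be non-negative")
        if self.vehicle_baseline_rfu <= 0:
            raise InvalidInputError("vehicle baseline must be positive")
        for cell, effects in self.toxic_singles.items():
            for c, mult in effects.items():
                if mult < 1:
                    raise InvalidInputError(
                        f"toxic-single multiplier for {c!r} in {cell!r} must be >= 1, got {mult}"
                    )
        self.synergistic_pairs = {
            cell: {_canonical(p): float(b) for p, b in pairs.items()}
            for cell, pairs in self.synergistic_pairs.items()
        }
        for cell, pairs in self.synergistic_pairs.items():
            for p, boost in pairs.items():
                if boost <= 0:
                    raise InvalidInputError(f"synergy boost for {p} in {cell!r} must be > 0")
        for cell in self.cell_lines:
            self.control_levels.setdefault(cell, CONTROL_LEVEL_HIGH)

    def additive_pairs(self, cell_line: str) -> list[tuple[str, str]]:
        """Pairs of planted toxic singles, whose co-occurrence is additive."""
        toxins = sorted(self.toxic_singles.get(cell_line, {}))
        return [(a, b) for i, a in enumerate(toxins) for b in toxins[i + 1 :]]

    def expected_normalized(self, cell_line: str, members: Iterable[str]) -> float:
        """Noise-free vehicle-normalized value of a well with these members."""
        members = set(members)
        singles = self.toxic_singles.get(cell_line, {})
        value = 1.0 + sum(singles[c] - 1.0 for c in members if c in singles)
        for (a, b), boost in self.synergistic_pairs.get(cell_line, {}).items():
            if a in members and b in members:
                value += boost
        return value


@dataclass
class SimulatedScreen:
    """Simulated plate readings plus the truth and seed that produced them."""

    readings: pd.DataFrame
    truth: GroundTruth
    seed: int


def _emit_stratum(
    rows: list[dict],
    rng: np.random.Generator,
    truth: GroundTruth,
    plate_id: str,
    cell_line: str,
    time_points: Sequence[float],
    treatments: Sequence[tuple[int, float, dict]],
) -> None:
    """Append treatment + control rows for one plate/cell-line stratum.

    ``treatments`` is a list of (well_id, expected_normalized, extra_cols).
    """
    base = truth.vehicle_baseline_rfu
    sd = truth.noise_sd
    for t in time_points:
        for well_id, expected, extra in treatments:
            noise = float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
            rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": well_id,
                    "cell_line": cell_line,
                    "time_h": float(t),
                    "rfu": base * expected * noise,
                    "role": "treatment",
                    **extra,
                }
            )
        for v in range(VEHICLE_WELLS_PER_STRATUM):
            noise = float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
            rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": _VEHICLE_ID_BASE + v,
                    "cell_line": cell_line,
                    "time_h": float(t),
                    "rfu": base * noise,
                    "role": "vehicle",
                }
            )
        level = truth.control_levels[cell_line]
        noise = float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
        rows.append(
            {
                "plate_id": plate_id,
                "well_id": _CONTROL_ID_BASE,
                "cell_line": cell_line,
                "time_h": float(t),
                "rfu": base * level * noise,
                "role": "cytotoxic-control",
            }
        )


def _finish(rows: list[dict], truth: GroundTruth, seed: int) -> SimulatedScreen:
    df = pd.DataFrame(rows)
    front = ["plate_id", "well_id", "cell_line", "time_h", "rfu", "role"]
    df = df[front + [c for c in df.columns if c not in front]]
    return SimulatedScreen(readings=df, truth=truth, seed=seed)


def simulate_single_agent(
    truth: GroundTruth,
    library: CompoundLibrary,
    concentrations: Sequence[float] = SINGLE_AGENT_CONCS_UM,
    time_points: Sequence[float] = TIME_POINTS_H,
    seed: int = 0,
) -> SimulatedScreen:
    """One well per (compound, concentration, cell line) plus controls.

    Planted toxic singles act at every tested concentration (no
    dose-response is modelled inside the screen; dose matrices serve that
    purpose), so a compound's expected normalized value is its multiplier
    at all concentrations.
    """
    if not concentrations or any(c <= 0 for c in concentrations):
        raise InvalidInputError("concentrations must be positive and non-empty")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for cell in truth.cell_lines:
        for conc in concentrations:
            treatments = [
                (
                    idx,
                    truth.expected_normalized(cell, [c]),
                    {"compound_id": c, "conc_uM": float(conc)},
                )
                for idx, c in enumerate(library.compounds)
            ]
            _emit_stratum(
                rows, rng, truth, f"SA-{cell}-{conc:g}uM", cell, time_points, treatments
            )
    return _finish(rows, truth, seed)


def simulate_combination_screen(
    truth: GroundTruth,
    design: ScreenDesign,
    time_points: Sequence[float] = TIME_POINTS_H,
    seed: int = 0,
) -> SimulatedScreen:
    """Pooled screen over a verified all-pairs design, one plate per cell line."""
    report = verify_coverage(design)
    if not report.complete:
        raise InvalidInputError(
            f"design does not cover all pairs ({len(report.missing)} missing); refusing to simulate"
        )
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for cell in truth.cell_lines:
        treatments = [
            (w.well_id, truth.expected_normalized(cell, w.members), {})
            for w in design.wells
        ]
        _emit_stratum(rows, rng, truth, f"COMBO-{cell}", cell, time_points, treatments)
    return _finish(rows, truth, seed)


def simulate_deconvolution(
    truth: GroundTruth,
    plan: DeconvolutionPlan,
    time_points: Sequence[float] = (72.0,),
    seed: int = 0,
) -> SimulatedScreen:
    """Pairwise follow-up plate for one hit pool."""
    if plan.size == 0:
        raise InvalidInputError("deconvolution plan is empty")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for cell in truth.cell_lines:
        treatments = [
            (
                k,
                truth.expected_normalized(cell, (p.first, p.second)),
                {
                    "compound_a": p.first,
                    "compound_b": p.second,
                    "dose_uM": plan.dose_uM,
                    "source_well": plan.source_well,
                },
            )
            for k, p in enumerate(plan.pairs)
        ]
        _emit_stratum(
            rows, rng, truth, f"DECON-{plan.source_well}-{cell}", cell, time_points, treatments
        )
    return _finish(rows, truth, seed)


def _fa_for_target_ci(
    d1: float, d2: float, fit1: DoseResponseCurve, fit2: DoseResponseCurve, target_ci: float
) -> float:
    """Combined fa making the dose pair score exactly ``target_ci``.

    CI(fa) = d1/Dx1(fa) + d2/Dx2(fa) is strictly decreasing in fa (the
    effect doses grow with fa), so the root is found by bisection.
    """
    lo, hi = 1e-9, 1.0 - 1e-9

    def ci_at(fa: float) -> float:
        return d1 / fit1.effect_dose(fa) + d2 / fit2.effect_dose(fa)

    if ci_at(lo) < target_ci or ci_at(hi) > target_ci:
        raise InvalidInputError(
            f"target CI {target_ci} unreachable for doses ({d1}, {d2}) under these fits"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ci_at(mid) > target_ci:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dose_matrix(
    fit1: DoseResponseCurve,
    fit2: DoseResponseCurve,
    d1_doses: Sequence[float],
    d2_doses: Sequence[float],
    target_ci: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Checkerboard (d1, d2, fa) data with a known interaction strength.

    Each cell's combined fraction affected is chosen so the dose pair's
    combination index equals ``target_ci`` exactly (1 = additivity, < 1 a
    planted synergy, > 1 antagonism), then optionally perturbed with
    Gaussian noise on fa (clipped into (0, 1)).  Serves as the round-trip
    oracle for CI estimation.
    """
    if target_ci <= 0:
        raise InvalidInputError("target CI must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d1 in d1_doses:
        for d2 in d2_doses:
            fa = _fa_for_target_ci(float(d1), float(d2), fit1, fit2, target_ci)
            if noise_sd > 0:
                fa = float(np.clip(fa + rng.normal(0.0, noise_sd), 1e-4, 1 - 1e-4))
            rows.append({"d1_uM": float(d1), "d2_uM": float(d2), "fa": fa})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified simulation setting: library + ground truth.

    ``pool_size`` is the recommended compounds-per-well for a pooled
    screen over this library (it must leave several wells in the design,
    or the mean + k.SD hit call has no background population).
    """

    name: str
    description: str
    library: CompoundLibrary
    truth: GroundTruth
    pool_size: int = 10


#: the ten compounds of the canonical synergy-pool scenario; the planted
#: synergistic pair is ABT-737 (Bcl-2 family inhibitor) + Purvalanol A
#: (CDK inhibitor)
POOL10_COMPOUNDS = (
    "ABT-737",
    "Nutlin-3",
    "RG-7112",
    "MG-101",
    "SU9516",
    "MI-773",
    "SecinH3",
    "LY2409881",
    "Akti-1/2",
    "Purvalanol A",
)

SYNERGY_PAIR = ("ABT-737", "Purvalanol A")

#: default screen-scale library: 80 compounds, three AML-like cell lines
DEFAULT_N = 80
DEFAULT_CELL_LINES = ("MV4-11", "CMK", "Kasumi-1")

#: seven-line validation panel; synergy is planted only in the two lines
#: carrying both a FLT3-ITD and an MLL rearrangement
PANEL7_CELL_LINES = ("MV4-11", "MOLM-13", "THP-1", "PL-21", "Kasumi-1", "CMS", "CMK")
FLT3ITD_MLLR_LINES = ("MV4-11", "MOLM-13")


def _default_library() -> CompoundLibrary:
    return CompoundLibrary([f"C{i:03d}" for i in range(1, DEFAULT_N + 1)])


def _default_controls(cell_lines: Iterable[str]) -> dict[str, float]:
    return {
        cell: CONTROL_LEVEL_LOW if cell == "CMK" else CONTROL_LEVEL_HIGH
        for cell in cell_lines
    }


def scenario_library() -> dict[str, Scenario]:
    """Documented simulation presets, keyed by name.

    - ``null``: no planted effects anywhere.
    - ``singles_only``: five toxic singles (multiplier 3.0) among 80
      compounds, identical in all three cell lines.
    - ``additive_only``: six moderately toxic singles (multiplier 1.8);
      any well pooling several of them responds additively.
    - ``well155_like``: a ten-compound pool of near-inert singles hiding
      one strongly synergistic pair (boost 2.5) in the MV4-11-like line
      and one weakly synergistic pair in the CMK-like line.
    - ``flt3itd_mllr``: the identified pair screened across a seven-line
      panel; the synergy boost is present in exactly the two lines
      carrying both lesions.
    """
    scenarios: dict[str, Scenario] = {}

    lib80 = _default_library()
    scenarios["null"] = Scenario(
        "null",
        "no planted effects; every well is inert",
        lib80,
        GroundTruth(
            cell_lines=DEFAULT_CELL_LINES,
            control_levels=_default_controls(DEFAULT_CELL_LINES),
        ),
    )

    toxins5 = ("C005", "C017", "C033", "C052", "C070")
    scenarios["singles_only"] = Scenario(
        "singles_only",
        "five toxic single agents (multiplier 3.0) among 80 compounds",
        lib80,
        GroundTruth(
            cell_lines=DEFAULT_CELL_LINES,
            toxic_singles={cell: {c: 3.0 for c in toxins5} for cell in DEFAULT_CELL_LINES},
            control_levels=_default_controls(DEFAULT_CELL_LINES),
        ),
    )

    toxins6 = ("C003", "C011", "C024", "C041", "C058", "C066")
    scenarios["additive_only"] = Scenario(
        "additive_only",
        "six moderate toxins (multiplier 1.8); pooled effects are purely additive",
        lib80,
        GroundTruth(
            cell_lines=DEFAULT_CELL_LINES,
            toxic_singles={cell: {c: 1.8 for c in toxins6} for cell in DEFAULT_CELL_LINES},
            control_levels=_default_controls(DEFAULT_CELL_LINES),
        ),
    )

    pool_lines = ("MV4-11", "CMK")
    # the ten named pool compounds embedded in an otherwise inert
    # 80-compound library, so pooled wells have a realistic background
    # population for the mean + 3SD hit call
    lib_well155 = CompoundLibrary(
        POOL10_COMPOUNDS + tuple(f"C{i:03d}" for i in range(11, DEFAULT_N + 1))
    )
    scenarios["well155_like"] = Scenario(
        "well155_like",
        "ten near-inert compounds hiding one synergistic pair, among 80",
        lib_well155,
        GroundTruth(
            cell_lines=pool_lines,
            toxic_singles={
                # faint single-agent activity well below the 2x hit line
                "MV4-11": {"ABT-737": 1.15, "SU9516": 1.1},
                "CMK": {"MG-101": 1.1},
            },
            synergistic_pairs={
                "MV4-11": {SYNERGY_PAIR: 2.5},
                "CMK": {("MG-101", "SU9516"): 0.25},
            },
            control_levels=_default_controls(pool_lines),
        ),
    )

    scenarios["flt3itd_mllr"] = Scenario(
        "flt3itd_mllr",
        "identified pair vs a seven-line panel; synergy only with FLT3-ITD + MLLr",
        CompoundLibrary(SYNERGY_PAIR),
        GroundTruth(
            cell_lines=PANEL7_CELL_LINES,
            toxic_singles={cell: {"ABT-737": 1.1} for cell in PANEL7_CELL_LINES},
            synergistic_pairs={
                cell: {SYNERGY_PAIR: 2.5} for cell in FLT3ITD_MLLR_LINES
            },
            control_levels=_default_controls(PANEL7_CELL_LINES),
        ),
        pool_size=2,
    )
    return scenarios


def get_scenario(name: str) -> Scenario:
    """Look up a preset by name; unknown names raise InvalidInputError."""
    scenarios = scenario_library()
    if name not in scenarios:
        raise InvalidInputError(
            f"unknown scenario {name!r}; available: {sorted(scenarios)}"
        )
    return scenarios[name]
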
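"""Median-effect dose-response fitting and combination-index synergy calls.

The median-effect model fa/fu = (D/Dm)^m (fa = fraction affected,
fu = 1 - fa, Dm = dose of half-maximal effect, m = sigmoidicity) is linear
after the logit/log transform, so single-agent curves are fitted by least
squares on log(fa/(1-fa)) vs log(D).  For a dose pair (d1, d2) producing a
combined fraction affected fa, the combination index is

    CI = d1/Dx1 + d2/Dx2,    Dx_i = Dm_i * (fa/(1-fa))^(1/m_i)

(the mutually exclusive form), i.e. each observed dose over the dose of
that drug alone that would produce the same effect.  CI < 1 flags synergy,
CI = 1 additivity and CI > 1 antagonism; because measured CIs never land
exactly on 1, calls use a configurable additive band (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "DoseResponseCurve",
    "CombinationIndexResult",
    "fraction_affected",
    "fit_median_effect",
    "combination_index",
    "dose_matrix_summary",
]

FA_CLIP = 1e-3  # keeps the logit finite on saturated wells
ADDITIVE_BAND = 0.05


def fraction_affected(
    normalized_rfu: float | np.ndarray,
    max_kill_rfu: float,
    eps: float = FA_CLIP,
) -> float | np.ndarray:
    """Map a vehicle-normalized cytotoxicity signal onto (0, 1).

    A cytotoxicity readout grows with cell death, so the vehicle level (1)
    anchors fa ~ 0 and the signal of a maximally killed well
    (``max_kill_rfu``, typically a cytotoxic-control well) anchors fa ~ 1;
    values are mapped linearly between the anchors and clipped to
    [eps, 1 - eps].
    """
    if max_kill_rfu <= 1:
        raise InvalidInputError(
            f"max_kill_rfu must exceed the vehicle level 1, got {max_kill_rfu}"
        )
    value = np.asarray(normalized_rfu, dtype=float)
    if (value < 0).any():
        raise InvalidInputError("normalized RFU must be non-negative")
    fa = np.clip((value - 1.0) / (max_kill_rfu - 1.0), eps, 1.0 - eps)
    return float(fa) if np.isscalar(normalized_rfu) else fa


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted median-effect parameters of one compound."""

    compound_id: str
    Dm_uM: float
    m_slope: float
    r_squared: float
    dose_range_uM: tuple[float, float]

    def effect_dose(self, fa: float) -> float:
        """Dose producing fraction affected ``fa`` under the fitted model."""
        if not 0 < fa < 1:
            raise InvalidInputError(f"fa must lie in (0, 1), got {fa}")
        return self.Dm_uM * (fa / (1.0 - fa)) ** (1.0 / self.m_slope)

    def predict_fa(self, dose_uM: float) -> float:
        r = (dose_uM / self.Dm_uM) ** self.m_slope
        return r / (1.0 + r)


def fit_median_effect(
    points: Sequence[tuple[float, float]],
    compound_id: str = "",
    eps: float = FA_CLIP,
) -> DoseResponseCurve:
    """Least-squares median-effect fit of (dose µM, fraction affected) points.

    Regresses log(fa/(1-fa)) on log(dose); the slope is m and the
    intercept -m*log(Dm).  fa values are clipped into [eps, 1-eps] before
    the transform.
    """
    pts = [(float(d), float(fa)) for d, fa in points]
    if any(d <= 0 for d, _ in pts):
        raise InvalidInputError("doses must be positive")
    doses = np.array([d for d, _ in pts])
    fa = np.clip(np.array([f for _, f in pts]), eps, 1.0 - eps)
    if len(set(doses.tolist())) < 2:
        raise InsufficientDataError(
            f"median-effect fit needs >= 2 distinct doses, got {len(set(doses.tolist()))}"
        )
    x = np.log(doses)
    y = np.log(fa / (1.0 - fa))
    if np.ptp(x) == 0:
        raise InsufficientDataError("zero variance in log-dose; fit is degenerate")
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m == 0:
        raise InsufficientDataError("flat dose-response; median-effect slope is zero")
    Dm = float(np.exp(-res.intercept / m))
    return DoseResponseCurve(
        compound_id=compound_id,
        Dm_uM=Dm,
        m_slope=m,
        r_squared=float(res.rvalue**2),
        dose_range_uM=(float(doses.min()), float(doses.max())),
    )


@dataclass(frozen=True)
class CombinationIndexResult:
    """Combination index of one dose pair at its observed combined effect."""

    d1_uM: float
    d2_uM: float
    fa_combo: float
    ci: float
    classification: str  # synergistic | additive | antagonistic
    extrapolated: bool = False


def _classify(ci: float, delta: float) -> str:
    if ci < 1.0 - delta:
        return "synergistic"
    if ci > 1.0 + delta:
        return "antagonistic"
    return "additive"


def combination_index(
    d1_uM: float,
    d2_uM: float,
    fit1: DoseResponseCurve,
    fit2: DoseResponseCurve,
    fa_combo: float,
    delta: float = ADDITIVE_BAND,
) -> CombinationIndexResult:
    """Mutually exclusive Chou-Talalay CI for one dose pair.

    ``fa_combo`` is the fraction affected observed with both drugs
    present; CI compares the applied doses with the single-agent doses
    that would achieve the same fa under each fitted curve.
    """
    if not 0 < fa_combo < 1:
        raise InvalidInputError(f"fa_combo must lie in (0, 1), got {fa_combo}")
    if d1_uM < 0 or d2_uM < 0 or d1_uM + d2_uM == 0:
        raise InvalidInputError("doses must be non-negative with a positive total")
    if delta < 0:
        raise InvalidInputError(f"additive band must be non-negative, got {delta}")
    ci = d1_uM / fit1.effect_dose(fa_combo) + d2_uM / fit2.effect_dose(fa_combo)
    return CombinationIndexResult(
        d1_uM=float(d1_uM),
        d2_uM=float(d2_uM),
        fa_combo=float(fa_combo),
        ci=float(ci),
        classification=_classify(float(ci), delta),
    )


def dose_matrix_summary(
    matrix: pd.DataFrame,
    fit1: DoseResponseCurve,
    fit2: DoseResponseCurve,
    delta: float = ADDITIVE_BAND,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """CI and class for every cell of a checkerboard dose matrix.

    ``matrix`` needs columns ``d1_uM, d2_uM, fa``.  Cells whose dose falls
    outside either compound's fitted dose range are still scored but
    flagged ``extrapolated``.  Returns the annotated table plus summary
    counts per class.
    """
    required = {"d1_uM", "d2_uM", "fa"}
    if matrix is None or len(matrix) == 0:
        raise InvalidInputError("dose matrix is empty")
    if not required <= set(matrix.columns):
        raise InvalidInputError(f"dose matrix needs columns {sorted(required)}")
    out = matrix.copy()
    results = []
    for _, row in out.iterrows():
        res = combination_index(row["d1_uM"], row["d2_uM"], fit1, fit2, row["fa"], delta)
        lo1, hi1 = fit1.dose_range_uM
        lo2, hi2 = fit2.dose_range_uM
        extrap = not (lo1 <= row["d1_uM"] <= hi1 and lo2 <= row["d2_uM"] <= hi2)
        results.append((res.ci, res.classification, extrap))
    out["ci"] = [r[0] for r in results]
    out["class"] = [r[1] for r in results]
    out["extrapolated"] = [r[2] for r in results]
    counts = out["class"].value_counts().to_dict()
    summary = {k: int(counts.get(k, 0)) for k in ("synergistic", "additive", "antagonistic")}
    return out, summary
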
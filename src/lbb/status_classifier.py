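"""Stock-status classification, indicator flags and management advice.

B/BMSY maps onto five categories with left-closed intervals:
healthy (>= 1.0), slightly overfished [0.8, 1.0), overfished
[0.5, 0.8), grossly overfished [0.2, 0.5), collapsed (< 0.2).
Auxiliary flags: F/M > 1 marks overfishing, B/B0 < 0.5 depletion,
L_mean/L_opt < 1 truncated size structure, L_c/L_c_opt < 1 capture of
undersized fish, and L_95th/L_inf >= 0.9 the continued presence of
large individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .reference_points import ReferencePoints

__all__ = [
    "STATUS_LABELS",
    "IndicatorFlags",
    "AssessmentRecord",
    "classify_status",
    "indicator_flags",
    "recommendations",
    "compare_years",
]

#: category labels from best to worst
STATUS_LABELS = (
    "healthy",
    "slightly overfished",
    "overfished",
    "grossly overfished",
    "collapsed",
)

#: left-closed lower bound of each category on B/BMSY
_STATUS_BOUNDS = ((1.0, "healthy"), (0.8, "slightly overfished"),
                  (0.5, "overfished"), (0.2, "grossly overfished"))


def classify_status(b_over_bmsy: float) -> str:
    """Five-category stock status from B/BMSY (intervals closed on the left)."""
    if b_over_bmsy < 0 or not math.isfinite(b_over_bmsy):
        raise ValueError(f"b_over_bmsy must be finite and >= 0, got {b_over_bmsy}")
    for lower, label in _STATUS_BOUNDS:
        if b_over_bmsy >= lower:
            return label
    return "collapsed"


@dataclass(frozen=True)
class IndicatorFlags:
    overfishing: bool  # F/M > 1
    depleted: bool  # B/B0 < 0.5
    truncated_sizes: bool  # L_mean/L_opt < 1
    undersized_capture: bool  # L_c/L_c_opt < 1
    large_fish_present: bool  # L_95th/L_inf >= 0.9


def indicator_flags(estimates: ReferencePoints) -> IndicatorFlags:
    """Boolean stock-condition flags; strict inequalities except the
    large-fish flag, where 'approaching or exceeding 0.9' is >= 0.9."""
    for name in ("f_over_m", "b_over_b0", "ratio_lmean_lopt", "ratio_lc_lcopt",
                 "ratio_l95_linf"):
        v = getattr(estimates, name)
        if v is None or not math.isfinite(v):
            raise ValueError(f"indicator_flags requires a finite {name}")
    return IndicatorFlags(
        overfishing=estimates.f_over_m > 1.0,
        depleted=estimates.b_over_b0 < 0.5,
        truncated_sizes=estimates.ratio_lmean_lopt < 1.0,
        undersized_capture=estimates.ratio_lc_lcopt < 1.0,
        large_fish_present=estimates.ratio_l95_linf >= 0.9,
    )


def recommendations(estimates: ReferencePoints,
                    bmsy_over_b0: float | None = None) -> list[str]:
    """Management advice: reduce catch while biomass sits below the MSY
    level (B/B0 < BMSY/B0), raise the size at first capture while L_c is
    below L_c_opt."""
    if bmsy_over_b0 is None:
        bmsy_over_b0 = estimates.bmsy_over_b0
    recs = []
    if estimates.b_over_b0 < bmsy_over_b0:
        recs.append("reduce_catch")
    if estimates.l_c_cm < estimates.l_c_opt_cm:
        recs.append("increase_size_at_first_capture")
    return recs


@dataclass(frozen=True)
class AssessmentRecord:
    """One assessed species-year: estimates, status, flags, advice."""

    species_id: str
    year: int
    estimates: ReferencePoints
    status_label: str = field(init=False)
    flags: IndicatorFlags = field(init=False)
    advice: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "status_label", classify_status(self.estimates.b_over_bmsy))
        object.__setattr__(self, "flags", indicator_flags(self.estimates))
        object.__setattr__(self, "advice", tuple(recommendations(self.estimates)))

    def to_row(self) -> dict:
        e = self.estimates
        return {
            "species": self.species_id,
            "year": self.year,
            "b_over_b0": e.b_over_b0,
            "b_over_bmsy": e.b_over_bmsy,
            "f_over_m": e.f_over_m,
            "z_over_k": e.z_over_k,
            "yr_prime": e.yield_per_recruit,
            "e": e.exploitation_rate_e,
            "linf_cm": e.l_inf_cm,
            "lc_over_lcopt": e.ratio_lc_lcopt,
            "lmean_over_lopt": e.ratio_lmean_lopt,
            "l95_over_linf": e.ratio_l95_linf,
            "stock_status": self.status_label,
            "advice": ";".join(self.advice),
        }


def compare_years(records_from: list[AssessmentRecord],
                  records_to: list[AssessmentRecord]) -> pd.DataFrame:
    """Per-species status transition and F/M direction between two surveys."""
    by_sp_from = {r.species_id: r for r in records_from}
    by_sp_to = {r.species_id: r for r in records_to}
    if set(by_sp_from) != set(by_sp_to):
        raise ValueError("the two record sets must cover the same species")
    rows = []
    for sp in sorted(by_sp_from):
        a, b = by_sp_from[sp], by_sp_to[sp]
        if b.estimates.f_over_m > a.estimates.f_over_m:
            direction = "increase"
        elif b.estimates.f_over_m < a.estimates.f_over_m:
            direction = "decrease"
        else:
            direction = "unchanged"
        rows.append({
            "species": sp,
            "year_from": a.year,
            "year_to": b.year,
            "status_from": a.status_label,
            "status_to": b.status_label,
            "status_change": "unchanged" if a.status_label == b.status_label else (
                "improved"
                if STATUS_LABELS.index(b.status_label) < STATUS_LABELS.index(a.status_label)
                else "worsened"
            ),
            "f_over_m_direction": direction,
        })
    return pd.DataFrame(rows)
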
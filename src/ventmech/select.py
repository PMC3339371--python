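"""PEEP-selection rules over a titration summary.

Two families of rules operate on a per-PEEP metric curve (constant elastance
``e_lung``, per-level median dynamic elastance ``edrs_median``, or
``edrs_area``):

* **minimum** -- the PEEP of the curve's minimum (maximum compliance); ties
  resolve toward the *lowest* PEEP, minimising applied pressure;
* **inflection** -- the point of diminishing returns: on the descending limb
  of the curve, the PEEP interval where the metric crosses 110% down to 105%
  of its minimum, found by linear interpolation in PEEP.  The interval's
  upper bound therefore never exceeds the argmin PEEP.

The titration grid is data: selections operate on whatever PEEP values the
summary carries (grids need not be multiples of 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import TitrationSummary

__all__ = [
    "SelectionResult",
    "MissingMetricError",
    "select_minimum",
    "select_inflection",
    "select_all",
    "selections_to_frame",
]

log = logging.getLogger(__name__)

#: metric name -> method label for minimum-based selection
_MIN_LABELS = {
    "e_lung": "min_elung",
    "edrs_median": "min_edrs",
    "edrs_min": "min_edrs_trajectory",
    "edrs_area": "min_edrs_area",
}
_INFLECTION_LABELS = {
    "e_lung": "inflection_elung",
    "edrs_area": "inflection_edrs_area",
    "edrs_median": "inflection_edrs",
}


class MissingMetricError(ValueError):
    """A requested metric is absent at one or more PEEP levels."""


@dataclass
class SelectionResult:
    """Outcome of one selection rule.

    Point selections carry ``peep``; the inflection rule carries
    ``peep_interval`` (lower bound = 110% crossing, upper = 105% crossing).
    ``basis_value`` is the metric minimum the rule was anchored to.
    """

    method: str
    peep: float | None = None
    peep_interval: tuple[float, float] | None = None
    basis_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.peep_interval is not None:
            lo, hi = self.peep_interval
            if lo > hi:
                raise ValueError(f"interval lower {lo} > upper {hi}")


def _metric_curve(summary: TitrationSummary, metric: str) -> tuple[np.ndarray, np.ndarray]:
    if len(summary) < 2:
        raise ValueError("selection rules need at least 2 PEEP levels")
    values = summary.metric_values(metric)
    if np.isnan(values).any():
        peep = summary.peeps[int(np.argmax(np.isnan(values)))]
        raise MissingMetricError(f"metric '{metric}' missing at PEEP {peep:g}")
    return summary.peeps, values


def select_minimum(summary: TitrationSummary, metric: str = "e_lung") -> SelectionResult:
    """PEEP at the minimum of the metric curve; ties break to the lowest PEEP."""
    if metric not in _MIN_LABELS:
        raise ValueError(f"metric must be one of {sorted(_MIN_LABELS)}")
    peeps, values = _metric_curve(summary, metric)
    idx = int(np.argmin(values))  # first occurrence = lowest PEEP on ties
    return SelectionResult(
        method=_MIN_LABELS[metric],
        peep=float(peeps[idx]),
        basis_value=float(values[idx]),
    )


def select_inflection(
    summary: TitrationSummary,
    metric: str = "e_lung",
    band: tuple[float, float] = (1.05, 1.10),
) -> SelectionResult:
    """PEEP interval where the descending limb enters 105--110% of the minimum.

    Crossings are linearly interpolated in PEEP between grid levels.  When the
    limb is non-monotone the last downward crossing before the argmin is used.
    A minimum at the first grid level yields a degenerate interval at that
    PEEP (with a warning).
    """
    if metric not in _INFLECTION_LABELS:
        raise ValueError(f"metric must be one of {sorted(_INFLECTION_LABELS)}")
    band_lo, band_hi = band
    if not (1.0 < band_lo < band_hi):
        raise ValueError(f"band must satisfy 1 < lo < hi, got {band}")
    peeps, values = _metric_curve(summary, metric)
    i_min = int(np.argmin(values))
    vmin = float(values[i_min])
    label = _INFLECTION_LABELS[metric]
    if i_min == 0:
        log.warning(
            "metric '%s' is minimal at the first PEEP level; inflection "
            "interval degenerates to (%g, %g)", metric, peeps[0], peeps[0],
        )
        return SelectionResult(
            method=label,
            peep_interval=(float(peeps[0]), float(peeps[0])),
            basis_value=vmin,
        )

    def last_downward_crossing(threshold: float) -> float:
        for i in range(i_min - 1, -1, -1):
            v0, v1 = values[i], values[i + 1]
            if v0 >= threshold > v1 and v0 != v1:
                frac = (v0 - threshold) / (v0 - v1)
                return float(peeps[i] + (peeps[i + 1] - peeps[i]) * frac)
        log.warning(
            "metric never exceeds %.4g on the descending limb; crossing "
            "clamped to PEEP %g", threshold, peeps[0],
        )
        return float(peeps[0])

    lo = last_downward_crossing(band_hi * vmin)
    hi = last_downward_crossing(band_lo * vmin)
    return SelectionResult(
        method=label, peep_interval=(lo, hi), basis_value=vmin
    )


def select_all(
    summary: TitrationSummary,
    band: tuple[float, float] = (1.05, 1.10),
    clinical_peep: float | None = None,
) -> list[SelectionResult]:
    """Apply every selection rule; one result per method.

    An optional clinician-entered PEEP is passed through as a ``clinical``
    row for side-by-side comparison.
    """
    results = [
        select_minimum(summary, "e_lung"),
        select_minimum(summary, "edrs_median"),
        select_minimum(summary, "edrs_area"),
        select_inflection(summary, "e_lung", band=band),
        select_inflection(summary, "edrs_area", band=band),
    ]
    if clinical_peep is not None:
        results.insert(0, SelectionResult(method="clinical", peep=float(clinical_peep)))
    return results


def selections_to_frame(
    results: list[SelectionResult], patient_id: str = ""
) -> pd.DataFrame:
    """Tabulate selection results (CSV shape: one row per method)."""
    rows = []
    for r in results:
        lo, hi = r.peep_interval if r.peep_interval is not None else (np.nan, np.nan)
        rows.append(
            {
                "patient": patient_id,
                "method": r.method,
                "peep": np.nan if r.peep is None else r.peep,
                "peep_lo": lo,
                "peep_hi": hi,
                "basis_value": r.basis_value,
            }
        )
    return pd.DataFrame(rows)
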
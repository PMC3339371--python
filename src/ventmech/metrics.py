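"""Per-breath and per-PEEP metrics: E_drs Area, work of breathing, summaries.

E_drs Area is the time integral of the dynamic elastance over one
inspiration (cmH2O.s/l); it is proportional to the elastic work of breathing
and so condenses a whole within-breath elastance trajectory into one number
per PEEP level.

With the offset pressure taken as atmospheric (P0 = 0) the per-sample work of
breathing decomposes exactly into elastic and resistive parts:

    WOB   = Paw * V = E * V**2 + R * Q * V = WOB_E + WOB_R
    Edrs(t) = WOB_E(t) / V(t)**2

Summary containers mirror the shape of a PEEP titration report: one
``PEEPLevelSummary`` per level, ordered into a ``TitrationSummary`` per
patient, which is what the selection rules consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .model import ConstantElastanceResults, DynamicElastanceResults
from .waveforms import Breath

__all__ = [
    "PEEPLevelSummary",
    "TitrationSummary",
    "WOBDecomposition",
    "edrs_area",
    "wob_decomposition",
    "summarize_level",
    "pearson",
    "cross_patient_median",
    "rank_sum_exact",
    "ZeroVarianceError",
]

log = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Correlation is undefined for a constant series."""


# --- per-PEEP containers ---------------------------------------------------


@dataclass
class PEEPLevelSummary:
    """Metrics for one PEEP level of a titration.

    ``edrs_median``/``edrs_iqr`` pool every dynamic-elastance window of every
    breath at the level; ``e_lung`` and ``edrs_area`` are medians across
    breaths.  ``edrs_min`` (minimum over the pooled within-breath trajectory)
    supports the trajectory-minimum selection mode; it is None when the
    summary was built from a pre-aggregated table.
    """

    peep: float
    e_lung: float
    edrs_median: float
    edrs_iqr: tuple[float, float] = (float("nan"), float("nan"))
    edrs_area: float = float("nan")
    wob_e: float = float("nan")
    wob_r: float = float("nan")
    n_breaths: int = 1
    edrs_min: float | None = None
    ape_median: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_breaths < 1:
            raise ValueError("n_breaths must be >= 1")
        lo, hi = self.edrs_iqr
        if not (math.isnan(lo) or math.isnan(hi)):
            if not (lo <= self.edrs_median <= hi):
                raise ValueError(
                    f"IQR ({lo}, {hi}) inconsistent with median {self.edrs_median}"
                )


@dataclass
class TitrationSummary:
    """Ordered per-PEEP summaries for one patient's titration."""

    patient_id: str
    levels: list[PEEPLevelSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        peeps = [lv.peep for lv in self.levels]
        if any(b <= a for a, b in zip(peeps, peeps[1:])):
            raise ValueError(f"PEEP levels must be strictly increasing: {peeps}")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def peeps(self) -> np.ndarray:
        return np.array([lv.peep for lv in self.levels])

    def metric_values(self, metric: str) -> np.ndarray:
        return np.array(
            [np.nan if getattr(lv, metric) is None else getattr(lv, metric)
             for lv in self.levels],
            dtype=float,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, patient_id: str = "") -> "TitrationSummary":
        """Build a summary from a pre-aggregated per-PEEP table.

        Expected columns: ``peep`` plus any of ``e_lung``, ``edrs_median``,
        ``edrs_area`` (missing metrics become NaN).
        """
        if "peep" not in df.columns:
            raise ValueError("summary table must have a 'peep' column")
        df = df.sort_values("peep")
        levels = []
        for _, row in df.iterrows():
            levels.append(
                PEEPLevelSummary(
                    peep=float(row["peep"]),
                    e_lung=float(row.get("e_lung", np.nan)),
                    edrs_median=float(row.get("edrs_median", np.nan)),
                    edrs_area=float(row.get("edrs_area", np.nan)),
                )
            )
        return cls(patient_id=str(patient_id), levels=levels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": self.patient_id,
                "peep": [lv.peep for lv in self.levels],
                "e_lung": [lv.e_lung for lv in self.levels],
                "edrs_median": [lv.edrs_median for lv in self.levels],
                "edrs_q1": [lv.edrs_iqr[0] for lv in self.levels],
                "edrs_q3": [lv.edrs_iqr[1] for lv in self.levels],
                "edrs_area": [lv.edrs_area for lv in self.levels],
                "ape_median": [lv.ape_median for lv in self.levels],
            }
        )

    def plot_metric(self, metric: str = "e_lung", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.peeps, self.metric_values(metric), marker="o")
        ax.set_xlabel("PEEP (cmH2O)")
        ax.set_ylabel(metric)
        ax.set_title(f"patient {self.patient_id}")
        return ax


# --- operations ------------------------------------------------------------


def edrs_area(series: DynamicElastanceResults) -> float:
    """Time integral of E_drs over the inspiration, cmH2O.s/l.

    Each retained window contributes value x cell duration (midpoint rule on
    the window grid); a single window degenerates to the rectangle rule.
    """
    if len(series) == 0:
        raise ValueError("cannot integrate an empty dynamic-elastance series")
    if len(series) == 1:
        log.info("single-window series: E_drs area uses the rectangle rule")
    return float(np.sum(series.edrs * series.durations))


@dataclass
class WOBDecomposition:
    """Per-sample work-of-breathing decomposition over one inspiration.

    All series are Paw x V products in cmH2O.l; totals are the
    end-inspiration values.  The identity ``wob = wob_e + wob_r`` holds per
    sample by construction (P0 = 0).
    """

    time: np.ndarray
    wob: np.ndarray
    wob_e: np.ndarray
    wob_r: np.ndarray

    @property
    def total_wob(self) -> float:
        return float(self.wob[-1])

    @property
    def total_wob_e(self) -> float:
        return float(self.wob_e[-1])

    @property
    def total_wob_r(self) -> float:
        return float(self.wob_r[-1])


def wob_decomposition(breath: Breath, fit) -> WOBDecomposition:
    """Elastic/resistive work decomposition, with P0 treated as atmospheric.

    ``fit`` may be a constant fit (scalar elastance) or a dynamic fit
    (piecewise-constant elastance over its retained windows; samples outside
    retained windows are excluded).
    """
    v, q, t = breath.volume_insp, breath.flow_insp, breath.time_insp
    if isinstance(fit, ConstantElastanceResults):
        e = np.full(breath.n_insp, fit.e_lung)
        r = fit.r_lung
        mask = np.ones(breath.n_insp, dtype=bool)
    elif isinstance(fit, DynamicElastanceResults):
        e = np.full(breath.n_insp, np.nan)
        for (a, z), ew in zip(fit.window_slices, fit.edrs):
            e[a:z] = ew
        r = fit.r_lung_used
        mask = ~np.isnan(e)
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    wob_e = e[mask] * v[mask] ** 2
    wob_r = r * q[mask] * v[mask]
    return WOBDecomposition(
        time=t[mask], wob=wob_e + wob_r, wob_e=wob_e, wob_r=wob_r
    )


def summarize_level(
    fits: list[tuple[Breath, ConstantElastanceResults, DynamicElastanceResults]],
    peep: float | None = None,
) -> PEEPLevelSummary:
    """Pool per-breath fits at one PEEP level into a summary row.

    ``edrs_median``/IQR pool all windows of all breaths; ``e_lung``,
    ``edrs_area`` and the work totals are medians across breaths.
    """
    if not fits:
        raise ValueError("at least one breath is required")
    if peep is None:
        peep = fits[0][0].recording.peep_set
    pooled = np.concatenate([dyn.edrs for _, _, dyn in fits])
    q1, med, q3 = np.percentile(pooled, [25, 50, 75])
    areas = [edrs_area(dyn) for _, _, dyn in fits]
    # work totals need the waveforms; skip them for pre-aggregated inputs
    wobs = [wob_decomposition(b, dyn) for b, _, dyn in fits if b is not None]
    return PEEPLevelSummary(
        peep=float(peep),
        e_lung=float(np.median([c.e_lung for _, c, _ in fits])),
        edrs_median=float(med),
        edrs_iqr=(float(q1), float(q3)),
        edrs_area=float(np.median(areas)),
        wob_e=float(np.median([w.total_wob_e for w in wobs])) if wobs else float("nan"),
        wob_r=float(np.median([w.total_wob_r for w in wobs])) if wobs else float("nan"),
        n_breaths=len(fits),
        edrs_min=float(pooled.min()),
        ape_median=float(np.median([dyn.ape_median for _, _, dyn in fits])),
    )


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


# --- cross-patient aggregation --------------------------------------------

_QUARTILE_METHODS = {"linear", "hazen"}


def _order_position(n: int, p: Fraction, method: str) -> Fraction:
    """0-based fractional order-statistic position for quantile ``p``."""
    if method == "linear":
        return (n - 1) * p
    # Hazen convention: position n*p + 0.5, 1-based
    pos = n * p + Fraction(1, 2) - 1
    return min(max(pos, Fraction(0)), Fraction(n - 1))


def cross_patient_median(
    values,
    ndigits: int | None = None,
    method: str = "linear",
) -> tuple[float, tuple[float, float]]:
    """Median and quartiles across patients.

    ``method`` selects the quartile convention: ``"linear"`` interpolates
    between order statistics, ``"hazen"`` uses positions n*p + 0.5 (the
    convention that reproduces typical clinical-report IQRs).  With
    ``ndigits`` the computation runs in exact decimal arithmetic and the
    results are rounded half-up to that many digits, the way a report table
    prints them.
    """
    vals = list(values)
    if not vals:
        raise ValueError("at least one value is required")
    if method not in _QUARTILE_METHODS:
        raise ValueError(f"method must be one of {_QUARTILE_METHODS}")
    n = len(vals)

    def _quantile_exact(ds, p: Fraction) -> Decimal:
        pos = _order_position(n, p, method)
        lo = int(pos)
        frac = pos - lo
        if frac == 0 or lo + 1 >= n:
            return ds[lo]
        return ds[lo] + (ds[lo + 1] - ds[lo]) * Decimal(frac.numerator) / Decimal(
            frac.denominator
        )

    if ndigits is not None:
        ds = sorted(Decimal(repr(float(v))) for v in vals)
        quantum = Decimal(1).scaleb(-ndigits)
        out = [
            float(_quantile_exact(ds, Fraction(k, 4)).quantize(quantum, ROUND_HALF_UP))
            for k in (2, 1, 3)
        ]
        return out[0], (out[1], out[2])

    arr = np.sort(np.asarray(vals, dtype=float))

    def _quantile(p: Fraction) -> float:
        pos = _order_position(n, p, method)
        lo = int(pos)
        frac = float(pos - lo)
        if frac == 0 or lo + 1 >= n:
            return float(arr[lo])
        return float(arr[lo] + (arr[lo + 1] - arr[lo]) * frac)

    return _quantile(Fraction(1, 2)), (
        _quantile(Fraction(1, 4)),
        _quantile(Fraction(3, 4)),
    )


def rank_sum_exact(x, y) -> float:
    """Exact two-sided rank-sum (Mann-Whitney) p-value for two small groups."""
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    )
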
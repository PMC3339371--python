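"""Single-compartment lung model identification.

The model relates airway pressure to volume and flow during a passive
(volume-controlled, no spontaneous effort) inspiration:

    Paw(t) = E * V(t) + R * Q(t) + P0            (constant elastance)
    Paw(t) = Edrs(t) * V(t) + R * Q(t) + P0      (dynamic elastance)

with E (cmH2O/l) the lung elastance, R (cmH2O.s/l) the airway resistance and
P0 (cmH2O) the offset pressure, taken as the measured PEEP by default.

Identification uses the integral-based method: integrating the model from the
inspiration onset t0 to every sample ti yields, per sample, one linear
equation

    int_{t0}^{ti} Paw dt = E int V dt + R int Q dt + P0 (ti - t0)

and the overdetermined system is solved by ordinary least squares.  Working
with cumulative integrals low-pass filters the data, which makes the method
markedly more noise-robust than regressing on the raw samples.

The dynamic elastance Edrs(t) is identified window-by-window: the inspiration
is partitioned into short consecutive windows (default 0.1 s) and the same
integral equation, with R and P0 fixed, is solved for a single elastance per
window.  Windows where the inflated volume is still close to zero are dropped
to guard the V -> 0 singularity at the onset.

Usage follows the statsmodels pattern::

    model = SingleCompartmentModel(breath)
    const = model.fit()                 # ConstantElastanceResults
    dyn = model.fit_dynamic(window=0.1) # DynamicElastanceResults
    print(const.summary())
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .waveforms import Breath

__all__ = [
    "SingularModelError",
    "EmptySeriesError",
    "SingleCompartmentModel",
    "ConstantElastanceResults",
    "DynamicElastanceResults",
    "identify_constant",
    "identify_dynamic",
    "reconstruct_pressure",
    "absolute_percentage_error",
]

log = logging.getLogger(__name__)

_MIN_INSP_SAMPLES = 10
_RANK_RTOL = 1e-10


class SingularModelError(ValueError):
    """The identification system is rank deficient."""


class EmptySeriesError(ValueError):
    """No dynamic-elastance window survived the volume floor."""


def absolute_percentage_error(measured: np.ndarray, modeled: np.ndarray) -> np.ndarray:
    """Per-sample absolute percentage error, %.

    Samples with non-positive measured pressure are excluded (with a warning)
    since the relative error is undefined there.
    """
    measured = np.asarray(measured, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    ok = measured > 0
    if not ok.all():
        warnings.warn(
            f"{np.count_nonzero(~ok)} sample(s) with non-positive measured "
            "pressure excluded from APE",
            stacklevel=2,
        )
    return np.abs(modeled[ok] - measured[ok]) / measured[ok] * 100.0


def _ape_summary(measured, modeled) -> tuple[float, tuple[float, float]]:
    ape = absolute_percentage_error(measured, modeled)
    if ape.size == 0:
        return float("nan"), (float("nan"), float("nan"))
    q1, med, q3 = np.percentile(ape, [25, 50, 75])
    return float(med), (float(q1), float(q3))


@dataclass
class ConstantElastanceResults:
    """Constant-elastance fit of one breath.

    Attributes
    ----------
    e_lung, r_lung, p0 : float
        Identified elastance (cmH2O/l), resistance (cmH2O.s/l) and offset
        pressure (cmH2O).  ``p0`` is the fixed value unless it was estimated.
    bse : array
        OLS standard errors of the estimated parameters (same order as
        ``params``).
    ape_median, ape_iqr : float, (float, float)
        Median and interquartile range of the absolute percentage error
        between the reconstructed and measured inspiratory pressure.
    """

    breath: Breath
    e_lung: float
    r_lung: float
    p0: float
    p0_estimated: bool
    params: np.ndarray = field(repr=False)
    bse: np.ndarray = field(repr=False)
    ape_median: float = float("nan")
    ape_iqr: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if not self.e_lung > 0:
            log.warning("identified e_lung %.3g is non-positive", self.e_lung)
        if self.r_lung < 0:
            log.warning("identified r_lung %.3g is negative", self.r_lung)

    def predict(self) -> np.ndarray:
        """Model-reconstructed airway pressure over the inspiration."""
        b = self.breath
        return self.e_lung * b.volume_insp + self.r_lung * b.flow_insp + self.p0

    def summary(self) -> str:
        lines = [
            "Single-compartment model, constant elastance",
            "-" * 46,
            f"inspiration samples      {self.breath.n_insp:>10d}",
            f"E_lung  (cmH2O/l)        {self.e_lung:>10.3f}  (se {self.bse[0]:.3f})",
            f"R_lung  (cmH2O.s/l)      {self.r_lung:>10.3f}  (se {self.bse[1]:.3f})",
            f"P0      (cmH2O)          {self.p0:>10.3f}"
            + ("  (estimated)" if self.p0_estimated else "  (fixed)"),
            f"APE median (%)           {self.ape_median:>10.2f}",
            f"APE IQR (%)              [{self.ape_iqr[0]:.2f}, {self.ape_iqr[1]:.2f}]",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured vs reconstructed inspiratory pressure."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.breath.time_insp
        ax.plot(t, self.breath.paw_insp, label="measured", lw=1.2)
        ax.plot(t, self.predict(), label="model", ls="--")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("Paw (cmH2O)")
        ax.legend()
        return ax


@dataclass
class DynamicElastanceResults:
    """Windowed dynamic-elastance fit of one breath.

    ``edrs`` holds one elastance value per retained window, ``times`` the
    window midpoints in seconds since the inspiration onset, ``pressures``
    the mean measured airway pressure per window (for elastance--pressure
    trajectories) and ``durations`` each window's length in seconds.
    """

    breath: Breath
    times: np.ndarray
    edrs: np.ndarray
    pressures: np.ndarray
    durations: np.ndarray
    window_slices: list[tuple[int, int]] = field(repr=False)
    r_lung_used: float = 0.0
    p0_used: float = 0.0
    window: float = 0.1
    ape_median: float = float("nan")
    ape_iqr: tuple[float, float] = (float("nan"), float("nan"))

    def __len__(self) -> int:
        return self.edrs.size

    @property
    def edrs_area(self) -> float:
        from .metrics import edrs_area

        return edrs_area(self)

    def predict(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant reconstruction over retained windows.

        Returns ``(paw_model, mask)`` where both cover the inspiration and
        ``mask`` flags the samples inside retained windows.
        """
        b = self.breath
        v, q = b.volume_insp, b.flow_insp
        paw_model = np.full(b.n_insp, np.nan)
        mask = np.zeros(b.n_insp, dtype=bool)
        for (a, z), e in zip(self.window_slices, self.edrs):
            paw_model[a:z] = e * v[a:z] + self.r_lung_used * q[a:z] + self.p0_used
            mask[a:z] = True
        return paw_model, mask

    def summary(self) -> str:
        lines = [
            "Single-compartment model, dynamic elastance",
            "-" * 46,
            f"windows retained          {len(self):>9d}  ({self.window * 1e3:.0f} ms each)",
            f"E_drs median (cmH2O/l)    {np.median(self.edrs):>9.3f}",
            f"E_drs range  (cmH2O/l)    [{self.edrs.min():.3f}, {self.edrs.max():.3f}]",
            f"R_lung used (cmH2O.s/l)   {self.r_lung_used:>9.3f}",
            f"P0 used (cmH2O)           {self.p0_used:>9.3f}",
            f"E_drs area (cmH2O.s/l)    {self.edrs_area:>9.3f}",
            f"APE median (%)            {self.ape_median:>9.2f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, against: str = "pressure"):
        """E_drs trajectory against mean window pressure (or time)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.pressures if against == "pressure" else self.times
        ax.plot(x, self.edrs, marker="o", ms=3)
        ax.set_xlabel("Paw (cmH2O)" if against == "pressure" else "time (s)")
        ax.set_ylabel("E_drs (cmH2O/l)")
        return ax


class SingleCompartmentModel:
    """Identify single-compartment lung mechanics from one breath.

    Parameters
    ----------
    breath : Breath
        Segmented breath; the inspiration must hold at least 10 samples.
    p0 : float, "measured" or None
        Offset pressure.  ``"measured"`` (default) fixes P0 to the breath's
        measured PEEP; a float fixes it to that value; ``None`` estimates it
        together with E and R.
    """

    def __init__(self, breath: Breath, p0: float | str | None = "measured"):
        if breath.n_insp < _MIN_INSP_SAMPLES:
            raise ValueError(
                f"inspiration has {breath.n_insp} samples; "
                f">= {_MIN_INSP_SAMPLES} required"
            )
        self.breath = breath
        if p0 == "measured":
            self._p0: float | None = float(breath.peep_measured)
        elif p0 is None:
            self._p0 = None
        else:
            self._p0 = float(p0)
        self._const_fit: ConstantElastanceResults | None = None

    # --- integral regressors ----------------------------------------------

    def _integrals(self):
        b = self.breath
        t = b.time_insp - b.time_insp[0]
        i_paw = cumulative_trapezoid(b.paw_insp, t, initial=0.0)
        i_v = cumulative_trapezoid(b.volume_insp, t, initial=0.0)
        i_q = cumulative_trapezoid(b.flow_insp, t, initial=0.0)
        return t, i_paw, i_v, i_q

    def fit(self) -> ConstantElastanceResults:
        """Identify constant (E, R) -- and P0 when not fixed -- by OLS."""
        t, i_paw, i_v, i_q = self._integrals()
        if self._p0 is None:
            x = np.column_stack([i_v, i_q, t])
            y = i_paw
        else:
            x = np.column_stack([i_v, i_q])
            y = i_paw - self._p0 * t

        sv = np.linalg.svd(x, compute_uv=False)
        if sv[0] == 0 or sv[-1] <= _RANK_RTOL * sv[0]:
            hint = (
                "" if self._p0 is not None
                else "; consider fixing p0 (e.g. p0='measured')"
            )
            raise SingularModelError(
                "integral regression system is rank deficient (volume, flow "
                f"and offset columns are linearly dependent){hint}"
            )
        beta, rss, _, _ = np.linalg.lstsq(x, y, rcond=None)
        n, k = x.shape
        sigma2 = float(rss[0]) / (n - k) if rss.size and n > k else 0.0
        cov = sigma2 * np.linalg.inv(x.T @ x)
        bse = np.sqrt(np.diag(cov))

        p0 = float(beta[2]) if self._p0 is None else self._p0
        res = ConstantElastanceResults(
            breath=self.breath,
            e_lung=float(beta[0]),
            r_lung=float(beta[1]),
            p0=p0,
            p0_estimated=self._p0 is None,
            params=beta,
            bse=bse,
        )
        res.ape_median, res.ape_iqr = _ape_summary(self.breath.paw_insp, res.predict())
        self._const_fit = res
        return res

    def fit_dynamic(
        self,
        window: float = 0.1,
        r_lung: float | None = None,
        p0: float | None = None,
        v_floor_frac: float = 0.05,
    ) -> DynamicElastanceResults:
        """Identify the windowed dynamic elastance Edrs(t).

        ``r_lung`` and ``p0`` default to the values of a constant fit on the
        same breath.  Windows whose mean inflated volume falls below
        ``v_floor_frac`` of the tidal volume are dropped.
        """
        b = self.breath
        if r_lung is None or (p0 is None and self._p0 is None):
            const = self._const_fit or self.fit()
            if r_lung is None:
                r_lung = const.r_lung
            if p0 is None:
                p0 = const.p0
        elif p0 is None:
            p0 = self._p0  # fixed value supplied at construction
        n_w = max(2, int(round(window * b.recording.sample_rate)))

        t = b.time_insp - b.time_insp[0]
        v, q, paw = b.volume_insp, b.flow_insp, b.paw_insp
        starts = list(range(0, b.n_insp, n_w))
        bounds = [(a, min(a + n_w, b.n_insp)) for a in starts]
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < 2:
            # fold a trailing 1-sample window into its neighbour
            a, _ = bounds.pop()
            bounds[-1] = (bounds[-1][0], b.n_insp)

        # each window owns the half-open time cell up to the next window's
        # start (the last one runs to the final inspiratory sample), so cell
        # durations sum to the inspiration span
        cell_ends = [t[bounds[i + 1][0]] for i in range(len(bounds) - 1)]
        cell_ends.append(float(t[-1]))

        v_floor = v_floor_frac * b.tidal_volume
        times, edrs, pressures, durations = [], [], [], []
        slices: list[tuple[int, int]] = []
        for (a, z), t_end in zip(bounds, cell_ends):
            if v[a:z].mean() < v_floor:
                continue
            tw = t[a:z]
            yw = cumulative_trapezoid(paw[a:z] - r_lung * q[a:z] - p0, tw, initial=0.0)
            xw = cumulative_trapezoid(v[a:z], tw, initial=0.0)
            sxx = float(xw @ xw)
            if sxx == 0.0:
                continue
            e = float(xw @ yw) / sxx
            edrs.append(e)
            times.append(float(0.5 * (tw[0] + tw[-1])))
            pressures.append(float(paw[a:z].mean()))
            durations.append(float(t_end - tw[0]))
            slices.append((a, z))
        if not edrs:
            raise EmptySeriesError(
                "all dynamic-elastance windows dropped (volume below floor)"
            )

        res = DynamicElastanceResults(
            breath=b,
            times=np.asarray(times),
            edrs=np.asarray(edrs),
            pressures=np.asarray(pressures),
            durations=np.asarray(durations),
            window_slices=slices,
            r_lung_used=float(r_lung),
            p0_used=float(p0),
            window=window,
        )
        paw_model, mask = res.predict()
        res.ape_median, res.ape_iqr = _ape_summary(paw[mask], paw_model[mask])
        return res


# --- thin functional layer -------------------------------------------------


def identify_constant(
    breath: Breath, fix_p0: float | str | None = "measured"
) -> ConstantElastanceResults:
    """Constant-elastance identification (functional form of ``fit``)."""
    return SingleCompartmentModel(breath, p0=fix_p0).fit()


def identify_dynamic(
    breath: Breath,
    r_lung: float | None = None,
    p0: float | None = None,
    window: float = 0.1,
    v_floor_frac: float = 0.05,
) -> DynamicElastanceResults:
    """Dynamic-elastance identification (functional form of ``fit_dynamic``)."""
    return SingleCompartmentModel(breath).fit_dynamic(
        window=window, r_lung=r_lung, p0=p0, v_floor_frac=v_floor_frac
    )


def reconstruct_pressure(breath: Breath, fit) -> tuple[np.ndarray, float, tuple]:
    """Reconstruct inspiratory pressure from a fit and summarise its APE.

    Returns ``(paw_model, ape_median, ape_iqr)``; for a dynamic fit the
    reconstruction is piecewise-constant and NaN outside retained windows.
    """
    if isinstance(fit, ConstantElastanceResults):
        paw_model = fit.predict()
        med, iqr = _ape_summary(breath.paw_insp, paw_model)
    elif isinstance(fit, DynamicElastanceResults):
        paw_model, mask = fit.predict()
        med, iqr = _ape_summary(breath.paw_insp[mask], paw_model[mask])
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    return paw_model, med, iqr
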
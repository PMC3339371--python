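"""Airway pressure--flow waveform handling.

This module holds the raw-signal layer of the package: a validated container
for a pressure/flow recording at one PEEP level, numerical volume integration,
and segmentation of a recording into individual breaths with inspiratory and
expiratory phases.

Conventions
-----------
* time in seconds on a uniform grid, airway pressure (``paw``) in cmH2O,
  flow in l/s with positive flow inspiratory, volume in litres;
* all index intervals are 0-based and half-open: a breath occupies
  ``[insp_start, exp_end)`` with the inspiration ``[insp_start, insp_end)``;
* volume is re-zeroed at each inspiration onset -- the analysis is strictly
  per-breath, so no global drift correction is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "WaveformFormatError",
    "PressureFlowRecording",
    "Breath",
    "read_recording",
    "integrate_flow",
    "segment_breaths",
    "breaths_to_frame",
]

log = logging.getLogger(__name__)

#: relative tolerance on the uniformity of the sample grid
_GRID_RTOL = 1e-6


class WaveformFormatError(ValueError):
    """Raised when an input file or signal violates the recording contract."""


@dataclass
class PressureFlowRecording:
    """A uniformly sampled airway pressure/flow recording at one PEEP level.

    Parameters
    ----------
    time : array
        Sample times in seconds, strictly increasing and uniform to within
        one part in 10**6.
    paw : array
        Airway pressure in cmH2O.
    flow : array
        Airway flow in l/s; positive is inspiratory.
    peep_set : float
        Nominal (set) PEEP for this recording, cmH2O.
    sample_rate : float, optional
        Sampling rate in Hz; inferred from ``time`` when omitted.
    """

    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    peep_set: float
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        n = self.time.size
        if n < 2 or self.paw.size != n or self.flow.size != n:
            raise WaveformFormatError(
                "time, paw and flow must have equal length >= 2 "
                f"(got {n}, {self.paw.size}, {self.flow.size})"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise WaveformFormatError(f"time not strictly increasing at row {row}")
        mean_dt = float(dt.mean())
        dev = np.abs(dt - mean_dt)
        if dev.max() > _GRID_RTOL * mean_dt:
            row = int(np.argmax(dev)) + 1
            raise WaveformFormatError(
                f"non-uniform time grid at row {row}: step {dt[row - 1]:.6g} s "
                f"vs mean {mean_dt:.6g} s"
            )
        if self.sample_rate is None:
            self.sample_rate = 1.0 / mean_dt
        if self.sample_rate <= 0:
            raise WaveformFormatError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class Breath:
    """One segmented respiratory cycle within a recording.

    The inspiration is ``[insp_start, insp_end)`` and the expiration
    ``[insp_end, exp_end)``.  ``volume`` covers ``[insp_start, exp_end)`` and
    is zeroed at the inspiration onset.  ``peep_measured`` is the mean airway
    pressure over the final 50 ms preceding the onset (the P0 convention used
    by the identification layer).
    """

    recording: PressureFlowRecording
    insp_start: int
    insp_end: int
    exp_end: int
    volume: np.ndarray = field(repr=False)
    peep_measured: float

    def __post_init__(self) -> None:
        if not (0 <= self.insp_start < self.insp_end <= self.exp_end):
            raise ValueError(
                f"invalid breath indices ({self.insp_start}, {self.insp_end}, "
                f"{self.exp_end})"
            )
        if self.exp_end > len(self.recording):
            raise ValueError("breath extends past end of recording")
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.size != self.exp_end - self.insp_start:
            raise ValueError("volume length does not match breath span")
        if self.volume[0] != 0.0:
            raise ValueError("volume must be zeroed at inspiration onset")
        if not np.isfinite(self.peep_measured):
            raise ValueError("peep_measured must be finite")

    # --- inspiration views -------------------------------------------------

    @property
    def n_insp(self) -> int:
        return self.insp_end - self.insp_start

    @property
    def time_insp(self) -> np.ndarray:
        return self.recording.time[self.insp_start : self.insp_end]

    @property
    def paw_insp(self) -> np.ndarray:
        return self.recording.paw[self.insp_start : self.insp_end]

    @property
    def flow_insp(self) -> np.ndarray:
        return self.recording.flow[self.insp_start : self.insp_end]

    @property
    def volume_insp(self) -> np.ndarray:
        return self.volume[: self.n_insp]

    @property
    def tidal_volume(self) -> float:
        """Delivered volume at end of inspiration, litres."""
        return float(self.volume_insp[-1])


def read_recording(
    path,
    peep_set: float,
    *,
    time_scale: float = 1.0,
    paw_scale: float = 1.0,
    flow_scale: float = 1.0,
) -> PressureFlowRecording:
    """Read a ``time,paw,flow`` CSV into a validated recording.

    Columns are interpreted as seconds, cmH2O and l/s after multiplication by
    the corresponding ``*_scale`` (e.g. ``flow_scale=0.001`` for a file in
    ml/s).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time", "paw", "flow") if c not in df.columns]
    if missing:
        raise WaveformFormatError(
            f"{path}: missing column(s) {', '.join(missing)}; header must be "
            "time,paw,flow"
        )
    num = df[["time", "paw", "flow"]].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, counting the header line
        raise WaveformFormatError(f"{path}: non-numeric value at line {row}")
    return PressureFlowRecording(
        time=num["time"].to_numpy() * time_scale,
        paw=num["paw"].to_numpy() * paw_scale,
        flow=num["flow"].to_numpy() * flow_scale,
        peep_set=float(peep_set),
    )


def write_recording(rec: PressureFlowRecording, path) -> None:
    """Write a recording back to its canonical CSV form."""
    pd.DataFrame({"time": rec.time, "paw": rec.paw, "flow": rec.flow}).to_csv(
        path, index=False
    )


def integrate_flow(rec: PressureFlowRecording, start: int, end: int) -> np.ndarray:
    """Cumulative trapezoidal volume (litres) over ``[start, end)``.

    The first value is exactly zero.
    """
    if not (0 <= start < end <= len(rec)):
        raise IndexError(f"indices ({start}, {end}) out of range for n={len(rec)}")
    return cumulative_trapezoid(
        rec.flow[start:end], rec.time[start:end], initial=0.0
    )


def segment_breaths(
    rec: PressureFlowRecording,
    min_insp_duration: float = 0.1,
    flow_threshold: float = 0.02,
) -> list[Breath]:
    """Split a recording into breaths.

    An inspiration onset is a rising crossing of ``+flow_threshold`` sustained
    for at least ``min_insp_duration``.  A breath runs from one onset to the
    next (the last breath runs to the end of the recording provided an
    expiratory phase, flow below ``-flow_threshold``, is present).  A partial
    cycle before the first onset is discarded.

    Returns an empty list (with a warning) when no complete breath is found.
    """
    flow = rec.flow
    n = len(rec)
    n_min = max(2, int(round(min_insp_duration * rec.sample_rate)))
    above = flow > flow_threshold

    # an onset needs an observed rising edge, so a recording that begins
    # mid-cycle has its partial first cycle discarded
    onsets: list[int] = []
    i = 1
    while i < n:
        if above[i] and not above[i - 1]:
            if i + n_min <= n and above[i : i + n_min].all():
                onsets.append(i)
                i += n_min
                continue
        i += 1

    breaths: list[Breath] = []
    k50 = max(1, int(round(0.05 * rec.sample_rate)))
    for j, onset in enumerate(onsets):
        end = onsets[j + 1] if j + 1 < len(onsets) else n
        # end of inspiration: first expiratory sample after the onset
        below = np.nonzero(flow[onset:end] < -flow_threshold)[0]
        if below.size == 0:
            log.debug("breath at sample %d has no expiration; discarded", onset)
            continue
        insp_end = onset + int(below[0])
        if insp_end - onset < 2:
            continue
        if onset >= k50:
            peep_measured = float(rec.paw[onset - k50 : onset].mean())
        elif onset > 0:
            peep_measured = float(rec.paw[:onset].mean())
        else:
            peep_measured = float(rec.paw[0])
        volume = integrate_flow(rec, onset, end)
        breaths.append(
            Breath(
                recording=rec,
                insp_start=onset,
                insp_end=insp_end,
                exp_end=end,
                volume=volume,
                peep_measured=peep_measured,
            )
        )
    if not breaths:
        log.warning("no complete breath found in recording (PEEP %s)", rec.peep_set)
    return breaths


def breaths_to_frame(breaths: list[Breath]) -> pd.DataFrame:
    """Tabulate segmented breaths (one row per breath)."""
    return pd.DataFrame(
        {
            "breath_id": range(len(breaths)),
            "peep_set": [b.recording.peep_set for b in breaths],
            "peep_measured": [b.peep_measured for b in breaths],
            "insp_start": [b.insp_start for b in breaths],
            "insp_end": [b.insp_end for b in breaths],
            "exp_end": [b.exp_end for b in breaths],
            "tidal_volume": [b.tidal_volume for b in breaths],
        }
    )
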
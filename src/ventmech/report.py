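"""Pipeline assembly: identify -> summarise -> select, with CSV reports.

``run_identify`` turns a set of per-PEEP recordings into per-breath fits and
a per-level summary table; ``run_report`` turns a summary table (computed, or
a pre-aggregated fixture in exactly that shape) into a selection comparison
table, one row per method per patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .metrics import TitrationSummary, summarize_level
from .model import SingleCompartmentModel
from .select import select_all, selections_to_frame
from .waveforms import (
    PressureFlowRecording,
    breaths_to_frame,
    read_recording,
    segment_breaths,
)

__all__ = ["RunConfig", "run_identify", "run_report", "summarize_titration"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one identify/report run."""

    inputs: list[tuple[Path, float]] = field(default_factory=list)  # (path, peep)
    out_dir: Path = Path(".")
    time_scale: float = 1.0
    paw_scale: float = 1.0
    flow_scale: float = 1.0
    min_insp_duration: float = 0.1
    flow_threshold: float = 0.02
    window: float = 0.1
    v_floor_frac: float = 0.05
    band: tuple[float, float] = (1.05, 1.10)
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not self.band[0] < self.band[1]:
            raise ValueError(f"band_lo must be < band_hi, got {self.band}")


def summarize_titration(
    recordings: list[PressureFlowRecording],
    window: float = 0.1,
    v_floor_frac: float = 0.05,
    min_insp_duration: float = 0.1,
    flow_threshold: float = 0.02,
    patient_id: str = "patient",
) -> tuple[TitrationSummary, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fit every breath of every recording and pool per-PEEP summaries.

    Returns ``(summary, breaths_table, constant_fits_table, edrs_long_table)``.
    """
    levels = []
    breath_frames, fit_rows, edrs_rows = [], [], []
    breath_counter = 0
    for rec in sorted(recordings, key=lambda r: r.peep_set):
        breaths = segment_breaths(
            rec, min_insp_duration=min_insp_duration, flow_threshold=flow_threshold
        )
        if not breaths:
            log.warning("recording at PEEP %g yielded no breaths", rec.peep_set)
            continue
        frame = breaths_to_frame(breaths)
        frame["breath_id"] = frame["breath_id"] + breath_counter
        breath_frames.append(frame)
        fits = []
        for b in breaths:
            model = SingleCompartmentModel(b)
            const = model.fit()
            dyn = model.fit_dynamic(window=window, v_floor_frac=v_floor_frac)
            fits.append((b, const, dyn))
            fit_rows.append(
                {
                    "breath_id": breath_counter,
                    "peep": rec.peep_set,
                    "e_lung": const.e_lung,
                    "r_lung": const.r_lung,
                    "p0": const.p0,
                    "ape_median": const.ape_median,
                    "ape_q1": const.ape_iqr[0],
                    "ape_q3": const.ape_iqr[1],
                }
            )
            for t_w, p_w, e_w in zip(dyn.times, dyn.pressures, dyn.edrs):
                edrs_rows.append(
                    {
                        "breath_id": breath_counter,
                        "window_time": t_w,
                        "pressure": p_w,
                        "edrs": e_w,
                    }
                )
            breath_counter += 1
        levels.append(summarize_level(fits, peep=rec.peep_set))
    summary = TitrationSummary(patient_id=patient_id, levels=levels)
    breaths_table = (
        pd.concat(breath_frames, ignore_index=True) if breath_frames else pd.DataFrame()
    )
    return summary, breaths_table, pd.DataFrame(fit_rows), pd.DataFrame(edrs_rows)


def run_identify(cfg: RunConfig) -> TitrationSummary:
    """Read recordings, fit all breaths and write the fit/summary CSVs."""
    if not cfg.inputs:
        raise FileNotFoundError("no input recordings given")
    recordings = [
        read_recording(
            path,
            peep,
            time_scale=cfg.time_scale,
            paw_scale=cfg.paw_scale,
            flow_scale=cfg.flow_scale,
        )
        for path, peep in cfg.inputs
    ]
    summary, breaths, fits, edrs = summarize_titration(
        recordings,
        window=cfg.window,
        v_floor_frac=cfg.v_floor_frac,
        min_insp_duration=cfg.min_insp_duration,
        flow_threshold=cfg.flow_threshold,
        patient_id=cfg.patient_id,
    )
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    breaths.to_csv(cfg.out_dir / "breaths.csv", index=False)
    fits.to_csv(cfg.out_dir / "constant_fits.csv", index=False)
    edrs.to_csv(cfg.out_dir / "edrs_series.csv", index=False)
    summary.to_dataframe().to_csv(cfg.out_dir / "summary.csv", index=False)
    log.info(
        "identified %d breaths over %d PEEP levels",
        len(breaths), len(summary),
    )
    return summary


def run_report(
    summary_table: pd.DataFrame,
    band: tuple[float, float] = (1.05, 1.10),
    clinical_peep: dict | None = None,
) -> pd.DataFrame:
    """Selection comparison table from a per-PEEP summary table.

    ``summary_table`` needs columns ``patient, peep, e_lung, edrs_median,
    edrs_area`` (the shape ``run_identify`` writes, or a hand-entered
    per-PEEP table).  Returns one row per method per patient.
    """
    required = {"peep", "e_lung", "edrs_median", "edrs_area"}
    missing = required - set(summary_table.columns)
    if missing:
        raise ValueError(
            f"summary table is missing column(s): {', '.join(sorted(missing))}"
        )
    if "patient" not in summary_table.columns:
        summary_table = summary_table.assign(patient="patient")
    frames = []
    for pid, group in summary_table.groupby("patient", sort=True):
        ts = TitrationSummary.from_dataframe(group, patient_id=str(pid))
        clin = None if clinical_peep is None else clinical_peep.get(pid)
        results = select_all(ts, band=band, clinical_peep=clin)
        frames.append(selections_to_frame(results, patient_id=str(pid)))
    return pd.concat(frames, ignore_index=True)


def format_report(table: pd.DataFrame) -> str:
    """Human-readable text rendering of a selection comparison table."""
    show = table.copy()
    show["PEEP"] = [
        f"{lo:g}~{hi:g}" if pd.notna(lo) else f"{p:g}"
        for p, lo, hi in zip(show["peep"], show["peep_lo"], show["peep_hi"])
    ]
    wide = show.pivot(index="method", columns="patient", values="PEEP")
    order = [
        m for m in (
            "clinical", "min_edrs", "min_edrs_area", "inflection_edrs_area",
            "min_elung", "inflection_elung",
        ) if m in wide.index
    ]
    return wide.loc[order].to_string(na_rep="-")
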
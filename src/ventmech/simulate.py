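"""Forward simulation of volume-controlled ventilation over a PEEP titration.

The generator produces pressure/flow waveforms with known ground truth so the
whole identify -> summarise -> select pipeline can be exercised and validated
without patient recordings.  It emulates a stepwise recruitment manoeuvre:
PEEP raised from zero in 5 cmH2O increments, stopping before any level whose
noiseless peak airway pressure would exceed a 45 cmH2O safety limit, with
volume-controlled breaths (tidal volume 0.4-0.6 l, square or decelerating
inspiratory flow) sampled at 100 Hz.

Ground truth follows the same single-compartment model the estimators assume,

    Paw = E(peep, V) * V + R * Q + PEEP + noise,
    E(peep, V) = baseline(peep) + slope(peep) * V,

with a U-shaped baseline elastance over PEEP (high at ZEEP, minimal at a
configurable argmin, rising again with over-distension) and an optional
intra-breath slope: negative at low PEEP (recruitment during inflation,
elastance falling within the breath) and positive at high PEEP (stretch,
elastance rising) reproduces the characteristic within-breath elastance
trajectories of recruitable vs over-distended lungs.  Expiration is passive
first-order decay with time constant R/E.  Noise is additive Gaussian on
both channels and the seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .waveforms import PressureFlowRecording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "u_shaped_profile",
    "simulate_breath",
    "simulate_level",
    "simulate_titration",
]

#: duration of the zero-flow baseline hold preceding the first breath, s
_LEAD_HOLD = 0.5


def u_shaped_profile(
    e_min: float = 22.0, peep_argmin: float = 15.0, curvature: float = 0.12
) -> Callable[[float], float]:
    """Quadratic U-shaped baseline elastance over PEEP (cmH2O/l).

    ``E(p) = e_min + curvature * (p - peep_argmin)**2`` -- high at ZEEP
    (recruitable collapsed lung), minimal at ``peep_argmin``, rising again as
    pressure over-distends recruited units.
    """

    def profile(peep: float) -> float:
        return e_min + curvature * (peep - peep_argmin) ** 2

    return profile


@dataclass
class SimConfig:
    """Study conditions for a simulated PEEP titration.

    Defaults emulate the protocol the package targets: 5 cmH2O PEEP steps
    from ZEEP, 45 cmH2O peak-pressure limit, 100 Hz sampling, tidal volume
    0.5 l with a 1.0 s inspiration at 15 breaths/min.
    """

    e_peep_profile: Callable[[float], float] = field(default_factory=u_shaped_profile)
    intra_breath_slope: float | Callable[[float], float] = 0.0
    r_lung: float = 5.0
    tidal_volume: float = 0.5
    flow_shape: str = "square"
    resp_rate: float = 15.0
    insp_time: float = 1.0
    peep_grid: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    peak_pressure_limit: float = 45.0
    noise_sd_paw: float = 0.5
    noise_sd_flow: float = 0.01
    seed: int = 0
    sample_rate: float = 100.0
    breaths_per_level: int = 6

    def __post_init__(self) -> None:
        if self.tidal_volume <= 0:
            raise ValueError("tidal_volume must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.flow_shape not in ("square", "decelerating"):
            raise ValueError("flow_shape must be 'square' or 'decelerating'")
        grid = tuple(float(p) for p in self.peep_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("peep_grid must be strictly increasing")
        self.peep_grid = grid
        if self.insp_time >= 60.0 / self.resp_rate:
            raise ValueError("inspiration longer than the respiratory cycle")

    def slope_at(self, peep: float) -> float:
        if callable(self.intra_breath_slope):
            return float(self.intra_breath_slope(peep))
        return float(self.intra_breath_slope)


@dataclass
class GroundTruth:
    """True parameters behind a simulated recording."""

    peep: float
    e_baseline: float
    intra_breath_slope: float
    r_lung: float
    p0: float

    def elastance(self, volume) -> np.ndarray:
        """True elastance at the given inflated volume(s)."""
        return self.e_baseline + self.intra_breath_slope * np.asarray(volume)


def _cycle_flow(cfg: SimConfig) -> np.ndarray:
    """Noiseless flow for one respiratory cycle (inspiration + expiration)."""
    dt = 1.0 / cfg.sample_rate
    n_i = int(round(cfg.insp_time * cfg.sample_rate))  # t = 0 .. Ti inclusive
    t_i = np.arange(n_i + 1) * dt
    if cfg.flow_shape == "square":
        q_i = np.full(n_i + 1, cfg.tidal_volume / cfg.insp_time)
    else:
        q_peak = 2.0 * cfg.tidal_volume / cfg.insp_time
        q_i = q_peak * (1.0 - t_i / cfg.insp_time)
    t_cycle = 60.0 / cfg.resp_rate
    n_e = int(round(t_cycle * cfg.sample_rate)) - (n_i + 1)
    return q_i, n_e


def _level_arrays(cfg: SimConfig, peep: float, n_breaths: int):
    """Noiseless flow/volume/pressure arrays for one PEEP level.

    Volume is zeroed per breath at the first inspiratory sample -- the same
    convention the breath segmenter uses -- so the forward model and the
    identification operate on identical volume signals.
    """
    dt = 1.0 / cfg.sample_rate
    truth = GroundTruth(
        peep=peep,
        e_baseline=float(cfg.e_peep_profile(peep)),
        intra_breath_slope=cfg.slope_at(peep),
        r_lung=cfg.r_lung,
        p0=peep,
    )
    q_i, n_e = _cycle_flow(cfg)
    e_end = truth.e_baseline + truth.intra_breath_slope * cfg.tidal_volume
    tau = max(cfg.r_lung / max(e_end, 1e-6), 2.0 * dt)
    t_e = (np.arange(n_e) + 1) * dt
    q_e = -(cfg.tidal_volume / tau) * np.exp(-t_e / tau)

    q_cycle = np.concatenate([q_i, q_e])
    t_cycle = np.arange(q_cycle.size) * dt
    v_cycle = cumulative_trapezoid(q_cycle, t_cycle, initial=0.0)
    paw_cycle = truth.elastance(v_cycle) * v_cycle + cfg.r_lung * q_cycle + peep

    n_hold = int(round(_LEAD_HOLD * cfg.sample_rate))
    q = np.concatenate([np.zeros(n_hold)] + [q_cycle] * n_breaths)
    volume = np.concatenate([np.zeros(n_hold)] + [v_cycle] * n_breaths)
    paw = np.concatenate([np.full(n_hold, float(peep))] + [paw_cycle] * n_breaths)
    time = np.arange(q.size) * dt
    return time, q, volume, paw, truth


def peak_pressure(cfg: SimConfig, peep: float) -> float:
    """Noiseless peak airway pressure at a PEEP level (stopping-rule input)."""
    _, _, _, paw, _ = _level_arrays(cfg, peep, 1)
    return float(paw.max())


def simulate_level(
    cfg: SimConfig,
    peep: float,
    rng: np.random.Generator | None = None,
    n_breaths: int | None = None,
) -> tuple[PressureFlowRecording, GroundTruth]:
    """Simulate one PEEP level: a baseline hold followed by ``n_breaths`` breaths."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_breaths is None:
        n_breaths = cfg.breaths_per_level
    time, q, _, paw, truth = _level_arrays(cfg, peep, n_breaths)
    paw = paw + rng.normal(0.0, cfg.noise_sd_paw, paw.size)
    q = q + rng.normal(0.0, cfg.noise_sd_flow, q.size)
    rec = PressureFlowRecording(
        time=time, paw=paw, flow=q, peep_set=peep, sample_rate=cfg.sample_rate
    )
    return rec, truth


def simulate_breath(
    cfg: SimConfig, peep: float, rng: np.random.Generator | None = None
) -> tuple[PressureFlowRecording, GroundTruth]:
    """Simulate a single breath (with its leading baseline hold)."""
    return simulate_level(cfg, peep, rng=rng, n_breaths=1)


def simulate_titration(
    cfg: SimConfig,
) -> tuple[list[PressureFlowRecording], dict[float, GroundTruth]]:
    """Simulate the full recruitment-manoeuvre titration.

    Iterates the PEEP grid in order and stops before the first level whose
    noiseless peak pressure would exceed ``peak_pressure_limit``.
    """
    rng = np.random.default_rng(cfg.seed)
    recordings: list[PressureFlowRecording] = []
    truths: dict[float, GroundTruth] = {}
    for peep in cfg.peep_grid:
        if peak_pressure(cfg, peep) > cfg.peak_pressure_limit:
            break
        rec, truth = simulate_level(cfg, peep, rng=rng)
        recordings.append(rec)
        truths[peep] = truth
    if not recordings:
        raise ValueError(
            "no PEEP level satisfies the peak-pressure limit "
            f"({cfg.peak_pressure_limit} cmH2O)"
        )
    return recordings, truths
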
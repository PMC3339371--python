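# Methods

## Model and identification

The package assumes a passive, single-compartment linear lung during
volume-controlled ventilation without spontaneous effort (sedated/paralysed
patients), so pleural pressure is neglected and airway pressure obeys
`Paw = E V + R Q + P0` during inspiration. Only inspiration is analysed:
rising pressure is what recruits or injures lung, and expiration adds no
information for PEEP selection under this model.

**Constant fit.** Integrating the model from the inspiration onset `t0` to
every sample `ti` gives one linear equation per sample,

```
∫ Paw dt = E ∫ V dt + R ∫ Q dt + P0 (ti − t0),
```

an overdetermined system solved by ordinary least squares
(`numpy.linalg.lstsq` on the cumulative-trapezoid integrals). Cumulative
integration acts as a low-pass filter, which is why this estimator tolerates
sensor noise far better than regressing on the raw samples; the suite
verifies agreement with a direct pointwise least-squares oracle on noisy
fixtures and exact recovery (< 1e-6 relative) on noiseless ones. `P0` is
fixed to the measured PEEP by default (mean airway pressure over the 50 ms
preceding the onset). Estimating `P0` freely is supported but is singular
under perfectly constant inspiratory flow, where `∫ Q dt` and `(ti − t0)`
are proportional; the error message says to fix `P0`. Rank deficiency is
detected via the singular values of the design matrix (ratio threshold
1e-10). OLS standard errors are reported with the estimates.

**Dynamic fit.** `E_drs(t)` is identified window-by-window: the inspiration
is partitioned into consecutive windows (default 0.1 s, ≥ 2 samples; a
trailing 1-sample remainder is folded into its neighbour) and the same
integral equation, with `R` and `P0` fixed, is solved for one scalar
elastance per window. A finite window is a deliberate choice: pointwise
division `(Paw − RQ − P0)/V` would reproduce the data exactly and make the
reported fitting error meaninglessly zero, whereas a windowed estimate
retains a genuine residual. Windows whose mean volume is below
`v_floor_frac` (default 0.05) of the tidal volume are dropped to guard the
`V → 0` singularity at the onset; consequently integrals over the retained
series cover slightly less than the full inspiration. With the window set to
the whole inspiration the dynamic fit reproduces the constant fit exactly
(verified to 1e-9), because the constant fit's normal equations make the
residual orthogonal to the volume-integral regressor.

`R` defaults to the same breath's constant fit. On a lung whose elastance
varies strongly within the breath the constant fit trades elastance trend
against resistance, so for trajectory studies a known or pooled `R` should
be supplied; the relevant tests do exactly that.

**Fit quality.** Absolute percentage error between reconstructed and
measured pressure is computed per inspiration sample and summarised as
median [IQR]; samples with non-positive measured pressure are excluded with
a warning. Whether to pool APE by mean or median is not standardised in the
literature this mirrors; median [IQR] is used throughout.

## Derived metrics

`E_drs Area = ∫ E_drs dt` is computed as `Σ E_w Δt_w` where each retained
window owns the half-open time cell up to the next window's start (the last
cell ends at the final inspiratory sample). For uniform windows this is the
midpoint rule — exact for constant and linear-in-time elastance — and a
single window degenerates to the rectangle rule. The work decomposition uses
`P0 = 0` (atmospheric reference), under which `WOB_E = E V²` and
`WOB_R = R Q V` sum to `Paw·V` exactly per sample, and
`E_drs(t) = WOB_E(t)/V(t)²` recovers the dynamic elastance.

Per PEEP level, `edrs_median`/IQR pool every window of every breath;
`e_lung` and `edrs_area` are medians across breaths (one value per level is
what the selection rules need; the aggregation choice is config-visible in
the code rather than hidden). Cross-patient rows are medians of per-patient
values. Quartiles default to linear interpolation between order statistics
with a Hazen (`n·p + 0.5`) alternative — published clinical tables follow
the latter, and the bundled reference IQRs only reproduce under it. Report
output rounds half-up in exact decimal arithmetic to one decimal, matching
how such tables are printed (floating-point round-half-even would turn a
51.85 median into 51.8).

## PEEP selection

* **Minimum**: argmin of the per-level metric; ties resolve to the lowest
  PEEP (the minimum-pressure reading of an equal-compliance tie, and the
  resolution consistent with the bundled reference selections).
* **Inflection**: on the descending limb (levels at or below the argmin),
  the PEEP interval where the metric crosses 110% down to 105% of its
  minimum, linearly interpolated in PEEP between grid levels. On a
  non-monotone limb the crossing nearest the argmin wins; a minimum at the
  first level degenerates to that PEEP with a warning; if the limb never
  exceeds the threshold the crossing clamps to the lowest grid PEEP. The
  interval's upper bound can therefore never exceed the argmin PEEP, and all
  selections are invariant under positive scaling of the metric.

The titration grid is data: patients whose manoeuvre stopped at off-grid
levels (PEEP 16, 22, 27, 28 in the bundled tables) are selected over their
actual grids.

Because the published "minimum median-E_drs" selections cannot all be
reproduced from the published per-level medians, a second mode minimises the
pooled within-breath trajectory minimum (`edrs_min`) instead of the
per-level median; neither mode is privileged.

## Synthetic titrations

The simulator emulates the study conditions end to end: PEEP raised from
ZEEP in 5 cmH2O steps, stopping before any level whose noiseless peak
pressure would exceed 45 cmH2O; volume control with square or decelerating
inspiratory flow; 100 Hz sampling. Defaults, chosen once as representative:
tidal volume 0.5 l, inspiration 1.0 s at 15 breaths/min, `R = 5` cmH2O·s/l,
baseline elastance `E(p) = 22 + 0.12 (p − 15)²` cmH2O/l (ZEEP value ≈ 49,
on the scale of the bundled ZEEP medians; argmin 15), Gaussian sensor noise
of 0.5 cmH2O and 0.01 l/s, six breaths per level. With these defaults the
stopping rule truncates the grid after PEEP 25. Ground truth is
`E(peep, V) = baseline(peep) + slope(peep)·V`: a negative slope at low PEEP
(recruitment during inflation) and positive at high PEEP (stretch) is the
simplest form that produces the characteristic falling-then-rising
within-breath elastance trajectories.

Volume is zeroed per breath at the first inspiratory sample — the same
convention the segmenter uses — so the forward model and the identification
operate on identical volume signals and noiseless round-trips are exact to
machine precision. Expiration is passive first-order decay with time
constant `R/E`; its discrete integral leaves a ~0.01 l residual volume,
which is irrelevant to the inspiration-only analysis.

What the simulator does *not* emulate: spontaneous effort, leaks, nonlinear
resistance, multi-compartment heterogeneity, cardiogenic oscillations, or
non-Gaussian sensor artefacts. Passing tests therefore show the estimators
are correct for the model class and robust to additive noise — not that the
single-compartment model is adequate for any particular patient.

## Numerical and interface choices

* Trapezoidal integration throughout (second-order accurate at 100 Hz).
* Breath segmentation: inspiration onset = flow rising through +0.02 l/s
  sustained ≥ 0.1 s (both config-exposed); a recording that begins mid-cycle
  has its partial first cycle discarded; 0-based half-open index intervals.
* Identification requires ≥ 10 inspiration samples.
* Degenerate inputs fail loudly: zero flow (rank-deficient system), an
  all-dropped dynamic series, zero-variance correlation inputs, single-level
  titrations.
* Simulation-based validation sizes (20 seeded titrations of 3 breaths per
  level; 50-replicate noise sweeps) keep the whole suite around five
  seconds while estimating rates and medians stably.

## Known limitations

* Resistance is assumed constant within a breath and, by default, fitted per
  breath rather than pooled across PEEP; a pooled value can be passed in.
* The inflection interval depends on the interpolation scheme; linear
  interpolation is used, and only containment properties (interval inside
  the descending limb, below the argmin) are guaranteed.
* Reported elastances are respiratory-system quantities: with pleural
  pressure omitted, chest-wall mechanics fold into `E`.
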
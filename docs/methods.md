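# Methods

## Model and assumptions

The analysis treats observations as exchangeable draws of a driver `x`, a
response `y`, and optional controls `Z`. It makes no model of `y` given
`x`; instead it measures the *local linear association* between the two
inside overlapping intervals of `x`'s value range, using the Pearson or
partial correlation coefficient as an order parameter. Implicit
assumptions:

- Within a window, the association is adequately summarized by a linear
  coefficient (windows narrow enough that curvature within a window is
  second-order).
- Samples are independent across rows. Panel structure (e.g. province ×
  year autocorrelation) is ignored; p-values are anti-conservative when it
  is present.
- Controls act linearly on both variables (partialling is least-squares
  residualization with an intercept).

## Windowing

Window `k` spans `[origin + k·l, origin + k·l + w]` in driver units.
Enumeration stops with the first window whose upper bound reaches the
driver maximum; that window is included, otherwise the highest-intensity
samples — often exactly the regime one wants to detect — would never enter
any window. Membership is half-open `[lower, upper)` except in the terminal
window, which is closed so the maximum sample is captured; half-open
interiors keep a sample sitting on a shared bound from being counted twice
at that bound. The closed-form window count is
`1 + ceil((max − w − origin)/l)` when `max > w + origin`, else 1.

Defaults `w = 40`, `l = 5` are a reasonable trade-off on a 0–100-normalized
driver between per-window sample size and resolution; on the package's own
generated data `w = 10`, `l = 2` resolves breakpoints to about one window
width. The minimum membership for a defined coefficient defaults to
`m + 3` (m = number of controls): the smallest n with at least one residual
degree of freedom in the t test. Smaller windows are reported with an
undefined coefficient, never silently dropped.

## Correlation and significance

Both routes share one significance rule: `t = r·√(df/(1 − r²))` with
`df = n − 2 − m`, referred to the exact Student t distribution (two-sided).
The exact distribution matters because windows can be small. Partial
correlation uses residual regression (numerically robust at small n); the
algebraically equivalent precision-matrix form `−Ω_xy/√(Ω_xx·Ω_yy)` is kept
in the test suite as an independent oracle, alongside a cross-check against
pingouin.

Degenerate inputs raise rather than guess: constant vectors, control
designs that are rank-deficient with the intercept, `n < m + 3`, and
variables whose residual norm after partialling falls below 1e-10 of their
centered norm (the variable is numerically an exact linear function of the
controls, so no partial variance remains).

Significance strata: NS (p ≥ 0.05, black), L1 ([0.01, 0.05), blue),
L2 ([0.001, 0.01), green), L3 (< 0.001, red). Interval endpoints belong to
the less significant class, extending the p = 0.05 → NS rule to 0.01 and
0.001.

No multiple-testing correction is applied across windows: the windows
overlap, so the per-window tests are strongly dependent and the curve is
read qualitatively; treat individual window p-values accordingly.

## Transition scan

Scanning defined windows in ascending order, the transition is the first
window with `p ≥ α` (default α = 0.05) after a run of at least `min_run`
(default 1) windows with `r > 0` and `p < α`. A significant *negative*
window does not itself constitute a transition — the rule is loss of
significance, not sign change — but any later window with `r < 0` and
`p < 0.001` upgrades the pattern from `pos->ns` to `pos->ns->neg`. The
reported threshold is the transition window's minimum *sample* value, not
its nominal lower bound: the nominal bound is a grid artifact, while the
sample minimum is the smallest driver value actually observed behaving
non-significantly. Patterns: `none` (no significant positive run),
`other` (a positive run that never loses significance — no transition to
report).

## Normalization

Min–max to [0, 100] per column over all rows — the unique affine map onto
that range. Parameters are persisted so thresholds can be stated in
original units (e.g. sej/ha) via the exact inverse
`min + value/100·(max − min)`. Scaling is computed as
`100·((x − min)/(max − min))` so the observed extremes land exactly on 0
and 100 in floating point. Constant columns are an error. Rows missing a
value in any analysis column are dropped (listwise deletion) with a logged
count; no imputation. An optional Tukey-fence outlier screen
(`k·IQR`, default k = 3, off by default) flags but never removes rows.

## Synthetic data generator

`PiecewiseCouplingModel` emulates the structure the method detects: driver
uniform on [0, 100]; response a *continuous* piecewise-linear function of
the driver (segments joined at the breakpoints, so window means vary
smoothly the way real intensity data do) plus confounder contributions and
additive Gaussian noise. Each confounder is
`driver_loading · z(x) + N(0, 1)` with `z` the standardized driver, and
adds `response_loading · c` to the response, so a nonzero loading product
opens a spurious path that partialling on the confounder removes. Defaults
(n = 2000; breakpoints 40, 60; slopes +1, 0, −1; noise_sd 4 ≈ 10% of the
response's signal range) give a clearly three-regime system at realistic
signal-to-noise. Everything is drawn from one seeded generator, so equal
seeds give byte-identical fixtures.

What the generator does **not** emulate: spatiotemporal panel dependence,
heteroscedastic or heavy-tailed noise, driver distributions with sparse
high-intensity tails (a skewed sampler can be layered on by the user), and
nonlinear confounding. Passing tests therefore demonstrate correctness of
the machinery and recoverability of piecewise-linear regimes under i.i.d.
Gaussian noise — not robustness to real survey data pathologies.

## Problem sizes

The test suite and the acceptance script run the generator at n between
500 and 5000 with 25–50 replicates for recovery-rate statistics; these
sizes put Monte-Carlo error comfortably below the asserted margins (e.g.
the ±0.05 marginal-vs-partial null gap at n = 5000) while each full sweep
remains sub-second.

## Known limitations

- Window-level inference ignores dependence between overlapping windows.
- The threshold estimate is biased toward the window grid: its resolution
  is one window width, and the first post-run non-significant window can
  precede the true breakpoint when power within mixed windows is low.
- Collinear controls are warned about (|pairwise r| > 0.9), not repaired.
- Listwise deletion assumes missingness unrelated to the analysis columns.
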
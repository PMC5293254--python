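# Methods

`platescreen` analyses plate-based phenotypic viability screens of the kind
used to reposition approved drugs against chemoresistant cancer cell lines:
a compound library dispensed at a single concentration into 384-well plates,
a fluorescent viability readout, control-based normalization, statistical
hit calling, a tiered confirmation screen, and dose-response follow-up of
the confirmed hits. This note records the models, conventions and numerical
choices, and what the synthetic-data tests do and do not establish.

## Plate model and dispense arithmetic

Plates are rectangular well grids (default 16 x 24 = 384 wells), addressed
0-based internally and by letter+number labels externally (`A01` is row 0,
column 0; single-digit columns are accepted on input and zero-padded on
output).

The **primary layout** frames every plate with controls: columns 1–2 are
vehicle-only negative controls (0.1% DMSO), columns 23–24 are positive
controls (doxorubicin 10 µM), and the 20 middle columns hold one test
compound per well — 320 compounds per 384-well plate, so a 1280-compound
library occupies four plate layouts. The **confirmation layout** leaves all
edge wells (rows A and P, columns 1 and 24) empty to avoid the edge effect,
giving a 14 x 22 = 308-well interior. Where controls sit inside that
interior is not dictated by the protocol; the package's declared convention
is negatives filling the leftmost interior columns top-to-bottom and
positives the rightmost (28 control wells by default, 14 + 14), with
compound duplicates in adjacent interior wells, column-major.

Acoustic-dispense concentrations use mass balance over the **total** volume:
a drop of `v` nl of stock at `S` mM into a `V` µl well gives
`S·1000·v / (V·1000 + v)` µM. The two protocol presets follow: 30 nl of
10 mM stock into 30 µl gives 9.99 µM (reported as 10 µM) with 0.0999%
DMSO; 2.5 nl gives 0.83 µM. The drop term in the denominator changes the
result by only 0.1% — below reporting precision — but the exact form is
fixed so the arithmetic is reproducible.

## Normalization and plate quality

Each plate is normalized strictly to **its own** controls:

    score(x) = (Av_neg − x) / (Av_neg − Av_pos)

so the plate's negative-control mean scores exactly 0 (no cytotoxicity) and
its positive-control mean exactly 1 (doxorubicin-level kill). Scores are
never clipped: negative scores (apparent growth stimulation) and scores
above 1 (stronger kill than the positive control) are preserved. The score
is invariant under any affine transform of the raw signals, which is what
makes per-plate normalization absorb reader-gain and cell-density drift.

Plate quality is gated on the screening-window coefficient

    Z' = 1 − 3 (SD_pos + SD_neg) / |Av_pos − Av_neg|

with a strict pass rule Z' > 0.5. Sample standard deviations (n − 1) are
used everywhere — the control populations are only 32 wells per plate.
Failing plates are flagged and excluded from downstream aggregation by
default (configurable to include-with-flag); they are never silently
dropped from the QC report.

## Hit calling

Per-compound scores are averaged over all replicate wells from QC-passed
plates; the design target is six wells per compound (three independent
experiments, each in duplicate), and compounds with fewer wells carry a
low-replicate flag. The hit threshold is

    mean + 3 × SD  of the pooled per-well negative-control scores,

pooled across all QC-passed plates of the campaign (a per-plate mode is
available). Because per-plate normalization pins every plate's
negative-control mean at 0, the pooled mean is ≈ 0 and the rule is
effectively 3 × SD of the vehicle scores; the rule is applied on the score
scale, the natural reading once data are normalized. Hits are strict
inequalities (`mean_score > threshold`), as is the confirmation tier cut.

Confirmation is tiered on the primary score: hits scoring strictly above
0.65 are re-tested at a 12x lower concentration (0.83 µM via a 2.5 nl
dispense), the rest again at 10 µM (30 nl). The protocol source states the
tier cut as 0.7 in one place and 0.65 in another; 0.65 — the operational
protocol value — is the default here, exposed as `tier_threshold`.
Confirmation plates are evaluated with the same 3 × SD rule against their
own negative controls, which is a declared convention of this package (the
protocol reports confirmation scores without stating a pass rule). This
setup reproduces the characteristic behaviours: persistently potent
compounds confirm at the low tier, while "all-or-none" compounds (high
score at 10 µM, none at 0.83 µM) fail confirmation.

## Dose-response fitting

Viability is normalized to untreated controls (`signal / mean(untreated)`,
fraction affected `fa = 1 − viability`, unclipped) and fitted with the
four-parameter logistic

    v(c) = bottom + (top − bottom) / (1 + (c / IC50)^hill).

Design follows screening practice: geometric dilution series with factor
2 or 3, at least 8 concentrations (warned below), 4 replicates per
concentration.

Numerical choices:

* **Parameterization.** IC50 is fitted as log10(IC50); potency is
  log-normal across compounds and the log scale stabilizes both the
  optimizer and the Wald interval. IC50 here is the curve midpoint
  ("relative" IC50); `absolute_ic50` converts to the viability = 0.5
  crossing when it exists.
* **Objective.** Unweighted least squares on the viability scale over all
  replicate wells (no pre-averaging).
* **Constraints.** `fix_bottom_zero` (complete kill at saturation) and
  `fix_top_one` (upper plateau anchored when the curve cannot reach it in
  the tested range) remove the parameter from the optimization entirely —
  fixed exactly, not penalized. A constrained fit's RSS is never below the
  free fit's on the same data.
* **Starting values and restarts.** top/bottom from the data extremes,
  IC50 at the tested concentration whose mean viability is nearest the
  half-range, hill ∈ {1, 0.5, 3}; the best of the three local fits (by
  RSS) is returned. Levenberg–Marquardt with 1e−12 relative tolerances;
  refitting from a returned estimate reproduces it to 1e−8.
* **Confidence intervals.** Wald on log10(IC50): residual-variance-scaled
  inverse Gauss–Newton Hessian, t(n − p) quantile, back-transformed — the
  interval is asymmetric in µM, collapses to the point estimate as noise
  vanishes, and achieves 90–98% empirical coverage at nominal 95% in the
  simulation suite (σ = 0.05, 8 x 4 design). A singular information matrix
  yields an undefined interval with a `ci_undefined` flag, never a crash.
* **Degenerate input.** Flat viability raises a degenerate-data error;
  batch fitting records per-compound failures and continues.

Fit flags: `steep_slope` when hill > 3 (all-or-none concentration window);
`incomplete_kill` when the bottom plateau leaves more than 5% of the top
viability (max attainable fraction affected < 0.95 — the fa ≈ 0.8 plateau
typical of phase-specific cytostatics such as taxanes and antimetabolites);
`high_variability` when the mean per-concentration replicate SD exceeds
0.15 viability units; `precipitation_suspect` when observed viability at
the highest concentration rebounds > 0.2 above the fitted curve (poorly
soluble compounds precipitating at high dose).

## Synthetic campaigns

The simulator generates the data structure the analysis assumes, with
ground truth recorded before any noise is drawn and emitted in a separate
table no analysis stage reads.

A compound with true effect score `s` has expected signal
`mu_neg − s·(mu_neg − mu_pos)`; defaults are mu_neg = 20000, mu_pos = 2000
(a 10x control window), 5% coefficient of variation on every role, a 5%
multiplicative per-plate scale factor, and three experiments in duplicate.
With these defaults the expected Z' is 1 − 3(0.05·2000 + 0.05·20000)/18000
≈ 0.817, inside the 0.6–0.85 band of a validated screen. Noise is Gaussian
with role-specific CV — fluorescence readouts at these intensities are far
from the Poisson regime. An optional fractional edge-well signal loss
demonstrates why the confirmation layout leaves edges empty; it defaults to
0 so the primary-screen simulations isolate the statistical behaviour of
the hit rule.

All randomness derives from one campaign seed through named
`SeedSequence` substreams keyed by (plate, well), so adding a compound or a
plate never perturbs other draws, zero-noise settings return the truth
exactly, and a fixed seed reproduces the campaign byte-for-byte.
Dose-response data are `4PL(c) + N(0, σ)` with σ = 0.05 as the realistic
replicate noise for a viability assay of this type.

What the simulations do **not** emulate: spatial autocorrelation beyond a
uniform edge offset, signal drift within a run, compound carry-over,
heteroscedastic noise at very low signal, or cytostatic-vs-cytotoxic
kinetics. Passing tests therefore establish the correctness and calibration
of the statistics under the stated noise model, not robustness to every
artefact of real plates.

## Problem sizes in the test and acceptance runs

The simulation suites use one-page campaigns (320 compounds, 6 plates) over
20 seeds for hit-recovery checks, 500 simulated datasets for CI coverage in
the test suite (300 in the acceptance script), and 8 x 4 dose-response
designs throughout — sizes chosen to make the Monte Carlo answers stable at
interactive run times.

## Known limitations

* Spatial correction (B-score/median polish, loess) is out of scope; the
  protocol this package models uses none.
* Profile-likelihood CIs are not implemented; Wald-on-log is the single
  documented method.
* Confirmation control placement and the confirmation pass rule are
  package conventions (documented above), as the protocol leaves both
  unstated.
* 1536-well formats and physical dispenser picklists are not supported.
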
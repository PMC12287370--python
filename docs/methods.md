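# Methods

This note records the models implemented in `screenscore`, the conventions
and defaults behind them, and the choices made where the underlying
procedures are conventionally under-specified.

## Viability normalization

Each sample's compound wells are normalized against that sample's own
control wells: viability% = 100·(signal − mean_pos)/(mean_neg − mean_pos),
where the negative control is vehicle (0.1% DMSO) and the positive control
a full-kill compound (100 µM benzethonium chloride). Conventions:

- Controls are summarized by the arithmetic mean (median available via
  `control_stat`); the mean matches the linearity of the formula.
- Each well is normalized first, then replicates are averaged per
  (treatment, concentration). Because the transform is affine, this equals
  normalizing the replicate-mean signal; the per-well order is kept because
  controls belong to the plate the well was measured on.
- Viability is **not** clipped at normalization. Values slightly above
  100% or below 0% are real measurement scatter and are informative for
  curve fitting; clipping happens only inside formulas that require it
  (the DSS integrand, Bliss inhibition fractions) and is documented there.
- mean_neg ≤ mean_pos raises a degenerate-controls error: that pattern
  means the assay failed, and silently producing inverted viabilities
  would poison everything downstream.
- Concentrations are carried in nM everywhere; series given in other units
  must be converted at the boundary.

Control pooling is per sample. Whether control wells are shared across the
plates of a print run or kept per plate is a facility detail; per-sample
pooling is the assumption, and a stricter per-plate split can be expressed
by treating plates as samples.

## Logistic dose-response model

v(x) = bottom + (top − bottom)/(1 + 10^{hill·(x − log10_ic50)}), with
x = log₁₀(concentration/nM). Parameter bounds: 0 ≤ bottom ≤ top ≤ 120
(viability above 100% occurs), hill ∈ [0, 10] (hill ≥ 0 makes the curve a
monotone non-increasing kill curve, which the sensitivity score assumes),
log10_ic50 within the tested range ± 2 decades.

Fitting is bounded least squares (`scipy.optimize.least_squares`, trust
region reflective) restarted from a fixed 5×5 grid over (log10_ic50, hill)
start values, with top/bottom started at the data extrema; the best
residual wins, and a flat-mean candidate always competes, so the reported
RSS never exceeds the flat fallback's. There is no randomness in fitting.
The bottom ≤ top ordering is kept by a soft penalty residual rather than a
reparameterization, which preserves simple box bounds. If the optimizer
produces no candidate at all, the flat fallback is returned with
`converged=False` — a screen-scale pipeline must degrade per-series, not
abort.

With five points and zero noise the fit reproduces *predictions* to well
under 0.5% viability at all tested doses; parameters themselves are
non-identifiable for nearly flat curves (any hill fits a constant), which
is why the recovery contract is stated on predictions.

## Drug sensitivity score (modified DSS3)

The score integrates inhibition y(x) = 100 − v(x) on the log-dose axis
over the full tested window [x_min, x_max], with the integrand clipped to
the activity window [0, y_cap], y_cap = 100 − t_v and t_v = 10% viability
floor by default:

DSS = 100 · ∫ clip(y(x), 0, y_cap) dx / (y_cap · (x_max − x_min)).

Geometrically this is the area between the fitted curve and the 100% line,
restricted to the 10–100% viability band — the activity window "from 100%
to 10%" — normalized by the window's area. The DSS2-style division by
log₁₀ of the upper asymptote is omitted.

A literal reading of the dose window — truncating the integral at the dose
where viability *reaches* 10% — would drive the score of a maximally
potent drug (which reaches the floor immediately) toward 0, contradicting
the score's defining property that 0–100 ranks sensitivity. The default
therefore integrates the capped inhibition over the full tested window,
which satisfies both endpoint anchors exactly: flat 100% viability → 0,
complete kill everywhere → 100. The literal variant survives as the
`apply_window_factor` option, multiplying by
(x_stop − x_min)/(x_max − x_min) where x_stop is where viability first
reaches the floor; results are labelled `DSS3m:windowed` so the two
variants cannot be silently mixed.

Other conventions: viability above 100% contributes zero area (no negative
inhibition; the score floor is 0); the dose axis is log₁₀(nM) because the
series are log-spaced and the metric family integrates on log dose; the
integral uses adaptive quadrature (`scipy.integrate.quad`, absolute
tolerance 1e-8) with the clip kinks — where the curve crosses 100% and the
floor, both available in closed form for the logistic — passed as
breakpoints. Against a 10,001-point trapezoid oracle the quadrature agrees
to ~1e-6 score units.

Because the score is normalized by the tested log-width, identical curve
shapes over different tested ranges of equal log-width score identically,
keeping drug-specific series (e.g. a 0.1–1000 nM series for very potent
compounds) comparable.

Across independent experiments the per-experiment DSS values are averaged
and their SD reported; combinations are scored exactly like singles using
the shared 1:1 series concentration as the dose axis.

## Target addiction score

TAS(target) = mean of experiment-mean DSS over all treatments — single
agents and combinations — whose annotation contains the target and which
have a score for the sample. Conventions: combinations contribute the
union of their components' targets, each target receiving the
combination's single DSS once (unweighted inclusion); unmeasured
treatments are excluded, not imputed; targets with no scored annotated
treatment are absent, not zero — absence of evidence is not a zero
addiction. The annotation table is the sole source of target mappings; no
external on-/off-target expansion is performed. Ranking is by TAS
descending with deterministic alphabetical tie-break.

## Bliss synergy

Viabilities are converted to inhibition fractions f = clip((100 − v)/100,
0, 1) — clipped because the Bliss formula f_a + f_b − f_a·f_b is a
probability identity. The per-cell excess is (f_obs − f_exp)·100 and the
surface score is the mean excess over cells where both doses are positive.
Calls: < −10 antagonistic, −10 to 10 (boundaries inclusive) additive,
> 10 synergistic.

The untreated cell is renormalized to exactly 100% before scoring (it
defines the f = 0 baseline). No baseline or outlier correction of the
surface is applied. For the diagonal 1:1 design the measured diagonal
cells are scored directly; no model-based imputation of the off-diagonal
cells is attempted, so the score is exact for the cells actually measured
but is not numerically comparable to scores computed on imputed full
matrices.

## Altered-transcript filter

Per line, replicate raw counts are averaged to one value per condition
(parental, resistant) before anything else; the condition's library sum is
the sum of these averaged counts. Then per transcript: CPM = count /
library sum × 10⁶; MC = (parental + resistant)/2; L2FC = log₂(resistant +
1) − log₂(parental + 1). Altered ⇔ CPM > 0.5 (strict) AND MC ≥ 10
(non-strict) AND |L2FC| > 2 (strict).

Two readings are genuinely ambiguous and exposed as config: the CPM clause
is applied to the *maximum* of the two conditions by default (the
permissive standard for expression filters; `cpm_mode="both"` requires
both), and replicates are averaged before CPM by default
(`replicate_mode="per_replicate_cpm"` computes CPM per replicate against
its own library and averages). Lines are always analyzed separately, and
set overlaps between lines use exact Venn arithmetic.

The filter is deliberately not a statistical test: no dispersion
modelling, no p-values, no multiple-testing correction. Its operating
characteristics are therefore checked by construction (spike-in recovery
and null false-positive rate on simulated counts) rather than by error
control guarantees.

## MFI transforms

Raw median fluorescence intensities are noise-corrected by subtracting the
isotype control; corrected values ≤ 0 are legal and flaggable. For
absolute display the corrected value is log₁₀-transformed with a floor of
1 AU (so zero/negative corrected values map to 0). "Relative to DMSO" is
the linear difference of corrected MFIs — not a ratio and not a log-scale
difference — because that is the transform under which the vehicle control
is *exactly* zero.

## Synthetic data generators

The generators define the conditions under which the pipeline is
validated. They emulate the screening design: a library of 93 single
agents and 87 1:1 fixed-molar combinations, five log-spaced concentrations
(1–10,000 nM default, drug-specific series allowed), in-plate vehicle and
full-kill controls, 2–3 replicates; combination surfaces built from
logistic monotherapies with an optional excess δ added to the
Bliss-independent inhibition before clipping; transcript counts as
negative binomial with log-normal baseline means, two replicates per
condition, and a spiked subset at a set fold change (alternating up/down).

Noise defaults, chosen once to resemble the corresponding real assays and
exposed as config: additive Gaussian viability noise of 5% (signals
truncated at zero; multiplicative CV available and off by default), 1%
noise for combination surfaces, negative-binomial dispersion 0.05 with
spiked transcripts at baseline mean 200 and 8-fold change, 25 spikes per
5,000 transcripts. All generators are pure functions of (ground truth,
seed).

What passing on these simulations shows — and what it does not: the
pipeline inverts its own generative model (normalization undoes the
control construction exactly at zero noise; injected Bliss excess is
recovered exactly on unsaturated cells; spiked fold changes are recovered
with ≲1 false positive per 5,000 transcripts at the default dispersion).
The generators contain no plate spatial artifacts, no edge effects, no
batch structure, no heteroscedastic count trends beyond NB dispersion, and
no correlated noise between monotherapy and combination wells, so the
tests certify the computations, not robustness to those real-data
pathologies.

## Problem sizes in the test suite and acceptance script

Stochastic checks run at sizes chosen to make their pass criteria stable
across seeds while keeping the default suite quick on one CPU: 100
treatments for IC50 recovery (±0.3 log units for ≥ 90%), 100 frozen
surfaces for Bliss null calibration (mean |score| < 2, ≥ 95 additive
calls), 200 random curves against the dense-trapezoid DSS oracle (1e-3),
1,000 parameter pairs for DSS monotonicity, 1,000 random toy tables for
TAS-vs-brute-force, and 5,000-transcript matrices for filter spike-in
recovery. The published altered-set sizes (204, 168, 7 overlapping, union
365) are checked as exact set arithmetic; re-deriving them from the
deposited count matrices is an integration test that activates when the
accession's counts are placed at `data/GSE173984_counts.tsv`.

## Known limitations

- Biphasic / bell-shaped dose responses are out of model; hill ≥ 0 will
  flatten them.
- Bliss only; no Loewe, HSA or ZIP reference models, no dose-localized
  synergy maps, no confidence intervals on synergy scores.
- The transcript filter's thresholds are conventions, not inference; at
  very high dispersion the fixed thresholds lose both sensitivity and
  specificity.
- IC50s are reported as fitted parameters and are only meaningful inside
  or near the tested window; DSS is the headline statistic.
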
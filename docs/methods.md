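# Methods

This note documents the models behind each module, the defaults that
matter, and the choices made where the design was genuinely open. It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Chelation equilibrium

The assay's trigger is EGTA chelation of extracellular divalent cations.
We solve the coupled mass balances for Ca²⁺, Mg²⁺ and EGTA using apparent
(proton-corrected) association constants:

```
alpha_H = 1 + K1[H] + K1·K2[H]² + K1·K2·K3[H]³ + K1·K2·K3·K4[H]⁴
Kd_app(M) = alpha_H / (K_ML + K_MHL · K1 · [H])
```

with a single unknown — unbound EGTA `L_f` (all protonation states) —
closing the system, since free metal is `M_T / (1 + L_f/Kd_app)` and the
ligand balance is strictly increasing in `L_f`. Newton iteration with a
bracketing bisection fallback; typical residuals are ~1e-18 M and the
solver refuses to return anything above 1e-12 M.

Corrections applied to the shipped reference constants
(`src/catscreen/data/egta_constants.json`; stepwise log K at 20 °C,
I = 0.1 M):

- **Ionic strength** — Davies activity coefficients with a
  temperature-dependent Debye slope, applied per association step through
  its charge product.
- **Temperature** — van't Hoff, using the enthalpies carried in the data
  file. The shipped file carries enthalpies for the metal-binding steps
  (Ca–EGTA −33.9 kJ/mol, Mg–EGTA +13 kJ/mol) and treats the protonation
  steps as temperature-invariant over the 15–40 °C range the package
  targets; this convention follows the widely used chelator calculators.
- **pH scale** — a pH meter reads H⁺ *activity*; it is converted to a
  concentration with the Davies single-ion coefficient before entering
  `alpha_H`, because the constants are concentration-based.

Published EGTA constant sets disagree enough that apparent Ca affinities
at pH 7.4 span a several-fold range; the shipped set and its corrections
are therefore documented in one data file so the package's numbers are
exactly reproducible, and the solver accepts alternative sets via
`load_constants(path)`. With the shipped set, the TYH design buffer
(1.71 mM Ca, 1.2 mM Mg, 3.5 mM EGTA, pH 7.4, 37 °C, I = 0.15 M) gives
free Ca²⁺ = 154.3 nM and apparent Kd(Ca–EGTA) = 1.486e-7 M; both are
locked as golden regression values in the tests.

Out of scope: chelators other than EGTA (the data format extends, but only
EGTA is shipped and tested) and activity models beyond Davies.

## Plate and barcode arithmetic

Default dye levels are the final concentrations of the 3-fold/4-fold
serial dilutions used for barcoding: CFSE {0.001, 0.25, 1} µM × Violet
{0.025, 1, 5, 20} µM → 12 signatures (`V<i>-C<j>`, Violet-major order).
Assay wells mix 30 µl sperm + 30 µl Violet 3X + 30 µl CFSE 3X + 5 µl
compound = 95 µl; after incubation a 205 µl top-up brings each well to
300 µl, and pooling 12 wells into 5 ml carrier gives the 8.6 ml matrix
tube. Because of the 5 µl compound aliquot, 30 µl of a "3X" stock in
95 µl is actually 0.947× the nominal final; the layout reports the
nominal value by convention and exposes the exact one via
`mixing_concentration`. Controls default to vehicle at signature V1-C1
and the CatSper inhibitor at V3-C1 in every matrix, both configurable, as
is an optional reserved no-sperm identification well.

## Synthetic event generator

One `numpy.random.Generator` drives every draw; per-well streams on a
plate get independent children of a single `SeedSequence`, so identical
seeds give bit-identical tables. Defaults (all overridable in
`WellSimSpec`):

| parameter | default | rationale |
|---|---|---|
| events/well | 20,000 | typical per-sample acquisition depth |
| debris / doublet / dead fractions | 0.05 / 0.05 / 0.10 | realistic for washed sperm preparations |
| scatter | FSC-H lognormal (median 5e4, CV 15%); FSC-A = 1.05·FSC-H·(1±5%); doublets 2.1× | tight singlet FSC-A~FSC-H line, doublets at double area |
| barcode intensity | median = 30 + 100·[Violet µM] or 30 + 800·[CFSE µM] AFU, CV 25% | log-separated clusters at the default levels; lowest CFSE level sits at autofluorescence background, as on the instrument |
| DiSC₃(5) | bimodal: high median 1500, low 150 AFU, CV 30%, 80% high at rest | two clearly separable membrane-potential populations |
| migration | each high live cell depolarizes with prob. `p_mig` at `t_egta + Exp(τ=10 s)` | migration completes well inside the 150 s post-EGTA window; the exact lag kinetics are a modeling choice |
| acquisition | events uniform over 0–180 s, EGTA at 30 s | 30 s basal + 150 s response protocol |
| viability | PI median 20 (live) vs 2000 (dead) AFU | decade-separated live/dead modes |
| spillover | CFSE→PI 10%, Violet→CFSE 5%, DiSC₃(5)→PI 5% | modest realistic bleed; any invertible matrix accepted |

Simulated plates draw per-well migration probabilities 0.7–0.9 for
vehicle controls and untreated compounds (the uninhibited range), ~0.02
for inhibitor controls, and injected actives via `p_mig_overrides`.

What the generator does **not** emulate: detector saturation and
digitization, non-linear (spectral-overlap-dependent) mixing, barcode
staining heterogeneity between cells of one well beyond lognormal CV,
time drift in instrument gain, and cell identity across time (events are
independent snapshots, as in real cytometry). Passing tests therefore
validate the analysis logic under the assumed statistical structure, not
instrument-specific behavior; gates for real data are expected to be
re-parameterized.

## Preprocessing

- **Compensation**: observed = true × S with S rows as dyes; estimation
  regresses each off-channel on the primary channel (with intercept, so
  autofluorescence does not bias the slope) over the brighter half of a
  single-stained tube. Compensated values may be negative and are kept.
- **Gating** is on log10(1+x). The sperm gate is a rectangle in
  (log FSC-A, log SSC-A) matched to the simulator; the doublet band keeps
  events within ±30% of the robust (median-ratio) singlet FSC-A/FSC-H
  line; the live gate defaults to a fixed PI threshold of 300 AFU
  (between the simulator's live and dead modes) with an automatic
  bimodal-valley mode (`pi_threshold=None`) plus quantile fallback for
  data-derived thresholds.
- **Barcode deconvolution**: per-dye 1-D Gaussian mixtures (components =
  known level count, fixed random state, quantile-subsampled to ≤20k
  events) give sorted centroids; events join the nearest signature in
  (log Violet, log CFSE) within a 0.45 log-unit radius, else stay
  `unassigned` and are dropped from scoring. Centroids closer than 0.2
  log units trigger a resolvability warning. Threshold and assignment are
  gain-invariant because everything happens in log space relative to
  fitted centroids.

## Depolarization scoring

The DiSC₃(5)⁺ threshold (the "dashed line") is the KDE antimode of the
negative control's basal-window log-intensity, reused for every sample in
the tube; a unimodal distribution raises an error rather than guessing.
Per sample, events are binned in 10 s bins over 0–180 s; the normalized
mean is the per-bin mean of the *current* DiSC₃(5)⁺ membership divided by
the first (basal) bin, so it starts at 1 by construction. The headline
statistic is the **migration fraction**
`1 − (post-EGTA DiSC₃(5)⁺ share)/(basal share)`, clipped to [0, 1], with
the post window starting 30 s after EGTA so the exponential migration lag
(<5% of migrators still high by then at the default τ) has played out.
Samples with fewer than 200 events in the basal or post window are
flagged and not scored.

ΔAFU uses F_R = mean of the 60 s before EGTA and F_EGTA = the first point
≥60 s after EGTA whose rolling 10 s slope falls below 1% of the
provisional step amplitude (trace end with a warning otherwise);
normalization divides by the mean of supplied control deltas. The Fluo-4
summary normalizes the sample median to the control median and counts
responders above the control's high-mode valley (quantile fallback when
the control is unimodal).

## Screening and QC

Compounds are scored per matrix against that matrix's own controls —
`(m_neg − m_well)/(m_neg − m_pos)` clipped to [0, 1] — and called hits at
score ≥ 0.5 by default; the threshold is deliberately exposed in
`ScreenConfig` since any cutoff between the control behaviors is
defensible. Matrices with inverted (`m_neg ≤ m_pos`) or unscorable
controls fail QC and leave their compounds unscored. Plate QC reports
control means/SD/CV across matrices and
`Z' = 1 − 3(σ_pos+σ_neg)/|µ_neg−µ_pos|`. A barcode observed in a tube
without a layout entry is a hard error when it exceeds 0.5% of assigned
events; below that it is recorded as stray misassignment (empty grid
cells inevitably catch a few boundary events).

## Problem sizes and runtime

The bundled tests run the full 80-compound/8-matrix screen at 5,000
events per well (hit recovery is identical to the 20,000-event setting,
and the suite stays fast); single-well analyses and the acceptance script
use the full 20,000 events. The whole suite runs in well under a minute
on one CPU.

## Known limitations

- Real sperm-gate polygon coordinates are instrument- and species-
  specific; the shipped rectangle is simulator-matched and must be
  overridden for real FCS-derived data (CSV import only; no FCS parser is
  bundled).
- The migration statistic compares population shares, not tracked single
  cells — cytometry provides no cell identity over time.
- Em is reported in relative fluorescence; no calibration to millivolts.
- Dose–response/IC₅₀ fitting and multi-plate batch correction are out of
  scope.
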
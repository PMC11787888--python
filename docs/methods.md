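# Methods

## The problem

Murine pneumonia models are used to benchmark antibiotics before clinical
study, but a mouse given a clinical dose does not see clinical exposure:
murine clearance is faster, plasma protein binding differs between species,
and penetration from plasma into pulmonary epithelial lining fluid (ELF) —
the target site in pneumonia — has its own, species-specific time course.
A *human-simulated regimen* (HSR) is a murine dosing schedule (here:
repeated subcutaneous injections) engineered so that the mouse's free-drug
exposure profile in a chosen matrix (plasma or ELF) approximates that of a
clinical human regimen. `hsrpk` implements the quantitative machinery for
developing and confirming such regimens: closed-form PK simulation,
PK/PD exposure indices, matrix corrections, naive-pooled parameter
estimation, and a regimen-design optimizer, together with a seeded
synthetic-data generator so the whole pipeline is testable without animal
data.

## Pharmacokinetic model

Each drug-matrix pair is described by a one-compartment model with
first-order absorption and first-order elimination. A subcutaneous dose D
(mg/kg) given at time τ contributes

    C(t) = (D/V) · ka/(ka − kel) · (e^(−kel(t−τ)) − e^(−ka(t−τ))),  t ≥ τ

with apparent volume V (L/kg), absorption constant ka (1/h) and
elimination constant kel (1/h). Per-kg dosing removes body weight from all
formulas, and bioavailability is folded into the apparent volume (F = 1):
the shipped fitted parameters reproduce the printed exposure indices under
that convention. When |ka − kel|/ka < 1e-9 the limit form
(D/V)·ka·(t−τ)·e^(−ka(t−τ)) is used.

Two non-obvious properties of this model matter downstream:

* **Flip-flop equivalence.** The curve is invariant under
  (V, ka, kel) → (V·kel/ka, kel, ka). Concentration data alone therefore
  cannot say which rate constant is absorption; meropenem in murine plasma
  is reported in the absorption-limited labelling (ka = 1.34 < kel =
  27.13 1/h). `hsrpk.fitting.flip_flop_alternative` produces the mirror,
  and all recovery tests score estimates against the closer member of the
  pair. (The curve is *not* invariant under a bare ka↔kel swap — the
  amplitude scales by ka/kel — although the peak time
  ln(ka/kel)/(ka−kel) is.)
* **Linearity.** Multi-dose profiles are exact superpositions of
  time-shifted single-dose terms, so profiles, Cmax and AUC are exactly
  proportional to dose.

Profiles are stored as term lists `coef·(t−τ)^p·e^(−λ(t−τ))`; evaluation,
integration (via regularized incomplete gamma functions) and steady-state
accumulation all stay analytic. Human comparator regimens delivered as
constant-rate infusions use the standard zero-order-input closed form,
expressed as the difference of two step responses so it fits the same term
algebra.

### Periodic steady state

For schedules repeated every T hours, the within-interval limiting profile
is obtained by geometric accumulation: each exponential term's
earlier-interval copies sum to a closed form with factor 1/(1 − e^(−λT))
(polynomial×exponential terms accumulate analogously). A brute-force
alternative (`method="simulate"`) repeats intervals until the
interval-start concentration is stable to 1e-6 relative; the two agree to
~1e-6 relative and the steady-state interval AUC equals the single-course
AUC(0,∞) exactly, which the tests assert. Note that carry-over shortly
after an interval start is governed by the decay since the *previous
interval's last dose*, not by e^(−λT); for the meropenem plasma fixture it
is ≈3.5% of the concentration at t = 0.5 h even though e^(−λT) ≈ 2e-5.

## Exposure metrics

* **%fT>MIC** — the percent of the evaluation window with free
  concentration strictly above a threshold. Crossings are bracketed on a
  ≤0.001 h grid (dose onsets always included) and bisected on the closed
  form to 1e-6 h, making the metric reproducible to well under 0.01
  percentage points. Tabulated across the doubling-dilution ladder
  1–128 mg/L; monotonicity in MIC is enforced by construction.
* **fCmax** — located by dense-grid bracketing plus bounded scalar
  maximisation of the closed form (xatol 1e-10 h). A per-segment analytic
  stationary point exists for pure bi-exponential segments but not for the
  polynomial×exponential terms produced by the penetration correction, so
  the numeric refinement is used uniformly.
* **fAUC** — the exact analytic integral of the term list; trapezoidal
  integration on a 0.001 h grid agrees within 0.1% and adaptive quadrature
  within 1e-8 relative (both tested).

**Evaluation window.** The q8h regimens are evaluated over one dosing
interval at periodic steady state; the single-course tobramycin regimens
over 0–24 h. This convention reproduces the printed murine indices from
the printed parameters (e.g. unbound plasma tobramycin Cmax 17.8 vs the
printed 17.7 mg/L) and is switchable per call via the window argument.

**Binding.** Fitted parameters describe total concentrations; unbound
correction is a post-hoc multiplication by the murine unbound fraction
(0.92 meropenem, 0.684 cefiderocol, 0.776 tobramycin). ELF concentrations
are treated as fully unbound (BAL fluid lacks albumin). Human reference
exposures (%fT>MIC ladders, tobramycin fCmax 18.3/6.8 mg/L and fAUC
103/79 mg·h/L) are literature fixtures loaded from the config, never
computed.

## Matrix corrections

* **Ultrafiltration free fraction**: fu = C_ultrafiltrate/C_total per
  replicate; dose-group means are pooled as an unweighted mean (binding is
  treated as exposure-independent across the studied dose range).
  Fractions > 1 are capped at 1 with a warning; non-positive totals are
  dropped with a warning.
* **BAL urea correction**: C_ELF = C_BAL · (urea_plasma/urea_BAL). Urea
  equilibrates freely into ELF, so the urea ratio measures the saline
  dilution of the lavage. Only the ratio matters, so any consistent urea
  unit is accepted (default mg/dL); urea_BAL > urea_plasma triggers a
  warning (lavage should dilute).
* **Penetration line**: an OLS fit ratio(t) = slope·t + intercept to
  single-timepoint ELF/plasma penetration estimates. The tobramycin line
  (0.1223/h, 0.1567, R² = 0.986, fitted over 0.5–8 h) ships as a fixture
  because the underlying ratios are not published; the fitter itself is
  validated on synthetic data. Applying the line to a profile maps each
  term exactly onto terms of one higher polynomial order, so the ELF
  profile stays analytic. Application outside the fitted time range
  requires an explicit `extrapolate=True`; a line that goes negative
  inside the window is an error. The literature human AUC_ELF/AUC_plasma
  ratio of 0.69 is stored as a fixture; it is not reproducible without the
  unpublished human plasma profile (applying the line to the *murine*
  plasma HSR gives 0.78).

## Model fitting

Destructive sparse sampling (each mouse gives at most two retro-orbital
samples plus one terminal sample) forces a naive-pooled analysis: all
observations form one curve per analyte and matrix.

1. **Outlier screen**: per timepoint × analyte × matrix group, values
   outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are excluded — single pass,
   quartiles by linear interpolation, groups with n < 4 pass through.
   Exclusion tallies are reported per matrix in "x/n (p%)" form. The
   grouping granularity is a package decision; the source protocol states
   only that the IQR method was applied per analyte.
2. **Weighted NLS**: minimise Σ wᵢ(obsᵢ − predᵢ)² in log-parameter space
   (scipy `least_squares`, trf). Weighting options none (default), 1/y,
   1/y²; the reference software's scheme is unknown, so sensitivity is
   left to the caller. Multi-start initialisation is deterministic: the
   terminal log-slope estimates the slower rate constant, V is
   back-extrapolated from the observed peak, and both flip-flop
   assignments of a log-spaced partner grid are tried (8 starts for the
   one-compartment model). Observations below a configured LLOQ are
   dropped, not imputed. Non-convergence is flagged, never silent.
3. **Model selection**: least-squares AIC = n·ln(RSS/n) + 2k among
   converged candidates; exact ties go to the simpler model. A
   two-compartment-with-absorption candidate (tri-exponential closed form)
   is provided purely for this comparison; on data generated from
   one-compartment truths AIC selects the one-compartment model in ≳80–90%
   of replicates.

## Regimen design

The humanization step is formalised as seeded, bounded, two-stage
optimization over dose amounts at fixed candidate injection times:
multi-start L-BFGS-B on the continuous amounts (starts log-uniform within
bounds from a seeded generator plus a midpoint start), then snapping to a
dose grid (default 0.05 mg/kg, finer than the 0.25 mg/kg granularity of
the shipped schedules) with single-step coordinate-descent polish.
Targets are either a profile matched as mean squared log-concentration
difference (floored at 0.01 mg/L so troughs stay finite) or a PD-metric
vector: weighted squared relative differences for fCmax and fAUC, and
squared differences scaled by the full 0–100 scale for %fT>MIC terms
(targets of 0% make a strictly relative form undefined). Class-aware
default weights follow the PD drivers: %fT>MIC for β-lactams, fCmax and
fAUC equally for aminoglycosides. Infeasible targets return the
best-effort regimen with its nonzero loss rather than raising. The
dose split recovered for a degenerate target (many schedules share a peak
and an area) need not equal the reference schedule; the achieved indices
match within 2% in the self-recovery test.

## Synthetic data generator

The generator emulates the structure of a murine PK study: cohorts of six
mice per timepoint, each mouse sampled at up to three consecutive
timepoints (the last terminal); observations are closed-form values with
proportional noise, obs = C(t)·(1 + ε), ε ~ Normal(0, CV) truncated at
−0.99, optional additive noise, and optional multiplicative outliers
(default ×5 or ×10) whose positions are recorded for filter scoring. BAL
studies draw a per-mouse lavage dilution d ~ Uniform(0.01, 0.10) applied
identically to the drug and urea channels (with independent proportional
noise), so the urea correction inverts the dilution exactly at zero noise.
Binding studies set total concentration proportional to dose and
ultrafiltrate = total × fu × (1 + ε). All randomness flows from one
explicit seed; the generating truth rides along in the dataset metadata.

Defaults and why: CV 20% (below the ~30% parameter-level variability
quoted for typical antibiotics in mice); outlier probability 0 unless
requested; urea_plasma 40 mg/dL (mid-normal for mouse, constant across
animals); dilution support 0.01–0.10 (plausible for a 1.6 mL lavage of
murine ELF). The recovery-study sampling schedule
(0.05, 0.1, 0.25, 0.5, 1, 2, 4, 6, 8 h) places two samples below the
~0.19 h tobramycin absorption peak: with a first sample at 0.25 h the
absorption constant is essentially unidentifiable (median error >60%),
which is a statement about study design, not the estimator.

What the generator does **not** emulate: inter-animal parameter
variability (the noise is observation-level only, matching the
naive-pooled estimand), infection or renal-impairment effects on
clearance, assay-specific error structure (the real assays have
concentration-dependent CVs of ~2–12%), blood contamination of BAL, or
inter-occasion variability. Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not performance on any
particular in-vivo dataset.

## Known limitations

* The IQR screen suffers quartile masking in groups of six: a lone ×10
  outlier is removed essentially always, but when two outliers land in the
  same six-animal timepoint group they drag Q3 up and both usually
  survive. At 9% contamination ~37% of outliers share a group, capping the
  expected hit rate near 63–67%; an iterated filter would do better but
  the implemented screen is deliberately single-pass.
* Parameters fitted from data are identifiable only up to the flip-flop
  pair; reported labellings follow whichever basin the best start reaches.
* Human reference exposures are fixtures; the package does not model the
  human PK studies that produced them, and the cefiderocol human ELF row
  is absent because it is only minimally characterized clinically.
* One-compartment kinetics and naive pooling are assumptions inherited
  from the study design; no mixed-effects or physiologic lung model is
  provided.
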
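# Methods

## Endpoint and partition algebra

The regression endpoint is the logarithm of intrinsic clearance referenced
to phospholipid, log10 CL_int,PL (L PL/h/kg^0.75). The reference matters:
P450 enzymes are embedded in the phospholipid bilayer of the endoplasmic
reticulum, and expressing the Michaelis constant in the phase where the
enzyme actually sees the substrate turns out to make clearance regress
cleanly on bulk solubility descriptors, where the blood-referenced endpoint
does not (the blood-referenced two-descriptor fit explains only R² ≈ 0.40
of the same data, versus 0.80 for the phospholipid-referenced fit).

The phospholipid:air partition coefficient is modeled as a 30% lipid / 70%
water mixture, giving

    P_plb = (0.3·P_oa + 0.7·P_wa) / P_ba.

The package never predicts P_wa from structure. For each fixture chemical
it is recovered from the tabulated pair (log P_bw, P_ba) as
P_wa = P_ba / P_bw, and P_oa = P_ow·P_wa. This keeps the package fully
offline and makes the stored P_plb values recomputable from each record's
own fields — a consistency that holds within the 2% printed-rounding
tolerance for 36 of the 37 fixture chemicals. The single exception,
trans-1,2-dichloroethylene, ships the compiled value 11.7 while its own
descriptors imply 9.63; the tests document the recomputed value. Downstream
this affects only that chemical's QPPR-scenario clearance (a few percent on
its AUC), not the extraction-bound scenarios.

## Regression engine

Ordinary least squares with intercept (statsmodels under the hood), with
the diagnostics conventional in QSAR/QPPR work:

- **Stepwise selection**: forward entry on the smallest partial-t p-value
  below `p_enter` (default 0.05), backward removal above `p_remove`
  (default 0.10), ties broken by candidate order — deterministic by
  construction. On the calibration data it selects exactly
  {log P_ow, log P_bw, IP}.
- **Leave-one-out Q²** = 1 − PRESS/SSY, with PRESS from literal refits
  without each point and SSY mean-centered. This is the standard exact
  convention, under which Q² ≤ R² always. On the calibration set it gives
  Q² = 0.722 for the primary model and 0.730 for the phospholipid:water
  variant. (Reference software sometimes reports slightly different Q²
  values depending on the PRESS/SSY convention; the exact-LOO value is the
  one this package asserts.)
- **VIF** per predictor from regressing it on the others with intercept;
  calibration values 2.42 / 2.38 / 1.04, comfortably below the usual
  collinearity alarm at 4.
- **Mean-response confidence interval** at descriptor vector x0 (with
  intercept entry): half-width t_{0.975, n−p−1} · s · sqrt(x0ᵀ(XᵀX)⁻¹x0),
  n−p−1 = 22 for the calibrated model. This is the CI of the *mean*
  prediction — the chosen measure of model uncertainty — not the wider
  prediction interval for a single new chemical.
- **Applicability domain**: the closed descriptor box spanned by the
  calibration set, log P_ow ∈ [1.09, 4.03], log P_bw ∈ [0.16, 2.492],
  IP ∈ [9.13, 11.276] eV. The box uses the data-derived edges rather than
  2-decimal roundings so that every calibration chemical is inside its own
  domain. Of the evaluation set only 1,2,4-trimethylbenzene falls outside
  (IP 9.084 eV).

## PBPK model

A standard inhalation structure for VOCs: four perfusion-limited
compartments (liver, richly perfused, poorly perfused, fat) and a
steady-state gas-exchange lung. The lung holds no mass; arterial blood is
the algebraic equilibrium C_art = (Q_p·C_inh + Q_c·C_ven)/(Q_c + Q_p/P_ba).
Metabolism is hepatic only, removed at rate CL_h·C_art with CL_h = Q_L·E
and the well-stirred extraction E = (CL_int + K_f·V_L)/(CL_int + K_f·V_L
+ Q_L). Four chemicals (chloroethane, dichloromethane, vinyl chloride,
dibromomethane) carry a first-order K_f (1, 2, 1, 0.7 h⁻¹) that
contributes through the liver volume.

Reference physiology: BW 70 kg; cardiac output and alveolar ventilation
both 18·BW^0.74 L/h; tissue volumes 2.6/5/62/19% of BW and flows
26/44/25/5% of cardiac output (liver/rich/poor/fat). The non-perfused 11.4%
of body mass holds no chemical. All defaults are overridable via
`PhysiologySpec` or the CLI `--config` YAML.

Unit and scaling conventions, each isolated so it can be flipped:

- ppm → mg/L via the 24 450 mL/mol molar volume (25 °C, 1 atm):
  C_inh = ppm·MW/24450.
- QPPR clearance is per kg^0.75 and scales to the whole body as
  10^pred · P_plb · BW^0.75 (`human_clint`). With the reference physiology
  this reproduces the published benchmark AUC table cell-by-cell to ~0.3%,
  which is the empirical confirmation of the allometric choice.
- Exposure profiles: the AUC tables use 1 ppm continuous over 24 h; the
  kinetic envelopes and end-of-exposure concentrations use the 8 h
  exposure / 24 h horizon convention.

Numerics: LSODA with rtol 1e-8, atol 1e-10 mg; integration split at the
exposure-off switch so the discontinuity never sits inside a solver step;
output on a 0.1 h grid. The venous AUC and the inhaled/exhaled/metabolized
ledgers are carried as extra ODE states (not post-hoc quadrature), so mass
balance — inhaled = in tissues + exhaled + metabolized — holds to solver
tolerance (observed ~1e-15 relative) at every output time, and halving
tolerances moves AUC₂₄ by far less than 0.01%. A negative-state guard
raises `SolverFailure` naming chemical and scenario.

## Metabolism scenarios and reliability classification

Each chemical runs under four scenarios: E fixed at 0.001 (operational "no
metabolism") and 0.999 ("complete extraction"), and CL_int set from the
LMCI and UMCI of the predicted clearance. Lower clearance ⇒ higher blood
levels, so the venous curves order E_min ≥ LMCI ≥ UMCI ≥ E_max at all
times; this envelope ordering is asserted as a property test.

The reliability call combines:

- **sensitivity** = AUC₂₄(E_min)/AUC₂₄(E_max), and
- **uncertainty** = 10^|pred − exp| on log CL_int,PL (the symmetric fold;
  forced to *high* when no experimental value exists — the screening
  situation, applied to the whole evaluation set).

Both axes bin as low (within a factor of 2), medium (within an order of
magnitude), high (beyond 10-fold); boundaries closed on the left. These
order-of-magnitude thresholds — not a 2–5/>5 split — are the ones under
which the classification reproduces the reference grid for the calibration
chemicals exactly. Confidence: low sensitivity ⇒ high confidence regardless
of uncertainty; medium sensitivity ⇒ high confidence only with low
uncertainty, otherwise medium. High-sensitivity cells are not populated by
the reference analysis; they return *low* with an `extrapolated` flag
rather than pretending to an observed rule. The uncertainty axis uses the
point prediction, not the nearest CI bound.

## Synthetic-chemical generator

`generate_synthetic_chemicals` emulates the study conditions for
property-based tests: descriptors uniform in the applicability box, P_wa
log-uniform over the span of the real chemicals (10^−2.2 to 10^0.7), P_ba
and P_plb derived self-consistently from the partition identities, tissue
PCs drawn from the ranges seen in the fixtures (fat:blood loosely
log-linear in log P_ow), and the endpoint generated from the calibrated
coefficients plus Gaussian noise of σ = 0.3 log units — the residual scale
of the calibrated fit (s = 0.347). Sample size 26 in the recovery test
matches the calibration set. What the generator does *not* emulate:
correlated descriptor structure (real log P_ow and log P_bw correlate at
r ≈ 0.76, giving the VIFs above, while synthetic descriptors are
independent), measurement error in the descriptors themselves, and any
chemistry linking K_f to structure (synthetic kf = 0). Passing recovery
tests on synthetic data therefore demonstrate estimator correctness, not
that three descriptors suffice for real chemistry outside the studied VOC
space.

## Known limitations

- The applicability domain is small: lipophilic, low-molecular-weight,
  mostly halogenated VOCs that are P450-2E1 substrates. No claim is made
  outside the box, and `in_domain` flags accompany every prediction.
- The liver term is linear (CL_int/E); saturable Michaelis–Menten kinetics
  are out of scope, so simulations are meaningful for low (sub-K_m)
  exposures such as the 1 ppm screening scenario.
- Blood-referenced regression of the same data is poor (R² ≈ 0.40) and is
  provided for comparison, not for use.
- The human physiology is a single reference adult; no population
  variability or Monte-Carlo propagation is implemented — uncertainty
  enters only through the clearance CI.
- The classification grid's high-sensitivity row is an explicit
  extrapolation, flagged as such.
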
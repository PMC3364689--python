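# qppr-pbpk

Screening-level prediction of the intrinsic metabolic clearance of volatile
organic chemicals (VOCs), and propagation of its uncertainty through a human
inhalation PBPK model.

## The problem

Building a physiologically based pharmacokinetic (PBPK) model for a new
inhaled chemical almost always stalls on one parameter: the hepatic
metabolism rate. Partition coefficients can be measured in vials or
estimated from composition, but intrinsic clearance (CL_int = V_max/K_m)
normally requires an in-vivo or in-vitro study. This package implements a
pragmatic alternative for risk screeners and toxicokinetic modelers: a
quantitative property–property relationship (QPPR) that predicts CL_int of
low-molecular-weight VOCs from three cheap descriptors, plus machinery to
carry the *uncertainty* of that prediction — not just its point value —
through to the blood-concentration dose metrics a risk assessor actually
uses.

## The model

Because cytochrome P450 enzymes sit in the phospholipid bilayer of the
endoplasmic reticulum, clearance is referenced to phospholipid rather than
blood. The endpoint transformation uses the phospholipid:blood partition
coefficient

    P_plb = (0.3·P_oa + 0.7·P_wa) / P_ba,

and the calibrated regression on 26 VOCs with in-vivo rat clearance data is

    log10 CL_int,PL = 5.63 − 1.287·log10 P_ow + 1.08·log10 P_bw − 0.328·IP

(R² = 0.796, leave-one-out Q² = 0.72, VIFs ≤ 2.42; CL_int,PL in
L PL/h/kg^0.75, IP the ionization potential in eV). The 95% confidence
bounds of the mean prediction (LMCI, UMCI) are converted to whole-body
blood-referenced clearance, CL_int = 10^pred · P_plb · BW^0.75, and fed
into a four-compartment (liver, fat, richly and poorly perfused) PBPK
model with a steady-state gas-exchange lung and a well-stirred liver:

    E = (CL_int + K_f·V_L) / (CL_int + K_f·V_L + Q_L),   CL_h = Q_L·E.

Each chemical is simulated under four metabolism scenarios — the
physiological bounds E = 0.001 and E = 0.999, and the two QPPR confidence
bounds — and the 24 h venous AUC under each scenario supports a two-axis
reliability call: how *sensitive* the AUC is to metabolism at all
(AUC ratio of the E bounds) versus how *uncertain* the clearance
prediction is (fold difference from experiment).

## Worked example

Predict benzene's clearance with its confidence bounds:

```sh
$ qppr-pbpk qppr predict --chemical benzene
{"chemical": "benzene", "point": 0.757, "lmci": 0.561, "umci": 0.953,
 "level": 0.95, "in_domain": true}
```

The model predicts log10 CL_int,PL = 0.76 (experimental: 0.667), with the
95% mean-confidence interval [0.56, 0.95] — a 0.39-log-unit band. Simulate
1 ppm inhaled benzene for 24 h with clearance at the lower bound:

```sh
$ qppr-pbpk pbpk --chemical benzene --scenario lmci --ppm 1 \
      --exposure-h 24 --sim-h 24
{"chemical": "benzene", "scenario": "LMCI", "auc24": 0.1553,
 "c_end_exposure": 0.00691, "mass_balance_error": 5.5e-16}
```

The 24 h venous AUC is 0.155 mg·h/L; the four scenarios for benzene give
0.437 (E_min), 0.155 (LMCI), 0.138 (UMCI) and 0.125 (E_max) mg·h/L, i.e.
the QPPR bounds shrink the 3.5-fold physiological ignorance band to a
1.12-fold band. The partition algebra is also exposed directly:

```sh
$ qppr-pbpk pc derive --log-pow 1.99 --log-pbw 0.820 --pba 8.19
{ ... "pplb": 4.543 ... }
```

`qppr-pbpk reproduce --out-dir out/` runs the whole pipeline (regression
report, CI widths, the 4-scenario AUC table for all 37 chemicals, and the
reliability tables) and writes CSV/JSON reports; two runs are
byte-identical.

## Layout

- `src/qppr_pbpk/datasets.py` — fixture records, physiology, synthetic
  chemical generator
- `src/qppr_pbpk/partitioning.py` — partition-coefficient algebra and
  clearance reference transforms
- `src/qppr_pbpk/regression.py` — OLS engine, stepwise selection, LOO Q²,
  VIF, mean-CI prediction, applicability domain
- `src/qppr_pbpk/pbpk.py` — inhalation PBPK model and scenarios
- `src/qppr_pbpk/reliability.py` — sensitivity × uncertainty confidence grid
- `src/qppr_pbpk/workflows.py`, `cli.py` — end-to-end reproduction and the
  `qppr-pbpk` command

See `docs/methods.md` for model assumptions, numerical choices and known
limitations.
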
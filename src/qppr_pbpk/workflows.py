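"""End-to-end workflows: calibrate the clearance model, propagate its
confidence bounds through the PBPK model for all 37 chemicals, classify
reliability, and write a machine-readable report.

All computations are deterministic: two consecutive runs produce identical
reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, pbpk, regression, reliability
from .datasets import ChemicalRecord, PhysiologySpec
from .pbpk import ExposureSpec, run_four_scenarios

__all__ = [
    "calibration_fit",
    "ci_width_table",
    "auc_table",
    "reliability_table",
    "regression_report",
    "export_envelopes",
    "reproduce_all",
]

log = logging.getLogger("qppr_pbpk")

PREDICTORS = ("log_pow", "log_pbw", "ip")


def _reg_records(records: list[ChemicalRecord],
                 response: str = "pl") -> list:
    """(descriptor-mapping, response) pairs for the regression engine.

    ``response="pl"`` uses the phospholipid-referenced endpoint;
    ``"blood"`` converts to blood reference by adding log10 P_plb;
    descriptor mappings also expose log_pplw = log P_plb + log P_bw for
    the phospholipid:water variant model.
    """
    out = []
    for r in records:
        log_pplb = np.log10(r.p_pl_blood)
        desc = {"log_pow": r.log_pow, "log_pbw": r.log_pbw, "ip": r.ip,
                "log_pplw": log_pplb + r.log_pbw}
        y = r.log_clint_pl_exp + (log_pplb if response == "blood" else 0.0)
        out.append((desc, y))
    return out


def calibration_fit(records: list[ChemicalRecord] | None = None
                    ) -> regression.RegressionFit:
    """The calibrated three-descriptor model for log10 CL_int,PL."""
    records = records or datasets.load_calibration_set()
    return regression.fit_multilinear(_reg_records(records), PREDICTORS)


def ci_width_table(fit: regression.RegressionFit,
                   records: list[ChemicalRecord],
                   level: float = 0.95) -> pd.DataFrame:
    """Per-chemical mean-CI bounds and widths at the fixture descriptors."""
    rows = []
    box = regression.DomainBox(datasets.DESCRIPTOR_DOMAIN)
    for r in records:
        ci = regression.predict_mean_ci(fit, r.descriptor_vector(), level,
                                        box=box)
        rows.append({"name": r.name, "dataset": r.dataset,
                     "point": ci.point, "lmci": ci.lmci, "umci": ci.umci,
                     "width": ci.width, "in_domain": ci.in_domain})
    return pd.DataFrame(rows)


def auc_table(fit: regression.RegressionFit,
              records: list[ChemicalRecord],
              phys: PhysiologySpec | None = None,
              conc_ppm: float = 1.0,
              exposure_h: float = 24.0,
              sim_h: float = 24.0) -> pd.DataFrame:
    """24 h venous AUC under the four metabolism scenarios, per chemical."""
    phys = phys or PhysiologySpec()
    rows = []
    for r in records:
        exp = ExposureSpec(conc_ppm=conc_ppm, mw=r.mw,
                           t_end_exposure=exposure_h, t_sim=sim_h)
        res = run_four_scenarios(r, phys, exp, fit)
        row = {"name": r.name, "dataset": r.dataset}
        for sc in pbpk.SCENARIOS:
            row[f"auc24_{sc}"] = res[sc].auc24
            row[f"c_end_{sc}"] = res[sc].c_end_exposure
        row["mass_balance_error"] = max(
            res[sc].mass_balance_error for sc in pbpk.SCENARIOS)
        rows.append(row)
    return pd.DataFrame(rows)


def reliability_table(fit: regression.RegressionFit,
                      aucs: pd.DataFrame,
                      records: list[ChemicalRecord],
                      withhold_experimental: bool = False) -> pd.DataFrame:
    """Two-axis reliability calls from the pipeline's own AUCs/predictions.

    ``withhold_experimental=True`` emulates the screening situation of a
    chemical with unknown clearance (uncertainty forced high), the
    convention applied to the evaluation set.
    """
    by_name = aucs.set_index("name")
    rows = []
    for r in records:
        pred = fit.predict(r.descriptor_vector())
        call = reliability.classify(
            r.name,
            auc_emin=by_name.loc[r.name, "auc24_E_min"],
            auc_emax=by_name.loc[r.name, "auc24_E_max"],
            pred_log_clint_pl=pred,
            exp_log_clint_pl=(None if withhold_experimental
                              else r.log_clint_pl_exp))
        rows.append(asdict(call))
    return pd.DataFrame(rows)


def regression_report(cal: list[ChemicalRecord] | None = None) -> dict:
    """Statistics of the primary, phospholipid:water-variant and
    blood-referenced regressions on the calibration set."""
    cal = cal or datasets.load_calibration_set()
    recs = _reg_records(cal)
    fit = regression.fit_multilinear(recs, PREDICTORS)
    fit_pplw = regression.fit_multilinear(recs, ("log_pplw", "log_pbw", "ip"))
    fit_blood = regression.fit_multilinear(_reg_records(cal, "blood"),
                                           ("log_pow", "ip"))
    step = regression.stepwise_select(recs, list(PREDICTORS))

    def block(f):
        return {
            "predictors": list(f.predictor_names),
            "coefficients": [float(c) for c in f.coefficients],
            "coef_standard_errors": [float(c)
                                     for c in f.coef_standard_errors],
            "r2": f.r2, "r2_adj": f.r2_adj, "q2": f.q2, "s": f.s,
            "f_stat": f.f_stat,
            "vifs": [float(v) for v in f.vifs],
        }

    return {
        "primary": block(fit),
        "pplw_variant": block(fit_pplw),
        "blood_referenced": block(fit_blood),
        "stepwise_selected": list(step.predictor_names),
        "applicability_domain": {k: list(v) for k, v in
                                 datasets.DESCRIPTOR_DOMAIN.items()},
    }


def export_envelopes(chemical: str, out: str | Path,
                     phys: PhysiologySpec | None = None,
                     conc_ppm: float = 1.0,
                     exposure_h: float = 8.0,
                     sim_h: float = 24.0) -> pd.DataFrame:
    """Four aligned venous-concentration series for one chemical.

    Uses the figure convention (8 h exposure, 24 h horizon, 0.1 h grid)
    and writes a CSV with one column per scenario; at every time point
    E_min >= LMCI >= UMCI >= E_max.
    """
    rec = datasets.get_record(chemical)
    phys = phys or PhysiologySpec()
    fit = calibration_fit()
    exp = ExposureSpec(conc_ppm=conc_ppm, mw=rec.mw,
                       t_end_exposure=exposure_h, t_sim=sim_h)
    res = run_four_scenarios(rec, phys, exp, fit)
    df = pd.DataFrame({"time_h": res["E_min"].time_grid})
    for sc in pbpk.SCENARIOS:
        df[f"c_ven_{sc}"] = res[sc].c_ven
    df.to_csv(out, index=False)
    return df


def _summary(aucs: pd.DataFrame) -> dict:
    r_e = aucs["auc24_E_min"] / aucs["auc24_E_max"]
    r_q = aucs["auc24_LMCI"] / aucs["auc24_UMCI"]
    c_e = aucs["c_end_E_min"] / aucs["c_end_E_max"]
    c_q = aucs["c_end_LMCI"] / aucs["c_end_UMCI"]
    return {
        "mean_auc_ratio_emin_emax": float(r_e.mean()),
        "sd_auc_ratio_emin_emax": float(r_e.std(ddof=1)),
        "mean_auc_ratio_qppr": float(r_q.mean()),
        "sd_auc_ratio_qppr": float(r_q.std(ddof=1)),
        "mean_cend_ratio_emin_emax": float(c_e.mean()),
        "mean_cend_ratio_qppr": float(c_q.mean()),
    }


def reproduce_all(out_dir: str | Path,
                  phys: PhysiologySpec | None = None) -> dict:
    """Run the complete pipeline and write report JSON plus CSV tables.

    Stages: regression block, per-chemical CI widths, the 4-scenario AUC
    table for all 37 chemicals (1 ppm continuous 24 h), the 8 h
    end-of-exposure concentration ratios, and the two reliability tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phys = phys or PhysiologySpec()
    report: dict = {}

    t0 = time.time()
    cal = datasets.load_calibration_set()
    ev = datasets.load_evaluation_set()
    fit = calibration_fit(cal)
    report["regression"] = regression_report(cal)
    log.info("regression block done in %.1fs", time.time() - t0)

    t0 = time.time()
    widths = ci_width_table(fit, cal + ev)
    widths.to_csv(out_dir / "ci_widths.csv", index=False)
    for ds in ("calibration", "evaluation"):
        w = widths[widths.dataset == ds]["width"]
        report[f"ci_widths_{ds}"] = {
            "mean": float(w.mean()), "sd": float(w.std(ddof=1)),
            "min": float(w.min()), "max": float(w.max())}
    log.info("CI block done in %.1fs", time.time() - t0)

    t0 = time.time()
    auc_cal = auc_table(fit, cal, phys)
    auc_ev = auc_table(fit, ev, phys)
    aucs = pd.concat([auc_cal, auc_ev], ignore_index=True)
    aucs.to_csv(out_dir / "auc_table.csv", index=False)
    # end-of-exposure concentrations under the 8 h figure convention
    cend_cal = auc_table(fit, cal, phys, exposure_h=8.0, sim_h=24.0)
    cend_ev = auc_table(fit, ev, phys, exposure_h=8.0, sim_h=24.0)
    report["summary"] = {
        "calibration": {**_summary(auc_cal),
                        "cend_8h": _summary(cend_cal)},
        "evaluation": {**_summary(auc_ev),
                       "cend_8h": _summary(cend_ev)},
    }
    log.info("PBPK block done in %.1fs", time.time() - t0)

    t0 = time.time()
    rel_cal = reliability_table(fit, auc_cal, cal)
    rel_ev = reliability_table(fit, auc_ev, ev, withhold_experimental=True)
    rel_cal.to_csv(out_dir / "reliability_calibration.csv", index=False)
    rel_ev.to_csv(out_dir / "reliability_evaluation.csv", index=False)
    report["reliability"] = {
        "calibration": rel_cal.groupby(
            ["sensitivity_class", "uncertainty_class"])["chemical"]
            .apply(sorted).apply(list).to_dict(),
        "evaluation": rel_ev.groupby(
            ["sensitivity_class", "uncertainty_class"])["chemical"]
            .apply(sorted).apply(list).to_dict(),
    }
    report["reliability"] = {
        ds: {f"{k[0]}|{k[1]}": v for k, v in grid.items()}
        for ds, grid in report["reliability"].items()}
    log.info("reliability block done in %.1fs", time.time() - t0)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
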
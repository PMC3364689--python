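"""Human inhalation PBPK model for volatile organic chemicals.

Four perfusion-limited tissue compartments (liver, richly perfused, poorly
perfused, fat) connected by blood flow, with a steady-state gas-exchange
lung.  The lung carries no chemical mass; arterial blood leaving it is the
flow-weighted equilibrium

    C_art = (Qp*C_inh + Qc*C_ven) / (Qc + Qp/P_ba)

Each tissue obeys dA_t/dt = Q_t*(C_art - C_t/P_tb); mixed venous blood is
C_ven = sum(Q_t * C_t/P_tb) / Qc.  Metabolism is hepatic only and removed
at the rate CL_h * C_art with CL_h = Q_L * E, where the extraction ratio E
comes either from a fixed value (the bounding scenarios E=0.001 and
E=0.999) or from the well-stirred relation

    E = (CL_int + K_f*V_L) / (CL_int + K_f*V_L + Q_L)

with CL_int the blood-referenced intrinsic clearance (L/h) and K_f an
optional first-order constant (1/h) acting on the liver volume V_L.

The venous AUC and the inhaled/exhaled/metabolized ledgers are carried as
extra ODE states, so they share the integrator's error control; mass
balance (inhaled = in tissues + exhaled + metabolized) holds to solver
tolerance at every output time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .datasets import ChemicalRecord, PhysiologySpec
from .regression import RegressionFit, predict_mean_ci

__all__ = [
    "ClearanceSpec",
    "ExposureSpec",
    "SimulationResult",
    "SolverFailure",
    "MOLAR_VOLUME_ML",
    "ppm_to_mg_per_l",
    "human_clint",
    "hepatic_extraction",
    "simulate",
    "run_four_scenarios",
    "auc",
    "SCENARIOS",
]

#: Molar volume of an ideal gas at 25 degC, 1 atm (mL/mol); the standard
#: convention for ppm -> mg/L conversion in inhalation PBPK work.
MOLAR_VOLUME_ML = 24450.0

SCENARIOS = ("E_min", "E_max", "LMCI", "UMCI")


class SolverFailure(RuntimeError):
    """The ODE integrator failed; message carries chemical and scenario."""


@dataclass(frozen=True)
class ClearanceSpec:
    """Hepatic clearance, either as a fixed extraction ratio or derived
    from a blood-referenced intrinsic clearance (L/h) plus optional kf."""

    mode: str                        # "fixed_extraction"|"intrinsic_clearance"
    e_fixed: float | None = None     # dimensionless, in (0, 1)
    clint_blood: float | None = None  # L blood/h, whole body
    kf: float = 0.0                  # 1/h

    def __post_init__(self) -> None:
        if self.mode == "fixed_extraction":
            if self.e_fixed is None or self.clint_blood is not None:
                raise ValueError("fixed_extraction needs e_fixed only")
            if not 0.0 < self.e_fixed < 1.0:
                raise ValueError(f"e_fixed must be in (0,1), "
                                 f"got {self.e_fixed}")
        elif self.mode == "intrinsic_clearance":
            if self.clint_blood is None or self.e_fixed is not None:
                raise ValueError("intrinsic_clearance needs clint_blood only")
            if self.clint_blood < 0 or self.kf < 0:
                raise ValueError("clint_blood and kf must be >= 0")
        else:
            raise ValueError(f"unknown clearance mode {self.mode!r}")

    def extraction(self, q_liver: float, v_liver: float) -> float:
        if self.mode == "fixed_extraction":
            return self.e_fixed
        return hepatic_extraction(self.clint_blood, self.kf,
                                  v_liver, q_liver)


@dataclass(frozen=True)
class ExposureSpec:
    """Inhalation exposure: ``conc_ppm`` from ``t_start`` to
    ``t_end_exposure``, simulated out to ``t_sim`` (hours)."""

    conc_ppm: float
    mw: float                 # g/mol
    t_start: float = 0.0
    t_end_exposure: float = 24.0
    t_sim: float = 24.0

    def __post_init__(self) -> None:
        if self.conc_ppm < 0 or self.mw <= 0:
            raise ValueError("conc_ppm must be >= 0 and mw > 0")
        if not (0.0 <= self.t_start < self.t_end_exposure <= self.t_sim):
            raise ValueError("need 0 <= t_start < t_end_exposure <= t_sim")

    @property
    def c_inhaled(self) -> float:
        """Inhaled air concentration during exposure, mg/L."""
        if self.conc_ppm == 0:
            return 0.0
        return ppm_to_mg_per_l(self.conc_ppm, self.mw)


@dataclass(frozen=True)
class SimulationResult:
    """Time courses and integrated dose metrics of one PBPK run."""

    time_grid: np.ndarray              # h
    c_ven: np.ndarray                  # mg/L
    c_art: np.ndarray                  # mg/L
    tissue_amounts: Mapping[str, np.ndarray]   # mg
    auc_series: np.ndarray             # mg*h/L, integral of c_ven from 0
    amount_inhaled: np.ndarray         # mg, cumulative
    amount_exhaled: np.ndarray         # mg, cumulative
    amount_metabolized: np.ndarray     # mg, cumulative
    auc24: float                       # mg*h/L
    c_end_exposure: float              # mg/L
    mass_balance_error: float          # max relative error over the grid


def ppm_to_mg_per_l(conc_ppm: float, mw: float) -> float:
    """Gas-phase ppm (v/v) to mg/L via the molar volume at 25 degC."""
    if conc_ppm <= 0 or mw <= 0:
        raise ValueError("conc_ppm and mw must be > 0")
    return conc_ppm * mw / MOLAR_VOLUME_ML


def human_clint(clint_pl_log10: float, pplb: float, bw: float) -> float:
    """Whole-body blood-referenced intrinsic clearance, L/h.

    Converts a log10 phospholipid-referenced clearance (L PL/h/kg^0.75) to
    blood reference via the phospholipid:blood PC and scales allometrically
    by bw^0.75.
    """
    if bw <= 0 or pplb <= 0:
        raise ValueError("bw and pplb must be > 0")
    return 10.0 ** clint_pl_log10 * pplb * bw ** 0.75


def hepatic_extraction(clint: float, kf: float, v_liver: float,
                       q_liver: float) -> float:
    """Well-stirred hepatic extraction ratio.

    ``E = (clint + kf*v_liver) / (clint + kf*v_liver + q_liver)``; the
    hepatic clearance is then ``Q_L * E``.
    """
    if q_liver <= 0:
        raise ValueError("q_liver must be > 0")
    if clint < 0 or kf < 0 or v_liver < 0:
        raise ValueError("clint, kf and v_liver must be >= 0")
    num = clint + kf * v_liver
    return num / (num + q_liver)


def simulate(chem: ChemicalRecord, phys: PhysiologySpec,
             exposure: ExposureSpec, clearance: ClearanceSpec,
             rtol: float = 1e-8, atol: float = 1e-10,
             output_dt: float = 0.1,
             scenario: str = "") -> SimulationResult:
    """Integrate the inhalation PBPK mass balances for one chemical.

    Integration is split at the end of exposure so the inlet-concentration
    step never sits inside a solver step.  Output is on a uniform
    ``output_dt`` grid (plus the switch time).
    """
    vols = phys.tissue_volumes()
    flows = phys.tissue_flows()
    qc = phys.cardiac_output
    qp = phys.alveolar_ventilation
    ptb = np.array([chem.p_liver_blood, chem.p_rich_blood,
                    chem.p_poor_blood, chem.p_fat_blood])
    pba = chem.pba
    clh = phys.liver_flow * clearance.extraction(phys.liver_flow,
                                                 phys.liver_volume)

    def c_art_of(c_inh: float, c_ven: float) -> float:
        return (qp * c_inh + qc * c_ven) / (qc + qp / pba)

    def rhs(t, state, c_inh):
        a = state[:4]
        cvt = a / vols / ptb
        c_ven = float(flows @ cvt) / qc
        c_art = c_art_of(c_inh, c_ven)
        da = flows * (c_art - cvt)
        da[0] -= clh * c_art
        # extra states: venous AUC, inhaled, exhaled, metabolized
        return np.concatenate([da, [c_ven,
                                    qp * c_inh,
                                    qp * c_art / pba,
                                    clh * c_art]])

    c_in = exposure.c_inhaled
    segments = []
    if exposure.t_start > 0:
        segments.append((0.0, exposure.t_start, 0.0))
    segments.append((exposure.t_start, exposure.t_end_exposure, c_in))
    if exposure.t_sim > exposure.t_end_exposure:
        segments.append((exposure.t_end_exposure, exposure.t_sim, 0.0))

    state = np.zeros(8)
    times = [np.array([0.0])]
    states = [state.reshape(-1, 1)]
    for t0, t1, c_inh in segments:
        n_pts = max(2, int(round((t1 - t0) / output_dt)) + 1)
        t_eval = np.linspace(t0, t1, n_pts)
        sol = solve_ivp(rhs, (t0, t1), state, args=(c_inh,),
                        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise SolverFailure(
                f"integration failed for {chem.name!r}"
                + (f" scenario {scenario!r}" if scenario else "")
                + f": {sol.message}")
        state = sol.y[:, -1]
        times.append(sol.t[1:])
        states.append(sol.y[:, 1:])
    t = np.concatenate(times)
    y = np.concatenate(states, axis=1)

    if np.any(y[:4] < -atol * 10):
        raise SolverFailure(
            f"negative tissue amount for {chem.name!r}; tighten tolerances")
    y[:4] = np.clip(y[:4], 0.0, None)

    amounts = y[:4]
    cvt = amounts / vols[:, None] / ptb[:, None]
    c_ven = (flows @ cvt) / qc
    c_inh_t = np.where((t >= exposure.t_start) & (t < exposure.t_end_exposure),
                       c_in, 0.0)
    c_art = (qp * c_inh_t + qc * c_ven) / (qc + qp / pba)

    inhaled, exhaled, metab = y[5], y[6], y[7]
    in_body = amounts.sum(axis=0)
    scale = np.maximum(inhaled, atol + c_in + 1e-12)
    mb_err = float(np.abs(inhaled - in_body - exhaled - metab).max()
                   / scale.max()) if inhaled.max() > 0 else 0.0

    auc24_val = float(np.interp(min(24.0, exposure.t_sim), t, y[4]))
    c_end = float(np.interp(exposure.t_end_exposure, t, c_ven))
    return SimulationResult(
        time_grid=t, c_ven=c_ven, c_art=c_art,
        tissue_amounts={name: amounts[i]
                        for i, name in enumerate(PhysiologySpec.TISSUES)},
        auc_series=y[4], amount_inhaled=inhaled, amount_exhaled=exhaled,
        amount_metabolized=metab, auc24=auc24_val, c_end_exposure=c_end,
        mass_balance_error=mb_err)


def run_four_scenarios(chem: ChemicalRecord, phys: PhysiologySpec,
                       exposure: ExposureSpec, fit: RegressionFit,
                       **solver_kw) -> dict[str, SimulationResult]:
    """The four bounding metabolism scenarios for one chemical.

    ``E_min``/``E_max`` fix the hepatic extraction ratio at 0.001 and
    0.999 (the physiological no-metabolism / complete-extraction bounds);
    ``LMCI``/``UMCI`` convert the lower and upper 95% mean-confidence
    bounds of the regression-predicted log10 phospholipid-referenced
    clearance into blood-referenced intrinsic clearance.  Lower clearance
    means higher blood levels, so AUC(E_min) >= AUC(LMCI) >= AUC(UMCI) >=
    AUC(E_max).
    """
    ci = predict_mean_ci(fit, chem.descriptor_vector())
    specs = {
        "E_min": ClearanceSpec(mode="fixed_extraction", e_fixed=0.001),
        "E_max": ClearanceSpec(mode="fixed_extraction", e_fixed=0.999),
        "LMCI": ClearanceSpec(
            mode="intrinsic_clearance",
            clint_blood=human_clint(ci.lmci, chem.p_pl_blood, phys.bw),
            kf=chem.kf),
        "UMCI": ClearanceSpec(
            mode="intrinsic_clearance",
            clint_blood=human_clint(ci.umci, chem.p_pl_blood, phys.bw),
            kf=chem.kf),
    }
    return {name: simulate(chem, phys, exposure, spec, scenario=name,
                           **solver_kw)
            for name, spec in specs.items()}


def auc(result: SimulationResult, t_end: float) -> float:
    """Venous AUC from 0 to ``t_end`` via the carried integral state."""
    if t_end > result.time_grid[-1] or t_end < 0:
        raise ValueError(
            f"t_end={t_end} outside simulated horizon "
            f"[0, {result.time_grid[-1]}]")
    return float(np.interp(t_end, result.time_grid, result.auc_series))
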
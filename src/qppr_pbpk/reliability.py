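"""Two-axis reliability classification of QPPR-driven PBPK predictions.

Whether a screening-level clearance model is good enough for a given
chemical depends on two independent questions:

* **Sensitivity** — how much does the dose metric (24 h venous AUC) depend
  on metabolism at all?  Measured as the ratio of the AUC with no
  metabolism (E = 0.001) to the AUC with maximal hepatic extraction
  (E = 0.999).  If that ratio is small, even a poor clearance estimate
  cannot mislead the PBPK prediction much.
* **Uncertainty** — how far is the model-predicted clearance from the
  experimental value?  Measured as the symmetric fold difference
  ``10**abs(log10 pred - log10 exp)``; when no experimental value exists
  (the screening situation), uncertainty is taken as *high*.

Both axes are binned as: low if within a factor of 2, medium if within an
order of magnitude, high beyond 10-fold.  Boundary values fall in the
lower class (closed on the left).  The combined confidence call follows
the grid used in screening practice: low sensitivity means high confidence
whatever the uncertainty; medium sensitivity gives high confidence only
with low uncertainty and medium confidence otherwise.  High-sensitivity
cells are not populated by the reference analysis; they return *low*
confidence flagged as extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReliabilityCall",
    "sensitivity_class",
    "uncertainty_class",
    "confidence_call",
    "SENSITIVITY_THRESHOLDS",
    "UNCERTAINTY_THRESHOLDS",
]

#: (low/medium boundary, medium/high boundary): within a factor of 2 is
#: low, within an order of magnitude is medium, beyond is high.
SENSITIVITY_THRESHOLDS = (2.0, 10.0)
UNCERTAINTY_THRESHOLDS = (2.0, 10.0)


@dataclass(frozen=True)
class ReliabilityCall:
    """Classification of one chemical on the sensitivity x uncertainty
    grid, with the underlying ratios."""

    chemical: str
    sensitivity_ratio: float   # AUC(E_min) / AUC(E_max), >= 1
    sensitivity_class: str
    uncertainty_ratio: float   # symmetric fold, >= 1
    uncertainty_class: str
    confidence: str
    extrapolated: bool = False


def _bin(ratio: float, thresholds: tuple[float, float]) -> str:
    lo, hi = thresholds
    if ratio <= lo:
        return "low"
    if ratio <= hi:
        return "medium"
    return "high"


def sensitivity_class(auc_emin: float, auc_emax: float
                      ) -> tuple[str, float]:
    """Class and ratio of the metabolism-sensitivity axis."""
    if auc_emin <= 0 or auc_emax <= 0:
        raise ValueError("AUCs must be > 0")
    ratio = auc_emin / auc_emax
    return _bin(ratio, SENSITIVITY_THRESHOLDS), ratio


def uncertainty_class(pred_log_clint_pl: float,
                      exp_log_clint_pl: float | None
                      ) -> tuple[str, float]:
    """Class and symmetric fold of the prediction-uncertainty axis.

    ``exp_log_clint_pl=None`` marks a chemical without experimental
    clearance; the screening convention assigns high uncertainty
    (fold reported as inf).
    """
    import math
    if exp_log_clint_pl is None:
        return "high", math.inf
    if not (math.isfinite(pred_log_clint_pl)
            and math.isfinite(exp_log_clint_pl)):
        raise ValueError("log clearances must be finite")
    fold = 10.0 ** abs(pred_log_clint_pl - exp_log_clint_pl)
    return _bin(fold, UNCERTAINTY_THRESHOLDS), fold


_CONFIDENCE_GRID = {
    ("low", "low"): "high",
    ("low", "medium"): "high",
    ("low", "high"): "high",
    ("medium", "low"): "high",
    ("medium", "medium"): "medium",
    ("medium", "high"): "medium",
}


def confidence_call(sensitivity: str, uncertainty: str
                    ) -> tuple[str, bool]:
    """Confidence in using the clearance model inside the PBPK model.

    Returns (confidence, extrapolated); ``extrapolated`` is True for the
    high-sensitivity cells, which the reference analysis never populates
    and for which *low* is a conservative default rather than an observed
    rule.
    """
    for v in (sensitivity, uncertainty):
        if v not in ("low", "medium", "high"):
            raise ValueError(f"unknown class {v!r}")
    if sensitivity == "high":
        return "low", True
    return _CONFIDENCE_GRID[(sensitivity, uncertainty)], False


def classify(chemical: str, auc_emin: float, auc_emax: float,
             pred_log_clint_pl: float,
             exp_log_clint_pl: float | None) -> ReliabilityCall:
    """Full two-axis call for one chemical."""
    s_cls, s_ratio = sensitivity_class(auc_emin, auc_emax)
    u_cls, u_fold = uncertainty_class(pred_log_clint_pl, exp_log_clint_pl)
    conf, extrap = confidence_call(s_cls, u_cls)
    return ReliabilityCall(
        chemical=chemical, sensitivity_ratio=s_ratio,
        sensitivity_class=s_cls, uncertainty_ratio=u_fold,
        uncertainty_class=u_cls, confidence=conf, extrapolated=extrap)
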
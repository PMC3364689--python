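"""Packaged chemical datasets and the synthetic-chemical generator.

The package ships a curated table of 37 low-molecular-weight volatile
organic chemicals (VOCs): a 26-chemical calibration set with experimental
in-vivo intrinsic clearance (phospholipid-referenced, from rat gas-uptake
studies) and an 11-chemical external evaluation set.  Each record carries
the three regression descriptors (log Pow, log Pbw, ionization potential),
the rat blood:air and human tissue:blood partition coefficients used by the
inhalation PBPK model, a standard molecular weight, and a first-order
hepatic rate constant kf (nonzero for four chemicals).

`generate_synthetic_chemicals` produces seeded, self-consistent records
inside the calibration descriptor box for property-based testing and
parameter-recovery studies.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .partitioning import derive_partition_set

__all__ = [
    "ChemicalRecord",
    "PhysiologySpec",
    "ValidationError",
    "DESCRIPTOR_DOMAIN",
    "CALIBRATED_COEFFICIENTS",
    "load_calibration_set",
    "load_evaluation_set",
    "load_all_records",
    "resolve_name",
    "records_to_csv",
    "records_from_csv",
    "generate_synthetic_chemicals",
]


class ValidationError(ValueError):
    """A fixture record violates the dataset schema."""


#: Descriptor applicability box of the calibrated clearance model:
#: [min, max] over the 26 calibration chemicals.
DESCRIPTOR_DOMAIN: dict[str, tuple[float, float]] = {
    "log_pow": (1.09, 4.03),
    "log_pbw": (0.16, 2.492),
    "ip": (9.13, 11.276),
}

#: Coefficients of the calibrated three-descriptor clearance model
#: (intercept, log_pow, log_pbw, ip), log10(L PL/h/kg^0.75) scale.  Used
#: only as the default ground truth of the synthetic generator; the
#: regression module always refits from data.
CALIBRATED_COEFFICIENTS: tuple[float, float, float, float] = (
    5.63, -1.287, 1.08, -0.328)


@dataclass(frozen=True)
class ChemicalRecord:
    """One VOC with descriptors, partition coefficients and endpoint.

    ``log_clint_pl_exp`` is log10 of the experimental intrinsic clearance
    referenced to phospholipid, in L PL/h/kg^0.75.  ``kf`` is a first-order
    hepatic metabolic constant (1/h).  All partition coefficients are
    dimensionless concentration ratios.
    """

    name: str
    dataset: str  # "calibration" | "evaluation" | "synthetic"
    log_pow: float
    log_pbw: float
    ip: float
    pba: float
    p_liver_blood: float
    p_rich_blood: float
    p_poor_blood: float
    p_fat_blood: float
    p_pl_blood: float
    log_clint_pl_exp: float
    mw: float
    kf: float = 0.0

    def descriptor_vector(self) -> np.ndarray:
        """Descriptors in regression order (log_pow, log_pbw, ip)."""
        return np.array([self.log_pow, self.log_pbw, self.ip])

    def validate(self) -> None:
        if self.dataset not in ("calibration", "evaluation", "synthetic"):
            raise ValidationError(
                f"{self.name}: unknown dataset {self.dataset!r}")
        for pc in ("pba", "p_liver_blood", "p_rich_blood", "p_poor_blood",
                   "p_fat_blood", "p_pl_blood", "mw"):
            v = getattr(self, pc)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{self.name}: field {pc} must be a positive finite "
                    f"number, got {v!r}")
        if self.kf < 0:
            raise ValidationError(f"{self.name}: kf must be >= 0")
        for f in ("log_pow", "log_pbw", "ip", "log_clint_pl_exp"):
            if not np.isfinite(getattr(self, f)):
                raise ValidationError(f"{self.name}: field {f} is not finite")


@dataclass(frozen=True)
class PhysiologySpec:
    """Reference adult human physiology for the inhalation PBPK model.

    Cardiac output and alveolar ventilation scale allometrically as
    ``coeff * bw**0.74`` (L/h).  Tissue volumes are fractions of body
    weight (1 kg ~ 1 L); the non-perfused remainder of the body holds no
    chemical.  Flows are fractions of cardiac output and must sum to 1.
    """

    bw: float = 70.0            # kg
    qc_coeff: float = 18.0      # L/h/kg^0.74
    qp_coeff: float = 18.0      # L/h/kg^0.74
    vol_frac: Mapping[str, float] = field(default_factory=lambda: {
        "liver": 0.026, "rich": 0.05, "poor": 0.62, "fat": 0.19})
    flow_frac: Mapping[str, float] = field(default_factory=lambda: {
        "liver": 0.26, "rich": 0.44, "poor": 0.25, "fat": 0.05})

    TISSUES = ("liver", "rich", "poor", "fat")

    def __post_init__(self) -> None:
        if self.bw <= 0 or self.qc_coeff <= 0 or self.qp_coeff <= 0:
            raise ValidationError("bw and flow coefficients must be > 0")
        if set(self.vol_frac) != set(self.TISSUES) or \
                set(self.flow_frac) != set(self.TISSUES):
            raise ValidationError(f"tissue maps must cover {self.TISSUES}")
        if any(v <= 0 for v in self.vol_frac.values()) or \
                any(v <= 0 for v in self.flow_frac.values()):
            raise ValidationError("tissue fractions must be > 0")
        if abs(sum(self.flow_frac.values()) - 1.0) > 1e-12:
            raise ValidationError("flow fractions must sum to 1")
        if sum(self.vol_frac.values()) > 1.0 + 1e-12:
            raise ValidationError("volume fractions must sum to <= 1")

    @property
    def cardiac_output(self) -> float:
        """Q_c, L/h."""
        return self.qc_coeff * self.bw ** 0.74

    @property
    def alveolar_ventilation(self) -> float:
        """Q_p, L/h."""
        return self.qp_coeff * self.bw ** 0.74

    def tissue_volumes(self) -> np.ndarray:
        """L, in TISSUES order."""
        return np.array([self.vol_frac[t] for t in self.TISSUES]) * self.bw

    def tissue_flows(self) -> np.ndarray:
        """L/h, in TISSUES order."""
        return (np.array([self.flow_frac[t] for t in self.TISSUES])
                * self.cardiac_output)

    @property
    def liver_volume(self) -> float:
        return self.vol_frac["liver"] * self.bw

    @property
    def liver_flow(self) -> float:
        return self.flow_frac["liver"] * self.cardiac_output


# The compiled tables use two orderings for substituted alkanes
# ("Dichloroethane (1,1-)" vs "1,1-dichloroethane"); canonical slugs are
# lowercase and locant-prefixed, with aliases for the other spelling.
_ALIASES = {
    "dichloroethane (1,1-)": "1,1-dichloroethane",
    "dichloroethane (1,2-)": "1,2-dichloroethane",
    "dichloroethylene (1,1-)": "1,1-dichloroethylene",
    "dichloroethylene (cis-1,2)": "cis-1,2-dichloroethylene",
    "dichloroethylene (cis-1,2-)": "cis-1,2-dichloroethylene",
    "dichloroethylene (trans-1,2-)": "trans-1,2-dichloroethylene",
    "hexane (n-)": "n-hexane",
    "tetrachloroethane (1,1,1,2-)": "1,1,1,2-tetrachloroethane",
    "tetrachloroethane (1,1,2,2-)": "1,1,2,2-tetrachloroethane",
    "trichloroethane (1,1,1-)": "1,1,1-trichloroethane",
    "trichloroethane (1,1,2-)": "1,1,2-trichloroethane",
    "trimethylbenzene (1,2,4-)": "1,2,4-trimethylbenzene",
    "xylene (m-)": "m-xylene",
    "xylene (o-)": "o-xylene",
    "chloromethane": "methyl chloride",
    "tetrachloromethane": "carbon tetrachloride",
}


def resolve_name(name: str) -> str:
    """Map a chemical name or alias to its canonical slug."""
    slug = name.strip().lower()
    return _ALIASES.get(slug, slug)


def _read_fixture(fname: str) -> list[dict]:
    text = (resources.files("qppr_pbpk") / "data" / fname).read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return list(csv.DictReader(io.StringIO("\n".join(lines))))


def _load_records() -> list[ChemicalRecord]:
    pcs = {r["name"]: r for r in _read_fixture("partition_coefficients.csv")}
    aux = {r["name"]: r for r in _read_fixture("auxiliary_properties.csv")}
    records = []
    for row in _read_fixture("clearance_descriptors.csv"):
        nm = row["name"]
        if nm not in pcs:
            raise ValidationError(f"{nm}: missing partition coefficients")
        if nm not in aux:
            raise ValidationError(f"{nm}: missing molecular weight / kf")
        pc, ax = pcs[nm], aux[nm]
        if pc["dataset"] != row["dataset"]:
            raise ValidationError(f"{nm}: dataset mismatch between fixtures")
        rec = ChemicalRecord(
            name=nm,
            dataset=row["dataset"],
            log_pow=float(row["log_pow"]),
            log_pbw=float(row["log_pbw"]),
            ip=float(row["ip"]),
            pba=float(pc["pba"]),
            p_liver_blood=float(pc["p_liver_blood"]),
            p_rich_blood=float(pc["p_rich_blood"]),
            p_poor_blood=float(pc["p_poor_blood"]),
            p_fat_blood=float(pc["p_fat_blood"]),
            p_pl_blood=float(pc["p_pl_blood"]),
            log_clint_pl_exp=float(row["log_clint_pl_exp"]),
            mw=float(ax["mw"]),
            kf=float(ax["kf"]),
        )
        rec.validate()
        records.append(rec)
    return records


def load_calibration_set() -> list[ChemicalRecord]:
    """The 26 VOCs used to calibrate the clearance model."""
    recs = [r for r in _load_records() if r.dataset == "calibration"]
    if len(recs) != 26:
        raise ValidationError(
            f"calibration fixture must have 26 records, found {len(recs)}")
    return recs


def load_evaluation_set() -> list[ChemicalRecord]:
    """The 11 VOCs of the external evaluation set."""
    recs = [r for r in _load_records() if r.dataset == "evaluation"]
    if len(recs) != 11:
        raise ValidationError(
            f"evaluation fixture must have 11 records, found {len(recs)}")
    return recs


def load_all_records() -> list[ChemicalRecord]:
    """All 37 fixture chemicals, calibration then evaluation."""
    return load_calibration_set() + load_evaluation_set()


def get_record(name: str) -> ChemicalRecord:
    """Look up a fixture chemical by name or alias."""
    slug = resolve_name(name)
    for r in _load_records():
        if r.name == slug:
            return r
    known = ", ".join(sorted(r.name for r in _load_records()))
    raise KeyError(
        f"unknown chemical {name!r} (resolved to {slug!r}); known names and "
        f"the alias table cover: {known}")


_FIELDS = [f.name for f in fields(ChemicalRecord)]


def records_to_csv(records: Iterable[ChemicalRecord], path) -> None:
    """Write records to CSV with full float precision (repr round-trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_FIELDS)
        for r in records:
            w.writerow([getattr(r, f) if isinstance(getattr(r, f), str)
                        else repr(getattr(r, f)) for f in _FIELDS])


def records_from_csv(path) -> list[ChemicalRecord]:
    """Read records previously written by :func:`records_to_csv`."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = ChemicalRecord(**{
                f: row[f] if f in ("name", "dataset") else float(row[f])
                for f in _FIELDS})
            rec.validate()
            out.append(rec)
    return out


def generate_synthetic_chemicals(
    n: int,
    seed: int,
    domain: Mapping[str, tuple[float, float]] | None = None,
    coefficients: tuple[float, float, float, float] = CALIBRATED_COEFFICIENTS,
    noise_sd: float = 0.3,
) -> list[ChemicalRecord]:
    """Seeded synthetic VOC records for property-based testing.

    Descriptors are uniform in ``domain`` (default: the calibration
    applicability box).  Partition coefficients are built self-consistently:
    a water:air PC is drawn log-uniformly over the range spanned by the
    fixture chemicals, blood:air follows from ``pba = pwa * 10**log_pbw``,
    and the phospholipid:blood PC follows from the partitioning identity, so
    recomputing it from the record's own fields reproduces the stored value
    exactly.  The endpoint is the calibrated-model response at the sampled
    descriptors plus Gaussian noise with standard deviation ``noise_sd``
    (the residual scale of the calibrated fit); ``noise_sd=0`` gives an
    exactly linear response.  ``kf`` is 0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    box = dict(DESCRIPTOR_DOMAIN if domain is None else domain)
    rng = np.random.default_rng(seed)
    b0, b_pow, b_pbw, b_ip = coefficients
    out = []
    for i in range(n):
        log_pow = rng.uniform(*box["log_pow"])
        log_pbw = rng.uniform(*box["log_pbw"])
        ip = rng.uniform(*box["ip"])
        # water:air PC spans ~0.007 (n-hexane) to ~5 (water-soluble VOCs)
        pwa = 10.0 ** rng.uniform(-2.2, 0.7)
        pba = pwa * 10.0 ** log_pbw
        ps = derive_partition_set(log_pow, log_pbw, pba)
        y = (b0 + b_pow * log_pow + b_pbw * log_pbw + b_ip * ip
             + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        rec = ChemicalRecord(
            name=f"synthetic-{seed}-{i:04d}",
            dataset="synthetic",
            log_pow=log_pow, log_pbw=log_pbw, ip=ip,
            pba=pba,
            p_liver_blood=rng.uniform(0.9, 7.0),
            p_rich_blood=rng.uniform(0.9, 7.0),
            p_poor_blood=rng.uniform(0.4, 3.5),
            p_fat_blood=10.0 ** (0.55 * log_pow + rng.uniform(0.3, 0.9)),
            p_pl_blood=ps.pplb,
            log_clint_pl_exp=y,
            mw=rng.uniform(28.0, 253.0),
            kf=0.0,
        )
        rec.validate()
        out.append(rec)
    return out
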
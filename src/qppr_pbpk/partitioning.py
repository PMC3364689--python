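"""Partition-coefficient algebra and the clearance reference transformation.

All logs are base 10.  The central identity expresses the phospholipid:blood
partition coefficient of a VOC as the ratio of its phospholipid:air to
blood:air partition coefficients, with phospholipid:air modeled as a
0.3/0.7 lipid/water mixture:

    P_plb = (0.3 * P_oa + 0.7 * P_wa) / P_ba

Intrinsic clearance referenced to blood and to phospholipid interconvert
through P_plb: CL_int = Vmax/Km, and Km on the phospholipid scale is Km in
blood times P_plb, so CL_int,blood = CL_int,PL * P_plb.

The water:air PC is recovered from the (log_pbw, pba) pair of each record
(P_wa = P_ba / P_bw) rather than re-predicted from structure; this is the
single source of P_wa in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PartitionSet",
    "phospholipid_blood_pc",
    "derive_partition_set",
    "clint_pl_to_blood",
    "clint_blood_to_pl",
]

#: Effective phospholipid composition: lipid-equivalent and water-equivalent
#: volume fractions used in the phospholipid:air mixture rule.
PL_LIPID_FRACTION = 0.3
PL_WATER_FRACTION = 0.7


@dataclass(frozen=True)
class PartitionSet:
    """Self-consistent set of partition coefficients for one chemical.

    Invariants: all entries positive; ``poa = pow * pwa``;
    ``pbw = pba / pwa``; ``pplw = pplb * pbw``.
    """

    pow: float    # n-octanol : water
    pwa: float    # water : air (inverse Henry constant at body temperature)
    poa: float    # n-octanol : air
    pba: float    # blood : air
    pbw: float    # blood : water
    pplb: float   # phospholipid : blood
    pplw: float   # phospholipid : water

    def __post_init__(self) -> None:
        for f in ("pow", "pwa", "poa", "pba", "pbw", "pplb", "pplw"):
            v = getattr(self, f)
            if not v > 0:
                raise ValueError(f"partition coefficient {f} must be > 0, "
                                 f"got {v!r}")


def phospholipid_blood_pc(poa: float, pwa: float, pba: float) -> float:
    """Phospholipid:blood PC from octanol:air, water:air and blood:air PCs.

    Returns ``(0.3*poa + 0.7*pwa) / pba``; strictly increasing in ``poa``
    and ``pwa``, strictly decreasing in ``pba``.
    """
    if not (poa > 0 and pwa > 0 and pba > 0):
        raise ValueError("poa, pwa and pba must all be > 0")
    return (PL_LIPID_FRACTION * poa + PL_WATER_FRACTION * pwa) / pba


def derive_partition_set(log_pow: float, log_pbw: float,
                         pba: float) -> PartitionSet:
    """Full partition set from the two log descriptors and blood:air PC.

    ``pwa`` is recovered as ``pba / 10**log_pbw``, ``poa`` as
    ``10**log_pow * pwa``; the phospholipid coefficients follow from the
    mixture rule.
    """
    if not pba > 0:
        raise ValueError(f"pba must be > 0, got {pba!r}")
    pow_ = 10.0 ** log_pow
    pbw = 10.0 ** log_pbw
    pwa = pba / pbw
    poa = pow_ * pwa
    pplb = phospholipid_blood_pc(poa, pwa, pba)
    return PartitionSet(pow=pow_, pwa=pwa, poa=poa, pba=pba, pbw=pbw,
                        pplb=pplb, pplw=pplb * pbw)


def clint_pl_to_blood(clint_pl: float, pplb: float) -> float:
    """Convert intrinsic clearance from phospholipid to blood reference.

    Both clearances are per kg^0.75; the conversion is multiplication by
    the phospholipid:blood PC.
    """
    if not (clint_pl > 0 and pplb > 0):
        raise ValueError("clint_pl and pplb must be > 0")
    return clint_pl * pplb


def clint_blood_to_pl(clint_blood: float, pplb: float) -> float:
    """Inverse of :func:`clint_pl_to_blood`."""
    if not (clint_blood > 0 and pplb > 0):
        raise ValueError("clint_blood and pplb must be > 0")
    return clint_blood / pplb
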
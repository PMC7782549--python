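"""Bench-side quantification formulas.

Three independent assay calculations used alongside the imaging pipeline:

* c-circle level from paired telomeric qPCR (with / without phi29
  rolling-circle amplification), the quantitative ALT marker;
* alanine uptake (delta fmol/cell over 24 h) from thermally polarized
  13C spectra of the culture medium;
* saturation-corrected steady-state metabolite quantification from 1H
  spectra against an external trimethylsilyl propionate (TSP) reference.

Saturation correction uses the steady-state (Ernst) signal expression
f = sin(theta) (1 - E) / (1 - cos(theta) E), E = exp(-TR/T1); the measured
integral is multiplied by 1/f to recover the fully relaxed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RefStandard",
    "c_circle_level",
    "alanine_uptake",
    "quantify_1h",
    "ernst_saturation_factor",
    "saturation_correction",
]


@dataclass(frozen=True)
class RefStandard:
    """External reference of known concentration (e.g. TSP).

    ``concentration`` in mM, ``volume`` in uL (so the reference amount is
    concentration x volume nanomol = concentration x volume x 1e6 fmol),
    ``nucleus_count`` the number of equivalent observed nuclei per molecule.
    """

    concentration_mm: float
    volume_ul: float
    nucleus_count: float = 9.0  # TSP trimethylsilyl protons

    def __post_init__(self) -> None:
        for name in ("concentration_mm", "volume_ul", "nucleus_count"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def amount_fmol(self) -> float:
        return self.concentration_mm * self.volume_ul * 1e6


def c_circle_level(ct: pd.DataFrame, efficiency: float = 2.0) -> pd.Series:
    """Per-sample c-circle level from a paired Ct table.

    For each condition the telomeric content relative to the single-copy
    reference is RQ = efficiency^-(ct_telomere - ct_reference); the c-circle
    level is RQ(with phi29) - RQ(without phi29). Negative levels are
    reported as-is — they signal assay noise in ALT-negative samples.
    """
    required = {"sample", "condition", "ct_telomere", "ct_reference"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if not efficiency > 1:
        raise ValueError("amplification efficiency must be > 1")
    vals = ct[["ct_telomere", "ct_reference"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("Ct values must be finite and > 0")
    levels: Dict[str, float] = {}
    for sample, grp in ct.groupby("sample", sort=False):
        conds = dict(zip(grp["condition"], zip(grp["ct_telomere"], grp["ct_reference"])))
        if "with_phi29" not in conds or "without_phi29" not in conds:
            raise ValueError(f"sample {sample!r}: missing paired condition")
        rq = {
            c: efficiency ** -(tel - ref)
            for c, (tel, ref) in conds.items()
        }
        levels[sample] = rq["with_phi29"] - rq["without_phi29"]
    return pd.Series(levels, name="c_circle_level")


def alanine_uptake(
    integral_t0: float,
    integral_t24: float,
    ref: RefStandard,
    ref_integral: float,
    saturation_factor: float = 1.0,
    n_cells: float = 1e7,
    nucleus_count: float = 1.0,
) -> float:
    """Alanine uptake as delta fmol/cell between 0 and 24 h of incubation.

    Each medium integral is converted to an absolute amount against the
    external reference, corrected for saturation (``saturation_factor`` is
    the multiplicative correction, 1/f of the Ernst factor), and the drop
    over 24 h is divided by the cell count.
    """
    if not ref_integral > 0:
        raise ValueError("reference integral must be > 0")
    if not n_cells > 0:
        raise ValueError("cell count must be > 0")

    def amount(integral: float) -> float:
        per_nucleus = (integral / nucleus_count) / (ref_integral / ref.nucleus_count)
        return per_nucleus * ref.amount_fmol * saturation_factor

    return (amount(integral_t0) - amount(integral_t24)) / n_cells


def ernst_saturation_factor(flip_deg: float, tr: float, t1: float) -> float:
    """Steady-state fractional signal f = sin(t)(1 - E)/(1 - cos(t) E).

    E = exp(-TR/T1). The fully relaxed integral is recovered by multiplying
    the measured one by 1/f.
    """
    if not (0 < flip_deg <= 90):
        raise ValueError("flip angle must lie in (0, 90] degrees")
    if not (tr > 0 and t1 > 0):
        raise ValueError("TR and T1 must be > 0")
    theta = np.radians(flip_deg)
    e = np.exp(-tr / t1)
    return float(np.sin(theta) * (1.0 - e) / (1.0 - np.cos(theta) * e))


def saturation_correction(flip_deg: float, tr: float, t1: float) -> float:
    """Multiplicative correction 1/f applied to a partially relaxed integral."""
    return 1.0 / ernst_saturation_factor(flip_deg, tr, t1)


def quantify_1h(
    integrals: Mapping[str, float],
    nucleus_counts: Mapping[str, float],
    ref: RefStandard,
    ref_integral: float,
    saturation_factors: Mapping[str, float],
    n_cells: float,
) -> pd.Series:
    """Absolute metabolite quantification (fmol/cell) from 1H integrals.

    conc_m = (I_m / nuc_m) / (I_ref / nuc_ref) x ref_amount x sat_m / n_cells

    where ``sat_m`` is the per-metabolite saturation correction
    (:func:`saturation_correction` of its flip/TR/T1).
    """
    if not ref_integral > 0:
        raise ValueError("reference integral must be > 0")
    if not n_cells > 0:
        raise ValueError("cell count must be > 0")
    out: Dict[str, float] = {}
    for name, integral in integrals.items():
        if name not in saturation_factors:
            raise ValueError(f"missing saturation factor for metabolite {name!r}")
        if name not in nucleus_counts or not nucleus_counts[name] > 0:
            raise ValueError(f"missing or invalid nucleus count for {name!r}")
        per_nucleus = (integral / nucleus_counts[name]) / (
            ref_integral / ref.nucleus_count
        )
        out[name] = per_nucleus * ref.amount_fmol * saturation_factors[name] / n_cells
    return pd.Series(out, name="fmol_per_cell")
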
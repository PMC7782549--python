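"""Kinetic readouts from dynamic spectra.

Turns a dynamic spectral series into the quantities reported for the
live-cell and slab experiments: per-metabolite build-up curves, AUC and
summed-spectrum conversion ratios, time-of-maximum, TMM classification
from ratio dominance, and estimation of the generating kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .spectra import DynamicSpectrumSeries, MetaboliteWindow, integrate_window, sum_spectra
from .synthkit import (
    METABOLITES,
    AcquisitionSchedule,
    BolusInput,
    KineticParams,
    simulate_kinetics,
)

__all__ = [
    "BuildupCurves",
    "RatioResult",
    "KineticFit",
    "DEFAULT_WINDOWS",
    "buildup_curves",
    "auc_ratio",
    "ratio_from_summed",
    "time_of_max",
    "classify_tmm",
    "fit_kinetics",
]

#: Integration windows matching the default synthetic peak positions.
#: Half-width ~4x the 0.12 ppm linewidth: captures 92% of each Lorentzian
#: (identically for every peak, so ratios are unbiased) while keeping the
#: positive noise floor of magnitude-mode integration small.
DEFAULT_WINDOWS: Dict[str, MetaboliteWindow] = {
    "alanine": MetaboliteWindow("alanine", 176.5, 0.5),
    "pyruvate": MetaboliteWindow("pyruvate", 170.6, 0.5),
    "lactate": MetaboliteWindow("lactate", 183.2, 0.5),
}

NORMALIZATIONS = ("raw", "max_substrate", "per_cell")


@dataclass
class BuildupCurves:
    """Per-metabolite integral time courses with a normalization record."""

    times: np.ndarray
    curves: Dict[str, np.ndarray]
    normalization: str
    cell_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        n = self.times.size
        for name, c in self.curves.items():
            if np.asarray(c).size != n:
                raise ValueError(f"curve {name!r} length mismatch")


@dataclass(frozen=True)
class RatioResult:
    """Product/substrate conversion ratios with the aggregation basis."""

    lac_over_ala: float
    pyr_over_ala: float
    basis: str  # 'summed_spectrum' or 'auc'

    def __post_init__(self) -> None:
        if self.basis not in ("summed_spectrum", "auc"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.lac_over_ala < 0 or self.pyr_over_ala < 0:
            raise ValueError("ratios must be non-negative")


@dataclass
class KineticFit:
    """Estimated kinetic parameters with the least-squares residual norm."""

    params: KineticParams
    residual_norm: float


def buildup_curves(
    series: DynamicSpectrumSeries,
    windows: Mapping[str, MetaboliteWindow] = DEFAULT_WINDOWS,
    mode: str = "magnitude",
    normalize: str = "raw",
    substrate: str = "alanine",
) -> BuildupCurves:
    """Integrate each metabolite window at every time point.

    ``normalize='max_substrate'`` divides every curve by the maximum of the
    substrate curve (and by the cell count when the series carries one,
    matching the live-cell normalization); ``'per_cell'`` divides by the
    cell count only.
    """
    curves = {
        name: np.array(
            [
                integrate_window(series.spectra[t], series.axis, w, mode=mode)
                for t in range(series.n_time)
            ]
        )
        for name, w in windows.items()
    }
    if normalize == "max_substrate":
        if substrate not in curves:
            raise ValueError(
                f"normalization requires a {substrate!r} window, got {sorted(curves)}"
            )
        peak = curves[substrate].max()
        if not peak > 0:
            raise ValueError("substrate curve maximum is not positive")
        scale = peak * (series.cell_count or 1)
        curves = {k: v / scale for k, v in curves.items()}
    elif normalize == "per_cell":
        if not series.cell_count:
            raise ValueError("per-cell normalization requires a cell count")
        curves = {k: v / series.cell_count for k, v in curves.items()}
    elif normalize != "raw":
        raise ValueError(f"unknown normalization {normalize!r}")
    return BuildupCurves(
        times=series.times,
        curves=curves,
        normalization=normalize,
        cell_count=series.cell_count,
    )


def auc_ratio(curves: BuildupCurves, product: str, substrate: str = "alanine") -> float:
    """Trapezoidal AUC(product) / AUC(substrate), per cell when counted."""
    for name in (product, substrate):
        if name not in curves.curves:
            raise ValueError(f"no curve named {name!r}")
    auc_sub = float(np.trapezoid(curves.curves[substrate], curves.times))
    if not auc_sub > 0:
        raise ValueError("substrate AUC must be > 0")
    auc_prod = float(np.trapezoid(curves.curves[product], curves.times))
    ratio = auc_prod / auc_sub
    if curves.cell_count and curves.normalization == "raw":
        ratio /= curves.cell_count
    return ratio


def ratio_from_summed(
    series: DynamicSpectrumSeries,
    windows: Mapping[str, MetaboliteWindow] = DEFAULT_WINDOWS,
    mode: str = "magnitude",
) -> RatioResult:
    """Pyruvate/alanine and lactate/alanine ratios of the summed spectrum."""
    summed = sum_spectra(series)
    integrals = {
        name: integrate_window(summed, series.axis, w, mode=mode)
        for name, w in windows.items()
    }
    ala = integrals["alanine"]
    if not ala > 0:
        raise ValueError(f"alanine integral of summed spectrum must be > 0, got {ala}")
    return RatioResult(
        lac_over_ala=max(integrals.get("lactate", 0.0), 0.0) / ala,
        pyr_over_ala=max(integrals.get("pyruvate", 0.0), 0.0) / ala,
        basis="summed_spectrum",
    )


def ratios_from_auc(
    curves: BuildupCurves, substrate: str = "alanine"
) -> RatioResult:
    """AUC-based counterpart of :func:`ratio_from_summed`."""
    return RatioResult(
        lac_over_ala=max(auc_ratio(curves, "lactate", substrate), 0.0),
        pyr_over_ala=max(auc_ratio(curves, "pyruvate", substrate), 0.0),
        basis="auc",
    )


def time_of_max(times: np.ndarray, curve: np.ndarray) -> float:
    """Time of the global curve maximum; earliest time on ties."""
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    if np.all(np.isnan(curve)):
        raise ValueError("all-NaN curve")
    return float(times[int(np.nanargmax(curve))])


def classify_tmm(
    ratios: RatioResult,
    min_conversion: float = 0.02,
    dominance_margin: float = 1.5,
) -> str:
    """Label a sample TERT, ALT, or NONE from its conversion ratios.

    No conversion above ``min_conversion`` in either product means NONE
    (CONTROL-like). Otherwise the dominant product decides: lactate
    dominance (by at least ``dominance_margin``-fold) is the TERT
    signature, pyruvate dominance the ALT signature; ties within the
    margin are indeterminate (NONE).
    """
    lac, pyr = ratios.lac_over_ala, ratios.pyr_over_ala
    if not (np.isfinite(lac) and np.isfinite(pyr)):
        raise ValueError("ratios must be finite")
    if lac < min_conversion and pyr < min_conversion:
        return "NONE"
    if lac >= dominance_margin * pyr:
        return "TERT"
    if pyr >= dominance_margin * lac:
        return "ALT"
    return "NONE"


def _t1_loglinear(
    signal: np.ndarray, tr: float, flip_deg: float
) -> Tuple[float, float]:
    """Closed-form T1 from a substrate-only decay.

    With no conversion, s(n) = s(0) * (exp(-TR/T1) cos(theta))^n, so the
    slope of ln s against shot index n is -TR/T1 + ln cos(theta) and
    T1 = -TR / (slope - ln cos(theta)).
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal <= 0):
        raise ValueError("log-linear T1 fit requires strictly positive signals")
    n = np.arange(signal.size)
    slope, intercept = np.polyfit(n, np.log(signal), 1)
    denom = slope - np.log(np.cos(np.radians(flip_deg)))
    if denom == 0:
        raise ValueError("degenerate decay: zero effective rate")
    t1 = -tr / denom
    resid = float(
        np.linalg.norm(np.log(signal) - (slope * n + intercept))
    )
    return float(t1), resid


def fit_kinetics(
    curves: BuildupCurves,
    sched: AcquisitionSchedule,
    fixed_t1s: Mapping[str, float] = None,
    fit_targets: Sequence[str] = ("m0", "k_ap", "k_pl"),
    bolus: BolusInput = BolusInput(),
) -> KineticFit:
    """Estimate kinetic parameters from build-up curves.

    Substrate-only data (``fit_targets=('t1_a',)``) uses the closed-form
    log-linear estimate with explicit cos(theta) depletion correction. Full
    chains are fitted by least squares over (m0, k_ap, k_pl) with T1s held
    fixed at ``fixed_t1s`` — rates and relaxation are not jointly
    identifiable from a single-flip dataset.
    """
    fixed_t1s = dict(fixed_t1s or {"t1_a": 44.0, "t1_p": 30.0, "t1_l": 30.0})
    for name, curve in curves.curves.items():
        if np.asarray(curve).size != sched.n_acq:
            raise ValueError(f"curve {name!r} inconsistent with schedule length")

    if tuple(fit_targets) == ("t1_a",):
        flip_a = float(sched.flip[METABOLITES.index("alanine")])
        t1, resid = _t1_loglinear(curves.curves["alanine"], sched.tr, flip_a)
        params = KineticParams(
            m0=float(np.max(curves.curves["alanine"])),
            k_ap=0.0,
            k_pl=0.0,
            t1_a=t1,
            t1_p=fixed_t1s["t1_p"],
            t1_l=fixed_t1s["t1_l"],
        )
        return KineticFit(params=params, residual_norm=resid)

    if set(fit_targets) != {"m0", "k_ap", "k_pl"}:
        raise ValueError(f"unsupported fit targets {fit_targets!r}")

    observed = np.concatenate([curves.curves[m] for m in METABOLITES])
    scale = observed.max()
    if not scale > 0:
        raise ValueError("cannot fit an all-zero dataset")

    def model(theta: np.ndarray) -> np.ndarray:
        m0, k_ap, k_pl = theta
        p = KineticParams(
            m0=max(m0, 1e-12),
            k_ap=max(k_ap, 0.0),
            k_pl=max(k_pl, 0.0),
            t1_a=fixed_t1s["t1_a"],
            t1_p=fixed_t1s["t1_p"],
            t1_l=fixed_t1s["t1_l"],
        )
        sim = simulate_kinetics(p, sched, bolus)
        return np.concatenate([sim.signal(m) for m in METABOLITES])

    x0 = np.array([scale / np.sin(np.radians(sched.flip)).max(), 0.01, 0.01])
    result = least_squares(
        lambda th: model(th) - observed,
        x0,
        bounds=([1e-12, 0.0, 0.0], [np.inf, 1.0, 1.0]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not result.success:
        raise RuntimeError(f"kinetic fit failed: {result.message}")
    m0, k_ap, k_pl = result.x
    params = KineticParams(
        m0=float(m0),
        k_ap=float(k_ap),
        k_pl=float(k_pl),
        t1_a=fixed_t1s["t1_a"],
        t1_p=fixed_t1s["t1_p"],
        t1_l=fixed_t1s["t1_l"],
    )
    return KineticFit(params=params, residual_norm=float(np.linalg.norm(result.fun)))
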
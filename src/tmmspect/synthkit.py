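"""Synthetic-data generators for the TMM imaging pipeline.

Everything the analysis consumes can be generated here: dynamic complex
carbon-13 spectral series mimicking live-cell and in vivo slab acquisitions
of hyperpolarized [1-13C]-alanine, 4D EPSI scenes with tumor / contralateral
/ out-of-brain noise voxels, steady-state metabolite concentration tables
for CONTROL / TERT / ALT cohorts, and paired qPCR Ct tables for the
c-circle assay.

Kinetic model
-------------
Hyperpolarized alanine (A) is converted to pyruvate (P) by alanine
aminotransferase and onward to lactate (L) by lactate dehydrogenase. The
longitudinal magnetizations follow the unidirectional precursor-product
chain with T1 relaxation::

    dA/dt = u(t) - (1/T1a + k_ap) A
    dP/dt = k_ap A - (1/T1p + k_pl) P
    dL/dt = k_pl P - L/T1l

where u(t) is the bolus input into the alanine pool. Each RF excitation
with flip angle theta observes a transverse signal m*sin(theta) and depletes
the longitudinal pool by cos(theta). The system is linear, so propagation
between events uses an exact matrix exponential (no step-size tolerances);
the piecewise-linear bolus is handled by augmenting the state with the
input and its constant slope.

Every stochastic generator takes an explicit integer seed; there is no
global random state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.constants import hbar, k as k_boltzmann
from scipy.linalg import expm

from .spectra import DynamicSpectrumSeries, PpmAxis, ppm_axis

__all__ = [
    "METABOLITES",
    "KineticParams",
    "AcquisitionSchedule",
    "BolusInput",
    "MagnetizationSeries",
    "SceneConfig",
    "GroupEffectSpec",
    "simulate_kinetics",
    "synth_dynamic_spectra",
    "synth_epsi_scene",
    "synth_metabolite_table",
    "synth_ct_table",
    "thermal_polarization",
    "polarization_enhancement",
    "DEFAULT_PEAKS",
    "CLASS_PARAMS",
    "default_cell_schedule",
    "default_invivo_schedule",
    "default_scene",
    "default_group_effects",
    "GAMMA_13C",
]

#: Metabolite order used for all per-metabolite vectors.
METABOLITES: Tuple[str, str, str] = ("alanine", "pyruvate", "lactate")

#: 13C gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_13C = 6.728284e7

#: Default chemical-shift centers (ppm) and linewidths (ppm FWHM) for the
#: carbonyl carbons; centers follow literature convention and are
#: configurable everywhere they are used.
DEFAULT_PEAKS: Dict[str, Tuple[float, float]] = {
    "alanine": (176.5, 0.12),
    "pyruvate": (170.6, 0.12),
    "lactate": (183.2, 0.12),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetics of the alanine -> pyruvate -> lactate chain.

    Parameters
    ----------
    m0 : initial alanine longitudinal magnetization (a.u., > 0)
    k_ap, k_pl : conversion rates (1/s, >= 0)
    t1_a, t1_p, t1_l : longitudinal relaxation times (s, > 0; inf allowed)
    pol : polarization fraction in [0, 1]
    """

    m0: float = 1.0
    k_ap: float = 0.0
    k_pl: float = 0.0
    t1_a: float = 44.0
    t1_p: float = 30.0
    t1_l: float = 30.0
    pol: float = 0.12

    def __post_init__(self) -> None:
        if not np.isfinite(self.m0) or self.m0 <= 0:
            raise ValueError(f"m0 must be finite and > 0, got {self.m0}")
        for name in ("k_ap", "k_pl"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("t1_a", "t1_p", "t1_l"):
            v = getattr(self, name)
            if np.isnan(v) or v <= 0:
                raise ValueError(f"{name} must be > 0 (inf allowed), got {v}")
        if not (0.0 <= self.pol <= 1.0):
            raise ValueError(f"pol must be in [0, 1], got {self.pol}")

    @property
    def r1(self) -> np.ndarray:
        """Relaxation rates 1/T1 per metabolite (0 for infinite T1)."""
        t1s = np.array([self.t1_a, self.t1_p, self.t1_l], dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(np.isinf(t1s), 0.0, 1.0 / t1s)


def _as_flips(flip) -> np.ndarray:
    """Normalize a scalar / sequence / mapping flip spec to a 3-vector (deg)."""
    if isinstance(flip, Mapping):
        arr = np.array([flip[m] for m in METABOLITES], dtype=float)
    elif np.isscalar(flip):
        arr = np.full(3, float(flip))
    else:
        arr = np.asarray(flip, dtype=float)
        if arr.shape != (3,):
            raise ValueError("flip must be scalar, 3-sequence, or metabolite mapping")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 90):
        raise ValueError(f"flip angles must lie in [0, 90] degrees, got {arr}")
    return arr


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Discrete excitation schedule: TR, shot count, per-metabolite flips.

    ``t0`` is the time of the first excitation relative to bolus onset.
    """

    tr: float
    n_acq: int
    flip: object = 13.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if int(self.n_acq) < 1:
            raise ValueError(f"n_acq must be >= 1, got {self.n_acq}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        object.__setattr__(self, "n_acq", int(self.n_acq))
        object.__setattr__(self, "flip", _as_flips(self.flip))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.tr * np.arange(self.n_acq)


@dataclass(frozen=True)
class BolusInput:
    """Substrate delivery into the alanine pool.

    ``instantaneous`` places the whole dose at t = 0 (substrate added
    directly to the tube in cell studies); ``trapezoid`` spreads it over
    ``duration`` seconds with 15 % rise and fall ramps (intravenous
    injection). ``amplitude`` scales the delivered dose relative to m0.
    """

    shape: str = "instantaneous"
    duration: float = 0.0
    amplitude: float = 1.0

    #: rise (= fall) ramp as a fraction of duration for the trapezoid shape
    ramp_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.shape not in ("instantaneous", "trapezoid"):
            raise ValueError(f"unknown bolus shape {self.shape!r}")
        if self.duration < 0 or not np.isfinite(self.duration):
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if (self.duration == 0) != (self.shape == "instantaneous"):
            raise ValueError("duration = 0 iff shape = 'instantaneous'")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not (0.0 <= self.ramp_fraction < 0.5):
            raise ValueError("ramp_fraction must lie in [0, 0.5)")

    def profile(self, dose: float) -> Tuple[np.ndarray, np.ndarray]:
        """Breakpoints and input-rate values of the piecewise-linear u(t).

        Returns (t_knots, u_knots) such that u is linear between knots and
        zero outside [0, duration]; the integral of u equals ``dose``.
        """
        if self.shape == "instantaneous":
            raise ValueError("instantaneous bolus has no rate profile")
        d = self.duration
        r = self.ramp_fraction * d
        # trapezoid area = h * (d - r)  (plateau d - 2r plus two ramps r/2 each)
        h = dose / (d - r)
        t = np.array([0.0, r, d - r, d])
        u = np.array([0.0, h, h, 0.0])
        return t, u


@dataclass
class MagnetizationSeries:
    """Discrete observation of the kinetic chain.

    ``m`` is the longitudinal magnetization just before each excitation and
    ``s = m * sin(flip)`` the observed transverse signal, both with shape
    (n_acq, 3) in :data:`METABOLITES` order.
    """

    times: np.ndarray
    m: np.ndarray
    s: np.ndarray
    params: Optional[KineticParams] = None
    schedule: Optional[AcquisitionSchedule] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.m.shape != self.s.shape or self.m.shape[0] != self.times.size:
            raise ValueError("inconsistent series shapes")
        if np.any(self.m < 0) or np.any(self.s < 0):
            raise ValueError("magnetization and signal must be non-negative")

    def signal(self, metabolite: str) -> np.ndarray:
        return self.s[:, METABOLITES.index(metabolite)]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, kinetics, and noise layout of a synthetic EPSI scene.

    ``regions`` maps region names (``tumor``, ``contralateral``, ``noise``)
    to (voxel index tuples, KineticParams or None). Region voxel sets must
    be disjoint; the noise region carries no signal.
    """

    grid: Tuple[int, int] = (8, 8)
    fov_mm: Tuple[float, float] = (43.0, 43.0)
    n_freq: int = 128
    bandwidth_ppm: float = 20.0
    center_ppm: float = 177.0
    n_time: int = 60
    tr: float = 3.0
    flip: object = None
    slice_thickness_mm: float = 8.0
    regions: Mapping[str, Tuple[Tuple[Tuple[int, int], ...], Optional[KineticParams]]] = field(
        default_factory=dict
    )
    peaks: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PEAKS)
    )
    bolus: BolusInput = field(
        default_factory=lambda: BolusInput("trapezoid", duration=12.0)
    )
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny = self.grid
        if nx < 1 or ny < 1:
            raise ValueError(f"grid dims must be >= 1, got {self.grid}")
        seen: set = set()
        for name, (voxels, params) in self.regions.items():
            for v in voxels:
                if v in seen:
                    raise ValueError(f"region voxel sets overlap at {v}")
                if not (0 <= v[0] < nx and 0 <= v[1] < ny):
                    raise ValueError(f"voxel {v} outside {self.grid} grid")
                seen.add(v)
            if name == "noise" and params is not None:
                raise ValueError("noise region must have zero signal (params=None)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.flip is None:
            # in vivo defaults: low flip on the substrate to preserve
            # magnetization, high flip on the products
            object.__setattr__(
                self, "flip", {"alanine": 3.0, "pyruvate": 30.0, "lactate": 30.0}
            )

    @property
    def schedule(self) -> AcquisitionSchedule:
        return AcquisitionSchedule(tr=self.tr, n_acq=self.n_time, flip=self.flip)

    @property
    def voxel_mm(self) -> Tuple[float, float]:
        return (self.fov_mm[0] / self.grid[0], self.fov_mm[1] / self.grid[1])


VALID_GROUPS = frozenset({"CONTROL", "TERT", "ALT", "GLIOSIS"})


@dataclass(frozen=True)
class GroupEffectSpec:
    """Group-wise metabolite means for the steady-state concentration table."""

    metabolites: Tuple[str, ...]
    group_means: Mapping[str, Sequence[float]]
    cv: float = 0.15
    n_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for g, means in self.group_means.items():
            if g not in VALID_GROUPS:
                raise ValueError(
                    f"unknown group label {g!r}; must be one of {sorted(VALID_GROUPS)}"
                )
            means = np.asarray(means, dtype=float)
            if means.shape != (len(self.metabolites),):
                raise ValueError(f"group {g}: wrong number of means")
            if np.any(means <= 0):
                raise ValueError(f"group {g}: means must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


# ---------------------------------------------------------------------------
# kinetic simulation
# ---------------------------------------------------------------------------


def _system_matrix(params: KineticParams) -> np.ndarray:
    r1a, r1p, r1l = params.r1
    return np.array(
        [
            [-(r1a + params.k_ap), 0.0, 0.0],
            [params.k_ap, -(r1p + params.k_pl), 0.0],
            [0.0, params.k_pl, -r1l],
        ]
    )


def simulate_kinetics(
    params: KineticParams,
    sched: AcquisitionSchedule,
    bolus: BolusInput = BolusInput(),
) -> MagnetizationSeries:
    """Simulate the three-pool chain under discrete RF sampling.

    Between excitations the linear ODE system is propagated exactly with a
    matrix exponential; the piecewise-linear bolus input is folded into an
    augmented LTI system per segment. At each excitation the transverse
    signal ``m*sin(flip)`` is recorded and the longitudinal pools are
    depleted by ``cos(flip)``.
    """
    M = _system_matrix(params)
    sin_f = np.sin(np.radians(sched.flip))
    cos_f = np.cos(np.radians(sched.flip))
    dose = params.m0 * bolus.amplitude

    x = np.zeros(3)
    t = 0.0
    if bolus.shape == "instantaneous":
        x[0] = dose
        knots_t = np.empty(0)
        knots_u = np.empty(0)
    else:
        knots_t, knots_u = bolus.profile(dose)

    def input_at(time: float) -> Tuple[float, float]:
        """(u, du/dt) of the bolus at `time` (0 outside the bolus)."""
        if knots_t.size == 0 or time >= knots_t[-1] or time < knots_t[0]:
            return 0.0, 0.0
        i = int(np.searchsorted(knots_t, time, side="right")) - 1
        t0k, t1k = knots_t[i], knots_t[i + 1]
        u0k, u1k = knots_u[i], knots_u[i + 1]
        slope = (u1k - u0k) / (t1k - t0k)
        return u0k + slope * (time - t0k), slope

    prop_cache: Dict[Tuple[float, float], np.ndarray] = {}

    def propagate(x: np.ndarray, t_from: float, t_to: float) -> np.ndarray:
        # split at bolus knots so the input is linear on every segment
        cuts = [t_from]
        cuts += [float(tk) for tk in knots_t if t_from < tk < t_to]
        cuts.append(t_to)
        for a, b in zip(cuts[:-1], cuts[1:]):
            dt = b - a
            if dt <= 0:
                continue
            u, slope = input_at(a)
            key = (round(dt, 12), round(slope, 12))
            if key not in prop_cache:
                aug = np.zeros((5, 5))
                aug[:3, :3] = M
                aug[0, 3] = 1.0  # input feeds the alanine pool
                aug[3, 4] = slope
                prop_cache[key] = expm(aug * dt)
            z = np.array([x[0], x[1], x[2], u, 1.0])
            z = prop_cache[key] @ z
            x = z[:3]
        return x

    times = sched.times
    m_out = np.empty((sched.n_acq, 3))
    s_out = np.empty((sched.n_acq, 3))
    for i, te in enumerate(times):
        x = propagate(x, t, float(te))
        t = float(te)
        m = np.maximum(x, 0.0)
        m_out[i] = m
        s_out[i] = m * sin_f
        x = x * cos_f

    return MagnetizationSeries(times=times, m=m_out, s=s_out, params=params, schedule=sched)


# ---------------------------------------------------------------------------
# spectral synthesis
# ---------------------------------------------------------------------------


def _lorentzian(ppm: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area absorption Lorentzian (area 1 over the full real line)."""
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)


def synth_dynamic_spectra(
    mag: MagnetizationSeries,
    peaks: Mapping[str, Tuple[float, float]] = DEFAULT_PEAKS,
    axis_spec=(512, 20.0, 177.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
    cell_count: Optional[int] = None,
) -> DynamicSpectrumSeries:
    """Render a magnetization series as a dynamic complex spectral array.

    Each time point is the sum of per-metabolite unit-area absorption
    Lorentzians scaled by the observed signal, plus i.i.d. circular complex
    Gaussian noise (sigma per real/imaginary component per bin), so the
    analytic peak area equals the metabolite signal.
    """
    axis = axis_spec if isinstance(axis_spec, PpmAxis) else ppm_axis(*axis_spec)
    for name, (center, fwhm) in peaks.items():
        if fwhm <= 0:
            raise ValueError(f"peak {name!r}: linewidth must be > 0, got {fwhm}")
        if not (axis.ppm_min <= center <= axis.ppm_max):
            raise ValueError(
                f"peak {name!r} at {center} ppm outside axis "
                f"[{axis.ppm_min}, {axis.ppm_max}]"
            )
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    shapes = {
        name: _lorentzian(axis.values, center, fwhm)
        for name, (center, fwhm) in peaks.items()
    }
    n_time = mag.times.size
    spectra = np.zeros((n_time, axis.n_points), dtype=complex)
    for j, met in enumerate(METABOLITES):
        if met in shapes:
            spectra += np.outer(mag.s[:, j], shapes[met])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        spectra = spectra + noise_sigma * (
            rng.standard_normal(spectra.shape)
            + 1j * rng.standard_normal(spectra.shape)
        )
    return DynamicSpectrumSeries(
        times=mag.times,
        spectra=spectra,
        axis=axis,
        schedule=mag.schedule,
        cell_count=cell_count,
    )


def synth_epsi_scene(scene: SceneConfig):
    """Generate a 4D EPSI dataset (x, y, frequency, time) from a scene.

    Tumor voxels carry conversion per their KineticParams; contralateral
    voxels carry an alanine-only signal (k_ap forced to 0); noise voxels —
    and all unassigned voxels — carry no signal. Circular complex Gaussian
    receiver noise is added to every voxel. Masks are stored with the
    dataset.
    """
    from .epsi import EPSIDataset, EPSIGeometry  # local import: avoid cycle

    nx, ny = scene.grid
    axis = ppm_axis(scene.n_freq, scene.bandwidth_ppm, scene.center_ppm)
    sched = scene.schedule
    data = np.zeros((nx, ny, scene.n_freq, scene.n_time), dtype=complex)
    masks = {
        name: np.zeros((nx, ny), dtype=bool)
        for name in ("tumor", "contralateral", "noise")
    }

    for name, (voxels, params) in scene.regions.items():
        if name in masks:
            for v in voxels:
                masks[name][v] = True
        if params is None:
            continue
        if name == "contralateral":
            params = replace(params, k_ap=0.0)
        mag = simulate_kinetics(params, sched, scene.bolus)
        clean = synth_dynamic_spectra(
            mag, peaks=scene.peaks, axis_spec=axis, noise_sigma=0.0
        )
        # (n_time, n_freq) -> (n_freq, n_time)
        block = clean.spectra.T
        for v in voxels:
            data[v[0], v[1]] = block

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        data = data + scene.noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    geometry = EPSIGeometry(
        fov_mm=scene.fov_mm,
        voxel_mm=scene.voxel_mm,
        slice_thickness_mm=scene.slice_thickness_mm,
    )
    return EPSIDataset(
        data=data,
        axis=axis,
        geometry=geometry,
        times=sched.times,
        masks=masks,
        schedule=sched,
    )


# ---------------------------------------------------------------------------
# steady-state tables and qPCR
# ---------------------------------------------------------------------------


def synth_metabolite_table(spec: GroupEffectSpec):
    """Sample a samples x metabolites concentration table (fmol/cell).

    Concentrations are log-normal around the group means with the given
    coefficient of variation (cv = 0 reproduces the means exactly). Returns
    a DataFrame with one row per sample, metabolite columns, and a
    ``group`` column.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    rows = []
    index = []
    groups = []
    for g in spec.group_means:
        means = np.asarray(spec.group_means[g], dtype=float)
        for i in range(spec.n_per_group):
            if spec.cv == 0:
                sample = means.copy()
            else:
                sigma = np.sqrt(np.log1p(spec.cv**2))
                mu = np.log(means) - sigma**2 / 2.0
                sample = np.exp(rng.normal(mu, sigma))
            rows.append(sample)
            index.append(f"{g}_{i + 1}")
            groups.append(g)
    table = pd.DataFrame(rows, index=index, columns=list(spec.metabolites))
    table["group"] = groups
    return table


def synth_ct_table(
    true_rq_with: float,
    true_rq_without: float,
    ct_ref: float = 18.0,
    noise_sd: float = 0.0,
    n: int = 3,
    seed: int = 0,
):
    """Paired qPCR Ct rows (with / without phi29 amplification) per sample.

    The telomere Ct is generated so that the relative quantity inverts to
    the requested truth: ``Ct_tel = ct_ref - log2(rq) + noise``.
    """
    import pandas as pd

    for name, rq in (("true_rq_with", true_rq_with), ("true_rq_without", true_rq_without)):
        if not rq > 0:
            raise ValueError(f"{name} must be > 0, got {rq}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        for cond, rq in (("with_phi29", true_rq_with), ("without_phi29", true_rq_without)):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            records.append(
                {
                    "sample": f"S{i + 1}",
                    "condition": cond,
                    "ct_telomere": ct_ref - np.log2(rq) + noise,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# polarization physics
# ---------------------------------------------------------------------------


def thermal_polarization(
    field_t: float, temperature_k: float, gamma: float = GAMMA_13C
) -> float:
    """Thermal-equilibrium polarization of a spin-1/2 nucleus.

    P = tanh(hbar * gamma * B / (2 k T)); in the high-temperature regime
    relevant at room temperature this equals the linearized Boltzmann
    population difference.
    """
    if field_t <= 0 or temperature_k <= 0:
        raise ValueError("field and temperature must be > 0")
    return float(np.tanh(hbar * gamma * field_t / (2.0 * k_boltzmann * temperature_k)))


def polarization_enhancement(
    pol: float, field_t: float = 14.0, temperature_k: float = 298.0
) -> float:
    """Fold signal enhancement of hyperpolarization over thermal equilibrium."""
    if not (0 < pol <= 1):
        raise ValueError(f"pol must be in (0, 1], got {pol}")
    return pol / thermal_polarization(field_t, temperature_k)


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------


def default_cell_schedule(n_acq: int = 100) -> AcquisitionSchedule:
    """Live-cell acquisition: 13 degree flip, TR 3 s, 300 s total."""
    return AcquisitionSchedule(tr=3.0, n_acq=n_acq, flip=13.0, t0=0.0)


def default_invivo_schedule(n_acq: int = 60) -> AcquisitionSchedule:
    """In vivo acquisition: 30 degrees on pyruvate/lactate, 3 on alanine."""
    return AcquisitionSchedule(
        tr=3.0, n_acq=n_acq, flip={"alanine": 3.0, "pyruvate": 30.0, "lactate": 30.0}
    )


#: Class-conditional kinetic parameters used by the demo cohorts. TERT-like
#: tumors convert alanine onward to lactate (high k_pl from abundant NADH);
#: ALT-like tumors accumulate pyruvate (high alanine aminotransferase flux
#: from abundant alpha-KG but little onward conversion); controls convert
#: neither.
CLASS_PARAMS: Dict[str, KineticParams] = {
    "CONTROL": KineticParams(m0=1.0, k_ap=0.0, k_pl=0.0),
    "TERT": KineticParams(m0=1.0, k_ap=0.008, k_pl=0.08),
    "ALT": KineticParams(m0=1.0, k_ap=0.008, k_pl=0.002),
}


def default_scene(kind: str = "TERT", noise_sigma: float = 0.002, seed: int = 0, n_time: int = 60) -> SceneConfig:
    """Default in vivo EPSI scene: 8x8 grid over 43x43 mm2, 128 spectral
    points over 20 ppm, 3 s temporal resolution.

    A 2x2 tumor block carries the class kinetics, a 2x2 contralateral block
    carries alanine only, and two out-of-brain corner voxels are designated
    noise voxels.
    """
    if kind not in CLASS_PARAMS:
        raise ValueError(f"kind must be one of {sorted(CLASS_PARAMS)}, got {kind!r}")
    tumor = tuple((x, y) for x in (2, 3) for y in (2, 3))
    contra = tuple((x, y) for x in (2, 3) for y in (5, 6))
    noise_vox = ((0, 0), (7, 7))
    regions = {
        "tumor": (tumor, CLASS_PARAMS[kind]),
        "contralateral": (contra, replace(CLASS_PARAMS[kind], k_ap=0.0, k_pl=0.0)),
        "noise": (noise_vox, None),
    }
    return SceneConfig(regions=regions, noise_sigma=noise_sigma, seed=seed, n_time=n_time)


def default_group_effects(
    n_per_group: int = 5, cv: float = 0.15, seed: int = 0, effect: float = 1.8
) -> GroupEffectSpec:
    """Three-group (CONTROL / TERT / ALT) steady-state metabolite panel.

    TERT elevates NAD(P)/H, GSH, aspartate, and AXP over CONTROL; ALT
    elevates alpha-KG, glutamate, alanine, and AXP. Baseline means are
    plausible fmol/cell magnitudes; ``effect`` is the fold change applied
    to the affected metabolites.
    """
    metabolites = (
        "NAD(P)/H",
        "GSH",
        "aspartate",
        "AXP",
        "alpha-KG",
        "glutamate",
        "alanine",
        "lactate",
        "creatine",
        "myo-inositol",
    )
    base = np.array([2.0, 25.0, 8.0, 12.0, 1.5, 30.0, 10.0, 20.0, 15.0, 18.0])
    tert_up = {"NAD(P)/H", "GSH", "aspartate", "AXP"}
    alt_up = {"alpha-KG", "glutamate", "alanine", "AXP"}
    tert = base * np.array([effect if m in tert_up else 1.0 for m in metabolites])
    alt = base * np.array([effect if m in alt_up else 1.0 for m in metabolites])
    return GroupEffectSpec(
        metabolites=metabolites,
        group_means={"CONTROL": base, "TERT": tert, "ALT": alt},
        cv=cv,
        n_per_group=n_per_group,
        seed=seed,
    )
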
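"""Spectroscopic analysis equations: SEC, MALS, CD, NMR, fluorescence.

Each function implements one published analysis formula exactly as used
for disordered-domain characterization:

* SEC Stokes radius from a log-linear column calibration,
  Ve = m log10(Rs) + b.
* SEC-MALS molecular weight, MW = R(0) / (K c (dn/dc)^2).
* CD mean residue ellipticity, MRE = MRW theta / (10 d c) with
  MRW = MW/(N-1).
* NMR chemical shift perturbation, sqrt(dH^2 + (dN/6.5)^2).
* NMR relative intensity change (line broadening) and hetNOE ratio.
* Single-exponential relaxation fits I = I0 exp(-t R).
* Intensity-weighted mean fluorescence emission wavelength on
  320-380 nm, and the Langmuir binding isotherm with the outer-leaflet
  accessible-lipid convention (accessible concentration = half the
  titrated lipid by default).

Note on the SEC standards: published radii are printed with "nm" units
but carry Angstrom-scale magnitudes (ferritin "61.0"); values here are
stored and returned in Angstrom and the discrepancy is documented
rather than propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

__all__ = [
    "SecCalibration",
    "MalsSample",
    "CdSample",
    "PeakShiftPair",
    "RelaxationSeries",
    "FluorSpectrum",
    "BindingCurve",
    "R1_DELAYS_S",
    "R2_LOOP_COUNTS",
    "R2_LOOP_LENGTH_S",
    "SEC_STANDARDS",
    "fit_sec_calibration",
    "sec_stokes_radius",
    "mals_molecular_weight",
    "cd_mre",
    "nmr_csp",
    "nmr_intensity_change",
    "relaxation_rate_fit",
    "het_noe",
    "fluor_mean_wavelength",
    "langmuir_fit",
]

#: R1 variable relaxation delays (s), in acquisition order.
R1_DELAYS_S = np.array(
    [1.000, 0.020, 1.500, 0.060, 3.000, 0.100, 0.800, 0.200, 0.040, 0.400,
     0.080, 0.600]
)
#: R2 loop counts, in acquisition order; one loop lasts 16.96 ms.
R2_LOOP_COUNTS = np.array([36, 15, 2, 12, 4, 22, 8, 28, 6, 10, 1, 18])
R2_LOOP_LENGTH_S = 0.01696

#: Column calibration standards: (name, MW kDa, Stokes radius in Angstrom).
SEC_STANDARDS = [
    ("ferritin", 440.0, 61.0),
    ("alcohol dehydrogenase", 150.0, 45.0),
    ("conalbumin", 75.0, 36.4),
    ("ovalbumin", 43.0, 30.5),
    ("carbonic anhydrase", 29.0, 23.0),
    ("ribonuclease A", 13.7, 16.4),
    ("aprotinin", 6.5, 13.5),
]


@dataclass
class SecCalibration:
    """Log-linear SEC calibration Ve = m log10(Rs) + b."""

    log_rs: np.ndarray  # log10 of standard Stokes radii (A)
    ve: np.ndarray  # elution volumes, mL
    slope_m: float = field(init=False)
    intercept_b: float = field(init=False)
    residuals: np.ndarray = field(init=False)

    def __post_init__(self):
        self.log_rs = np.asarray(self.log_rs, dtype=float)
        self.ve = np.asarray(self.ve, dtype=float)
        if len(self.log_rs) < 2 or len(self.log_rs) != len(self.ve):
            raise ValueError("need >= 2 matched standards")
        A = np.vstack([self.log_rs, np.ones_like(self.log_rs)]).T
        (self.slope_m, self.intercept_b), *_ = np.linalg.lstsq(A, self.ve, rcond=None)
        self.residuals = self.ve - (self.slope_m * self.log_rs + self.intercept_b)


def fit_sec_calibration(
    standards: Sequence[tuple[str, float, float]], elution_volumes: Sequence[float]
) -> SecCalibration:
    """Build a calibration from (name, MW, Rs[A]) standards and their
    measured elution volumes (mL), in matching order."""
    rs = np.array([s[2] for s in standards], dtype=float)
    return SecCalibration(log_rs=np.log10(rs), ve=np.asarray(elution_volumes))


def sec_stokes_radius(cal: SecCalibration, Ve: float) -> float:
    """Invert the calibration: Rs = 10^((Ve - b)/m), Angstrom.

    Elution volumes outside the calibrated range are extrapolations and
    are flagged with a warning.
    """
    if cal.slope_m == 0:
        raise ValueError("degenerate calibration: zero slope")
    if not (min(cal.ve) <= Ve <= max(cal.ve)):
        import warnings

        warnings.warn("elution volume outside calibration range; extrapolating")
    return float(10.0 ** ((Ve - cal.intercept_b) / cal.slope_m))


@dataclass(frozen=True)
class MalsSample:
    R0: float  # reduced Rayleigh ratio extrapolated to zero angle
    K: float  # optical constant
    c: float  # g/mL
    dndc: float = 0.185  # mL/g, standard protein value

    def __post_init__(self):
        if min(self.R0, self.K, self.c, self.dndc) <= 0:
            raise ValueError("all MALS quantities must be positive")


def mals_molecular_weight(s: MalsSample) -> float:
    """MW = R(0) / (K c (dn/dc)^2), Da."""
    return s.R0 / (s.K * s.c * s.dndc**2)


@dataclass
class CdSample:
    wavelengths: np.ndarray  # nm
    theta: np.ndarray  # measured ellipticity, deg
    pathlength_d: float  # cm
    conc_c: float  # g/mL
    MW: float  # Da
    n_residues: int

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.pathlength_d <= 0 or self.conc_c <= 0:
            raise ValueError("pathlength and concentration must be positive")
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues for MRW")

    @property
    def mrw(self) -> float:
        return self.MW / (self.n_residues - 1)


def cd_mre(s: CdSample) -> np.ndarray:
    """Mean residue ellipticity per wavelength, deg cm^2 dmol^-1:
    MRE = MRW * theta / (10 d c)."""
    return s.mrw * s.theta / (10.0 * s.pathlength_d * s.conc_c)


@dataclass(frozen=True)
class PeakShiftPair:
    residue: int
    delta_H: float  # ppm
    delta_N: float  # ppm


def nmr_csp(a: PeakShiftPair | tuple[float, float]) -> float:
    """Weighted amide chemical shift perturbation,
    sqrt(dH^2 + (dN/6.5)^2), ppm."""
    if isinstance(a, PeakShiftPair):
        dh, dn = a.delta_H, a.delta_N
    else:
        dh, dn = a
    if not (np.isfinite(dh) and np.isfinite(dn)):
        raise ValueError("shifts must be finite")
    return float(np.hypot(dh, dn / 6.5))


def nmr_intensity_change(
    I0: float, Ii: float, mode: Literal["relative_change", "ratio"] = "relative_change"
) -> float:
    """Peak intensity response to titration.

    ``relative_change`` is the signed (Ii - I0)/I0 (negative for signal
    loss, -1 for complete line broadening); ``ratio`` is Ii/I0 (0.5
    means halved intensity, 0 complete broadening).
    """
    if I0 <= 0:
        raise ValueError("reference intensity must be positive")
    if mode == "relative_change":
        return (Ii - I0) / I0
    if mode == "ratio":
        return Ii / I0
    raise ValueError("mode must be 'relative_change' or 'ratio'")


def het_noe(I_sat: float, I_ref: float) -> float:
    """Heteronuclear NOE: ratio of saturated to reference peak volume."""
    if I_ref == 0:
        raise ValueError("reference intensity must be nonzero")
    return I_sat / I_ref


@dataclass
class RelaxationSeries:
    delays: np.ndarray  # s (or loop counts for kind='R2' + loops=True)
    intensities: np.ndarray
    kind: Literal["R1", "R2"] = "R1"

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.delays) < 3:
            raise ValueError("need at least 3 relaxation delays")
        if np.any(self.delays < 0):
            raise ValueError("delays must be nonnegative")

    @classmethod
    def from_loop_counts(cls, loop_counts, intensities) -> "RelaxationSeries":
        """R2 series specified as loop counts (16.96 ms per loop)."""
        delays = np.asarray(loop_counts, dtype=float) * R2_LOOP_LENGTH_S
        return cls(delays=delays, intensities=intensities, kind="R2")


def relaxation_rate_fit(
    s: RelaxationSeries, confidence: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Fit I = I0 exp(-t R) by nonlinear least squares.

    Returns (R in s^-1, I0, CI) where CI is the two-sided confidence
    interval on R from the parameter covariance.  A constant series
    fits R = 0 exactly.
    """
    if len(np.unique(s.delays)) < 3:
        raise ValueError("need at least 3 distinct delays")

    def model(t, i0, r):
        return i0 * np.exp(-t * r)

    i0_guess = float(s.intensities[np.argmin(s.delays)])
    span = s.delays.max() - s.delays.min()
    with np.errstate(all="ignore"):
        pos = s.intensities > 0
        if pos.sum() >= 2:
            slope = np.polyfit(s.delays[pos], np.log(s.intensities[pos]), 1)[0]
            r_guess = max(-slope, 0.0)
        else:
            r_guess = 1.0 / max(span, 1e-6)
    try:
        import warnings
        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # a constant series fits R = 0 with a singular covariance
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(
                model, s.delays, s.intensities, p0=[i0_guess or 1.0, r_guess],
                maxfev=10000,
            )
    except RuntimeError as err:
        raise RuntimeError(f"relaxation fit did not converge: {err}") from err
    i0, r = popt
    dof = max(len(s.delays) - 2, 1)
    se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    tq = t_dist.ppf(0.5 + confidence / 2.0, dof)
    return float(r), float(i0), (float(r - tq * se), float(r + tq * se))


@dataclass
class FluorSpectrum:
    wavelengths: np.ndarray  # nm, strictly increasing, covering 320-380
    intensity: np.ndarray  # counts per second

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths[0] > 320.0 or self.wavelengths[-1] < 380.0:
            raise ValueError("spectrum must cover 320-380 nm")


def fluor_mean_wavelength(s: FluorSpectrum) -> float:
    """Intensity-weighted mean emission wavelength over 320-380 nm:
    <lambda> = sum I_i lambda_i / sum I_i."""
    win = (s.wavelengths >= 320.0) & (s.wavelengths <= 380.0)
    I = s.intensity[win]
    lam = s.wavelengths[win]
    total = I.sum()
    if total <= 0:
        raise ValueError("zero total intensity in the 320-380 nm window")
    return float((I * lam).sum() / total)


@dataclass
class BindingCurve:
    lipid_total: np.ndarray  # titrated lipid concentration series
    observable: np.ndarray  # e.g. Delta<lambda> in nm
    accessible_fraction: float = 0.5  # outer leaflet only

    def __post_init__(self):
        self.lipid_total = np.asarray(self.lipid_total, dtype=float)
        self.observable = np.asarray(self.observable, dtype=float)
        if np.any(self.lipid_total < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(np.diff(self.lipid_total) < 0):
            raise ValueError("concentration series must be nondecreasing")
        if not 0 < self.accessible_fraction <= 1:
            raise ValueError("accessible_fraction must lie in (0, 1]")


def langmuir_fit(
    b: BindingCurve, confidence: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Fit the Langmuir isotherm D = Dmax c / (Kd + c).

    The accessible concentration c is ``accessible_fraction`` times the
    titrated lipid concentration (default one half: binding to the
    outer liposome leaflet only).  Returns (Kd, Dmax, CI on Kd); Kd is
    expressed in accessible-concentration units.  Fewer than 4 points
    or a series that does not bracket the apparent Kd triggers a
    warning; negative fitted parameters are an error.
    """
    import warnings

    c = b.accessible_fraction * b.lipid_total
    y = b.observable
    if len(c) < 4:
        warnings.warn("fewer than 4 titration points; Kd poorly constrained")

    def model(cc, dmax, kd):
        return dmax * cc / (kd + cc)

    dmax0 = float(y.max()) or 1.0
    half = dmax0 / 2.0
    kd0 = float(np.interp(half, y, c)) if np.any(y > half) else float(c[len(c) // 2] or 1.0)
    popt, pcov = curve_fit(model, c, y, p0=[dmax0, max(kd0, 1e-12)], maxfev=10000)
    dmax, kd = popt
    if dmax <= 0 or kd <= 0:
        raise RuntimeError("Langmuir fit produced nonpositive parameters")
    if kd > c.max():
        warnings.warn("apparent Kd above the highest accessible concentration")
    dof = max(len(c) - 2, 1)
    se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    tq = t_dist.ppf(0.5 + confidence / 2.0, dof)
    return float(kd), float(dmax), (float(kd - tq * se), float(kd + tq * se))
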
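"""Per-shot wavelength determination and detector-distance refinement.

The inline spectrometer disperses photon energy along the 1024-pixel axis
of its readout; each colour appears as a Lorentzian ridge.  Collapsing the
readout and fitting a double Lorentzian gives the two ridge centres, which
a two-point linear energy calibration (from reference runs at the nominal
7 and 9 keV) converts to per-shot photon energies and wavelengths.

Detector distance is refined against powder rings of known d-spacing:
ring radii from the azimuthally averaged radial profile, distance from
least squares on r_i = D tan(2 theta_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks as _signal_find_peaks

from .geometry import BeamColour, DetectorGeometry


@dataclass(frozen=True)
class SpectralFit:
    """Double-Lorentzian fit of a collapsed spectrometer profile.

    Components ordered by centre column.  amplitude in ADU, centre and
    half-width in pixels.
    """

    amplitudes: tuple[float, float]
    centers: tuple[float, float]
    widths: tuple[float, float]
    baseline: float
    residual_norm: float
    converged: bool

    def __post_init__(self):
        if self.centers[0] > self.centers[1]:
            raise ValueError("components must be ordered by center")


@dataclass(frozen=True)
class EnergyCalibration:
    """Linear dispersion: energy(eV) = offset + slope * column."""

    slope: float  # eV / px
    offset: float  # eV
    source: str = ""

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def column_to_energy(self, column: float) -> float:
        return self.offset + self.slope * column

    def energy_to_column(self, energy_ev: float) -> float:
        return (energy_ev - self.offset) / self.slope

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"slope_ev_per_px = {self.slope!r}\n")
            fh.write(f"offset_ev = {self.offset!r}\n")
            fh.write(f"source = {self.source}\n")

    @classmethod
    def read(cls, path) -> "EnergyCalibration":
        vals = {}
        with open(path) as fh:
            for line in fh:
                key, _, val = line.partition("=")
                vals[key.strip()] = val.strip()
        return cls(slope=float(vals["slope_ev_per_px"]),
                   offset=float(vals["offset_ev"]),
                   source=vals.get("source", ""))


@dataclass(frozen=True)
class DistanceFit:
    """Refined detector distance with per-ring residuals and the score
    (sum of squared radial residuals, px^2) at the optimum."""

    distance: float  # mm
    residuals: np.ndarray  # per ring, px
    score: float
    consistent: bool  # True when the rms residual is within tolerance

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def collapse_spectrum(image) -> np.ndarray:
    """Sum all reads of each dispersion column: (n_reads, 1024) -> (1024,)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("spectrometer image must be 2D")
    return img.sum(axis=0)


def _double_lorentzian(x, baseline, a1, c1, w1, a2, c2, w2):
    return (baseline
            + a1 / (1.0 + ((x - c1) / w1) ** 2)
            + a2 / (1.0 + ((x - c2) / w2) ** 2))


def _estimate_start(profile: np.ndarray):
    """Starting values: the two highest well-separated local maxima; widths
    from half-maximum crossings around each."""
    base = float(np.median(profile))
    resid = profile - base
    prominence = max(0.05 * float(resid.max()), 1e-9)
    idx, props = _signal_find_peaks(resid, prominence=prominence, distance=10)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(resid))])
    order = np.argsort(resid[idx])[::-1]
    first = idx[order[0]]
    second = None
    for k in order[1:]:
        if abs(idx[k] - first) > 20:
            second = idx[k]
            break
    if second is None:
        # degenerate: start the second component on the same peak, tiny
        second = min(first + 30, len(profile) - 1)
    centres = sorted([int(first), int(second)])

    def width_at(c):
        half = resid[c] / 2.0
        left = c
        while left > 0 and resid[left] > half:
            left -= 1
        right = c
        while right < len(resid) - 1 and resid[right] > half:
            right += 1
        return max((right - left) / 2.0, 1.0)

    return base, centres, [width_at(c) for c in centres]


def fit_double_lorentzian(profile) -> SpectralFit:
    """Least-squares fit of baseline + two Lorentzian components with
    automatically estimated starting values."""
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1:
        raise ValueError("profile must be 1D")
    if np.ptp(y) == 0:
        raise ValueError("profile is constant; nothing to fit")
    x = np.arange(len(y), dtype=float)
    base, (c1, c2), (w1, w2) = _estimate_start(y)
    a1 = max(y[c1] - base, 1e-6)
    a2 = max(y[c2] - base, 1e-6)
    p0 = [base, a1, c1, w1, a2, c2, w2]
    lo = [-np.inf, 0, 0, 0.1, 0, 0, 0.1]
    hi = [np.inf, np.inf, len(y) - 1.0, len(y) / 2.0,
          np.inf, len(y) - 1.0, len(y) / 2.0]

    def resid(p):
        return _double_lorentzian(x, *p) - y

    fit = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                        max_nfev=5000)
    p = fit.x
    comps = sorted([(p[2], p[1], p[3]), (p[5], p[4], p[6])])
    return SpectralFit(
        amplitudes=(comps[0][1], comps[1][1]),
        centers=(comps[0][0], comps[1][0]),
        widths=(comps[0][2], comps[1][2]),
        baseline=float(p[0]),
        residual_norm=float(np.linalg.norm(fit.fun)),
        converged=bool(fit.success),
    )


def calibrate_energy(reference_fits, known_energies=(7000.0, 9000.0),
                     source: str = "") -> EnergyCalibration:
    """Two-point linear dispersion from reference runs at known energies.

    Each reference fit contributes the centre of its dominant component.
    """
    if len(reference_fits) != 2 or len(known_energies) != 2:
        raise ValueError("exactly two reference fits and energies required")
    centres = []
    for f in reference_fits:
        k = int(np.argmax(f.amplitudes))
        centres.append(f.centers[k])
    c1, c2 = centres
    e1, e2 = known_energies
    if c1 == c2:
        raise ValueError("reference centers coincide; cannot calibrate")
    slope = (e2 - e1) / (c2 - c1)
    offset = e1 - slope * c1
    return EnergyCalibration(slope=slope, offset=offset, source=source)


def assign_wavelengths(fit: SpectralFit, calib: EnergyCalibration,
                       pulse_energies: tuple[float, float] | None = None):
    """Map the two fitted centres to (lower-energy colour, higher-energy
    colour) — the 7 keV-like colour first.  Invariant under component order
    and under the sign of the dispersion slope."""
    energies = [calib.column_to_energy(c) / 1000.0 for c in fit.centers]  # keV
    amps = list(fit.amplitudes)
    pairs = sorted(zip(energies, amps))
    pe = pulse_energies if pulse_energies is not None else (pairs[0][1], pairs[1][1])
    return (
        BeamColour.from_energy(pairs[0][0], pe[0]),
        BeamColour.from_energy(pairs[1][0], pe[1]),
    )


def radial_profile(image, geom: DetectorGeometry):
    """Azimuthally averaged intensity vs integer radius (px) about the beam
    centre.  Returns (radii, mean_intensity)."""
    img = np.asarray(image, dtype=float)
    cf, cs = geom.beam_center
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    rr = np.hypot(xx - cf, yy - cs)
    ri = np.rint(rr).astype(int).ravel()
    sums = np.bincount(ri, weights=img.ravel())
    counts = np.bincount(ri)
    valid = counts > 0
    prof = np.zeros_like(sums)
    prof[valid] = sums[valid] / counts[valid]
    return np.arange(len(prof))[valid], prof[valid]


def detect_rings(powder_image, geom: DetectorGeometry,
                 prominence_sigma: float = 5.0,
                 centroid_halfwidth: int = 6) -> np.ndarray:
    """Ring radii (px) from local maxima of the radial profile.

    Maxima must rise `prominence_sigma` robust standard deviations above
    the profile's background; each radius is refined by the local
    intensity-weighted centroid of the background-subtracted profile.
    """
    radii, prof = radial_profile(powder_image, geom)
    if len(prof) < 5:
        return np.array([])
    base = np.median(prof)
    spread = np.median(np.abs(prof - base)) * 1.4826
    prominence = max(prominence_sigma * spread, 1e-9)
    idx, _ = _signal_find_peaks(prof, prominence=prominence)
    out = []
    for i in idx:
        lo = max(i - centroid_halfwidth, 0)
        hi = min(i + centroid_halfwidth + 1, len(prof))
        w = np.clip(prof[lo:hi] - base, 0, None)
        if w.sum() <= 0:
            continue
        out.append(float(np.sum(radii[lo:hi] * w) / w.sum()))
    return np.array(out)


def refine_distance(radii_px, d_spacings, colour: BeamColour,
                    geom: DetectorGeometry, rms_tolerance: float = 1.0) -> DistanceFit:
    """Refine detector distance from rings with assigned d-spacings.

    Minimises score(D) = sum_i (r_i - D tan(2 theta_i) / pixel_size)^2.
    The model is linear in D, so the optimum is closed-form; with a single
    ring it reduces to D = r * pixel_size / tan(2 theta).
    """
    r = np.atleast_1d(np.asarray(radii_px, dtype=float))
    d = np.atleast_1d(np.asarray(d_spacings, dtype=float))
    if len(r) == 0 or len(r) != len(d):
        raise ValueError("need >= 1 ring with matching d-spacing assignments")
    sin_t = colour.wavelength / (2.0 * d)
    if np.any(sin_t >= 1.0):
        raise ValueError("d-spacing unreachable at this wavelength")
    t = np.tan(2.0 * np.arcsin(sin_t)) / geom.pixel_size  # px per mm of distance
    dist = float(np.dot(r, t) / np.dot(t, t))  # linear least squares in D
    resid = r - dist * t
    score = float(np.dot(resid, resid))
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return DistanceFit(distance=dist, residuals=resid, score=score,
                       consistent=rms <= rms_tolerance)
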
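"""Experiment geometry for two-colour still diffraction.

Conventions
-----------
* Laboratory frame: X-ray beam along +z; `fast` is the image column (x),
  `slow` is the image row (y).  Single flat panel, no tilts.
* Pixel coordinates are 0-based with pixel centres at integer coordinates.
* Reciprocal vectors use crystallographic units (A^-1, no 2*pi factor):
  an elastic scattering event with unit incident direction z and unit
  outgoing direction s has ``q = (s - z) / wavelength``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import HC_KEV_ANGSTROM

#: Sentinel returned for the resolution "at" the direct beam position.
LOW_RESOLUTION_LIMIT = math.inf


def energy_to_wavelength(photon_energy: float) -> float:
    """Convert photon energy (keV) to wavelength (A)."""
    if photon_energy <= 0:
        raise ValueError(f"photon energy must be positive, got {photon_energy}")
    return HC_KEV_ANGSTROM / photon_energy


def wavelength_to_energy(wavelength: float) -> float:
    """Convert wavelength (A) to photon energy (keV). Exact inverse of
    :func:`energy_to_wavelength`."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    return HC_KEV_ANGSTROM / wavelength


@dataclass(frozen=True)
class BeamColour:
    """One of the two simultaneous XFEL beams ("colours").

    photon_energy in keV, wavelength in A (always hc / E with the
    package-wide constant), pulse_energy in arbitrary relative units.
    """

    photon_energy: float
    wavelength: float
    pulse_energy: float = 1.0

    def __post_init__(self):
        if self.photon_energy <= 0 or self.wavelength <= 0:
            raise ValueError("photon energy and wavelength must be positive")
        expected = HC_KEV_ANGSTROM / self.photon_energy
        if not math.isclose(self.wavelength, expected, rel_tol=1e-9):
            raise ValueError(
                f"wavelength {self.wavelength} inconsistent with energy "
                f"{self.photon_energy} keV (expected {expected:.6f} A)"
            )

    @classmethod
    def from_energy(cls, photon_energy: float, pulse_energy: float = 1.0) -> "BeamColour":
        return cls(photon_energy, energy_to_wavelength(photon_energy), pulse_energy)

    @classmethod
    def from_wavelength(cls, wavelength: float, pulse_energy: float = 1.0) -> "BeamColour":
        return cls(wavelength_to_energy(wavelength), wavelength, pulse_energy)

    @property
    def label(self) -> str:
        return f"{self.photon_energy:g}keV"

    def with_wavelength(self, wavelength: float) -> "BeamColour":
        return BeamColour.from_wavelength(wavelength, self.pulse_energy)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat single-panel detector.

    beam_center is (fast, slow) in pixels; distance and pixel_size in mm.
    """

    n_fast: int
    n_slow: int
    pixel_size: float  # mm
    distance: float  # mm
    beam_center: tuple[float, float]  # (fast, slow), pixels
    saturation_level: float = 65535.0  # ADU

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("detector distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        cf, cs = self.beam_center
        if not (0 <= cf < self.n_fast and 0 <= cs < self.n_slow):
            raise ValueError("beam center must lie inside the panel")

    def contains(self, fast, slow):
        """Vectorised panel-membership test for pixel coordinates."""
        fast = np.asarray(fast)
        slow = np.asarray(slow)
        return (fast >= 0) & (fast <= self.n_fast - 1) & (slow >= 0) & (slow <= self.n_slow - 1)

    def pixel_radius_mm(self, fast, slow):
        cf, cs = self.beam_center
        return np.hypot(np.asarray(fast) - cf, np.asarray(slow) - cs) * self.pixel_size

    def with_distance(self, distance: float) -> "DetectorGeometry":
        return replace(self, distance=distance)


@dataclass(frozen=True)
class UnitCell:
    """Direct-space unit cell. Lengths in A, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    lattice_type: str = "triclinic"
    centering: str = "P"
    space_group: str = "P1"

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        if self.lattice_type == "tetragonal":
            if not (math.isclose(self.a, self.b)
                    and all(math.isclose(getattr(self, n), 90.0)
                            for n in ("alpha", "beta", "gamma"))):
                raise ValueError("tetragonal cell requires a = b and all angles 90")

    def direct_matrix(self) -> np.ndarray:
        """Rows are the direct basis vectors a, b, c in a standard setting
        (a along x, b in the xy plane)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        sg = math.sin(ga)
        ax = np.array([self.a, 0.0, 0.0])
        bx = np.array([self.b * cg, self.b * sg, 0.0])
        cx_x = self.c * cb
        cx_y = self.c * (ca - cb * cg) / sg
        cx_z = self.c * math.sqrt(max(1 - cb * cb - ((ca - cb * cg) / sg) ** 2, 0.0))
        cx = np.array([cx_x, cx_y, cx_z])
        return np.vstack([ax, bx, cx])

    def b_matrix(self) -> np.ndarray:
        """Reciprocal basis matrix B: columns are a*, b*, c* (A^-1) so that
        q = B @ hkl for an unrotated crystal."""
        return np.linalg.inv(self.direct_matrix())

    def volume(self) -> float:
        return float(abs(np.linalg.det(self.direct_matrix())))

    def d_spacing(self, hkl) -> np.ndarray:
        """Resolution of reflections hkl (array-like, shape (..., 3))."""
        h = np.asarray(hkl, dtype=float)
        g = h @ self.b_matrix().T
        return 1.0 / np.linalg.norm(g, axis=-1)


#: Gadoteridol-derivatised lysozyme cell used throughout the synthetic studies.
LYSOZYME_GD_CELL = UnitCell(
    78.3, 78.3, 39.1, 90.0, 90.0, 90.0,
    lattice_type="tetragonal", centering="P", space_group="P43212",
)


@dataclass(frozen=True)
class Orientation:
    """Crystal orientation: 3x3 matrix mapping integer hkl to a laboratory
    frame reciprocal vector (A^-1): q = reciprocal_basis @ hkl."""

    reciprocal_basis: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.reciprocal_basis, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("reciprocal basis must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("reciprocal basis is singular")
        object.__setattr__(self, "reciprocal_basis", m)

    @classmethod
    def from_rotation(cls, rotation: np.ndarray, cell: UnitCell) -> "Orientation":
        return cls(np.asarray(rotation, float) @ cell.b_matrix())

    def rotation_relative_to(self, cell: UnitCell) -> np.ndarray:
        """Polar-decompose reciprocal_basis = R @ B(cell); returns R."""
        m = self.reciprocal_basis @ np.linalg.inv(cell.b_matrix())
        u, _, vt = np.linalg.svd(m)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        return r

    def cell(self) -> UnitCell:
        """Extract cell lengths/angles from the basis (lattice-type agnostic:
        returns a triclinic description)."""
        direct = np.linalg.inv(self.reciprocal_basis)  # rows a, b, c
        av, bv, cv = direct
        a, b, c = (float(np.linalg.norm(v)) for v in (av, bv, cv))

        def ang(u, v):
            return math.degrees(math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

        return UnitCell(a, b, c, ang(bv, cv), ang(av, cv), ang(av, bv))


def resolution_at_pixel(geom: DetectorGeometry, wavelength: float, pixel) -> float:
    """Bragg resolution d (A) of the pixel's scattering angle.

    d = lambda / (2 sin theta), 2*theta = atan(r / D). The beam-center pixel
    has no defined scattering angle; the low-resolution sentinel (inf) is
    returned there.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    fast, slow = pixel
    if not np.all(geom.contains(fast, slow)):
        raise ValueError("pixel outside the panel")
    r = geom.pixel_radius_mm(fast, slow)
    if np.ndim(r) == 0 and r == 0:
        return LOW_RESOLUTION_LIMIT
    two_theta = np.arctan2(r, geom.distance)
    with np.errstate(divide="ignore"):
        d = wavelength / (2.0 * np.sin(two_theta / 2.0))
    return float(d) if np.ndim(d) == 0 else d


def scale_resolution_between_colours(d_ref: float, lambda_ref: float, lambda_new: float) -> float:
    """Rescale a resolution quoted at one wavelength to the same scattering
    angle at another wavelength (Bragg's law at fixed theta)."""
    if d_ref <= 0 or lambda_ref <= 0 or lambda_new <= 0:
        raise ValueError("all inputs must be positive")
    return d_ref * lambda_new / lambda_ref


def pixel_to_scattering_vector(geom: DetectorGeometry, wavelength: float, fast, slow) -> np.ndarray:
    """Map pixel coordinates to the elastic scattering vector q (A^-1),
    shape (..., 3). q lies on the Ewald sphere of radius 1/lambda."""
    cf, cs = geom.beam_center
    x = (np.asarray(fast, float) - cf) * geom.pixel_size
    y = (np.asarray(slow, float) - cs) * geom.pixel_size
    z = np.full_like(x, geom.distance)
    s = np.stack([x, y, z], axis=-1)
    s /= np.linalg.norm(s, axis=-1, keepdims=True)
    k = 1.0 / wavelength
    q = k * (s - np.array([0.0, 0.0, 1.0]))
    return q


def predict_spot_positions(
    orient: Orientation,
    cell: UnitCell,
    colour: BeamColour,
    geom: DetectorGeometry,
    excitation_tolerance: float = 0.002,
    d_min: float = 2.0,
) -> list[tuple[tuple[int, int, int], float, float]]:
    """Predict Bragg spot positions for a still image.

    A reflection is emitted when its reciprocal lattice point g = M @ hkl
    lies within `excitation_tolerance` (A^-1) of the Ewald sphere, has
    d >= d_min, and its diffracted ray intersects the panel.  The spot is
    the flat-detector projection of the ray through g + k*z (the vector
    from the Ewald sphere centre to the lattice point).

    Returns a list of (hkl, fast, slow).
    """
    if excitation_tolerance <= 0:
        raise ValueError("excitation tolerance must be positive")
    m = orient.reciprocal_basis
    k = 1.0 / colour.wavelength

    hmax = np.ceil(1.0 / (d_min * np.min(np.linalg.norm(m, axis=0)))).astype(int)
    rng = np.arange(-hmax, hmax + 1)
    hh, kk, ll = np.meshgrid(rng, rng, rng, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]

    g = hkl @ m.T
    glen = np.linalg.norm(g, axis=1)
    keep = (glen <= 1.0 / d_min) & (glen > 1e-12)
    hkl, g = hkl[keep], g[keep]

    # excitation error: distance of g from the Ewald sphere centred at -k z
    centre = np.array([0.0, 0.0, -k])
    s_vec = g - centre  # direction of the diffracted beam
    exc = np.abs(np.linalg.norm(s_vec, axis=1) - k)
    keep = exc <= excitation_tolerance
    hkl, s_vec = hkl[keep], s_vec[keep]

    forward = s_vec[:, 2] > 1e-12
    hkl, s_vec = hkl[forward], s_vec[forward]

    scale = geom.distance / s_vec[:, 2]
    x = s_vec[:, 0] * scale
    y = s_vec[:, 1] * scale
    cf, cs = geom.beam_center
    fast = cf + x / geom.pixel_size
    slow = cs + y / geom.pixel_size
    on = geom.contains(fast, slow)

    return [
        ((int(h), int(kk_), int(l)), float(f), float(s))
        for (h, kk_, l), f, s in zip(hkl[on], fast[on], slow[on])
    ]


# ---------------------------------------------------------------------------
# flat key=value serialisation

def write_geometry(geom: DetectorGeometry, path) -> None:
    with open(path, "w") as fh:
        fh.write("; sfx2c detector geometry\n")
        fh.write(f"n_fast = {geom.n_fast}\n")
        fh.write(f"n_slow = {geom.n_slow}\n")
        fh.write(f"pixel_size_mm = {geom.pixel_size!r}\n")
        fh.write(f"distance_mm = {geom.distance!r}\n")
        fh.write(f"beam_center_fast = {geom.beam_center[0]!r}\n")
        fh.write(f"beam_center_slow = {geom.beam_center[1]!r}\n")
        fh.write(f"saturation_adu = {geom.saturation_level!r}\n")


def read_geometry(path) -> DetectorGeometry:
    vals = {}
    with open(path) as fh:
        for line in fh:
            line = line.split(";")[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            vals[key.strip()] = float(val.strip())
    return DetectorGeometry(
        n_fast=int(vals["n_fast"]),
        n_slow=int(vals["n_slow"]),
        pixel_size=vals["pixel_size_mm"],
        distance=vals["distance_mm"],
        beam_center=(vals["beam_center_fast"], vals["beam_center_slow"]),
        saturation_level=vals.get("saturation_adu", 65535.0),
    )
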
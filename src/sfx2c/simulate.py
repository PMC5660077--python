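"""Synthetic two-colour SFX data with full ground truth.

The generators emulate the statistical structure of a two-colour split-
undulator experiment: one crystal orientation shared by both colours, a
log-normal shot-to-shot imbalance between the two patterns' intensities,
fractional wavelength jitter per colour, a diffuse grease-carrier ring,
flat background, optional Poisson noise and hard saturation clipping.
Everything drawn is recorded in a ground-truth structure so downstream
steps (peak finding, indexing, integration, phasing) can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import symmetry
from .constants import F0_BY_ELEMENT
from .geometry import (
    BeamColour,
    DetectorGeometry,
    LYSOZYME_GD_CELL,
    Orientation,
    UnitCell,
    predict_spot_positions,
)


def default_geometry() -> DetectorGeometry:
    """MPCCD-like single flat panel: 2048 x 2048 pixels of 0.05 mm at 50 mm.

    Panel size and pixel pitch are simulator parameters; the 50 mm distance
    places the panel edge near 1.8 A and the corner near 1.5 A for the
    9 keV colour.
    """
    return DetectorGeometry(2048, 2048, 0.05, 50.0, (1023.5, 1023.5),
                            saturation_level=65535.0)


def desk_geometry() -> DetectorGeometry:
    """Down-sampled panel for ensemble studies: 768 x 768 pixels of 0.2 mm
    at 200 mm.

    The ratio distance * wavelength / (cell edge * pixel pitch) — i.e. the
    Bragg spot spacing in pixels, ~17.6 px at 9 keV for the 78.3 A cell —
    matches the full-scale geometry, so pixel-denominated processing
    parameters (10 px subtraction radius, 16 px median window, 4 px match
    radius) keep their meaning while each image costs an order of magnitude
    less to render and filter.  Panel edge reaches ~3.8 A at 9 keV.
    """
    return DetectorGeometry(768, 768, 0.2, 200.0, (383.5, 383.5),
                            saturation_level=65535.0)


def two_colour_beams(pulse_energy_7: float = 1.0, pulse_energy_9: float = 1.0):
    """The nominal (7 keV, 9 keV) colour pair."""
    return (BeamColour.from_energy(7.0, pulse_energy_7),
            BeamColour.from_energy(9.0, pulse_energy_9))


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic experiment; `seed` fixes every draw.

    colour_ratio_sigma is the standard deviation of the log of the
    strong:weak intensity ratio (log-normal, median 1); colour_ratio_fixed
    pins the ratio instead when not None.
    """

    colour_ratio_sigma: float = 1.0
    colour_ratio_fixed: float | None = None
    wavelength_jitter: float = 0.002  # fractional sd per colour
    background_level: float = 20.0  # ADU
    grease_ring_radius: float = 150.0  # pixels
    grease_ring_width: float = 20.0  # pixels
    grease_ring_amplitude: float = 30.0  # ADU
    noise: str = "none"  # "none" | "poisson"
    saturate: bool = False
    spot_sigma: float = 1.0  # 2D Gaussian sd, pixels
    spot_intensity_mean: float = 10_000.0  # mean integrated ADU (exponential)
    excitation_tolerance: float = 0.002  # A^-1
    d_min: float = 2.0  # A
    spectro_width: float = 8.0  # Lorentzian half-width, pixels
    spectro_amplitude: float = 200.0  # ADU per row at the ridge centre
    spectro_baseline: float = 10.0  # ADU
    spectro_noise: float = 1.0  # Gaussian sd, ADU (with noise="poisson" too)
    ring_amplitude: float = 500.0  # powder ring peak, ADU
    ring_width: float = 3.0  # powder ring radial sd, pixels
    seed: int = 0

    def __post_init__(self):
        for name in ("colour_ratio_sigma", "wavelength_jitter", "background_level",
                     "grease_ring_radius", "grease_ring_width", "grease_ring_amplitude",
                     "spot_sigma", "spot_intensity_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")

    @classmethod
    def cell_recovery_study(cls, seed: int = 1) -> "SimConfig":
        """Noise-free ensemble conditions for unit-cell recovery: random
        orientations, log-normal colour imbalance, spots to the panel
        edge of the desk geometry."""
        return cls(seed=seed, noise="none", d_min=3.5)

    @classmethod
    def disentangling_study(cls, seed: int = 1) -> "SimConfig":
        """Conditions of the strong/weak disentangling regression: fixed
        10:1 colour ratio, Poisson noise, and spot intensities placed so
        the weak pattern hovers at the detection threshold — the regime
        where the peak list is dominated by the strong pattern and the
        subtraction step decides whether the weak colour indexes."""
        return cls(seed=seed, noise="poisson", colour_ratio_fixed=10.0,
                   spot_intensity_mean=650.0, d_min=3.5)


@dataclass
class GroundTruth:
    """Everything the simulator drew for one image."""

    orientation: Orientation
    cell: UnitCell
    colours: tuple[BeamColour, BeamColour]  # with jittered wavelengths
    peak_table: pd.DataFrame  # h, k, l, colour (index), fast, slow, intensity
    colour_scales: tuple[float, float]
    background: dict
    seed: int


@dataclass(frozen=True)
class HeavySite:
    """Anomalous scatterer site: fractional coordinates, occupancy, B (A^2)."""

    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "xyz", tuple(float(v) % 1.0 for v in self.xyz))
        if self.occupancy <= 0:
            raise ValueError("occupancy must be positive")


@dataclass(frozen=True)
class AnomalousScatterer:
    """Element with per-energy anomalous corrections.

    `corrections` maps photon energy (keV) to (f_prime, f_double_prime) in
    electrons; lookup uses the nearest tabulated energy.
    """

    element: str = "Gd"
    corrections: tuple[tuple[float, float, float], ...] = (
        # (photon_energy_keV, f', f'') — Gd just below / above its L edges
        (9.0, -4.0, 11.7),
        (7.0, -10.0, 3.8),
    )

    def __post_init__(self):
        for _, _, fpp in self.corrections:
            if fpp < 0:
                raise ValueError("f'' must be non-negative")

    def for_colour(self, colour: BeamColour) -> tuple[float, float]:
        energies = np.array([e for e, _, _ in self.corrections])
        i = int(np.argmin(np.abs(energies - colour.photon_energy)))
        return self.corrections[i][1], self.corrections[i][2]

    @property
    def f0(self) -> float:
        return F0_BY_ELEMENT.get(self.element, float(len(self.element)))


#: The two independent Gd sites per asymmetric unit used by the synthetic
#: phasing studies: fixed general-position fractional coordinates chosen so
#: that the two sites' full equivalence classes (symmetry, allowed origin
#: shifts, inversion) stay well separated (> 6 A), full occupancy.
GD_SITES = (
    HeavySite((0.214, 0.068, 0.172), occupancy=1.0, b_iso=12.0),
    HeavySite((0.066, 0.333, 0.628), occupancy=1.0, b_iso=12.0),
)


@dataclass(frozen=True)
class PseudoAtomProtein:
    """Random pseudo-atom stand-in for the protein: carbon-like scatterers
    at fixed random fractional positions (no biological structure)."""

    xyz: np.ndarray  # (n, 3) fractional
    f0: float = 6.0
    b_iso: float = 15.0


def make_pseudo_protein(n_atoms: int = 300, seed: int = 1234,
                        f0: float = 6.0, b_iso: float = 15.0) -> PseudoAtomProtein:
    rng = np.random.default_rng(seed)
    return PseudoAtomProtein(xyz=rng.random((n_atoms, 3)), f0=f0, b_iso=b_iso)


def _rng_for(cfg_seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg_seed), *map(int, stream)]))


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()


def _paint_spots(image: np.ndarray, fast, slow, intensity, sigma: float) -> None:
    """Accumulate 2D Gaussian footprints of given integrated intensities."""
    half = max(int(np.ceil(4 * sigma)), 2)
    n_slow, n_fast = image.shape
    for f, s, inten in zip(fast, slow, intensity):
        j0, j1 = int(np.floor(f)) - half, int(np.floor(f)) + half + 1
        i0, i1 = int(np.floor(s)) - half, int(np.floor(s)) + half + 1
        j0c, j1c = max(j0, 0), min(j1, n_fast)
        i0c, i1c = max(i0, 0), min(i1, n_slow)
        if j0c >= j1c or i0c >= i1c:
            continue
        jj = np.arange(j0c, j1c)
        ii = np.arange(i0c, i1c)
        gx = np.exp(-0.5 * ((jj - f) / sigma) ** 2)
        gy = np.exp(-0.5 * ((ii - s) / sigma) ** 2)
        footprint = np.outer(gy, gx)
        footprint *= inten / (2.0 * np.pi * sigma * sigma)
        image[i0c:i1c, j0c:j1c] += footprint


def _radial_background(geom: DetectorGeometry, level: float,
                       ring_r: float, ring_w: float, ring_a: float) -> np.ndarray:
    bg = np.full((geom.n_slow, geom.n_fast), float(level))
    if ring_a > 0 and ring_w > 0:
        cf, cs = geom.beam_center
        yy, xx = np.mgrid[0:geom.n_slow, 0:geom.n_fast]
        rr = np.hypot(xx - cf, yy - cs)
        bg += ring_a * np.exp(-0.5 * ((rr - ring_r) / ring_w) ** 2)
    return bg


def simulate_two_colour_image(
    cell: UnitCell,
    geom: DetectorGeometry,
    colours: tuple[BeamColour, BeamColour],
    cfg: SimConfig,
    image_index: int = 0,
):
    """One two-colour still: a single random orientation diffracting at both
    wavelengths, with a drawn strong:weak intensity ratio.

    Returns (image, GroundTruth).  Deterministic in (inputs, cfg.seed,
    image_index).
    """
    rng = _rng_for(cfg.seed, 7, image_index)
    rot = random_orientation(rng)
    orient = Orientation.from_rotation(rot, cell)

    jittered = tuple(
        c.with_wavelength(c.wavelength * (1.0 + cfg.wavelength_jitter * rng.normal()))
        for c in colours
    )

    if cfg.colour_ratio_fixed is not None:
        ratio = float(cfg.colour_ratio_fixed)
    else:
        ratio = float(np.exp(cfg.colour_ratio_sigma * rng.normal()))
    # ratio multiplies colour 0; colour 1 keeps scale 1
    scales = (ratio, 1.0)

    rows = []
    for ci, col in enumerate(jittered):
        spots = predict_spot_positions(orient, cell, col, geom,
                                       cfg.excitation_tolerance, cfg.d_min)
        for (h, k, l), f, s in spots:
            # Wilson-like (exponential) intensity statistics: many weak
            # reflections, a steep bright tail
            inten = scales[ci] * float(rng.exponential(cfg.spot_intensity_mean))
            rows.append((h, k, l, ci, f, s, inten))
    if not rows:
        raise ValueError(
            "no reflection of either colour hits the panel; check the "
            "cell/wavelength/geometry combination")
    table = pd.DataFrame(rows, columns=["h", "k", "l", "colour", "fast", "slow",
                                        "intensity"])

    image = _radial_background(geom, cfg.background_level,
                               cfg.grease_ring_radius, cfg.grease_ring_width,
                               cfg.grease_ring_amplitude)
    _paint_spots(image, table["fast"].to_numpy(), table["slow"].to_numpy(),
                 table["intensity"].to_numpy(), cfg.spot_sigma)

    if cfg.noise == "poisson":
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if cfg.saturate:
        np.clip(image, None, geom.saturation_level, out=image)

    truth = GroundTruth(
        orientation=orient, cell=cell, colours=jittered, peak_table=table,
        colour_scales=scales,
        background={"level": cfg.background_level,
                    "ring_radius": cfg.grease_ring_radius,
                    "ring_width": cfg.grease_ring_width,
                    "ring_amplitude": cfg.grease_ring_amplitude},
        seed=cfg.seed,
    )
    return image, truth


def simulate_spectrometer_trace(colours, calib, cfg: SimConfig,
                                image_index: int = 0) -> np.ndarray:
    """Inline-spectrometer readout, shape (512, 1024): 512 reads of a
    1024-pixel dispersion axis.  Each colour contributes a Lorentzian ridge
    centred at its calibrated column, amplitude proportional to its pulse
    energy; a flat baseline (plus Gaussian read noise unless noise='none')
    underlies everything."""
    rng = _rng_for(cfg.seed, 11, image_index)
    cols = np.arange(1024.0)
    profile = np.full(1024, float(cfg.spectro_baseline))
    for colour in colours:
        if colour.pulse_energy <= 0:
            continue
        centre = calib.energy_to_column(colour.photon_energy * 1000.0)
        profile = profile + (cfg.spectro_amplitude * colour.pulse_energy
                             / (1.0 + ((cols - centre) / cfg.spectro_width) ** 2))
    image = np.tile(profile, (512, 1))
    if cfg.noise != "none" and cfg.spectro_noise > 0:
        image = image + rng.normal(scale=cfg.spectro_noise, size=image.shape)
    return image


def simulate_powder_image(d_spacings, colour: BeamColour, geom: DetectorGeometry,
                          cfg: SimConfig, image_index: int = 0) -> np.ndarray:
    """Powder (Debye-Scherrer) rings at radii D tan(2 theta_i) with Gaussian
    radial profiles, on the configured flat background."""
    rng = _rng_for(cfg.seed, 13, image_index)
    image = _radial_background(geom, cfg.background_level, 0.0, 1.0, 0.0)
    cf, cs = geom.beam_center
    yy, xx = np.mgrid[0:geom.n_slow, 0:geom.n_fast]
    rr = np.hypot(xx - cf, yy - cs)
    for d in np.atleast_1d(np.asarray(d_spacings, dtype=float)):
        sin_t = colour.wavelength / (2.0 * d)
        if sin_t >= 1.0:
            continue
        two_theta = 2.0 * np.arcsin(sin_t)
        radius = geom.distance * np.tan(two_theta) / geom.pixel_size
        image += cfg.ring_amplitude * np.exp(-0.5 * ((rr - radius) / cfg.ring_width) ** 2)
    if cfg.noise == "poisson":
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    return image


def powder_ring_radius(d: float, colour: BeamColour, geom: DetectorGeometry) -> float:
    """Closed-form ring radius in pixels for one d-spacing."""
    two_theta = 2.0 * np.arcsin(colour.wavelength / (2.0 * d))
    return float(geom.distance * np.tan(two_theta) / geom.pixel_size)


# ---------------------------------------------------------------------------
# anomalous structure factors


@dataclass
class StructureFactorSet:
    """Friedel-separated structure factors for both colours.

    One row per unique reflection under the 422 rotation group (centrics
    once; acentrics represented by their Friedel-positive canonical hkl,
    with F_minus holding F(-h)).  true_phase is the phase (degrees) of the
    normal-scattering total structure factor — the phasing reference that
    stands in for a refined model.
    """

    hkl: np.ndarray  # (n, 3)
    d: np.ndarray  # (n,)
    centric: np.ndarray  # (n,) bool
    f_plus: dict  # colour label -> complex (n,)
    f_minus: dict
    true_phase: np.ndarray  # (n,) degrees
    cell: UnitCell
    space_group: str
    colours: tuple[BeamColour, BeamColour]

    def amplitudes(self, label: str):
        return np.abs(self.f_plus[label]), np.abs(self.f_minus[label])


def _partial_structure_factor(hkl, d, xyz, f, b_iso, occ, space_group):
    """F(h) = sum_sites occ * f * exp(-B s^2/4) * sum_ops exp(2 pi i h.(Rx+t)).

    f may be complex (anomalous); broadcasting over (n_hkl,) x (n_atoms,).
    """
    h = np.asarray(hkl, dtype=float)
    x = np.atleast_2d(np.asarray(xyz, dtype=float))
    f = np.broadcast_to(np.asarray(f, dtype=complex), (x.shape[0],))
    b = np.broadcast_to(np.asarray(b_iso, dtype=float), (x.shape[0],))
    occ = np.broadcast_to(np.asarray(occ, dtype=float), (x.shape[0],))
    s2 = (1.0 / np.asarray(d)) ** 2  # (n_hkl,)
    debye = np.exp(-np.outer(s2, b) / 4.0)  # (n_hkl, n_atoms)
    total = np.zeros(h.shape[0], dtype=complex)
    for r, t in symmetry.operators(space_group):
        hr = h @ r  # (n_hkl, 3)
        phase = np.exp(2j * np.pi * (hr @ x.T + (h @ t)[:, None]))
        total += (phase * debye) @ (occ * f)
    return total


def simulate_structure_factors(
    cell: UnitCell,
    sites,
    scatterer: AnomalousScatterer,
    protein_model: PseudoAtomProtein,
    colours,
    d_min: float,
    space_group: str = "P43212",
) -> StructureFactorSet:
    """Error-free anomalous structure factors for both colours.

    F+/F- are computed independently at +h and -h; with f'' = 0 they obey
    Friedel's law exactly, and centric reflections have zero anomalous
    difference regardless of f''.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    uniq = symmetry.unique_reflections(cell, d_min, space_group)
    if len(uniq) == 0:
        raise ValueError("empty reflection set at this d_min")
    # keep one representative per Friedel pair
    mates = symmetry.canonical_hkl(-uniq, space_group)
    keep = [tuple(h) >= tuple(m) for h, m in zip(uniq, mates)]
    hkl = uniq[np.array(keep)]
    d = cell.d_spacing(hkl)
    cen = symmetry.is_centric(hkl, space_group)

    site_xyz = np.array([s.xyz for s in sites]) if len(sites) else np.empty((0, 3))
    site_b = np.array([s.b_iso for s in sites])
    site_occ = np.array([s.occupancy for s in sites])
    if len(sites) and np.any((site_xyz < 0) | (site_xyz >= 1)):
        raise ValueError("heavy sites must be reduced to [0, 1)")

    f_plus, f_minus = {}, {}
    f_prot_plus = _partial_structure_factor(
        hkl, d, protein_model.xyz, protein_model.f0, protein_model.b_iso, 1.0,
        space_group)
    f_prot_minus = _partial_structure_factor(
        -hkl, d, protein_model.xyz, protein_model.f0, protein_model.b_iso, 1.0,
        space_group)
    if len(sites):
        heavy_normal = _partial_structure_factor(
            hkl, d, site_xyz, scatterer.f0, site_b, site_occ, space_group)
    else:
        heavy_normal = np.zeros(len(hkl), dtype=complex)
    true_phase = np.degrees(np.angle(f_prot_plus + heavy_normal))

    for colour in colours:
        fp, fpp = scatterer.for_colour(colour)
        f_heavy = scatterer.f0 + fp + 1j * fpp
        if len(sites):
            hp = _partial_structure_factor(hkl, d, site_xyz, f_heavy, site_b,
                                           site_occ, space_group)
            hm = _partial_structure_factor(-hkl, d, site_xyz, f_heavy, site_b,
                                           site_occ, space_group)
        else:
            hp = hm = np.zeros(len(hkl), dtype=complex)
        f_plus[colour.label] = f_prot_plus + hp
        f_minus[colour.label] = f_prot_minus + hm

    return StructureFactorSet(
        hkl=hkl, d=d, centric=np.asarray(cen), f_plus=f_plus, f_minus=f_minus,
        true_phase=true_phase, cell=cell, space_group=space_group,
        colours=tuple(colours),
    )


def heavy_partial_structure_factors(hkl, d, sites, scatterer,
                                    colour: BeamColour, space_group: str,
                                    include_f0: bool = True):
    """Complex heavy-atom partial structure factors at +h and -h for one
    colour.

    With include_f0=False only the anomalous corrections (f' + i f'')
    contribute — the partial structure the phase-probability engine needs,
    where the unknown is the total *normal* structure factor (protein plus
    heavy f0) whose phase matches a refined model's.
    """
    fp, fpp = scatterer.for_colour(colour)
    f = (scatterer.f0 if include_f0 else 0.0) + fp + 1j * fpp
    xyz = np.array([s.xyz for s in sites])
    b = np.array([s.b_iso for s in sites])
    occ = np.array([s.occupancy for s in sites])
    plus = _partial_structure_factor(hkl, d, xyz, f, b, occ, space_group)
    minus = _partial_structure_factor(-np.asarray(hkl), d, xyz, f, b, occ, space_group)
    return plus, minus
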
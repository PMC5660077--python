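# Methods

`sfx2c` processes two-colour serial femtosecond crystallography (SFX)
still images: snapshots from microcrystals exposed to two simultaneous
XFEL pulses of different photon energy (nominally 7.0 and 9.0 keV,
λ = hc/E with hc = 12.3984 keV·Å, so 1.771 Å and 1.378 Å). Every
simulator, processing step and statistic operates on synthetic data with
known ground truth; this note records the models, the parameter choices
and what they do and do not establish.

## Geometry model

A single flat detector panel, beam along +z, fast coordinate = image
column, slow = row, 0-based pixels with centres on integer coordinates,
no panel tilts. Reciprocal vectors are crystallographic (Å⁻¹, no 2π).
A reflection with reciprocal vector **g** (= R·B·**h** for orientation R
and cell matrix B) diffracts when **g** lies within an excitation
tolerance of the Ewald sphere; the spot is the flat-panel projection of
the ray from the sphere centre through **g**. The excitation tolerance
(default 0.002 Å⁻¹) lumps crystal mosaicity, beam bandwidth and
divergence into one reciprocal-space acceptance width — still images
need *some* acceptance width and no partiality model is attempted.

Two detector samplings are used. `default_geometry()` is MPCCD-like:
2048×2048 pixels of 0.05 mm at 50 mm, placing the panel edge near 1.8 Å
and the corner near 1.5 Å at 9 keV (and 2.3/1.9 Å at 7 keV by Bragg
rescaling d′ = d·λ′/λ). `desk_geometry()` (768×768 pixels of 0.2 mm at
200 mm) keeps the dimensionless ratio that matters for processing — the
Bragg spot spacing D·λ/(a·pixel) ≈ 17.6 px at 9 keV for the 78.3 Å
cell — while costing an order of magnitude less per image; all
pixel-denominated parameters (10 px subtraction radius, 16 px median
window, 4 px match radius) therefore keep their meaning. Ensemble
studies (50-image cell recovery, 20-image disentangling regression) use
the desk geometry; powder-ring distance refinement uses the full-size
geometry, where the three strongest silicon rings (diamond cubic,
a = 5.431 Å) fall on the panel.

## Synthetic data

One random orientation per image diffracts at both wavelengths.
Stochastic elements, all driven by a single seed through independent
substreams per image index:

* **Colour imbalance.** The strong:weak intensity ratio of the two
  patterns is log-normal, median 1, σ(log) = 1 — split-undulator pulse
  energies drift shot to shot, and a typical image shows a clearly
  stronger and weaker pattern. A fixed ratio can be pinned for
  controlled studies.
* **Spot intensities.** Exponential (Wilson-like) draws: many weak
  reflections, a steep bright tail. Mean integrated intensity 10 000 ADU
  by default; the disentangling study (below) uses 650 ADU.
* **Wavelength jitter.** Fractional σ = 2×10⁻³ per colour per shot —
  the per-shot spectral drift that motivates inline-spectrometer
  calibration.
* **Background.** Flat 20 ADU plus a Gaussian "grease ring" (radius
  150 px, width 20 px, amplitude 30 ADU) emulating the diffuse scatter
  of the high-viscosity carrier medium; optional Poisson noise; optional
  hard clip at the panel saturation level.

Spots are 2D Gaussians (σ = 1 px) truncated at 4σ. The ground-truth
record stores the orientation, jittered wavelengths, drawn ratio, and
every injected spot (hkl, colour, position, intensity).

Anomalous structure factors are computed as
F±(**h**) = F_prot + Σ_sites occ·(f₀ + f′ + i f″)·exp(−B·s²/4)·Σ_ops e^{2πi h·(Rx+t)},
with Friedel mates evaluated independently at ±**h**; Friedel's law is
exact when f″ = 0, and centric reflections have zero anomalous
difference by construction. The "protein" is 300 random carbon-like
pseudo-atoms (flat f₀ = 6, B = 15 Ų, fixed seed) — it supplies a
realistic phase background and Wilson-like amplitude statistics but no
biological structure, so nothing downstream may rely on map
interpretability. The heavy model is two independent gadolinium sites
per asymmetric unit at fixed general-position coordinates chosen so the
two sites' full equivalence classes (symmetry × allowed origin shifts ×
inversion) stay > 6 Å apart; f′/f″ are −4.0/11.7 e⁻ at 9 keV and
−10.0/3.8 e⁻ at 7 keV (below/above the Gd L edges). Space-group
machinery (P1 and P4₃2₁2 only) uses explicit operator lists;
reflection-level conventions (canonical hkl under the 422 rotations,
Friedel mates kept separate, centricity, the 0 0 l ≡ 4n and h 0 0 ≡ 2n
absences) are cross-checked against an independent crystallographic
library in the test suite.

## Peak finding

Background is a moving-window median (window 16 px, covering
[i−8, i+7] per axis; truncated at panel edges; the median of an even
pixel count is the upper order statistic — the same convention as the
brute-force oracle the tests compare against). Thresholding operates on
the background-corrected image; the working threshold is the median over
images of μ + 4σ, with plain sample mean and standard deviation — the
rule is applied exactly as stated even though the heavy-tailed (Cauchy)
reading of the pixel distribution, under which μ + 4σ sits at the
½ + atan(4)/π ≈ 0.922 quantile, is exposed separately as an interpretive
check with robust surrogates (median, half-IQR).

Connected components (8-connectivity) above threshold become peaks when
the bounding box fits in 10 px, the squared-gradient criterion passes,
and the annulus signal-to-noise (local background annulus of radius 2×
the component extent; σ from the annulus spread) reaches the cut.
`min_gradient` = 10 000 is interpreted as a minimum **squared** central-
difference gradient magnitude (ADU²/px²), i.e. |∇I| ≥ 100 ADU/px at the
spot's steepest pixel, matching the convention of the established
peak-search tools whose parameter value this is; reading it as an
unsquared gradient would reject essentially every realistic spot.
First-pass parameters: threshold 700 ADU, snr 5; second pass (weak
colour): threshold 150 ADU, snr 3; gradient and window unchanged. A hit
is an image with ≥ 15 peaks.

## Known-cell indexing and two-colour disentangling

Each peak maps to a scattering vector on the Ewald sphere of the colour
under test. Candidate orientations come from pairs of low-resolution
peaks whose |q| match reference lattice-vector lengths (tolerance
0.004 Å⁻¹) and whose mutual angle matches within 2.5°; each consistent
assignment yields a rotation (two-vector Kabsch), scored by how many
peaks sit within 0.003 Å⁻¹ of a reciprocal lattice node. The best
candidates are refined by least squares over orientation plus the free
cell lengths (tetragonal: a and c), bounded by the loose cell restraints
(10% lengths, 2% angles). A solution is accepted when ≥ 40% of the peak
list lies within the 4 px match radius of a predicted spot and at least
the quorum (10 peaks) is matched. The 40% acceptance fraction is
deliberate: a two-colour image's peak list is a *mixture*, and a
balanced image gives each colour only ~half the list, so a
single-pattern majority requirement could never accept either colour;
40% accepts genuine patterns (accidental matches contribute only a few
per cent) while rejecting wrong cells and wrong wavelengths.

The pipeline indexes the dominant pattern first — both wavelengths are
attempted on the first-pass peak list and the higher-scoring solution
kept, since per-shot dominance is not known a priori — then removes
every second-pass peak within 10 px of the first pattern's predicted or
observed spots, and indexes the remainder at the other wavelength with
the lowered parameters.

The disentangling study (`SimConfig.disentangling_study`) fixes the
ratio at 10:1 with Poisson noise and mean spot intensity 650 ADU, which
places the weak pattern at the detection threshold: the first pass sees
almost only strong spots, the lowered second pass sees both, and the
weak pattern occupies well under 40% of the un-subtracted list — the
regime in which the subtraction step alone decides whether the weak
colour indexes. With comfortably brighter weak patterns the subtraction
is unnecessary and the regression would be vacuous.

## Spectrometer and distance calibration

Spectrometer readouts are 512 reads × 1024 dispersion columns; each
colour is a Lorentzian ridge. The collapsed profile is fitted with
baseline + two Lorentzians, starting values from the two highest
well-separated local maxima and half-maximum widths. "Double
Lorentzian" is read as the sum of two one-colour Lorentzian peaks; the
profile function is isolated in one seam should a squared-Lorentzian
line shape be preferred. Energy calibration is the two-point line
through the reference-run centres at 7000 and 9000 eV (a higher-order
fit can be substituted but the cross-calibration's functional form is
not specified further). Per-shot assignment maps both fitted centres to
energies and orders the pair low/high, invariant under component order
and dispersion sign.

Powder rings: azimuthally averaged radial profile, local maxima above a
robust prominence threshold (5 × MAD-σ), radii refined by local
intensity-weighted centroid. Distance minimises Σᵢ (rᵢ − D·tan 2θᵢ)² —
linear in D, closed form; with one ring it reduces to D = r/tan 2θ. An
rms ring residual above 1 px flags an inconsistent assignment (e.g. the
wrong colour's wavelength).

## Integration and merging statistics

Fixed-radius integration at every predicted spot with radii (6, 6, 8):
I = Σ(disc r ≤ 6) − n_disc · median(annulus 6 < r ≤ 8), σ² = n·var_bg·
(1 + n/n_bg) + max(I, 0). Merging is the unweighted Monte-Carlo mean
per canonical hkl and colour, σ_mean = sd/√n, Friedel mates separate,
negative means retained. Half datasets split by even/odd acquisition
index give R_split (with the 1/√2 factor), CC_1/2 and CCano (Pearson on
unweighted I⁺−I⁻ of common acentric pairs). Completeness counts
observed unique reflections against the enumerated possible set
(absences excluded, mates separate). Shell tables use 10 equal-volume
shells by default.

## Substructure search and phase probabilities

The anomalous-difference Patterson uses sharpened coefficients
(ΔF²/⟨ΔF²⟩_shell − 1): shell normalisation flattens the resolution
falloff and removing the mean kills the origin peak, whose shoulders
otherwise make candidates with near-origin self-vectors score
spuriously. Candidate sites on a grid (0.8 Å default) are scored by a
symmetry **minimum function**: the smallest Patterson value over all
self-vectors between the candidate's symmetry mates. Candidates within
2 Å of a special position are excluded (their vector set degenerates);
sites on special positions are therefore not findable — a documented
limitation, irrelevant to the general-position study substructure.
Every site after the first must *additionally* sit on positive Patterson
density at all cross-vectors to the already-accepted sites, a much
stricter criterion that also fixes the relative hand and origin of the
configuration. Grid scores are re-ranked by a half-step neighbourhood
maximum (the minimum function is sharper than the grid), refined by
Nelder–Mead on the interpolated score, and accepted while the combined
score reaches 25% of the first site's. Reported occupancies are
relative, √(Harker-score ratio), since peak heights scale with
occupancy². The absolute hand and the choice among the four allowed
origin shifts ((0,0,0), (0,0,½), (½,½,0), (½,½,½)) remain undetermined,
as for any difference-Patterson method.

Phase probabilities follow Blow & Crick on a 1° grid. For a trial
protein phase φ the lack of closure is the geometric misfit of the two
Friedel observations: ε²(φ) = min_t Σ_mates (|t·e^{iφ} − c| − r)², with
c = −F_H(±h) the heavy-atom partial structure factors computed from
f′ + i f″ only — the unknown is then the total *normal* structure
factor, whose phase is directly comparable to a refined model's. The t
minimisation uses a 48-node grid (10% margin beyond max |c| + r, where
the optimum can sit) with parabolic refinement, and ε² is refined to its
per-bin parabolic minimum over φ so that a sharp zero between bins is
not missed. σ_E is estimated per resolution shell from the ε² minima
with a small floor (10⁻⁴ of the amplitude scale); P(φ) ∝
exp(−ε²/2σ_E²), normalised. Centric reflections are collapsed onto
their two allowed phases. SAD distributions are intrinsically bimodal
(two circle intersections; one mode at the true phase for error-free
data, coalescing only when the circles meet tangentially); MAD
multiplies the per-colour likelihoods, and the mode shared by both
colours survives. FOM is the modulus of the circular mean; the best
phase is its direction.

The end-to-end SAD-vs-MAD comparison draws per-image intensity
observations with 20% multiplicative noise, merges 100 of them
(≈ 2% noise on merged intensities — a plausible Monte-Carlo merging
precision at modest multiplicity), finds the substructure from the
merged 9 keV differences, phases all acentric reflections by SAD
(9 keV) and two-colour MAD, and evaluates both substructure hands with
analytic origin alignment, keeping the better per method — the
synthetic counterpart of the hand screening every experimental phasing
run performs. At these settings initial phase errors are ~60–70° with
MAD consistently more accurate than SAD by both median FOM and mean
phase error; the absolute values are typical of *initial* experimental
phases before density modification, which this package deliberately
does not attempt. The discrimination between the SAD modes is a
second-order effect on large |F|, so the margin, not its size, is the
tested claim.

## What the synthetic studies do not show

The generators reproduce the statistical structure of the experiment —
mixture peak lists, intensity imbalance, wavelength jitter, Wilson-like
intensities, grease background — but not detector PSF, per-pixel gain,
multi-panel geometry, partiality, absolute Thomson scales, or real
macromolecular structure. Passing tests establish the correctness and
self-consistency of the algorithms under these conditions, not their
performance on deposited experimental data, whose headline numbers
(dataset-scale indexing rates, table statistics, absolute FOMs) depend
on 2×10⁵-image statistics and external phasing software.

## Determinism and problem sizes

Every stochastic step derives from one integer seed (per-image
substreams via seed sequences); identical seeds give byte-identical
simulated containers. Default study sizes — 50 images for cell
recovery, 20 for the disentangling regression, 20 seeded replicates for
the phasing comparison, structure factors to 2.5–3 Å — are the
package's chosen desk-scale conditions; all are single-CPU and
re-runnable in minutes.
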
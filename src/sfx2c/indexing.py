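"""Known-cell indexing of still images and two-colour disentangling.

The indexer maps every observed peak onto the Ewald sphere for the colour
being tested, proposes crystal orientations from pairs of low-resolution
peaks whose scattering-vector lengths and mutual angle match reference
lattice vectors of the known cell, scores each proposal by how many peaks
fall near a reciprocal lattice point, and refines orientation plus cell
lengths by least squares under the cell restraints.  A solution is accepted
when a sufficient fraction of the peak list lies within the match radius of
a predicted spot.

The two-colour procedure indexes the dominant pattern first, removes every
peak within the subtraction radius of that pattern's spot positions, and
indexes the remainder at the other wavelength with lowered peak-search
parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import (
    BeamColour,
    DetectorGeometry,
    Orientation,
    UnitCell,
    pixel_to_scattering_vector,
    predict_spot_positions,
)
from .peaks import PeakList, PeakSearchParams, find_peaks


@dataclass(frozen=True)
class CellRestraints:
    """Loose cell imposition: maximum fractional deviation of lengths and
    angles of a refined cell from the reference."""

    max_length_deviation: float = 0.10
    max_angle_deviation: float = 0.02


@dataclass
class IndexingSolution:
    orientation: Orientation
    cell: UnitCell  # refined
    colour: BeamColour
    n_peaks_indexed: int
    n_peaks_total: int
    rms_residual_px: float
    matched_hkl: np.ndarray  # (n_indexed, 3)
    matched_peak_index: np.ndarray  # indices into the input peak list
    predicted: list  # [(hkl, fast, slow)] all predicted spots on the panel

    @property
    def match_fraction(self) -> float:
        return self.n_peaks_indexed / max(self.n_peaks_total, 1)

    @property
    def predicted_positions(self) -> np.ndarray:
        if not self.predicted:
            return np.empty((0, 2))
        return np.array([[f, s] for _, f, s in self.predicted])


def _reference_lattice(cell: UnitCell, q_max: float):
    """Reciprocal lattice vectors of the unrotated cell with |g| <= q_max."""
    b = cell.b_matrix()
    hmax = int(np.ceil(q_max / np.min(np.linalg.norm(b, axis=0)))) + 1
    rng = np.arange(-hmax, hmax + 1)
    hh, kk, ll = np.meshgrid(rng, rng, rng, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g = hkl @ b.T
    glen = np.linalg.norm(g, axis=1)
    keep = glen <= q_max
    return hkl[keep], g[keep], glen[keep]


def _refined_cell_params(cell: UnitCell):
    """Free length parameters by lattice type (angles stay fixed at 90 for
    orthogonal lattices; non-orthogonal cells are not refined)."""
    if cell.lattice_type == "tetragonal":
        return ["a", "c"]
    if all(abs(getattr(cell, n) - 90.0) < 1e-6 for n in ("alpha", "beta", "gamma")):
        return ["a", "b", "c"]
    return []


def _build_cell(cell: UnitCell, names, values) -> UnitCell:
    kw = dict(a=cell.a, b=cell.b, c=cell.c, alpha=cell.alpha, beta=cell.beta,
              gamma=cell.gamma, lattice_type=cell.lattice_type,
              centering=cell.centering, space_group=cell.space_group)
    for n, v in zip(names, values):
        kw[n] = v
        if cell.lattice_type == "tetragonal" and n == "a":
            kw["b"] = v
    return UnitCell(**kw)


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(v)
    if theta < 1e-15:
        return np.eye(3)
    k = v / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx


def index_known_cell(
    peaks: PeakList,
    cell: UnitCell,
    colour: BeamColour,
    geom: DetectorGeometry,
    restraints: CellRestraints = CellRestraints(),
    quorum: int = 10,
    match_radius: float = 4.0,
    accept_fraction: float = 0.4,
    q_tol: float = 0.003,
    length_tol: float = 0.004,
    angle_tol_deg: float = 2.5,
    n_seed_peaks: int = 14,
    max_candidate_rotations: int = 12,
) -> IndexingSolution | None:
    """Orientation search for one colour against a known cell.

    Returns None when fewer than `quorum` peaks are supplied or when no
    orientation explains at least `accept_fraction` of the peaks within
    `match_radius` pixels.
    """
    if len(peaks) < quorum:
        return None
    pos = peaks.positions
    q_obs = pixel_to_scattering_vector(geom, colour.wavelength, pos[:, 0], pos[:, 1])
    q_len = np.linalg.norm(q_obs, axis=1)
    usable = q_len > 1e-6
    q_obs, q_len, peak_idx = q_obs[usable], q_len[usable], np.nonzero(usable)[0]
    if len(q_obs) < quorum:
        return None

    hkl_ref, g_ref, g_len = _reference_lattice(cell, float(q_len.max()) * 1.05)

    # ---- seed pairs from low-resolution peaks (few length-candidates there)
    order = np.argsort(q_len)
    seeds = order[: min(n_seed_peaks, len(order))]
    cand = {
        int(i): np.nonzero(np.abs(g_len - q_len[i]) < length_tol)[0]
        for i in seeds
    }
    g_i, g_j, q_i, q_j = [], [], [], []
    for i, j in itertools.combinations(list(seeds), 2):
        qi, qj = q_obs[i], q_obs[j]
        cos_obs = float(qi @ qj / (q_len[i] * q_len[j]))
        ang_obs = np.degrees(np.arccos(np.clip(cos_obs, -1, 1)))
        if ang_obs < 15.0 or ang_obs > 165.0:
            continue
        ci, cj = cand[int(i)], cand[int(j)]
        if len(ci) == 0 or len(cj) == 0:
            continue
        gi, gj = g_ref[ci], g_ref[cj]
        cosm = (gi @ gj.T) / np.outer(g_len[ci], g_len[cj])
        angm = np.degrees(np.arccos(np.clip(cosm, -1, 1)))
        hits = np.argwhere(np.abs(angm - ang_obs) < angle_tol_deg)
        if len(hits):
            g_i.append(gi[hits[:, 0]])
            g_j.append(gj[hits[:, 1]])
            q_i.append(np.broadcast_to(qi, (len(hits), 3)))
            q_j.append(np.broadcast_to(qj, (len(hits), 3)))
    if not g_i:
        return None
    g_i, g_j = np.concatenate(g_i), np.concatenate(g_j)
    q_i, q_j = np.concatenate(q_i), np.concatenate(q_j)
    if len(g_i) > 6000:  # cap the candidate count; keep a deterministic subset
        step = len(g_i) // 6000 + 1
        g_i, g_j, q_i, q_j = g_i[::step], g_j[::step], q_i[::step], q_j[::step]
    # batched Kabsch: C = qi (x) gi + qj (x) gj, R = U diag(1,1,det) V^T
    c = q_i[:, :, None] * g_i[:, None, :] + q_j[:, :, None] * g_j[:, None, :]
    u, _, vt = np.linalg.svd(c)
    det = np.linalg.det(u @ vt)
    u[:, :, 2] *= det[:, None]
    rot_stack = u @ vt

    # ---- score candidates: peaks whose q sits within q_tol of a lattice node
    b_mat = cell.b_matrix()
    b_inv = np.linalg.inv(b_mat)
    # h_est = round(B^-1 R^T q); residual = |R B h_est - q|
    rtq = np.einsum("kij,ni->knj", rot_stack, q_obs)  # (k, n, 3): R^T q
    h_est = np.rint(np.einsum("ij,knj->kni", b_inv.T, rtq))
    g_pred = np.einsum("ij,knj->kni", b_mat.T, h_est)  # B h in crystal frame
    resid = np.linalg.norm(g_pred - rtq, axis=2)
    scores = (resid < q_tol).sum(axis=1)
    best_order = np.argsort(scores)[::-1][:max_candidate_rotations]

    best_solution = None
    names = _refined_cell_params(cell)
    lo = [getattr(cell, n) * (1 - restraints.max_length_deviation) for n in names]
    hi = [getattr(cell, n) * (1 + restraints.max_length_deviation) for n in names]

    for k in best_order:
        if scores[k] < max(3, quorum // 2):
            continue
        r0 = rot_stack[k]
        assigned = resid[k] < q_tol
        hkl_a = h_est[k][assigned]
        q_a = q_obs[assigned]

        def residuals(p, hkl_a=hkl_a, q_a=q_a, r0=r0):
            r = _rotvec_matrix(p[:3]) @ r0
            c = _build_cell(cell, names, p[3:])
            m = r @ c.b_matrix()
            return (hkl_a @ m.T - q_a).ravel()

        p0 = np.concatenate([np.zeros(3), [getattr(cell, n) for n in names]])
        bounds = (np.concatenate([[-0.2] * 3, lo]),
                  np.concatenate([[0.2] * 3, hi]))
        try:
            fit = least_squares(residuals, p0, bounds=bounds, xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        r_fit = _rotvec_matrix(fit.x[:3]) @ r0
        cell_fit = _build_cell(cell, names, fit.x[3:])

        # reassign with the refined model and refine once more
        m = r_fit @ cell_fit.b_matrix()
        h2 = np.rint(q_obs @ np.linalg.inv(m).T)
        res2 = np.linalg.norm(h2 @ m.T - q_obs, axis=1)
        assigned = res2 < q_tol
        if assigned.sum() < max(3, quorum // 2):
            continue
        hkl_a, q_a = h2[assigned], q_obs[assigned]

        def residuals2(p, hkl_a=hkl_a, q_a=q_a, r_fit=r_fit):
            r = _rotvec_matrix(p[:3]) @ r_fit
            c = _build_cell(cell, names, p[3:])
            return (hkl_a @ (r @ c.b_matrix()).T - q_a).ravel()

        p0 = np.concatenate([np.zeros(3), [getattr(cell_fit, n) for n in names]])
        fit = least_squares(residuals2, p0, bounds=bounds, xtol=1e-12, ftol=1e-12)
        r_fit = _rotvec_matrix(fit.x[:3]) @ r_fit
        cell_fit = _build_cell(cell, names, fit.x[3:])
        orient = Orientation.from_rotation(r_fit, cell_fit)

        # ---- final detector-space acceptance
        d_min_panel = 1.0 / (float(q_len.max()) * 1.02)
        predicted = predict_spot_positions(orient, cell_fit, colour, geom,
                                           excitation_tolerance=0.0025,
                                           d_min=d_min_panel)
        if not predicted:
            continue
        pred_pos = np.array([[f, s] for _, f, s in predicted])
        d2 = np.sum((pos[peak_idx][:, None, :] - pred_pos[None, :, :]) ** 2, axis=2)
        nearest = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(len(peak_idx)), nearest])
        matched = dist < match_radius
        n_matched = int(matched.sum())
        if n_matched / len(peaks) < accept_fraction or n_matched < quorum:
            continue
        rms = float(np.sqrt(np.mean(dist[matched] ** 2)))
        sol = IndexingSolution(
            orientation=orient, cell=cell_fit, colour=colour,
            n_peaks_indexed=n_matched, n_peaks_total=len(peaks),
            rms_residual_px=rms,
            matched_hkl=np.array([predicted[n][0] for n in nearest[matched]]),
            matched_peak_index=peak_idx[matched],
            predicted=predicted,
        )
        if best_solution is None or sol.n_peaks_indexed > best_solution.n_peaks_indexed:
            best_solution = sol
    return best_solution


def subtract_indexed_peaks(peaks: PeakList, indexed_positions,
                           radius: float = 10.0) -> PeakList:
    """Drop every peak strictly closer than `radius` pixels to any indexed
    spot position.  Order is preserved; with no positions, or radius 0,
    this is the identity."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    ipos = np.atleast_2d(np.asarray(indexed_positions, dtype=float))
    if ipos.size == 0 or len(peaks) == 0:
        return PeakList(list(peaks))
    pos = peaks.positions
    d2 = np.sum((pos[:, None, :] - ipos[None, :, :]) ** 2, axis=2)
    keep = np.min(d2, axis=1) >= radius * radius
    return PeakList([p for p, k in zip(peaks, keep) if k])


def _first_colour_positions(solution: IndexingSolution, peaks: PeakList) -> np.ndarray:
    """Spot positions attributed to the first colour: its predictions plus
    the observed peaks it indexed."""
    parts = [solution.predicted_positions]
    if len(solution.matched_peak_index):
        parts.append(peaks.positions[solution.matched_peak_index])
    return np.vstack([p for p in parts if p.size])


def index_second_colour(
    image,
    first: IndexingSolution,
    cell: UnitCell,
    second_colour: BeamColour,
    geom: DetectorGeometry,
    second_pass: PeakSearchParams | None = None,
    subtract_radius: float = 10.0,
    first_pass_peaks: PeakList | None = None,
    **index_kwargs,
) -> IndexingSolution | None:
    """Second-colour indexing: re-search peaks with lowered parameters,
    remove everything near the first pattern, index the remainder."""
    params = second_pass or PeakSearchParams.second_pass()
    peaks2 = find_peaks(image, params)
    if first_pass_peaks is not None:
        remove = _first_colour_positions(first, first_pass_peaks)
    else:
        # matched_peak_index refers to the list `first` was indexed from;
        # without it only the predicted positions are available
        remove = first.predicted_positions
    survivors = subtract_indexed_peaks(peaks2, remove, subtract_radius)
    return index_known_cell(survivors, cell, second_colour, geom, **index_kwargs)


def two_colour_pipeline(
    image,
    cell: UnitCell,
    colours,
    geom: DetectorGeometry,
    params1: PeakSearchParams | None = None,
    params2: PeakSearchParams | None = None,
    subtract_radius: float = 10.0,
    **index_kwargs,
):
    """Full two-colour chain on one image.

    1. strong-parameter peak search;
    2. known-cell indexing attempted at both wavelengths, keeping the
       higher-scoring solution (per-shot colour dominance is not known
       a priori);
    3. peaks near the first pattern removed; the other wavelength indexed
       on the remainder found with lowered parameters.

    Returns (solution_colour0, solution_colour1, report) with solutions
    ordered like `colours`.
    """
    p1 = params1 or PeakSearchParams()
    peaks1 = find_peaks(image, p1)
    report = {"n_peaks_pass1": len(peaks1)}

    first_sols = [
        index_known_cell(peaks1, cell, c, geom, **index_kwargs) for c in colours
    ]
    scores = [s.n_peaks_indexed if s else -1 for s in first_sols]
    if max(scores) < 0:
        report.update(first_colour=None, indexed=(False, False), category="none")
        return None, None, report
    first_i = int(np.argmax(scores))
    first = first_sols[first_i]
    second_i = 1 - first_i

    second = index_second_colour(
        image, first, cell, colours[second_i], geom,
        second_pass=params2, subtract_radius=subtract_radius,
        first_pass_peaks=peaks1, **index_kwargs,
    )
    out = [None, None]
    out[first_i] = first
    out[second_i] = second
    flags = tuple(s is not None for s in out)
    category = {
        (True, True): "both",
        (True, False): colours[0].label,
        (False, True): colours[1].label,
        (False, False): "none",
    }[flags]
    report.update(
        first_colour=colours[first_i].label,
        indexed=flags,
        category=category,
        n_indexed_first=first.n_peaks_indexed,
        n_indexed_second=second.n_peaks_indexed if second else 0,
    )
    return out[0], out[1], report
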
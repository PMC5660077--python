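"""Space-group machinery for P1 and P43212 via explicit operator lists.

Operators are pairs (R, t): x' = R @ x + t on fractional coordinates.
Reflection symmetry uses the row convention h' = h @ R (so that
F(h @ R) = F(h) * exp(-2*pi*i h.t)).  Friedel mates are *not* merged:
the canonical key of h and of -h differ for acentric reflections.
"""

from __future__ import annotations

import itertools

import numpy as np

_I = np.eye(3, dtype=int)


def _op(triplet: str):
    """Parse an xyz triplet like '-y+1/2,x+1/2,z+3/4' into (R, t)."""
    rows, trans = [], []
    for part in triplet.split(","):
        part = part.replace(" ", "")
        row = [0, 0, 0]
        t = 0.0
        i = 0
        sign = 1
        while i < len(part):
            ch = part[i]
            if ch == "+":
                sign = 1
                i += 1
            elif ch == "-":
                sign = -1
                i += 1
            elif ch in "xyz":
                row["xyz".index(ch)] = sign
                sign = 1
                i += 1
            else:  # fraction n/m
                j = i
                while j < len(part) and part[j] not in "+-":
                    j += 1
                num, _, den = part[i:j].partition("/")
                t += sign * float(num) / (float(den) if den else 1.0)
                sign = 1
                i = j
        rows.append(row)
        trans.append(t % 1.0)
    return np.array(rows, dtype=int), np.array(trans, dtype=float)


_P43212_TRIPLETS = [
    "x,y,z",
    "-y+1/2,x+1/2,z+3/4",
    "-x,-y,z+1/2",
    "y+1/2,-x+1/2,z+1/4",
    "x+1/2,-y+1/2,-z+1/4",
    "-y,-x,-z+1/2",
    "-x+1/2,y+1/2,-z+3/4",
    "y,x,-z",
]

_GROUPS = {
    "P1": [( _I.copy(), np.zeros(3) )],
    "P43212": [_op(t) for t in _P43212_TRIPLETS],
}

_ALIASES = {
    "p1": "P1",
    "p 1": "P1",
    "p43212": "P43212",
    "p 43 21 2": "P43212",
    "p4(3)2(1)2": "P43212",
    "p 4 3 2 1 2": "P43212",
}


def normalise_space_group(name: str) -> str:
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValueError(f"unsupported space group {name!r} (supported: P1, P43212)")


def operators(space_group: str):
    """List of (R, t) pairs for the space group."""
    return _GROUPS[normalise_space_group(space_group)]


def rotations(space_group: str) -> np.ndarray:
    """Stack of rotation parts, shape (n_ops, 3, 3)."""
    return np.stack([r for r, _ in operators(space_group)])


def hkl_orbit(hkl, space_group: str) -> np.ndarray:
    """All point-group images h @ R of one reflection (may repeat)."""
    h = np.asarray(hkl, dtype=int)
    return np.einsum("j,njk->nk", h, rotations(space_group))


def canonical_hkl(hkl, space_group: str):
    """Canonical representative of the rotation orbit of h.

    Friedel mates are kept separate (only proper/improper ops of the group
    itself are applied, never -h explicitly). The representative is the
    lexicographically greatest (h, k, l) tuple in the orbit.

    Accepts a single hkl or an (n, 3) array; vectorised in the latter case.
    """
    h = np.asarray(hkl, dtype=int)
    single = h.ndim == 1
    h = np.atleast_2d(h)
    rots = rotations(space_group)
    orbit = np.einsum("mj,njk->mnk", h, rots)  # (m, n_ops, 3)
    # lexicographic argmax over the orbit axis
    key = (orbit[..., 0] * 4_000_000_000_000 + orbit[..., 1] * 2_000_000 + orbit[..., 2])
    best = np.argmax(key, axis=1)
    out = orbit[np.arange(len(h)), best]
    if single:
        return tuple(int(v) for v in out[0])
    return out


def is_centric(hkl, space_group: str):
    """True where -h belongs to the rotation orbit of h."""
    h = np.atleast_2d(np.asarray(hkl, dtype=int))
    rots = rotations(space_group)
    orbit = np.einsum("mj,njk->mnk", h, rots)
    cen = np.any(np.all(orbit == -h[:, None, :], axis=2), axis=1)
    return bool(cen[0]) if np.asarray(hkl).ndim == 1 else cen


def centric_phase(hkl, space_group: str) -> float:
    """Allowed phase (degrees, in [0, 180)) of a centric reflection; the
    other allowed value is this + 180."""
    h = np.asarray(hkl, dtype=int)
    for r, t in operators(space_group):
        if np.all(h @ r == -h):
            # F(h) = conj(F(h)) exp(+2 pi i h.t)  =>  phi = pi * h.t  (mod pi)
            return (180.0 * float(h @ t)) % 180.0
    raise ValueError(f"{tuple(h)} is not centric in {space_group}")


def is_absent(hkl, space_group: str):
    """Systematic absence test. For P43212: (0,0,l) absent unless l = 4n;
    (h,0,0)/(0,k,0) absent unless the index is even."""
    sg = normalise_space_group(space_group)
    h = np.atleast_2d(np.asarray(hkl, dtype=int))
    if sg == "P1":
        out = np.zeros(len(h), dtype=bool)
    else:
        hh, kk, ll = h[:, 0], h[:, 1], h[:, 2]
        on_l = (hh == 0) & (kk == 0)
        on_h = (kk == 0) & (ll == 0)
        on_k = (hh == 0) & (ll == 0)
        out = (on_l & (ll % 4 != 0)) | (on_h & (hh % 2 != 0)) | (on_k & (kk % 2 != 0))
    return bool(out[0]) if np.asarray(hkl).ndim == 1 else out


def unique_reflections(cell, d_min: float, space_group: str) -> np.ndarray:
    """All distinct canonical reflections with d >= d_min, systematic
    absences excluded, Friedel mates counted separately.

    Returns an (n, 3) int array of canonical hkl.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    b = cell.b_matrix()
    hmax = int(np.ceil(1.0 / (d_min * np.min(np.linalg.norm(b, axis=0)))))
    rng = np.arange(-hmax, hmax + 1)
    hh, kk, ll = np.meshgrid(rng, rng, rng, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min]
    hkl = hkl[~is_absent(hkl, space_group)]
    canon = canonical_hkl(hkl, space_group)
    return np.unique(canon, axis=0)


def allowed_origin_shifts(space_group: str) -> np.ndarray:
    """Translations tau with (R - I) tau = 0 (mod 1) for every rotation R:
    shifting the origin by tau leaves the operator set unchanged."""
    shifts = []
    rots = rotations(space_group)
    for tau in itertools.product((0.0, 0.5), repeat=3):
        tau = np.array(tau)
        ok = True
        for r in rots:
            v = (r - _I) @ tau
            if not np.allclose(np.mod(v + 0.5, 1.0) - 0.5, 0.0, atol=1e-9):
                ok = False
                break
        if ok:
            shifts.append(tau)
    return np.array(shifts)


def site_distance(x, y, cell) -> float:
    """Minimum-image Cartesian distance (A) between fractional sites."""
    dx = np.asarray(x, float) - np.asarray(y, float)
    dx -= np.round(dx)
    return float(np.linalg.norm(dx @ cell.direct_matrix()))


def sites_equivalent(
    x, y, cell, space_group: str,
    tol: float = 0.5, allow_inversion: bool = True,
) -> bool:
    """Whether two fractional sites coincide (within tol, A) up to space-group
    symmetry, allowed origin shifts and (optionally) inversion through the
    origin — the equivalence class a difference-Patterson search can resolve."""
    x = np.asarray(x, float)
    hands = [np.asarray(y, float)]
    if allow_inversion:
        hands.append(-np.asarray(y, float))
    shifts = allowed_origin_shifts(space_group)
    for yy in hands:
        for r, t in operators(space_group):
            img = r @ yy + t
            for tau in shifts:
                if site_distance(x, img + tau, cell) <= tol:
                    return True
    return False
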
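"""Spot integration and Monte-Carlo merging with serial-crystallography
quality statistics.

Still-image intensities are partial; averaging many randomly oriented
snapshots per unique reflection (Monte-Carlo merging) converges to values
proportional to the true intensities.  Quality is quantified by comparing
half datasets built from even- and odd-numbered images: R_split (with its
1/sqrt(2) correction), CC_1/2, and CCano on anomalous differences.
Friedel mates are merged separately throughout so the anomalous signal
survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import symmetry
from .geometry import UnitCell
from .indexing import IndexingSolution

OBSERVATION_COLUMNS = ["h", "k", "l", "intensity", "sigma", "image_id", "colour"]


@dataclass(frozen=True)
class ReflectionObservation:
    """One integrated spot, indexed as measured (signed hkl)."""

    hkl: tuple[int, int, int]
    intensity: float
    sigma: float
    image_id: int
    colour: str

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def observations_frame(obs) -> pd.DataFrame:
    """Normalise a list of ReflectionObservation or a DataFrame to the
    canonical observation table."""
    if isinstance(obs, pd.DataFrame):
        missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
        if missing:
            raise ValueError(f"observation table lacks columns {missing}")
        return obs
    rows = [(o.hkl[0], o.hkl[1], o.hkl[2], o.intensity, o.sigma, o.image_id,
             o.colour) for o in obs]
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def _disc_offsets(radius: float):
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dx * dx + dy * dy <= radius * radius
    return dx[keep], dy[keep]


def disc_pixel_count(radius: float) -> int:
    """Number of integer lattice points with x^2 + y^2 <= radius^2."""
    dx, _ = _disc_offsets(radius)
    return len(dx)


def integrate(
    image,
    solution: IndexingSolution,
    radii: tuple[float, float, float] = (6.0, 6.0, 8.0),
    image_id: int = 0,
) -> pd.DataFrame:
    """Fixed-radius integration at every predicted spot of a solution.

    radii = (peak, background inner, background outer):
    I = sum(disc r <= peak) - n_peak * median(annulus inner < r <= outer);
    sigma combines the background spread over the annulus with a counting
    term: sigma^2 = n_peak * var_bg * (1 + n_peak / n_bg) + max(I, 0).
    Spots whose annulus leaves the panel are skipped.
    """
    r_peak, r_in, r_out = radii
    if not (r_out > r_in >= r_peak):
        raise ValueError("radii must satisfy bg_outer > bg_inner >= peak")
    img = np.asarray(image, dtype=float)
    n_slow, n_fast = img.shape
    dxp, dyp = _disc_offsets(r_peak)
    dxa, dya = _disc_offsets(r_out)
    ann = (dxa * dxa + dya * dya) > r_in * r_in
    dxa, dya = dxa[ann], dya[ann]

    rows = []
    for (h, k, l), fast, slow in solution.predicted:
        ci, cj = int(round(slow)), int(round(fast))
        if (ci - r_out < 0 or ci + r_out >= n_slow
                or cj - r_out < 0 or cj + r_out >= n_fast):
            continue  # annulus off the panel
        peak_vals = img[ci + dyp, cj + dxp]
        bg_vals = img[ci + dya, cj + dxa]
        bg = float(np.median(bg_vals))
        inten = float(peak_vals.sum() - len(peak_vals) * bg)
        var_bg = float(bg_vals.var())
        n_pk, n_bg = len(peak_vals), len(bg_vals)
        sigma = float(np.sqrt(n_pk * var_bg * (1.0 + n_pk / n_bg)
                              + max(inten, 0.0)))
        rows.append((h, k, l, inten, max(sigma, 1e-6), image_id,
                     solution.colour.label))
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


@dataclass
class MergedDataset:
    """Per unique reflection (422 rotations, Friedel mates separate):
    mean intensity, sigma of the mean, multiplicity."""

    table: pd.DataFrame  # h, k, l (canonical), colour, intensity, sigma, n_obs, d, centric
    cell: UnitCell
    space_group: str

    def __len__(self):
        return len(self.table)

    def select_colour(self, colour: str) -> "MergedDataset":
        return MergedDataset(self.table[self.table["colour"] == colour].copy(),
                             self.cell, self.space_group)

    def friedel_pairs(self) -> pd.DataFrame:
        """Acentric reflections with both mates merged: columns h, k, l
        (plus-mate canonical), i_plus, i_minus, d, colour."""
        t = self.table[~self.table["centric"]]
        if t.empty:
            return pd.DataFrame(columns=["h", "k", "l", "i_plus", "i_minus",
                                         "d", "colour"])
        mates = symmetry.canonical_hkl(
            -t[["h", "k", "l"]].to_numpy(), self.space_group)
        t = t.assign(mh=mates[:, 0], mk=mates[:, 1], ml=mates[:, 2])
        plus = t[[tuple(r) >= tuple(m) for r, m in zip(
            t[["h", "k", "l"]].to_numpy(), mates)]]
        merged = plus.merge(
            t, left_on=["mh", "mk", "ml", "colour"],
            right_on=["h", "k", "l", "colour"], suffixes=("", "_m"))
        return pd.DataFrame({
            "h": merged["h"], "k": merged["k"], "l": merged["l"],
            "i_plus": merged["intensity"], "i_minus": merged["intensity_m"],
            "sigma_plus": merged["sigma"], "sigma_minus": merged["sigma_m"],
            "d": merged["d"], "colour": merged["colour"],
        })

    def to_tsv(self, path) -> None:
        cols = ["h", "k", "l", "colour", "intensity", "sigma", "n_obs"]
        self.table[cols].rename(columns={"n_obs": "nmeas"}).to_csv(
            path, sep="\t", index=False)


def merge(observations, cell: UnitCell, space_group: str = "P43212") -> MergedDataset:
    """Unweighted Monte-Carlo merge per canonical hkl and colour.

    sigma of the mean = sample sd / sqrt(n) (0 for multiplicity 1, where
    the sd is undefined; such reflections carry sigma 0 and are retained).
    Negative means are retained — merging statistics require them.
    """
    df = observations_frame(observations)
    if df.empty:
        raise ValueError("no observations to merge")
    canon = symmetry.canonical_hkl(df[["h", "k", "l"]].to_numpy(dtype=int),
                                   space_group)
    df = df.assign(h=canon[:, 0], k=canon[:, 1], l=canon[:, 2])
    grouped = df.groupby(["h", "k", "l", "colour"], sort=True)["intensity"]
    out = grouped.agg(intensity="mean", sd="std", n_obs="size").reset_index()
    out["sigma"] = (out["sd"] / np.sqrt(out["n_obs"])).fillna(0.0)
    out = out.drop(columns="sd")
    hkl = out[["h", "k", "l"]].to_numpy(dtype=int)
    out["d"] = cell.d_spacing(hkl)
    out["centric"] = symmetry.is_centric(hkl, space_group)
    return MergedDataset(out, cell, space_group)


def split_half_datasets(observations, cell: UnitCell,
                        space_group: str = "P43212"):
    """Even/odd split by image acquisition index, merged separately."""
    df = observations_frame(observations)
    even = df[df["image_id"] % 2 == 0]
    odd = df[df["image_id"] % 2 == 1]
    if even.empty or odd.empty:
        raise ValueError("need observations in both even and odd images")
    return merge(even, cell, space_group), merge(odd, cell, space_group)


def _common(even: MergedDataset, odd: MergedDataset) -> pd.DataFrame:
    return even.table.merge(odd.table, on=["h", "k", "l", "colour"],
                            suffixes=("_e", "_o"))


def r_split(even: MergedDataset, odd: MergedDataset) -> float:
    """R_split = (1/sqrt 2) * sum|I_e - I_o| / sum((I_e + I_o)/2) over
    reflections common to the half datasets."""
    c = _common(even, odd)
    if c.empty:
        raise ValueError("half datasets share no reflections")
    num = np.abs(c["intensity_e"] - c["intensity_o"]).sum()
    den = (0.5 * (c["intensity_e"] + c["intensity_o"])).sum()
    return float(num / den / np.sqrt(2.0))


def cc_half(even: MergedDataset, odd: MergedDataset) -> float:
    """Pearson correlation of half-dataset mean intensities."""
    c = _common(even, odd)
    if len(c) < 3:
        raise ValueError("too few common reflections")
    return float(np.corrcoef(c["intensity_e"], c["intensity_o"])[0, 1])


def cc_ano(even: MergedDataset, odd: MergedDataset) -> float:
    """Pearson correlation of half-dataset anomalous differences
    I+ - I- over common acentric Friedel pairs (unweighted)."""
    pe = even.friedel_pairs()
    po = odd.friedel_pairs()
    c = pe.merge(po, on=["h", "k", "l", "colour"], suffixes=("_e", "_o"))
    if len(c) < 3:
        raise ValueError("too few common Friedel pairs")
    de = c["i_plus_e"] - c["i_minus_e"]
    do = c["i_plus_o"] - c["i_minus_o"]
    return float(np.corrcoef(de, do)[0, 1])


def completeness(merged: MergedDataset, d_min: float,
                 d_max: float | None = None,
                 colour: str | None = None) -> float:
    """Observed unique reflections as a percentage of the theoretically
    possible unique set in [d_min, d_max] (absences excluded, Friedel
    mates counted separately). d_max=None means no low-resolution bound."""
    t = merged.table
    if colour is not None:
        t = t[t["colour"] == colour]
    sel = t["d"] >= d_min
    if d_max is not None:
        sel &= t["d"] <= d_max
    observed = t[sel][["h", "k", "l"]].drop_duplicates()
    possible = symmetry.unique_reflections(merged.cell, d_min, merged.space_group)
    if d_max is not None:
        dp = merged.cell.d_spacing(possible)
        possible = possible[dp <= d_max]
    if len(possible) == 0:
        return float("nan")
    return 100.0 * len(observed) / len(possible)


def multiplicity(merged: MergedDataset) -> float:
    return float(merged.table["n_obs"].mean())


def i_over_sigma(merged: MergedDataset) -> float:
    """Mean I/sigma(I) over reflections with defined sigma."""
    t = merged.table[merged.table["sigma"] > 0]
    if t.empty:
        return float("nan")
    return float((t["intensity"] / t["sigma"]).mean())


def resolution_shells(d: np.ndarray, n_shells: int = 10) -> np.ndarray:
    """Equal-volume shell edges over the resolution range of `d` (edges in
    d, length n_shells + 1, decreasing)."""
    s3 = np.sort(1.0 / np.asarray(d) ** 3)
    lo, hi = s3[0], s3[-1]
    edges = np.linspace(lo, hi, n_shells + 1)
    edges[-1] *= 1 + 1e-9  # include the last reflection
    return edges ** (-1.0 / 3.0)


def shell_table(observations, cell: UnitCell, space_group: str = "P43212",
                n_shells: int = 10, colour: str | None = None) -> pd.DataFrame:
    """Per-shell merging statistics from an observation table.

    Columns: d_max, d_min, n_unique, completeness, multiplicity, r_split,
    cc_half, cc_ano, i_over_sigma; one row per shell plus an 'overall' row
    (marked by shell = -1).
    """
    df = observations_frame(observations)
    if colour is not None:
        df = df[df["colour"] == colour]
    merged = merge(df, cell, space_group)
    even, odd = split_half_datasets(df, cell, space_group)
    edges = resolution_shells(merged.table["d"].to_numpy(), n_shells)

    rows = []
    for i in range(n_shells):
        d_hi, d_lo = edges[i], edges[i + 1]  # d_hi > d_lo
        sel_m = merged.table[(merged.table["d"] <= d_hi) & (merged.table["d"] > d_lo)]
        sub_e = MergedDataset(even.table[(even.table["d"] <= d_hi)
                                         & (even.table["d"] > d_lo)], cell, space_group)
        sub_o = MergedDataset(odd.table[(odd.table["d"] <= d_hi)
                                        & (odd.table["d"] > d_lo)], cell, space_group)
        try:
            rs = r_split(sub_e, sub_o)
            ch = cc_half(sub_e, sub_o)
        except ValueError:
            rs = ch = float("nan")
        try:
            ca = cc_ano(sub_e, sub_o)
        except ValueError:
            ca = float("nan")
        sub_m = MergedDataset(sel_m, cell, space_group)
        rows.append((i, d_hi, d_lo, len(sel_m),
                     multiplicity(sub_m) if len(sel_m) else float("nan"),
                     rs, ch, ca,
                     i_over_sigma(sub_m) if len(sel_m) else float("nan")))
    try:
        ca_overall = cc_ano(even, odd)
    except ValueError:
        ca_overall = float("nan")
    rows.append((-1, edges[0], edges[-1], len(merged.table),
                 multiplicity(merged), r_split(even, odd),
                 cc_half(even, odd), ca_overall, i_over_sigma(merged)))
    out = pd.DataFrame(rows, columns=["shell", "d_max", "d_min", "n_unique",
                                      "multiplicity", "r_split", "cc_half",
                                      "cc_ano", "i_over_sigma"])
    comp = [completeness(merged, r.d_min, d_max=r.d_max if r.shell >= 0 else None)
            for r in out.itertuples()]
    out.insert(4, "completeness", comp)
    return out
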
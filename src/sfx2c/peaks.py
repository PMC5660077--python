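"""Background handling and Bragg-spot detection.

The detection chain: a moving-window median estimates the (slowly varying)
background which is subtracted before thresholding; connected components of
above-threshold pixels become candidate spots, filtered by size, local
signal-to-noise and a squared-gradient criterion; surviving components are
reported with intensity-weighted centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class ThresholdEstimate:
    """Global threshold tau = median over images of (mu + 4 sigma)."""

    tau: float
    mu: np.ndarray  # per-image mean, ADU
    sigma: np.ndarray  # per-image standard deviation, ADU
    n_images: int


@dataclass(frozen=True)
class PeakSearchParams:
    """Spot-search parameters (defaults: first-pass values; see
    `second_pass()` for the lowered second-colour search)."""

    threshold: float = 700.0  # ADU, applied to the background-corrected image
    min_snr: float = 5.0
    min_gradient: float = 10_000.0  # minimum squared intensity gradient, ADU^2/px^2
    median_window: int = 16  # pixels; 0 disables background correction
    peak_max_diameter: int = 10  # pixels, bounding-box extent limit

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.median_window and self.median_window < 3:
            raise ValueError("median window must be >= 3 (or 0 to disable)")

    @classmethod
    def second_pass(cls) -> "PeakSearchParams":
        """Lowered parameters used to pick up the weaker colour's spots."""
        return cls(threshold=150.0, min_snr=3.0, min_gradient=10_000.0,
                   median_window=16)


@dataclass(frozen=True)
class Peak:
    fast: float  # fractional pixel, intensity-weighted centroid
    slow: float
    intensity: float  # background-corrected integrated value, ADU
    background: float  # local background level, ADU
    snr: float


class PeakList:
    """Ordered collection of peaks with tab-separated round-trip."""

    def __init__(self, peaks: list[Peak] | None = None):
        self.peaks = list(peaks) if peaks else []

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (fast, slow)."""
        if not self.peaks:
            return np.empty((0, 2))
        return np.array([[p.fast, p.slow] for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.fast, p.slow, p.intensity, p.background, p.snr) for p in self.peaks],
            columns=["fast", "slow", "intensity", "background", "snr"],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        df = pd.read_csv(path, sep="\t")
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PeakList":
        return cls([
            Peak(float(r.fast), float(r.slow), float(r.intensity),
                 float(getattr(r, "background", 0.0)), float(getattr(r, "snr", 0.0)))
            for r in df.itertuples()
        ])


def estimate_threshold(images) -> ThresholdEstimate:
    """Per-image mean mu and standard deviation sigma over all pixels;
    the working threshold is the median over images of mu + 4 sigma."""
    mus, sigmas = [], []
    n = 0
    for img in images:
        arr = np.asarray(img, dtype=float)
        if arr.size == 0:
            raise ValueError("image with zero pixels")
        mus.append(float(arr.mean()))
        sigmas.append(float(arr.std()))
        n += 1
    if n == 0:
        raise ValueError("empty image set")
    mu = np.array(mus)
    sigma = np.array(sigmas)
    return ThresholdEstimate(tau=float(np.median(mu + 4.0 * sigma)),
                             mu=mu, sigma=sigma, n_images=n)


def cauchy_quantile_at_sigma(k: float = 4.0) -> float:
    """CDF of the Cauchy law at location + k*scale: 1/2 + atan(k)/pi.

    At k = 4 this is 0.9220: under a heavy-tailed (Cauchy) model of the pixel
    read distribution, the mu + 4 sigma threshold sits at the 0.92 quantile.
    """
    return 0.5 + math.atan(k) / math.pi


def cauchy_quantile_at_four_sigma() -> float:
    return cauchy_quantile_at_sigma(4.0)


def median_filter_background(image, window: int = 16):
    """Moving-window median background and the corrected image.

    The window covers pixels [i - w//2, i + w - w//2 - 1] along each axis
    (for the default even window 16: [i-8, i+7]); at the panel edge the
    window is truncated to the pixels that exist.  The median of an even
    pixel count is the upper order statistic (element n//2 of the sorted
    window), matching the brute-force oracle convention.

    Returns (background, corrected) with corrected = image - background.
    """
    img = np.asarray(image, dtype=float)
    if window < 3 or window >= min(img.shape):
        raise ValueError("window must be >= 3 and smaller than the panel")
    lo = window // 2  # offsets [-lo, window - lo - 1]
    hi = window - lo - 1
    bg = ndimage.median_filter(img, size=window, mode="nearest")
    # fix the edge band: truncated-window median, computed directly
    n0, n1 = img.shape
    edge_rows = list(range(0, min(lo, n0))) + list(range(max(n0 - hi, 0), n0))
    edge_cols = list(range(0, min(lo, n1))) + list(range(max(n1 - hi, 0), n1))

    def _trunc_median(i, j):
        w = img[max(i - lo, 0):i + hi + 1, max(j - lo, 0):j + hi + 1].ravel()
        return np.sort(w)[w.size // 2]

    for i in edge_rows:
        for j in range(n1):
            bg[i, j] = _trunc_median(i, j)
    inner_rows = [i for i in range(n0) if i not in set(edge_rows)]
    for j in edge_cols:
        for i in inner_rows:
            bg[i, j] = _trunc_median(i, j)
    return bg, img - bg


def _squared_gradient(img: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(img)
    return gx * gx + gy * gy


def find_peaks(image, params: PeakSearchParams) -> PeakList:
    """Threshold-based spot search on the background-corrected image.

    Connected components (8-connectivity) of pixels above `threshold` are
    candidate spots.  A component is kept when its bounding box fits within
    `peak_max_diameter`, its peak squared intensity gradient reaches
    `min_gradient`, and its annulus-based signal-to-noise reaches `min_snr`.
    """
    img = np.asarray(image, dtype=float)
    if params.median_window:
        _, corrected = median_filter_background(img, params.median_window)
    else:
        corrected = img

    mask = corrected > params.threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return PeakList()

    grad2 = _squared_gradient(corrected)
    objects = ndimage.find_objects(labels)
    peaks = []
    for idx, sl in enumerate(objects, start=1):
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if max(h, w) > params.peak_max_diameter:
            continue
        sub = corrected[sl]
        sub_mask = labels[sl] == idx
        vals = np.where(sub_mask, sub, 0.0)
        total = float(vals.sum())
        if total <= 0:
            continue
        # brightest pixel (ties: lowest (slow, fast))
        flat = np.argmax(np.where(sub_mask, sub, -np.inf))
        pi, pj = np.unravel_index(flat, sub.shape)
        peak_slow = sl[0].start + pi
        peak_fast = sl[1].start + pj
        if grad2[sl][sub_mask].max() < params.min_gradient:
            continue
        # intensity-weighted centroid
        ys, xs = np.nonzero(sub_mask)
        slow_c = float((ys * vals[ys, xs]).sum() / total) + sl[0].start
        fast_c = float((xs * vals[ys, xs]).sum() / total) + sl[1].start
        # local background from an annulus of radius 2x the component radius
        r_comp = max(h, w) / 2.0
        r_out = max(2.0 * max(h, w), 4.0)
        yy0 = max(int(peak_slow - r_out), 0)
        yy1 = min(int(peak_slow + r_out) + 1, img.shape[0])
        xx0 = max(int(peak_fast - r_out), 0)
        xx1 = min(int(peak_fast + r_out) + 1, img.shape[1])
        region = corrected[yy0:yy1, xx0:xx1]
        ry, rx = np.mgrid[yy0:yy1, xx0:xx1]
        rr = np.hypot(ry - peak_slow, rx - peak_fast)
        ann = region[(rr > r_comp + 1.0) & (rr <= r_out) & (labels[yy0:yy1, xx0:xx1] == 0)]
        if ann.size >= 4:
            local_bg = float(np.median(ann))
            noise = float(ann.std())
        else:
            local_bg, noise = 0.0, 0.0
        peak_height = float(sub[pi, pj]) - local_bg
        snr = peak_height / noise if noise > 0 else math.inf
        if snr < params.min_snr:
            continue
        peaks.append(Peak(fast=fast_c, slow=slow_c, intensity=total,
                          background=local_bg,
                          snr=snr if math.isfinite(snr) else float(1e9)))
    peaks.sort(key=lambda p: -p.intensity)
    return PeakList(peaks)


def is_hit(peaks: PeakList, min_peaks: int = 15) -> bool:
    """Hit selection: an image is a crystal hit when at least `min_peaks`
    spots were found."""
    return len(peaks) >= min_peaks
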
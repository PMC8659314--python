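"""Binarization of enhanced OCTA MIPs into vessel / not-vessel masks.

Five classical thresholding families are provided for comparison:
Huang–Wang fuzzy-entropy, local-mean adaptive, global mean intensity,
ISODATA (Ridler–Calvard intermeans), and two-cluster 1-D k-means.  All
histogram-shape thresholds operate on a 256-bin quantization of the
[0, 1] intensities regardless of input bit depth, which keeps thresholds
reproducible across sources.  The tie convention is uniform: a pixel
exactly at the threshold is foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DegenerateImageError, ParameterError, UndefinedMetricError
from .preprocess import AngiogramImage

__all__ = [
    "BinaryMask",
    "threshold_fuzzy",
    "threshold_adaptive",
    "threshold_global_mean",
    "threshold_isodata",
    "threshold_kmeans",
    "segment",
    "SEGMENTERS",
    "connectivity_factor",
    "compare_segmenters",
]


@dataclass
class BinaryMask:
    """Boolean vessel mask on the image grid.

    ``excluded`` marks out-of-ROI pixels; they are never foreground and
    are removed from every density denominator.
    """

    pixels: np.ndarray
    pixel_size_um: float
    excluded: np.ndarray | None = None
    threshold: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.excluded is not None:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != self.pixels.shape:
                raise ParameterError("excluded mask shape mismatch")
            self.pixels = self.pixels & ~self.excluded

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def quantize256(pixels: np.ndarray) -> np.ndarray:
    """Quantize [0, 1] intensities to 256 gray levels (0..255)."""
    return np.clip(np.round(np.asarray(pixels, float) * 255), 0, 255).astype(np.uint8)


def _histogram256(image: AngiogramImage) -> tuple[np.ndarray, np.ndarray]:
    levels = quantize256(image.pixels)
    valid = np.ones(levels.shape, bool) if image.excluded is None else ~image.excluded
    hist = np.bincount(levels[valid].ravel(), minlength=256).astype(float)
    return hist, levels


def _check_contrast(hist: np.ndarray) -> None:
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("image has fewer than 2 distinct gray levels; no threshold exists")


def _mask_from_level(image: AngiogramImage, levels: np.ndarray, thr_level: float,
                     method: str) -> BinaryMask:
    fg = levels >= thr_level
    return BinaryMask(fg, image.pixel_size_um, excluded=image.excluded,
                      threshold=float(thr_level) / 255.0, method=method)


def huang_fuzziness(hist: np.ndarray, t: int) -> float:
    """Huang–Wang fuzziness of the split background<=t < foreground.

    Membership of gray level g is u = 1/(1 + |g - mu_region| / C) with C
    the gray-level dynamic range; the measure is the summed Shannon
    entropy -u ln u - (1-u) ln(1-u) weighted by the histogram.
    """
    g = np.arange(256, dtype=float)
    nz = np.nonzero(hist)[0]
    c = float(nz[-1] - nz[0])
    w = hist
    n0, n1 = w[: t + 1].sum(), w[t + 1 :].sum()
    if n0 == 0 or n1 == 0:
        return np.inf
    mu0 = (w[: t + 1] * g[: t + 1]).sum() / n0
    mu1 = (w[t + 1 :] * g[t + 1 :]).sum() / n1
    u = np.empty(256)
    u[: t + 1] = 1.0 / (1.0 + np.abs(g[: t + 1] - mu0) / c)
    u[t + 1 :] = 1.0 / (1.0 + np.abs(g[t + 1 :] - mu1) / c)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(u * np.log(u) + (1 - u) * np.log(1 - u))
    h[~np.isfinite(h)] = 0.0  # u == 1 contributes zero entropy
    return float((w * h).sum())


def threshold_fuzzy(image: AngiogramImage) -> BinaryMask:
    """Exhaustive Huang–Wang fuzzy threshold (the recommended default).

    Searches all 256 candidate splits of the gray histogram for the one
    minimizing the entropy-of-fuzziness measure; pixels at or above the
    resulting threshold are vessel.
    """
    hist, levels = _histogram256(image)
    _check_contrast(hist)
    nz = np.nonzero(hist)[0]
    candidates = range(nz[0], nz[-1])
    scores = [huang_fuzziness(hist, t) for t in candidates]
    best = int(np.argmin(scores)) + nz[0]
    return _mask_from_level(image, levels, best + 1, "fuzzy")


def threshold_adaptive(image: AngiogramImage, kernel_px: int | None = None,
                       offset: float = 0.0) -> BinaryMask:
    """Local-mean adaptive threshold: vessel iff I > local_mean - offset.

    Included mainly as a basis for comparison; on noisy but largely
    uniform regions it fabricates structure (foreground fraction ~50%
    at offset 0), which is its documented failure mode.
    """
    if kernel_px is None:
        kernel_px = image.shape[1] // 8 | 1  # odd, ~width/8
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ParameterError(f"adaptive kernel must be odd and >= 3, got {kernel_px}")
    local_mean = ndi.uniform_filter(image.pixels, size=kernel_px, mode="reflect")
    fg = image.pixels > local_mean - offset
    return BinaryMask(fg, image.pixel_size_um, excluded=image.excluded,
                      threshold=None, method="adaptive")


def threshold_global_mean(image: AngiogramImage) -> BinaryMask:
    """Global threshold at the mean image intensity.

    This is also the manual-VAD reference convention used when scoring
    segmenters against a known-geometry image.
    """
    hist, levels = _histogram256(image)
    _check_contrast(hist)
    valid = np.ones(image.shape, bool) if image.excluded is None else ~image.excluded
    thr = float(image.pixels[valid].mean())
    fg = image.pixels >= thr
    return BinaryMask(fg, image.pixel_size_um, excluded=image.excluded,
                      threshold=thr, method="global-mean")


def isodata_level(hist: np.ndarray) -> float:
    """Ridler–Calvard intermeans fixed point on a 256-bin histogram.

    Iterates T <- (mean below T + mean above T) / 2 to convergence; the
    fixed point satisfies the intermeans condition within one gray
    level.
    """
    g = np.arange(256, dtype=float)
    t = (hist * g).sum() / hist.sum()
    for _ in range(500):
        below = g <= t
        n0, n1 = hist[below].sum(), hist[~below].sum()
        if n0 == 0 or n1 == 0:
            break
        t_new = 0.5 * ((hist[below] * g[below]).sum() / n0 + (hist[~below] * g[~below]).sum() / n1)
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return float(t)


def threshold_isodata(image: AngiogramImage) -> BinaryMask:
    hist, levels = _histogram256(image)
    _check_contrast(hist)
    t = isodata_level(hist)
    return _mask_from_level(image, levels, np.ceil(t), "isodata")


def threshold_kmeans(image: AngiogramImage) -> BinaryMask:
    """Two-cluster 1-D Lloyd's algorithm on gray levels.

    Centroids are initialized at the min and max intensities, which
    makes the result deterministic; vessel = the brighter cluster.
    """
    hist, levels = _histogram256(image)
    _check_contrast(hist)
    g = np.arange(256, dtype=float)
    nz = np.nonzero(hist)[0]
    c0, c1 = float(nz[0]), float(nz[-1])
    for _ in range(500):
        mid = (c0 + c1) / 2.0
        lo = g < mid
        hi = ~lo
        n0, n1 = hist[lo].sum(), hist[hi].sum()
        if n0 == 0 or n1 == 0:
            break
        c0n = (hist[lo] * g[lo]).sum() / n0
        c1n = (hist[hi] * g[hi]).sum() / n1
        if c0n == c0 and c1n == c1:
            break
        c0, c1 = c0n, c1n
    thr_level = np.ceil((c0 + c1) / 2.0)
    return _mask_from_level(image, levels, thr_level, "kmeans")


SEGMENTERS = {
    "fuzzy": threshold_fuzzy,
    "adaptive": threshold_adaptive,
    "global-mean": threshold_global_mean,
    "isodata": threshold_isodata,
    "kmeans": threshold_kmeans,
}


def segment(image: AngiogramImage, method: str = "fuzzy", **kwargs) -> BinaryMask:
    """Dispatch to a named segmenter (default: fuzzy)."""
    try:
        fn = SEGMENTERS[method]
    except KeyError:
        raise ParameterError(f"unknown segmenter {method!r}; choose from {sorted(SEGMENTERS)}")
    return fn(image, **kwargs)


def connectivity_factor(network) -> float:
    """CF = 1 - S_i / S_t: the fraction of identified vessel elements
    attached to the main network (S_i isolated, S_t total elements)."""
    total = len(network.elements)
    if total < 1:
        raise UndefinedMetricError("connectivity factor undefined on an empty network")
    isolated = sum(1 for e in network.elements if e.kind == "isolated")
    return 1.0 - isolated / total


def compare_segmenters(image: AngiogramImage, methods: list[str] | None = None,
                       reference_vad: float | None = None,
                       twig_size_px: int = 0) -> pd.DataFrame:
    """Run several segmenters on the same enhanced image and score them.

    Each method is scored by vessel area density and network
    connectivity factor; if ``reference_vad`` is given (conventionally
    the mean-intensity global threshold of a known-geometry image) the
    absolute VAD deviation from it is reported too.  A method that
    fails on the input yields a flagged row; the others still report.
    """
    from .metrics import vessel_area_density
    from .network import classify_elements, detect_nodes, local_thickness, skeletonize_mask

    if methods is None:
        methods = list(SEGMENTERS)
    if not methods:
        raise ParameterError("at least one method must be requested")
    rows = []
    for name in methods:
        row = {"method": name, "vad_pct": np.nan, "connectivity_factor": np.nan,
               "threshold": np.nan, "failed": False}
        try:
            mask = segment(image, name)
            row["threshold"] = np.nan if mask.threshold is None else mask.threshold
            row["vad_pct"] = vessel_area_density(mask)
            skel = skeletonize_mask(mask)
            thick = local_thickness(mask)
            net = classify_elements(skel, detect_nodes(skel), thick, twig_size_px=twig_size_px)
            row["connectivity_factor"] = connectivity_factor(net)
        except Exception:
            row["failed"] = True
        if reference_vad is not None:
            row["vad_abs_dev"] = abs(row["vad_pct"] - reference_vad) if not row["failed"] else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
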
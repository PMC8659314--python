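"""Deterministic synthetic phantoms with exact ground truth.

Two generators stand in for physical validation targets: a microfluidic
style channel grid with two known channel widths (50 μm and 300 μm by
default, rasterized at 4 μm/pixel), and a curvy-vessel network image
with intensity variations along vessels and multiplicative speckle-like
background noise (9.3 μm/pixel by default).  Every ground-truth field
is derived from the geometric model — lengths, widths and tortuosities
from the generating polylines, junction counts from curve crossings —
except the area fraction, which is raster-exact from the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import GeometryError, ParameterError
from .preprocess import AngiogramImage
from .segmentation import BinaryMask

__all__ = [
    "PhantomGroundTruth",
    "channel_grid_phantom",
    "network_phantom",
    "add_motion_streak",
]


@dataclass
class PhantomGroundTruth:
    """Exact geometry of a generated phantom.

    ``centerlines`` are the rasterized true centerline paths (one array
    of (row, col) per vessel); ``per_vessel`` holds true lengths (mm),
    widths (μm) and tortuosities from the generating model.
    """

    mask: BinaryMask
    centerlines: list[np.ndarray]
    per_vessel: pd.DataFrame
    junction_count: int
    area_fraction: float
    seed: int | None = None

    @property
    def vad_pct(self) -> float:
        return 100.0 * self.area_fraction

    @property
    def vld_pct(self) -> float:
        pixels = {tuple(p) for path in self.centerlines for p in path}
        h, w = self.mask.shape
        return 100.0 * len(pixels) / (h * w)

    @property
    def total_length_mm(self) -> float:
        return float(self.per_vessel["length_mm"].sum())

    @property
    def mean_diameter_um(self) -> float:
        return float(self.per_vessel["width_um"].mean())

    @property
    def mean_tortuosity(self) -> float:
        return float(self.per_vessel["tortuosity"].mean())


def channel_grid_phantom(small_width_um: float = 50.0, large_width_um: float = 300.0,
                         pixel_size_um: float = 4.0, tiles: int = 2,
                         tile_mm: float = 1.08, n_small: int = 6,
                         foreground: float = 0.9, background: float = 0.1,
                         ) -> tuple[AngiogramImage, PhantomGroundTruth]:
    """Microfluidic-style grid: per tile, ``n_small`` narrow vertical
    channels merging at right angles into one wide horizontal channel,
    tiled ``tiles`` × ``tiles``.

    Bright channels (0.9) on a dark background (0.1); fully
    deterministic.  Ground truth records the analytic channel area,
    centerlines and widths.
    """
    px = pixel_size_um
    tile_px = int(round(tile_mm * 1000.0 / px))
    w_s = int(round(small_width_um / px))
    w_l = int(round(large_width_um / px))
    if w_s < 2 or w_l < 2:
        raise ParameterError("channel widths must be at least 2 px at this pixel size")
    if w_l >= tile_px or tile_px / n_small <= w_s:
        raise GeometryError("channels do not fit the tile geometry")
    size = tiles * tile_px
    mask = np.zeros((size, size), bool)
    centerlines: list[np.ndarray] = []
    rows = []
    vid = 0
    for tr in range(tiles):
        top = tr * tile_px
        crow = top + tile_px // 2
        r0 = crow - w_l // 2
        mask[r0:r0 + w_l, :] = True
        vid += 1
        path = np.stack([np.full(size, crow), np.arange(size)], axis=1)
        centerlines.append(path)
        rows.append({"vessel_id": vid, "kind": "large", "width_um": w_l * px,
                     "nominal_width_um": large_width_um,
                     "length_mm": size * px / 1000.0, "tortuosity": 0.0})
        for tc in range(tiles):
            left = tc * tile_px
            for j in range(n_small):
                ccol = left + int(round((j + 0.5) * tile_px / n_small))
                c0 = ccol - w_s // 2
                mask[top:crow, c0:c0 + w_s] = True
                vid += 1
                path = np.stack([np.arange(top, crow + 1), np.full(crow + 1 - top, ccol)], axis=1)
                centerlines.append(path)
                rows.append({"vessel_id": vid, "kind": "small", "width_um": w_s * px,
                             "nominal_width_um": small_width_um,
                             "length_mm": (crow - top) * px / 1000.0, "tortuosity": 0.0})
    image = AngiogramImage(background + (foreground - background) * mask.astype(float),
                           px, source_id="channel_grid_phantom")
    gt = PhantomGroundTruth(
        mask=BinaryMask(mask, px, method="ground-truth"),
        centerlines=centerlines, per_vessel=pd.DataFrame(rows),
        junction_count=n_small * tiles * tiles,
        area_fraction=float(mask.mean()),
    )
    return image, gt


def _amplitude_for_tortuosity(tau: float, k: float, span: float) -> float:
    """Amplitude of y = A sin(2πk x/span) whose arc/chord - 1 = tau."""
    if tau <= 0:
        return 0.0
    u = np.linspace(0, 2 * np.pi, 2001)

    def f(a):
        return np.sqrt(1 + (a * np.cos(u)) ** 2).mean() - 1 - tau

    lo, hi = 0.0, 8.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    a = (lo + hi) / 2
    return a * span / (2 * np.pi * k)


def _polyline_stats(xy: np.ndarray, px: float) -> tuple[float, float]:
    """(arc length mm, tortuosity) of a dense polyline in pixel coords."""
    d = np.diff(xy, axis=0)
    arc = float(np.hypot(d[:, 0], d[:, 1]).sum())
    chord = float(np.hypot(*(xy[-1] - xy[0])))
    return arc * px / 1000.0, arc / chord - 1.0 if chord > 0 else np.nan


def _rasterize_centerline(xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """8-connected (Bresenham) pixel chain through the polyline, so that
    ground-truth centerline pixel counts are comparable to a thinned
    skeleton (a 4-connected rounding would overcount diagonal runs)."""
    from skimage.draw import line

    rc = np.round(xy).astype(int)
    rc[:, 0] = np.clip(rc[:, 0], 0, shape[0] - 1)
    rc[:, 1] = np.clip(rc[:, 1], 0, shape[1] - 1)
    keep = np.ones(len(rc), bool)
    keep[1:] = np.any(rc[1:] != rc[:-1], axis=1)
    rc = rc[keep]
    chain = [tuple(rc[0])]
    for a, b in zip(rc[:-1], rc[1:]):
        rr, cc = line(a[0], a[1], b[0], b[1])
        for p in zip(rr.tolist()[1:], cc.tolist()[1:]):
            if p == chain[-1]:
                continue
            # corner cutting: collapse 4-connected stairs into diagonals
            if len(chain) >= 2 and max(abs(p[0] - chain[-2][0]), abs(p[1] - chain[-2][1])) == 1:
                chain[-1] = p
            else:
                chain.append(p)
    return np.array(chain, dtype=int)


def network_phantom(seed: int = 0, n_vessels: int = 9,
                    diameter_range_um: tuple[float, float] = (60.0, 160.0),
                    sinuosity: float = 0.15, pixel_size_um: float = 9.3,
                    noise_level: float = 0.2, intensity_variation: float = 0.3,
                    extent_mm: float = 10.0, n_connectors: int = 8,
                    foreground: float = 0.8, background: float = 0.05,
                    ) -> tuple[AngiogramImage, PhantomGroundTruth]:
    """Seeded synthetic vascular network image with exact ground truth.

    ``n_vessels`` smooth sinusoidal curves run left-to-right in disjoint
    horizontal bands; ``n_connectors`` straight rungs join adjacent
    curves, each creating two T-junctions.  ``sinuosity`` is the target
    per-vessel tortuosity (amplitudes are solved for it, then jittered
    ±30%).
    Vessel intensity is modulated sinusoidally along the centerline
    (amplitude = ``intensity_variation``) and the whole image receives
    multiplicative unit-mean gamma speckle with standard deviation
    ``noise_level``.  Ground truth is recorded before noise.
    """
    if not (0 < diameter_range_um[0] <= diameter_range_um[1]):
        raise ParameterError("invalid diameter range")
    if sinuosity < 0 or noise_level < 0 or not (0 <= intensity_variation < 1):
        raise ParameterError("sinuosity/noise/intensity parameters out of range")
    px = pixel_size_um
    size = int(round(extent_mm * 1000.0 / px))
    rng = np.random.default_rng(seed)
    margin = 0.04 * size
    band_h = (size - 2 * margin) / max(n_vessels, 1)
    max_r = diameter_range_um[1] / px / 2
    if band_h < 2 * (max_r + 3):
        raise ParameterError("vessel bands too narrow for the requested diameters")

    curves: list[dict] = []
    band_fns = []
    t = np.arange(0, size - 1 + 0.25, 0.25)
    for i in range(n_vessels):
        y0 = margin + (i + 0.5) * band_h
        k = float(rng.integers(2, 5))
        tau = sinuosity * rng.uniform(0.7, 1.3)
        amp = min(_amplitude_for_tortuosity(tau, k, size), band_h / 2 - max_r - 2)
        phase = rng.uniform(0, 2 * np.pi)
        y = y0 + amp * np.sin(2 * np.pi * k * t / size + phase)
        band_fns.append(lambda x, y0=y0, amp=amp, k=k, phase=phase:
                        y0 + amp * np.sin(2 * np.pi * k * x / size + phase))
        curves.append({"xy": np.stack([y, t], axis=1),
                       "width_um": float(rng.uniform(*diameter_range_um))})
    n_rungs = n_connectors if n_vessels >= 2 else 0
    for j in range(n_rungs):
        x0 = margin + (j + 0.5) * (size - 2 * margin) / n_rungs
        i = int(rng.integers(0, n_vessels - 1))
        ya, yb = band_fns[i](x0), band_fns[i + 1](x0)
        xy = np.stack([np.linspace(ya, yb, 200), np.full(200, x0)], axis=1)
        curves.append({"xy": xy, "width_um": float(rng.uniform(*diameter_range_um))})

    img = np.full((size, size), background)
    mask = np.zeros((size, size), bool)
    centerlines, rows = [], []
    wavelength_px = 1000.0 / px  # 1 mm intensity modulation period
    for vid, cv in enumerate(curves, start=1):
        rc = _rasterize_centerline(cv["xy"], (size, size))
        centerlines.append(rc)
        arc_mm, tort = _polyline_stats(cv["xy"], px)
        rows.append({"vessel_id": vid, "width_um": cv["width_um"],
                     "length_mm": arc_mm, "tortuosity": tort})
        line = np.zeros((size, size), bool)
        line[rc[:, 0], rc[:, 1]] = True
        w_px = cv["width_um"] / px
        dist, (ir, ic) = ndi.distance_transform_edt(~line, return_indices=True)
        tube = dist <= (w_px - 1) / 2
        mask |= tube
        # intensity varies along the vessel; each tube pixel takes the
        # value of its nearest centerline pixel
        order = np.full((size, size), 0.0)
        s = np.arange(len(rc), dtype=float)
        phase2 = rng.uniform(0, 2 * np.pi)
        vals = foreground * (1 + intensity_variation * np.sin(2 * np.pi * s / wavelength_px + phase2))
        order[rc[:, 0], rc[:, 1]] = vals
        img[tube] = np.maximum(img[tube], order[ir[tube], ic[tube]])

    gt = PhantomGroundTruth(
        mask=BinaryMask(mask, px, method="ground-truth"),
        centerlines=centerlines, per_vessel=pd.DataFrame(rows),
        junction_count=2 * n_rungs,
        area_fraction=float(mask.mean()), seed=seed,
    )
    if noise_level > 0:
        shape_k = 1.0 / noise_level**2
        img = img * rng.gamma(shape_k, 1.0 / shape_k, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return AngiogramImage(img, px, source_id=f"network_phantom_seed{seed}"), gt


def add_motion_streak(image: AngiogramImage, row_band: tuple[int, int],
                      intensity: float = 1.0) -> AngiogramImage:
    """Inject a horizontal bright stripe (motion-artifact morphology).

    The band ``[row_band[0], row_band[1])`` is raised to at least
    ``intensity``; a zero-intensity streak is the identity.
    """
    r0, r1 = row_band
    if not (0 <= r0 < r1 <= image.shape[0]):
        raise GeometryError(f"row band {row_band} outside image of height {image.shape[0]}")
    out = image.pixels.copy()
    out[r0:r1, :] = np.maximum(out[r0:r1, :], np.clip(intensity, 0, 1))
    return replace(image, pixels=out)
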
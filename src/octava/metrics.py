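"""The eight microvascular network metrics, histograms and the report.

Metrics and units: vessel area density (VAD, %), vessel length density
(VLD, %), total vessel length (mm), mean/median vessel diameter (μm),
mean/median vessel length (mm), mean tortuosity (dimensionless),
branchpoint density (nodes/mm), box-counting fractal dimension
(dimensionless, with a local-slope standard deviation), and the network
connectivity factor.  Everything is computed from the 2-D MIP-derived
mask, skeleton, thickness map and classified network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .errors import UndefinedMetricError
from .network import SkeletonMask, ThicknessMap, VesselNetwork
from .segmentation import BinaryMask, connectivity_factor

__all__ = [
    "vessel_area_density",
    "vessel_length_density",
    "total_vessel_length",
    "diameter_stats",
    "length_stats",
    "mean_tortuosity",
    "branchpoint_density",
    "fractal_dimension",
    "histogram",
    "histogram_modes",
    "MetricsReport",
    "compile_report",
]


def _denominator(shape: tuple[int, int], excluded: np.ndarray | None) -> int:
    total = shape[0] * shape[1]
    if excluded is not None:
        total -= int(excluded.sum())
    if total <= 0:
        raise UndefinedMetricError("all pixels excluded: density denominator is empty")
    return total


def vessel_area_density(mask: BinaryMask) -> float:
    """VAD (%): foreground fraction of the non-excluded pixels."""
    return 100.0 * int(mask.pixels.sum()) / _denominator(mask.shape, mask.excluded)


def vessel_length_density(skeleton: SkeletonMask) -> float:
    """VLD (%): skeleton-pixel fraction of the non-excluded pixels
    (each centerline pixel stands for a 1-px-diameter vessel)."""
    return 100.0 * int(skeleton.pixels.sum()) / _denominator(skeleton.shape, skeleton.excluded)


def total_vessel_length(table: pd.DataFrame) -> float:
    """Sum of per-element centerline arc lengths, in mm."""
    return float(table["arc_length_mm"].sum())


def histogram(values: np.ndarray, bin_width: float) -> dict:
    """Fixed-width histogram anchored at zero; returns edges + counts."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    hi = values.max() if values.size else bin_width
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


def histogram_modes(values: np.ndarray, bin_width: float, n_modes: int = 2) -> list[float]:
    """Locate the modes of a (possibly multi-modal) sample.

    Samples are split into ``n_modes`` groups by deterministic 1-D
    k-means (extreme-value initialization); each group's mode is the
    left edge of its most populated fixed-width bin.  Returned sorted
    ascending.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise UndefinedMetricError("no samples for mode estimation")
    cents = np.linspace(values.min(), values.max(), n_modes)
    for _ in range(200):
        assign = np.argmin(np.abs(values[:, None] - cents[None, :]), axis=1)
        new = np.array([values[assign == k].mean() if (assign == k).any() else cents[k]
                        for k in range(n_modes)])
        if np.allclose(new, cents):
            break
        cents = new
    modes = []
    for k in range(n_modes):
        sub = values[assign == k]
        if sub.size == 0:
            continue
        h = histogram(sub, bin_width)
        modes.append(h["bin_edges"][int(np.argmax(h["counts"]))])
    return sorted(modes)


def diameter_stats(table: pd.DataFrame, bin_um: float = 10.0) -> tuple[float, float, dict]:
    """Mean and median of the per-element mean diameters, plus histogram.

    Statistics are over elements (not pooled pixels): each element
    contributes its mean diameter over diameter-included centerline
    pixels.
    """
    d = table["mean_diameter_um"].dropna().to_numpy()
    if d.size == 0:
        raise UndefinedMetricError("no diameter samples")
    return float(d.mean()), float(np.median(d)), histogram(d, bin_um)


def length_stats(table: pd.DataFrame, bin_mm: float = 0.1) -> tuple[float, float, dict]:
    ls = table["arc_length_mm"].dropna().to_numpy()
    if ls.size == 0:
        raise UndefinedMetricError("no length samples")
    return float(ls.mean()), float(np.median(ls)), histogram(ls, bin_mm)


def mean_tortuosity(table: pd.DataFrame, bin_width: float = 0.05) -> tuple[float, dict]:
    """Mean of per-element tortuosity (L_s/L_c - 1), plus histogram."""
    t = table["tortuosity"].dropna().to_numpy()
    if t.size == 0:
        raise UndefinedMetricError("no elements with defined tortuosity")
    return float(t.mean()), histogram(t, bin_width)


def branchpoint_density(network: VesselNetwork, total_length_mm: float) -> float:
    """Nodes per mm of total vessel length."""
    if total_length_mm <= 0:
        raise UndefinedMetricError("branchpoint density undefined at zero total length")
    return len(network.nodes) / total_length_mm


def fractal_dimension(pixels: np.ndarray) -> tuple[float, float]:
    """Box-counting fractal dimension of a binary raster.

    Occupied boxes N(s) are counted on dyadic box sizes s = 2, 4, ...
    <= min(H, W)/4 with the grid origin fixed at (0, 0); FD is the
    least-squares slope of log N versus log(1/s), clipped to [0, 2],
    and the quoted spread is the standard deviation of the successive
    two-point local slopes.
    """
    fg = np.asarray(pixels, bool)
    if not fg.any():
        raise UndefinedMetricError("fractal dimension undefined on an empty mask")
    h, w = fg.shape
    sizes = []
    s = 2
    while s <= min(h, w) / 4:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        raise UndefinedMetricError("fewer than 3 usable box scales")
    counts = []
    for s in sizes:
        ph, pw = (-h) % s, (-w) % s
        padded = np.pad(fg, ((0, ph), (0, pw)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    logn = np.log(counts)
    logi = np.log(1.0 / np.asarray(sizes, float))
    fd = float(np.polyfit(logi, logn, 1)[0])
    local = np.diff(logn) / np.diff(logi)
    sd = float(np.std(local, ddof=1)) if len(local) > 1 else 0.0
    return float(np.clip(fd, 0.0, 2.0)), sd


@dataclass
class MetricsReport:
    """Compiled scalar metrics, histograms and provenance for one image.

    Any metric that is undefined for the input is recorded as
    ``{"value": None, "reason": ...}`` instead of a number.
    """

    source_id: str
    pixel_size_um: float
    metrics: dict
    histograms: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"source_id": self.source_id, "pixel_size_um": self.pixel_size_um,
                "metrics": self.metrics, "histograms": self.histograms,
                "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def flat_row(self) -> dict:
        """One flat row per image (scalar metrics only) for combined CSVs."""
        row = {"source_id": self.source_id, "pixel_size_um": self.pixel_size_um}
        for k, v in self.metrics.items():
            row[k] = v["value"] if isinstance(v, dict) else v
        return row


def compile_report(mask: BinaryMask, skeleton: SkeletonMask, thickness: ThicknessMap,
                   network: VesselNetwork, table: pd.DataFrame,
                   parameters: dict | None = None, source_id: str = "",
                   diameter_bin_um: float = 10.0, length_bin_mm: float = 0.1,
                   tortuosity_bin: float = 0.05) -> MetricsReport:
    """Assemble every metric into a single serializable report.

    Undefined metrics (e.g. on an empty or degenerate mask) are
    recorded with their reason; the report is always produced.
    """
    metrics: dict = {}
    histograms: dict = {}

    def put(name, fn):
        try:
            metrics[name] = {"value": fn()}
        except UndefinedMetricError as exc:
            metrics[name] = {"value": None, "reason": str(exc)}

    put("vad_pct", lambda: vessel_area_density(mask))
    put("vld_pct", lambda: vessel_length_density(skeleton))
    put("total_vessel_length_mm", lambda: total_vessel_length(table))

    try:
        mean_d, med_d, hist_d = diameter_stats(table, diameter_bin_um)
        metrics["mean_diameter_um"] = {"value": mean_d}
        metrics["median_diameter_um"] = {"value": med_d}
        histograms["diameter_um"] = hist_d
    except UndefinedMetricError as exc:
        metrics["mean_diameter_um"] = {"value": None, "reason": str(exc)}
        metrics["median_diameter_um"] = {"value": None, "reason": str(exc)}

    try:
        mean_l, med_l, hist_l = length_stats(table, length_bin_mm)
        metrics["mean_length_mm"] = {"value": mean_l}
        metrics["median_length_mm"] = {"value": med_l}
        histograms["length_mm"] = hist_l
    except UndefinedMetricError as exc:
        metrics["mean_length_mm"] = {"value": None, "reason": str(exc)}
        metrics["median_length_mm"] = {"value": None, "reason": str(exc)}

    try:
        mt, hist_t = mean_tortuosity(table, tortuosity_bin)
        metrics["mean_tortuosity"] = {"value": mt}
        histograms["tortuosity"] = hist_t
    except UndefinedMetricError as exc:
        metrics["mean_tortuosity"] = {"value": None, "reason": str(exc)}

    total_len = metrics["total_vessel_length_mm"]["value"] or 0.0
    put("branchpoint_density_per_mm", lambda: branchpoint_density(network, total_len))

    def fd():
        v, sd = fractal_dimension(mask.pixels)
        metrics["fractal_dimension_sd"] = {"value": sd}
        return v

    put("fractal_dimension", fd)
    if "fractal_dimension_sd" not in metrics:
        metrics["fractal_dimension_sd"] = {"value": None,
                                           "reason": metrics["fractal_dimension"].get("reason", "")}
    put("connectivity_factor", lambda: connectivity_factor(network))
    metrics["n_elements"] = {"value": len(network.elements)}
    metrics["n_nodes"] = {"value": len(network.nodes)}
    metrics["n_mesh_regions"] = {"value": len(network.mesh_regions)}

    prov = {"software": "octava", "version": __version__,
            "parameters": parameters or {}}
    return MetricsReport(source_id=source_id, pixel_size_um=mask.pixel_size_um,
                         metrics=metrics, histograms=histograms, provenance=prov)
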
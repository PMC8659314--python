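"""Rendered artifacts: network overlay and thickness heatmap.

Overlay palette: segments yellow, branches green, isolated elements
dark blue, mesh-region fill cyan (faint), nodes red circles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage as ndi
from skimage.draw import disk

from .network import VesselNetwork
from .preprocess import AngiogramImage

_KIND_COLORS = {
    "segment": (255, 255, 0),
    "branch": (0, 200, 0),
    "isolated": (40, 40, 160),
}
_NODE_COLOR = (255, 0, 0)
_MESH_COLOR = (0, 180, 180)


def overlay_image(image: AngiogramImage, network: VesselNetwork) -> np.ndarray:
    """Color-coded skeleton overlay on the grayscale image (uint8 RGB)."""
    base = (np.clip(image.pixels, 0, 1) * 180).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    h, w = image.shape

    # faint mesh fill: enclosed background components
    skel = np.zeros((h, w), bool)
    for e in network.elements:
        skel[e.path[:, 0], e.path[:, 1]] = True
    lab, n = ndi.label(~skel, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    border = set(np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
    mesh = ~np.isin(lab, list(border)) & (lab > 0)
    rgb[mesh] = (0.75 * rgb[mesh] + 0.25 * np.array(_MESH_COLOR)).astype(np.uint8)

    for e in network.elements:
        rgb[e.path[:, 0], e.path[:, 1]] = _KIND_COLORS[e.kind]
    for node in network.nodes:
        rr, cc = disk(node.centroid, max(2.0, node.radius_px or 2.0), shape=(h, w))
        ring = disk(node.centroid, max(1.0, (node.radius_px or 2.0) - 1.0), shape=(h, w))
        m = np.zeros((h, w), bool)
        m[rr, cc] = True
        m[ring] = False
        rgb[m] = _NODE_COLOR
    return rgb


def save_overlay(image: AngiogramImage, network: VesselNetwork, path: str | Path) -> Path:
    PILImage.fromarray(overlay_image(image, network)).save(path)
    return Path(path)


def save_mask(mask_pixels: np.ndarray, path: str | Path) -> Path:
    PILImage.fromarray(mask_pixels.astype(np.uint8) * 255).convert("1").save(path)
    return Path(path)


def save_thickness_heatmap(thickness, path: str | Path) -> Path:
    """Thickness heatmap PNG with a μm colorbar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    vals = np.ma.masked_where(thickness.values_um == 0, thickness.values_um)
    im = ax.imshow(vals, cmap="inferno")
    fig.colorbar(im, ax=ax, label="vessel diameter (μm)")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
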
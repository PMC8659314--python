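"""Single-image and batch analysis pipelines behind the CLI.

``run_single`` executes the full workflow on one image (enhance ->
segment -> skeletonize -> thickness -> classify -> metrics) and writes
the report plus rendered artifacts; ``run_batch`` applies identical
parameters to every image in a directory and produces one combined CSV
suitable as repeatability input.  All stages are deterministic: the
same image and configuration yield a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import DegenerateImageError, OctavaError
from .metrics import MetricsReport, compile_report
from .network import (
    apply_curation,
    classify_elements,
    detect_nodes,
    exclude_nodes_from_diametry,
    local_thickness,
    measure_vessels,
    skeletonize_mask,
)
from .preprocess import (
    AngiogramImage,
    FrangiParams,
    RoiSpec,
    frangi_enhance,
    load_angiogram,
    median_denoise,
    rescale_image,
    select_roi,
)
from .segmentation import SEGMENTERS, BinaryMask, segment

log = logging.getLogger("octava")


class FrangiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    sigma_min: float = 1.0
    sigma_max: float = 7.0
    n_scales: Optional[int] = None
    beta: float = 0.5
    c: Optional[float] = None

    def params(self) -> FrangiParams:
        return FrangiParams(sigma_min=self.sigma_min, sigma_max=self.sigma_max,
                            n_scales=self.n_scales, anisotropy_sensitivity=self.beta,
                            structureness_sensitivity=self.c)


class RoiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: str = "full"
    center: Optional[tuple[float, float]] = None
    height: Optional[int] = None
    width: Optional[int] = None
    radius: Optional[float] = None

    def spec(self) -> RoiSpec:
        return RoiSpec(shape=self.shape, center=self.center, height=self.height,
                       width=self.width, radius=self.radius)


class RunConfig(BaseModel):
    """Full parameter set of one analysis run; serialized into every
    report for reproducibility.  Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    pixel_size_um: float = Field(gt=0)
    roi: RoiConfig = RoiConfig()
    rescale_factor: float = 1.0
    median_kernel: int = 3
    frangi: FrangiConfig = FrangiConfig()
    segmenter: str = "fuzzy"
    adaptive_kernel_px: Optional[int] = None
    adaptive_offset: float = 0.0
    twig_size_px: int = 3
    diameter_bin_um: float = 10.0
    length_bin_mm: float = 0.1
    tortuosity_bin: float = 0.05
    curation_file: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _segment_kwargs(config: RunConfig) -> dict:
    if config.segmenter == "adaptive":
        return {"kernel_px": config.adaptive_kernel_px, "offset": config.adaptive_offset}
    return {}


def analyze_image(image: AngiogramImage, config: RunConfig):
    """Run the workflow in memory; returns (report, intermediates)."""
    t0 = time.perf_counter()
    if config.roi.shape != "full":
        image = select_roi(image, config.roi.spec())
    if config.rescale_factor != 1.0:
        image = rescale_image(image, config.rescale_factor)
    if config.median_kernel > 1:
        image = median_denoise(image, config.median_kernel)
    enhanced = frangi_enhance(image, config.frangi.params()) if config.frangi.enabled else image

    params = json.loads(config.model_dump_json())
    try:
        mask = segment(enhanced, config.segmenter, **_segment_kwargs(config))
    except DegenerateImageError as exc:
        log.warning("segmentation degenerate: %s", exc)
        mask = BinaryMask(enhanced.pixels > 1.0, image.pixel_size_um,
                          excluded=image.excluded, method=config.segmenter)
    import warnings as _warnings

    with _warnings.catch_warnings():
        if not mask.pixels.any():
            _warnings.simplefilter("ignore")  # empty-mask warning already logged above
        skeleton = skeletonize_mask(mask)
    thickness = local_thickness(mask)
    nodes = detect_nodes(skeleton)
    network = classify_elements(skeleton, nodes, thickness, twig_size_px=config.twig_size_px)
    network = exclude_nodes_from_diametry(network, thickness)
    if config.curation_file:
        network = apply_curation(network, config.curation_file)
    table = measure_vessels(network)
    report = compile_report(mask, skeleton, thickness, network, table,
                            parameters=params, source_id=image.source_id,
                            diameter_bin_um=config.diameter_bin_um,
                            length_bin_mm=config.length_bin_mm,
                            tortuosity_bin=config.tortuosity_bin)
    log.info("analyzed %s in %.2f s", image.source_id or "<image>", time.perf_counter() - t0)
    return report, {"image": image, "enhanced": enhanced, "mask": mask,
                    "skeleton": skeleton, "thickness": thickness,
                    "network": network, "table": table}


def run_single(input_path: str | Path, config: RunConfig, out_dir: str | Path,
               image: AngiogramImage | None = None) -> MetricsReport:
    """Analyze one image and write the full artifact set.

    Artifacts: report.json, report.csv (flat), vessels.csv, mask.png,
    overlay.png, thickness.png and histogram CSVs.
    """
    from .render import save_mask, save_overlay, save_thickness_heatmap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if image is None:
        image = load_angiogram(input_path, config.pixel_size_um)
    report, inter = analyze_image(image, config)
    (out_dir / "report.json").write_text(report.to_json())
    pd.DataFrame([report.flat_row()]).to_csv(out_dir / "report.csv", index=False)
    inter["table"].to_csv(out_dir / "vessels.csv", index=False)
    for name, hist in report.histograms.items():
        pd.DataFrame({"bin_left_edge": hist["bin_edges"][:-1],
                      "count": hist["counts"]}).to_csv(
            out_dir / f"histogram_{name}.csv", index=False)
    save_mask(inter["mask"].pixels, out_dir / "mask.png")
    save_overlay(inter["image"], inter["network"], out_dir / "overlay.png")
    save_thickness_heatmap(inter["thickness"], out_dir / "thickness.png")
    return report


def run_batch(input_dir: str | Path, config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Analyze every readable image in a directory with one parameter
    set; returns (and writes) the combined one-row-per-image CSV."""
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff", ".png"))
    if not paths:
        raise OctavaError(f"no readable images in {input_dir}")
    rows = []
    for p in paths:
        try:
            report = run_single(p, config, out_dir / p.stem)
            rows.append(report.flat_row())
        except Exception as exc:
            log.error("failed on %s: %s", p.name, exc)
    if not rows:
        raise OctavaError("all images failed")
    combined = pd.DataFrame(rows)
    combined.to_csv(out_dir / "combined.csv", index=False)
    return combined
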
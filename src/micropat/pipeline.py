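"""End-to-end runs: image -> ROI -> profile / regions / metrics -> CSV tables.

A run is driven by a :class:`RunConfig` in which every parameter has a
default, executes the requested stages in dependency order, and writes one
CSV per stage plus a JSON manifest recording the config, its hash, the
package version, input checksums and per-stage output paths.  Outputs carry
no timestamps, so a repeated run with the same inputs and config produces
byte-identical files.

Hypothesis testing is deliberately excluded: the pipeline emits tidy tables
ready for external statistics tools.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cells import (
    average_line_scans,
    contact_index,
    count_cells,
    junction_area_per_cell,
    line_scan,
)
from .errors import MicropatError, SchemaError, StageError
from .geometry import IslandROI, detect_island, to_polar
from .io import read_config, read_contours, read_image, write_table
from .quant import (
    estimate_background,
    fold_change,
    place_region_rois,
    quantify_regions,
    radial_profile,
)

log = logging.getLogger("micropat")

STAGES = ("profile", "regions", "contact", "count", "linescan", "junction_area")


@dataclass
class RunConfig:
    """Fully-defaulted configuration of one pipeline run.

    ``stages`` selects which analyses to perform; the island ROI is
    auto-detected unless ``roi_path`` supplies a manual one (which always
    wins).  All quantification parameters from the analysis modules appear
    here under the same names as their config keys.
    """

    image_path: str = ""
    roi_path: str | None = None
    contours_path: str | None = None
    segments_path: str | None = None
    output_dir: str = "micropat_out"
    stages: list[str] = field(default_factory=lambda: ["profile"])
    seed: int = 0
    # island detection
    min_area_fraction: float = 0.05
    smooth_sigma: float = 2.0
    circularity_cutoff: float = 0.85
    # radial profile
    n_bins: int = 50
    normalization: str = "raw"
    # region quantification
    n_rois: int = 5
    roi_side: float = 0.1
    center_r: float = 0.1
    edge_r: float = 0.85
    start_angle: float = 0.0
    background_mode: str = "none"  # "none" | "median_outside"
    # cell counting
    cell_diameter: float = 16.0
    threshold_k: float = 2.0
    # line scans
    linescan_width: int = 3
    linescan_samples: int = 41
    # junction area
    threshold_mode: str = "otsu"
    fixed_threshold: float | None = None
    band_halfwidth: float = 2.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(read_config(path))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest (also written).

    Any stage failure aborts the run with a :class:`StageError` naming the
    stage; outputs written before the failure are flagged in the manifest
    on disk as partial.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "micropat",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": {},
        "outputs": {},
        "warnings": [],
        "complete": False,
    }
    manifest_path = out / "manifest.json"

    def fail(stage, exc):
        manifest["warnings"].append(f"aborted in stage '{stage}': {exc}")
        _write_manifest(manifest, manifest_path)
        raise StageError(stage, exc) from exc

    # ---- inputs ----
    try:
        image = read_image(config.image_path)
        manifest["inputs"]["image"] = {
            "path": str(config.image_path),
            "sha256": _sha256(config.image_path),
        }
    except (OSError, MicropatError) as exc:
        fail("load", exc)

    contours = None
    if config.contours_path:
        try:
            contours = read_contours(config.contours_path)
            contours.validate_bounds(image.shape)
            manifest["inputs"]["contours"] = {
                "path": str(config.contours_path),
                "sha256": _sha256(config.contours_path),
            }
        except (OSError, MicropatError) as exc:
            fail("load", exc)

    # ---- ROI (manual overrides auto) ----
    t0 = time.perf_counter()
    try:
        if config.roi_path:
            with open(config.roi_path) as fh:
                roi = IslandROI.from_dict(json.load(fh))
            manifest["inputs"]["roi"] = {
                "path": str(config.roi_path),
                "sha256": _sha256(config.roi_path),
            }
        else:
            roi = detect_island(
                image,
                min_area_fraction=config.min_area_fraction,
                smooth_sigma=config.smooth_sigma,
                circularity_cutoff=config.circularity_cutoff,
            )
        roi_out = out / "island_roi.json"
        with open(roi_out, "w") as fh:
            json.dump(roi.to_dict(), fh, indent=1)
            fh.write("\n")
        manifest["outputs"]["island_roi"] = str(roi_out)
    except (OSError, MicropatError) as exc:
        fail("detect", exc)
    log.info("detect: %.3f s", time.perf_counter() - t0)

    background = 0.0
    if config.background_mode == "median_outside":
        background = estimate_background(image, roi)
        manifest["background"] = background

    # ---- stages ----
    for stage in config.stages:
        if stage not in STAGES:
            fail(stage, MicropatError(f"unknown stage {stage!r}"))
        t0 = time.perf_counter()
        try:
            if stage == "profile":
                polar = to_polar(image, roi)
                prof = radial_profile(
                    polar, n_bins=config.n_bins, normalization=config.normalization
                )
                path = out / "radial_profile.csv"
                prof.to_dataframe().to_csv(path, index=False, float_format="%.9g")
            elif stage == "regions":
                rqs = {}
                for region in ("center", "edge"):
                    squares = place_region_rois(
                        roi,
                        region,
                        n=config.n_rois,
                        roi_side=config.roi_side,
                        start_angle=config.start_angle,
                        center_r=config.center_r,
                        edge_r=config.edge_r,
                    )
                    rqs[region] = quantify_regions(image, squares, region=region)
                rows = [
                    {
                        "region": rq.region,
                        "roi_index": i,
                        "x": rq.roi_centers[i][0],
                        "y": rq.roi_centers[i][1],
                        "mean": m,
                    }
                    for rq in rqs.values()
                    for i, m in enumerate(rq.per_roi_mean)
                ]
                path = out / "region_quant.csv"
                write_table(rows, path)
                fc = fold_change(rqs["edge"], rqs["center"], background=background)
                fc_path = out / "fold_change.csv"
                write_table(
                    [
                        {
                            "edge_mean": rqs["edge"].region_mean,
                            "center_mean": rqs["center"].region_mean,
                            "background": background,
                            "fold_change": fc,
                        }
                    ],
                    fc_path,
                )
                manifest["outputs"]["fold_change"] = str(fc_path)
            elif stage == "contact":
                if contours is None or len(contours) < 2:
                    raise MicropatError("contact stage needs >= 2 contours")
                rows = []
                cl = contours.contours
                for i in range(len(cl)):
                    for j in range(i + 1, len(cl)):
                        res = contact_index(cl[i], cl[j])
                        rows.append(
                            {
                                "id_a": res.pair[0],
                                "id_b": res.pair[1],
                                "and_area": res.and_area,
                                "or_area": res.or_area,
                                "contact_index": res.index,
                            }
                        )
                path = out / "contact_index.csv"
                write_table(rows, path)
            elif stage == "count":
                res = count_cells(
                    image,
                    roi,
                    cell_diameter=config.cell_diameter,
                    threshold_k=config.threshold_k,
                )
                path = out / "cell_count.csv"
                write_table(
                    [
                        {
                            "count": res.count,
                            "density": res.density,
                            "density_units": res.density_units,
                        }
                    ],
                    path,
                )
            elif stage == "linescan":
                if not config.segments_path:
                    raise MicropatError("linescan stage needs segments_path")
                segs = pd.read_csv(config.segments_path)
                scans = [
                    line_scan(
                        image,
                        (row.x0, row.y0),
                        (row.x1, row.y1),
                        width=config.linescan_width,
                        n_samples=config.linescan_samples,
                    )
                    for row in segs.itertuples()
                ]
                prof = average_line_scans(scans)
                path = out / "line_scans.csv"
                prof.to_dataframe().to_csv(path, index=False, float_format="%.9g")
            else:  # junction_area
                if contours is None:
                    raise MicropatError("junction_area stage needs contours_path")
                df = junction_area_per_cell(
                    image,
                    contours,
                    threshold_mode=config.threshold_mode,
                    threshold=config.fixed_threshold,
                    band_halfwidth=config.band_halfwidth,
                )
                path = out / "junction_area.csv"
                df.to_csv(path, index=False, float_format="%.9g")
            manifest["outputs"][stage] = str(path)
        except (OSError, MicropatError) as exc:
            fail(stage, exc)
        log.info("%s: %.3f s", stage, time.perf_counter() - t0)

    manifest["complete"] = True
    _write_manifest(manifest, manifest_path)
    return manifest


def _write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def compare_conditions(
    manifest_paths: list, metric: str, labels: list[str] | None = None
) -> pd.DataFrame:
    """Stack one metric's per-micropattern values across conditions.

    ``metric`` names a stage output present in every manifest (e.g.
    ``fold_change``, ``regions``, ``contact``, ``count``).  Returns a tidy
    long-format table with a ``condition`` column; no hypothesis testing is
    performed.
    """
    if len(manifest_paths) < 2:
        raise SchemaError("compare_conditions needs >= 2 manifests")
    if labels is None:
        labels = [f"condition_{i}" for i in range(len(manifest_paths))]
    if len(labels) != len(manifest_paths):
        raise SchemaError("one label per manifest required")
    frames = []
    for label, mp in zip(labels, manifest_paths):
        with open(mp) as fh:
            man = json.load(fh)
        outputs = man.get("outputs", {})
        if metric not in outputs:
            raise SchemaError(
                f"metric {metric!r} absent from manifest {mp!s} "
                f"(has {sorted(outputs)})"
            )
        df = pd.read_csv(outputs[metric])
        df.insert(0, "condition", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
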
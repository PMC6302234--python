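"""End-to-end orchestration over a directory of tiles.

Stage order is fixed: threshold -> small-group filter -> pixel classes
-> nuclear phenotyping -> co-registration -> mask transfer -> densities
-> distances.  A tile failing one stage is excluded from the stages
downstream of it with a logged warning, never silently; the run
manifest records a terminal status per tile and checksums of every
output, so reruns on identical inputs can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import MarkerMask, PixelplexError
from .io import read_channel, write_mask, write_transform
from .masks import (
    MCM_MARKERS,
    MCM_MASK_MARKERS,
    ThresholdSpec,
    aggregate_case,
    decompose_pixel_classes,
    mask_class_breakdown,
    remove_small_groups,
    restrict_cd206,
    threshold_channel,
    union_masks,
)
from .phenotyping import DoughnutSpec, SegmentationSpec, phenotype_tile
from .registration import RegistrationError, RegistrationOptions, estimate_affine, transfer_mask
from .spatial import (
    BorderBandSpec,
    density_under_mask,
    distance_histogram,
    distance_map_um,
    find_border_nuclei,
    nearest_class_distance,
    tumor_stroma_ratio,
)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "make_report"]

log = logging.getLogger("pixelplex")

IF_CHANNEL_SET = ("DAPI",) + MCM_MARKERS
IHC_CHANNEL_SET = ("hematoxylin", "CD3", "HMW_CK", "LMW_CK")
CHANNEL_VOCABULARY = IF_CHANNEL_SET + IHC_CHANNEL_SET


class PipelineError(PixelplexError):
    pass


@dataclass
class PipelineConfig:
    """One YAML-loadable configuration driving a whole run.

    ``channels`` maps channel labels to file patterns with a ``{tile}``
    placeholder; tiles are discovered from the DAPI pattern.  Channels
    without a ``thresholds`` entry are binarized with Otsu's method.
    """

    case_id: str = "case"
    if_pixel_size_um: float = 0.3
    ihc_pixel_size_um: float = 0.5
    channels: dict[str, str] = field(
        default_factory=lambda: {ch: "{tile}_" + ch + ".tif" for ch in CHANNEL_VOCABULARY}
    )
    thresholds: dict[str, float | str] = field(default_factory=dict)
    min_group_size_px: int = 9
    connectivity: int = 8
    doughnut: DoughnutSpec = field(default_factory=DoughnutSpec)
    segmentation: SegmentationSpec = field(default_factory=SegmentationSpec)
    border_band_um: float = 10.0
    tumor_markers: tuple[str, ...] = ("HMW_CK", "LMW_CK")
    registration_per_case: bool = False
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.channels) - set(CHANNEL_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown channel labels in config: {sorted(unknown)}")
        if "DAPI" not in self.channels:
            raise ValueError("config must map the DAPI channel (used for tile discovery)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = raw[f.name]
        if "doughnut" in raw:
            kwargs["doughnut"] = DoughnutSpec(**raw["doughnut"])
        if "segmentation" in raw:
            kwargs["segmentation"] = SegmentationSpec(**raw["segmentation"])
        if "registration" in raw:
            kwargs["registration"] = RegistrationOptions(**raw["registration"])
        if "tumor_markers" in raw:
            kwargs["tumor_markers"] = tuple(raw["tumor_markers"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def threshold_spec(self, channel: str) -> ThresholdSpec:
        return ThresholdSpec(
            threshold=self.thresholds.get(channel, "otsu"),
            min_group_size_px=self.min_group_size_px,
            connectivity=self.connectivity,
        )


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    tile_status: dict[str, str]
    warnings: list[str]
    checksums: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _discover_tiles(config: PipelineConfig, tiles_dir: Path) -> list[str]:
    pattern = config.channels["DAPI"]
    prefix, suffix = pattern.split("{tile}")
    tiles = sorted(
        p.name[len(prefix) : len(p.name) - len(suffix)]
        for p in tiles_dir.glob(pattern.replace("{tile}", "*"))
    )
    return tiles


def run_pipeline(config: PipelineConfig, tiles_dir: str | Path, out_dir: str | Path) -> RunManifest:
    """Run every stage over every discovered tile.

    Raises :class:`PipelineError` when no tile completes any stage.
    """
    config.validate()
    tiles_dir, out = Path(tiles_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    tile_ids = _discover_tiles(config, tiles_dir)
    if not tile_ids:
        raise PipelineError(f"no tiles found in {tiles_dir} for pattern {config.channels['DAPI']}")

    warnings: list[str] = []
    status: dict[str, str] = {}
    class_tables = []
    anchor_tables: dict[str, list] = {"CD68": [], "CD163": []}
    # holds the case-wide transform when registration_per_case is set
    case_transform_holder: list = [None]

    for tile_id in tile_ids:
        tdir = out / "tiles" / tile_id
        tdir.mkdir(parents=True, exist_ok=True)
        try:
            _run_tile(config, tiles_dir, tdir, tile_id, warnings,
                      class_tables, anchor_tables, case_transform_holder)
            status[tile_id] = "complete"
        except PixelplexError as exc:
            warnings.append(f"{tile_id}: {exc}")
            status[tile_id] = f"failed: {exc}"
            log.warning("tile %s failed: %s", tile_id, exc)

    if not any(s == "complete" for s in status.values()):
        raise PipelineError("zero tiles completed the pipeline")

    case_dir = out / "case"
    case_dir.mkdir(exist_ok=True)
    if class_tables:
        summary = aggregate_case(class_tables, case_id=config.case_id)
        summary.stats.to_csv(case_dir / "class_summary.csv", index=False)
    for anchor, tabs in anchor_tables.items():
        if tabs:
            aggregate_case(tabs, case_id=config.case_id).stats.to_csv(
                case_dir / f"{anchor}_breakdown_summary.csv", index=False
            )

    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        tile_status=status,
        warnings=warnings,
        checksums=checksums,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _run_tile(
    config: PipelineConfig,
    tiles_dir: Path,
    tdir: Path,
    tile_id: str,
    warnings: list[str],
    class_tables: list,
    anchor_tables: dict[str, list],
    case_transform_holder: list,
) -> None:
    def _path(channel: str) -> Path:
        return tiles_dir / config.channels[channel].format(tile=tile_id)

    def _load(channel: str, ps: float):
        p = _path(channel)
        if not p.exists():
            return None
        return read_channel(p, ps, channel=channel, tile_id=tile_id)

    # ---- fluorescent side: masks and pixel classes -------------------
    if_ps = config.if_pixel_size_um
    dapi = _load("DAPI", if_ps)
    if dapi is None:
        raise PipelineError(f"missing DAPI channel for tile {tile_id}")
    marker_masks: dict[str, MarkerMask] = {}
    for m in MCM_MARKERS:
        img = _load(m, if_ps)
        if img is None:
            warnings.append(f"{tile_id}: missing channel {m}; treated as empty mask")
            marker_masks[m] = MarkerMask(
                pixels=np.zeros(dapi.shape, bool), pixel_size_um=if_ps,
                label=m, tile_id=tile_id)
            continue
        spec = config.threshold_spec(m)
        marker_masks[m] = remove_small_groups(threshold_channel(img, spec), spec)
    mcm = union_masks([marker_masks[m] for m in MCM_MASK_MARKERS])
    marker_masks["CD206"] = restrict_cd206(marker_masks["CD206"], mcm)
    for m, mask in marker_masks.items():
        write_mask(mask, tdir / f"{m}_mask.tif")
    write_mask(mcm, tdir / "MCM_mask.tif")

    table = decompose_pixel_classes(marker_masks, mcm)
    table.to_frame().to_csv(tdir / "pixel_classes.csv", index=False)
    class_tables.append(table)
    for anchor in anchor_tables:
        t = mask_class_breakdown(anchor, marker_masks)
        t.to_frame().to_csv(tdir / f"{anchor}_breakdown.csv", index=False)
        anchor_tables[anchor].append(t)

    # ---- nuclear phenotyping -----------------------------------------
    nuclei, nuclear_mask, cell_table = phenotype_tile(
        dapi, marker_masks, config.segmentation, config.doughnut
    )
    write_mask(nuclear_mask, tdir / "nuclear_mask.tif")
    cell_table.to_csv(tdir / "cells.csv", index=False)

    # ---- chromogenic side: registration and transferred masks --------
    ihc_ps = config.ihc_pixel_size_um
    hema = _load("hematoxylin", ihc_ps)
    tumor_if = cd3_if = covered = None
    if hema is None:
        warnings.append(f"{tile_id}: no hematoxylin channel; tumor/T-cell analyses skipped")
    else:
        transform = case_transform_holder[0]
        if transform is None:
            try:
                transform, quality = estimate_affine(hema, dapi, config.registration)
                write_transform(transform, tdir / "transform.json", ncc=quality.ncc)
                if config.registration_per_case:
                    case_transform_holder[0] = transform
            except RegistrationError as exc:
                warnings.append(f"{tile_id}: registration failed ({exc})")
                transform = None
        if transform is not None:
            ck_masks = []
            for m in config.tumor_markers:
                img = _load(m, ihc_ps)
                if img is not None:
                    spec = config.threshold_spec(m)
                    ck_masks.append(remove_small_groups(threshold_channel(img, spec), spec))
            if ck_masks:
                tumor_ihc = union_masks(ck_masks, label="tumor")
                tumor_if, covered = transfer_mask(tumor_ihc, transform, dapi.shape, if_ps)
                write_mask(tumor_if, tdir / "tumor_mask_if.tif")
                write_mask(covered, tdir / "covered_mask.tif")
            cd3_img = _load("CD3", ihc_ps)
            if cd3_img is None:
                warnings.append(f"{tile_id}: missing CD3 channel; T-cell analyses skipped")
            else:
                spec = config.threshold_spec("CD3")
                cd3_ihc = remove_small_groups(threshold_channel(cd3_img, spec), spec)
                cd3_if, _ = transfer_mask(cd3_ihc, transform, dapi.shape, if_ps)
                write_mask(cd3_if, tdir / "CD3_mask_if.tif")

    # ---- spatial statistics ------------------------------------------
    if tumor_if is not None:
        tissue = covered.with_label("tissue")
        rows = []
        for m in MCM_MASK_MARKERS:
            d_t = density_under_mask(marker_masks[m], tumor_if)
            stroma = MarkerMask(pixels=tissue.pixels & ~tumor_if.pixels,
                                pixel_size_um=if_ps, label="stroma", tile_id=tile_id)
            d_s = density_under_mask(marker_masks[m], stroma)
            d_cd3 = density_under_mask(marker_masks[m], cd3_if) if cd3_if is not None else None
            ratio = tumor_stroma_ratio(marker_masks[m], tumor_if, tissue)
            rows.append({
                "tile_id": tile_id, "marker": m,
                "density_tumor_fraction": d_t, "density_stroma_fraction": d_s,
                "density_CD3_fraction": d_cd3, "tumor_stroma_ratio": ratio,
                "tumor_px": tumor_if.positive_count, "stroma_px": stroma.positive_count,
            })
        pd.DataFrame(rows).to_csv(tdir / "densities.csv", index=False)

        border = find_border_nuclei(nuclei, tumor_if, BorderBandSpec(config.border_band_um))
        drows, hrows = [], []
        for m in MCM_MASK_MARKERS:
            dmap = distance_map_um(marker_masks[m])
            ds = [nearest_class_distance(n.centroid_px, marker_masks[m], _dmap=dmap)
                  for n in border]
            for n, d in zip(border, ds):
                drows.append({"tile_id": tile_id, "nucleus_id": n.nucleus_id,
                              "marker": m, "distance_um": d})
            hist = distance_histogram(ds, marker=m)
            hrows.append(hist.to_frame().assign(tile_id=tile_id,
                                                band_width_um=config.border_band_um))
        pd.DataFrame(drows).to_csv(tdir / "distances.csv", index=False)
        if hrows:
            pd.concat(hrows, ignore_index=True).to_csv(tdir / "distance_histograms.csv",
                                                       index=False)


def make_report(out_dir: str | Path, figures: bool = True) -> pd.DataFrame:
    """Summarize a finished run: case-level pie-chart fraction tables,
    density bars and distance histograms as CSV (and PNG figures).

    Returns the case-level class-fraction table; stages whose outputs
    are absent are listed in ``report/missing.txt``.
    """
    out = Path(out_dir)
    rep = out / "report"
    rep.mkdir(exist_ok=True)
    missing = []

    summary_path = out / "case" / "class_summary.csv"
    pie = pd.DataFrame()
    if summary_path.exists():
        pie = pd.read_csv(summary_path)
        pie.to_csv(rep / "pie_fractions.csv", index=False)
    else:
        missing.append("case/class_summary.csv")

    dens_files = sorted(out.glob("tiles/*/densities.csv"))
    if dens_files:
        dens = pd.concat([pd.read_csv(f) for f in dens_files], ignore_index=True)
        agg = dens.groupby("marker", sort=False).agg(
            mean_density_tumor_fraction=("density_tumor_fraction", "mean"),
            mean_density_stroma_fraction=("density_stroma_fraction", "mean"),
            mean_tumor_stroma_ratio=("tumor_stroma_ratio", "mean"),
            n_tiles=("tile_id", "nunique"),
        ).reset_index()
        agg.to_csv(rep / "density_summary.csv", index=False)
    else:
        missing.append("tiles/*/densities.csv")

    hist_files = sorted(out.glob("tiles/*/distance_histograms.csv"))
    if hist_files:
        hists = pd.concat([pd.read_csv(f) for f in hist_files], ignore_index=True)
        hists.to_csv(rep / "distance_histograms.csv", index=False)
        mean_d = hists.groupby("marker", sort=False)["mean_distance_um"].mean().reset_index()
        mean_d.to_csv(rep / "mean_distances.csv", index=False)
    else:
        missing.append("tiles/*/distance_histograms.csv")

    if figures:
        _report_figures(rep, pie)
    (rep / "missing.txt").write_text("\n".join(missing) + ("\n" if missing else ""))
    return pie


def _report_figures(rep: Path, pie: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(pie):
        shown = pie[pie["mean_percent"] > 0]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.pie(shown["mean_percent"], labels=shown["class_label"],
               autopct="%.1f%%", textprops={"fontsize": 7})
        ax.set_title("MC&M pixel classes (case mean, % of MC&M mask)")
        fig.savefig(rep / "pie_classes.png", dpi=150)
        plt.close(fig)
    dens_path = rep / "density_summary.csv"
    if dens_path.exists():
        dens = pd.read_csv(dens_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(dens))
        ax.bar(x - 0.2, dens["mean_density_tumor_fraction"], width=0.4, label="tumor")
        ax.bar(x + 0.2, dens["mean_density_stroma_fraction"], width=0.4, label="stroma")
        ax.set_xticks(x, dens["marker"])
        ax.set_ylabel("pixel density (fraction of region)")
        ax.legend()
        fig.savefig(rep / "density_bars.png", dpi=150)
        plt.close(fig)
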
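"""Reading and writing the package's on-disk formats.

Channels are single-channel TIFFs (16-bit fluorescent, 8-bit
chromogenic), masks are 8-bit TIFFs with 0/255 coding, transforms are
JSON, tables are CSV, configs are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import AffineTransform, ChannelImage, MarkerMask
from .synthetic import (
    AcquisitionSpec,
    MorphologySpec,
    NoiseSpec,
    PlacementSpec,
    SimulationConfig,
    SyntheticTile,
)

__all__ = [
    "read_channel",
    "write_channel",
    "read_mask",
    "write_mask",
    "read_transform",
    "write_transform",
    "load_simulation_config",
    "write_tile",
]


def read_channel(
    path: str | Path, pixel_size_um: float, channel: str = "", tile_id: str = ""
) -> ChannelImage:
    px = tifffile.imread(str(path))
    return ChannelImage(pixels=px, pixel_size_um=pixel_size_um,
                        channel=channel or Path(path).stem, tile_id=tile_id)


def write_channel(image: ChannelImage, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(image.pixels))


def read_mask(
    path: str | Path, pixel_size_um: float, label: str = "", tile_id: str = ""
) -> MarkerMask:
    px = tifffile.imread(str(path))
    return MarkerMask(pixels=px > 0, pixel_size_um=pixel_size_um,
                      label=label or Path(path).stem, tile_id=tile_id)


def write_mask(mask: MarkerMask, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))


def write_transform(transform: AffineTransform, path: str | Path, ncc: float | None = None) -> None:
    d = transform.to_dict()
    if ncc is not None:
        d["ncc"] = ncc
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(d, indent=2))


def read_transform(path: str | Path) -> AffineTransform:
    return AffineTransform.from_dict(json.loads(Path(path).read_text()))


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file; nested
    sections (morphology, placement, noise, acquisition) map onto the
    corresponding spec dataclasses, missing keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    simple = {
        f.name for f in dataclasses.fields(SimulationConfig)
        if f.name not in ("coexpression", "morphology", "placement", "noise", "acquisition")
    }
    for k, v in raw.items():
        if k in simple:
            kwargs[k] = v
    if "coexpression" in raw:
        kwargs["coexpression"] = raw["coexpression"]
    if "morphology" in raw:
        kwargs["morphology"] = {
            ct: MorphologySpec(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in mo.items()})
            for ct, mo in raw["morphology"].items()
        }
    if "placement" in raw:
        kwargs["placement"] = {ct: PlacementSpec(**pl) for ct, pl in raw["placement"].items()}
    if "noise" in raw:
        kwargs["noise"] = NoiseSpec(**raw["noise"])
    if "acquisition" in raw:
        acq = dict(raw["acquisition"])
        if "translation_um" in acq:
            acq["translation_um"] = tuple(acq["translation_um"])
        kwargs["acquisition"] = AcquisitionSpec(**acq)
    cfg = SimulationConfig(**kwargs)
    # YAML configs may override only some of the per-type dicts; fill gaps
    for name, default in (
        ("morphology", SimulationConfig().morphology),
        ("placement", SimulationConfig().placement),
        ("coexpression", SimulationConfig().coexpression),
    ):
        merged = dict(default)
        merged.update(getattr(cfg, name))
        setattr(cfg, name, merged)
    cfg.validate()
    return cfg


def write_tile(tile: SyntheticTile, outdir: str | Path) -> None:
    """Persist one synthetic tile: channel TIFFs, truth masks, the cell
    table (CSV), the ground-truth transform and a config echo (JSON)."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for ch, img in tile.if_channels.items():
        write_channel(img, out / f"{tile.tile_id}_{ch}.tif")
    for ch, img in tile.ihc_channels.items():
        write_channel(img, out / f"{tile.tile_id}_{ch}.tif")
    write_mask(tile.truth_tumor_mask, out / f"{tile.tile_id}_truth_tumor.tif")
    write_mask(tile.truth_nuclear_mask, out / f"{tile.tile_id}_truth_nuclei.tif")
    for m, mask in tile.truth_marker_masks.items():
        write_mask(mask, out / f"{tile.tile_id}_truth_{m}.tif")
    rows = []
    for i, cell in enumerate(tile.truth_cells):
        row = {
            "cell_id": i,
            "cell_type": cell.cell_type,
            "centroid_row_um": cell.centroid_um[0],
            "centroid_col_um": cell.centroid_um[1],
            "nuclear_radius_um": cell.nuclear_radius_um,
            "n_processes": len(cell.process_polylines),
            "nucleus_in_section": cell.nucleus_in_section,
            "soma_in_section": cell.soma_in_section,
        }
        for m, v in cell.marker_positivity.items():
            row[f"{m}_positive"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / f"{tile.tile_id}_truth_cells.csv", index=False)
    write_transform(tile.truth_transform, out / f"{tile.tile_id}_truth_transform.json")
    echo = dataclasses.asdict(tile.config)
    (out / f"{tile.tile_id}_config.json").write_text(json.dumps(echo, indent=2, default=str))
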
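"""Raster, tabular and config I/O.

Volumes and masks travel as OME-TIFF with physical voxel spacing recorded in
the OME pixels metadata; spot and measurement tables are plain CSV; configs
are JSON.  Channel identity is by declared name, never inferred from content.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError, ValidationError
from .grid import SPOT_COLUMNS, ImageVolume, SpotSet, StructureMask


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as a multi-channel OME-TIFF (axes CZYX)."""
    names = list(vol.channels)
    data = np.stack([vol.channels[n] for n in names], axis=0)
    sz, sy, sx = vol.spacing
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": sz,
            "PhysicalSizeY": sy,
            "PhysicalSizeX": sx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def _ome_spacing_and_names(tf: tifffile.TiffFile):
    """Pull (sz, sy, sx) and channel names out of OME metadata, if present."""
    if tf.ome_metadata is None:
        return None, None
    meta = tifffile.xml2dict(tf.ome_metadata)
    try:
        pixels = meta["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
    except (KeyError, TypeError):
        return None, None
    spacing = None
    if all(f"PhysicalSize{a}" in pixels for a in "ZYX"):
        spacing = tuple(float(pixels[f"PhysicalSize{a}"]) for a in "ZYX")
    names = None
    chan = pixels.get("Channel")
    if chan is not None:
        if isinstance(chan, dict):
            chan = [chan]
        if all(isinstance(c, dict) and "Name" in c for c in chan):
            names = [c["Name"] for c in chan]
    return spacing, names


def read_volume(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
) -> ImageVolume:
    """Read a TIFF/OME-TIFF stack into an :class:`ImageVolume`.

    ``channel_names`` declares the channel order; when omitted, OME channel
    names from the file are used, falling back to ``ch0..chN``.  Spacing comes
    from OME metadata unless overridden; a stack with neither raises
    :class:`ConfigurationError`.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = np.asarray(series.asarray())
        axes = series.axes
        meta_spacing, meta_names = _ome_spacing_and_names(tf)

    # normalise page/sample axes: plain multi-page TIFFs read as Q/S/I
    for alias in "SQI":
        axes = axes.replace(alias, "C" if "C" not in axes else "Z")
    if "C" not in axes:
        data = data[None]
        axes = "C" + axes
    if "Z" not in axes:
        data = np.expand_dims(data, axis=axes.index("C") + 1)
        axes = axes.replace("C", "CZ")
    if sorted(axes) != sorted("CZYX"):
        raise FormatError(f"unsupported TIFF axes {axes!r}; expected some order of CZYX")
    data = np.transpose(data, [axes.index(a) for a in "CZYX"])

    spacing = spacing_override or meta_spacing
    if spacing is None:
        raise ConfigurationError(
            f"{path}: no physical voxel spacing in metadata and no spacing_override given"
        )

    n_chan = data.shape[0]
    names = channel_names or meta_names or [f"ch{i}" for i in range(n_chan)]
    if len(names) != n_chan:
        raise FormatError(
            f"{path}: file has {n_chan} channels but {len(names)} names declared: {names}"
        )
    channels = {name: np.ascontiguousarray(data[i]) for i, name in enumerate(names)}
    return ImageVolume(channels=channels, spacing=tuple(float(s) for s in spacing))


def write_mask(mask: StructureMask, path: str | Path) -> None:
    """Store a binary structure mask losslessly as uint8 OME-TIFF."""
    vol = ImageVolume(channels={mask.name: mask.voxels.astype(np.uint8)}, spacing=mask.spacing)
    write_volume(vol, path)


def read_mask(path: str | Path, name: str | None = None) -> StructureMask:
    vol = read_volume(path)
    chan_name = name or next(iter(vol.channels))
    return StructureMask(chan_name, vol.channels[next(iter(vol.channels))] > 0, vol.spacing)


def read_spot_table(path: str | Path) -> SpotSet:
    """Read a spot CSV (columns id, x_um, y_um, z_um, radius_um, kind, ...)."""
    tab = pd.read_csv(path)
    missing = [c for c in SPOT_COLUMNS if c not in tab.columns]
    if missing:
        raise FormatError(f"{path}: spot table missing columns {missing}")
    try:
        return SpotSet(table=tab, source=str(path))
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err


def write_spot_table(spots: SpotSet, path: str | Path) -> None:
    ordered = list(SPOT_COLUMNS) + [c for c in spots.table.columns if c not in SPOT_COLUMNS]
    spots.table[ordered].to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        try:
            cfg = json.load(fh)
        except json.JSONDecodeError as err:
            raise ConfigurationError(f"{path}: invalid JSON ({err})") from err
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config root must be a JSON object")
    return cfg


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
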
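"""OME-TIFF reading/writing and sidecar metadata for simulated scenes.

Images travel as :class:`~laminq.simulate.ImageStack` objects — pixels in
``(channel, z, y, x)`` order with the pixel size in nanometres.  Thickness in
nm is meaningless without a pixel size, so :func:`read_stack` insists on one:
either from OME metadata or from an explicit override (override wins).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .simulate import GroundTruth, ImageStack, OpticsConfig, SceneConfig


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an OME-TIFF with CZYX axes, pixel-size metadata and channel names."""
    path = Path(path)
    size_um = stack.pixel_size / 1000.0
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeX": size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.pixels.shape[1] > 1 and stack.z_step > 0:
        metadata["PhysicalSizeZ"] = stack.z_step / 1000.0
        metadata["PhysicalSizeZUnit"] = "µm"
    if stack.provenance:
        metadata["Description"] = stack.provenance
    tifffile.imwrite(path, stack.pixels.astype(np.float32), ome=True, metadata=metadata)


def read_stack(path: str | Path, pixel_size_nm: Optional[float] = None) -> ImageStack:
    """Read a TIFF/OME-TIFF into the internal channel x z x y x x order.

    Pixel-size precedence: explicit ``pixel_size_nm`` argument, then OME
    ``PhysicalSizeX`` metadata; with neither, the read fails.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome_pixel_nm: Optional[float] = None
        z_step = 0.0
        channel_names: list[str] = []
        if tif.ome_metadata:
            meta = tifffile.xml2dict(tif.ome_metadata)
            try:
                px = meta["OME"]["Image"]["Pixels"]
            except (KeyError, TypeError):
                px = None
            if isinstance(px, dict):
                if "PhysicalSizeX" in px:
                    unit = px.get("PhysicalSizeXUnit", "µm")
                    scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "mm": 1e6}.get(unit)
                    if scale is not None:
                        ome_pixel_nm = float(px["PhysicalSizeX"]) * scale
                if "PhysicalSizeZ" in px:
                    z_step = float(px["PhysicalSizeZ"]) * 1000.0
                ch = px.get("Channel", [])
                if isinstance(ch, dict):
                    ch = [ch]
                channel_names = [c.get("Name", f"ch{i}") for i, c in enumerate(ch)]

    pixel_size = pixel_size_nm if pixel_size_nm is not None else ome_pixel_nm
    if pixel_size is None:
        raise ValueError(
            f"{path}: no pixel size in metadata; pass pixel_size_nm explicitly "
            "(thickness in nm is meaningless without it)"
        )

    # normalize axes to CZYX
    data = np.asarray(data)
    axes = axes.replace("S", "C")  # samples-per-pixel treated as channels
    for missing in "CZ":
        if missing not in axes:
            data = data[None]
            axes = missing + axes
    order = [axes.index(c) for c in "CZYX"]
    data = np.transpose(data, order)
    if not channel_names:
        channel_names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(
        pixels=data.astype(float),
        channel_names=channel_names[: data.shape[0]],
        pixel_size=float(pixel_size),
        z_step=z_step,
        provenance=str(path),
    )


def write_scene_sidecar(
    path: str | Path,
    scene: SceneConfig,
    optics: OpticsConfig,
    gt: GroundTruth,
    seed: int,
    true_r: Optional[float] = None,
) -> None:
    """JSON sidecar recording the full simulation parameters and ground truth."""
    payload = {
        "scene": {**scene.__dict__, "nucleus_semi_axes": list(scene.nucleus_semi_axes)},
        "optics": dict(optics.__dict__),
        "seed": seed,
        "ground_truth": {
            "true_thickness_nm": gt.true_thickness,
            "shared_fraction": gt.shared_fraction,
            "radial_offset_nm": gt.radial_offset,
            "true_pearson": true_r,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
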
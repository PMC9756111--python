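"""File formats: calibrated kymogram TIFFs, CSV tables, JSON configs."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Kymogram", "read_image_stack", "write_image_stack",
           "load_config", "dump_config"]

BP_PER_NM = 1.0 / 0.34  # 1 bp of B-DNA spans 0.34 nm


@dataclass
class Kymogram:
    """Channel x time x position intensity array with physical calibration.

    ``pixel_size`` is um/px along the DNA axis, ``frame_interval`` s per
    scan line.  Axis order is (channel, time, position), matching how
    ImageJ displays multi-channel kymographs.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: tuple = ()
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("kymogram data must be (channel, time, position)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """Pixel-center positions in um."""
        return (np.arange(self.data.shape[2]) + 0.0) * self.pixel_size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) * self.frame_interval


def write_image_stack(kymo: Kymogram, path) -> None:
    """Write a kymogram as TIFF with the calibration embedded in the image
    description (JSON), so it reads back without a sidecar."""
    meta = {
        "axes": "CTX",
        "pixel_size_um": kymo.pixel_size,
        "frame_interval_s": kymo.frame_interval,
        "channel_names": list(kymo.channel_names),
    }
    tifffile.imwrite(path, kymo.data.astype(np.float32),
                     description=json.dumps(meta))


def read_image_stack(path) -> Kymogram:
    """Read a kymogram TIFF, taking calibration from the embedded JSON
    description or, failing that, from a ``<path>.json`` sidecar.

    A missing calibration raises (the physical scale cannot be guessed);
    an implausible axis order (more than 8 "channels") is flagged.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = None
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = None
    if not isinstance(meta, dict) or "pixel_size_um" not in meta:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            raise ValueError(
                f"{path} carries no calibration; provide a {sidecar.name} "
                "sidecar with pixel_size_um and frame_interval_s"
            )
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] > 8:
        warnings.warn(
            f"first axis has length {data.shape[0]}; expected few channels "
            "(axis order should be channel, time, position)", stacklevel=2,
        )
    return Kymogram(
        data,
        float(meta["pixel_size_um"]),
        float(meta["frame_interval_s"]),
        tuple(meta.get("channel_names", ())),
    )


def load_config(path) -> dict:
    return json.loads(Path(path).read_text())


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
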
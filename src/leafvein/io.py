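"""Reading and writing capture stacks, maps and masks.

Frames are 8/16-bit integer TIFF or PNG, scaled to [0, 1] on read (255 or
65535 maps to 1.0).  Float maps are written as 32-bit float TIFF; binary
masks as 8-bit PNG (0/255), which round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .photometric import LightRig, PSStack

__all__ = [
    "read_lights",
    "write_lights",
    "read_frame",
    "write_frame_u16",
    "read_stack",
    "write_stack",
    "write_float_map",
    "read_float_map",
    "write_mask",
    "read_mask",
]

FRAME_NAMES = "light_{i}.tif"
AMBIENT_NAME = "ambient.tif"


def read_lights(path) -> LightRig:
    """Load a light rig from a YAML file with a ``lights`` list of vectors."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return LightRig(np.asarray(data["lights"], dtype=np.float64))


def write_lights(rig: LightRig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"lights": rig.vectors.tolist()}, fh)


def read_frame(path) -> np.ndarray:
    """Read one greyscale frame, scaling integer dtypes to [0, 1]."""
    img = iio.imread(path)
    if img.ndim == 3:  # collapse accidental RGB
        img = img.mean(axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / np.iinfo(img.dtype).max
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def write_frame_u16(frame: np.ndarray, path) -> None:
    """Write a [0, 1] frame as 16-bit TIFF."""
    data = np.clip(np.asarray(frame), 0.0, 1.0)
    tifffile.imwrite(str(path), np.round(data * 65535).astype(np.uint16))


def read_stack(stack_dir, lights_path=None) -> PSStack:
    """Read a capture directory (``light_*.tif`` + ``ambient.tif``).

    The light rig comes from ``lights_path`` or ``lights.yaml`` inside the
    directory; the frame count must match the number of light vectors.
    """
    stack_dir = Path(stack_dir)
    lights_path = lights_path or stack_dir / "lights.yaml"
    rig = read_lights(lights_path)
    frame_paths = sorted(stack_dir.glob("light_*.tif"))
    if len(frame_paths) != len(rig):
        raise ValueError(
            f"{len(frame_paths)} frames in {stack_dir} but "
            f"{len(rig)} light vectors"
        )
    frames = np.stack([read_frame(p) for p in frame_paths])
    ambient = read_frame(stack_dir / AMBIENT_NAME)
    return PSStack(frames=frames, ambient=ambient, lights=rig)


def write_stack(stack: PSStack, out_dir, sidecar: dict | None = None) -> None:
    """Write frames as 16-bit TIFF plus the light rig and a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        write_frame_u16(frame, out_dir / FRAME_NAMES.format(i=i))
    write_frame_u16(stack.ambient, out_dir / AMBIENT_NAME)
    write_lights(stack.lights, out_dir / "lights.yaml")
    if sidecar is not None:
        with open(out_dir / "capture.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)


def write_float_map(arr: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32))


def read_float_map(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 0
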
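"""Volume and image readers/writers shared by all modules.

Volumes are accepted as MetaImage (.mhd/.mha), NIfTI (.nii/.nii.gz) or a
raw binary file with a JSON sidecar; header spacing and origin are honoured.
On disk the fastest-varying axis conventions differ between formats, so all
readers normalise to the package convention: ``data[i, j, k]`` along world
(x, y, z).  Radiographs are 8-bit PNG or 16-bit TIFF grayscale; colour
inputs are rejected rather than silently converted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk

from .drr import Image2D, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
    "setup_logging",
]

logger = logging.getLogger(__name__)

_SITK_SUFFIXES = (".mhd", ".mha", ".nii", ".nii.gz")


def _has_suffix(path: Path, suffixes) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in suffixes)


def read_volume(path) -> Volume:
    """Read a volume, honouring header spacing and origin.

    MetaImage and NIfTI go through SimpleITK (arrays come back as [z, y, x]
    and are transposed to the package's [x, y, z] order).  A ``.raw`` file
    is read with its JSON sidecar (same stem, ``.json``) holding ``shape``
    (x, y, z), ``dtype``, ``spacing`` and ``origin``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if _has_suffix(path, _SITK_SUFFIXES):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
        spacing = np.array(img.GetSpacing(), dtype=float)
        origin = np.array(img.GetOrigin(), dtype=float)
        if spacing.min() != spacing.max():
            logger.info("volume %s has anisotropic spacing %s", path.name, spacing)
        return Volume(data=data, spacing=spacing, origin=origin)
    if path.suffix.lower() == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw volume {path} needs a JSON sidecar at {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(int(s) for s in meta["shape"])
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(shape)
        return Volume(
            data=data.astype(np.float64),
            spacing=np.asarray(meta.get("spacing", (1.0, 1.0, 1.0)), dtype=float),
            origin=np.asarray(meta.get("origin", (0.0, 0.0, 0.0)), dtype=float),
        )
    raise ValueError(f"unsupported volume format: {path.name} (expected .mhd/.mha/.nii/.nii.gz/.raw)")


def write_volume(volume: Volume, path) -> None:
    """Write a volume as MetaImage or NIfTI (chosen by extension)."""
    path = Path(path)
    if not _has_suffix(path, _SITK_SUFFIXES):
        raise ValueError(f"unsupported volume format for writing: {path.name}")
    img = sitk.GetImageFromArray(volume.data.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_image(path, pixel_spacing: float = 1.0) -> Image2D:
    """Read an 8- or 16-bit grayscale radiograph (PNG/TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-channel grayscale image, got shape {arr.shape}")
    return Image2D(pixels=arr.astype(np.float64), pixel_spacing=pixel_spacing)


def write_image(image: Image2D, path, bit_depth: int = 8) -> None:
    """Write an image as 8-bit PNG or 16-bit TIFF.

    Pixel values are clipped to the target range; the [0, 255] grayscale
    range is rescaled for 16-bit output.
    """
    path = Path(path)
    if bit_depth == 8:
        arr = np.clip(np.round(image.pixels), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.clip(np.round(image.pixels * (65535.0 / 255.0)), 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"bit depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(path, arr)


def setup_logging(level=logging.INFO) -> None:
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")
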
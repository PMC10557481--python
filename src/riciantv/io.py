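"""Image reading/writing with a uniform 0-255 float intensity convention.

All model constants (the noise levels sigma in {5, 15, 25}, the PSNR peak
255^2, the SSIM stabilizers) assume intensities on a 0-255 scale, so every
image is mapped to that scale on read regardless of storage depth:

* 8-bit PNG/TIFF: identity mapping;
* 16-bit TIFF/PNG: linear rescale by 255/65535 (the factor is returned in
  the metadata so writes can invert it losslessly up to quantization);
* NIfTI volumes: a named slice along the last axis, rescaled from the
  volume's own max to 255 (factor recorded).

Writes quantize back to the requested bit depth.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]

_U16_SCALE = 255.0 / 65535.0


def read_image(path: str | Path, slice_index: int | None = None,
               to_gray: bool = False) -> tuple[np.ndarray, dict]:
    """Read a PNG/TIFF image or one NIfTI slice as float 0-255.

    Returns ``(image, meta)`` where ``meta`` records the source dtype and
    the linear factor applied, so ``write_image`` can restore the original
    scale.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if vol.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI volume, got shape {vol.shape}")
        if slice_index is None:
            slice_index = vol.shape[-1] // 2
        img = vol[..., slice_index]
        peak = float(vol.max()) or 1.0
        return img * (255.0 / peak), {"format": "nifti", "scale": 255.0 / peak,
                                      "slice": slice_index}

    arr = iio.imread(path)
    if arr.ndim == 3:
        if not to_gray:
            raise ValueError(
                f"{path.name} is not grayscale; pass to_gray to convert")
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(float), {"format": suffix, "dtype": "uint8", "scale": 1.0}
    if arr.dtype == np.uint16:
        return arr.astype(float) * _U16_SCALE, {"format": suffix,
                                                "dtype": "uint16",
                                                "scale": _U16_SCALE}
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path.name}; "
                     "8- or 16-bit grayscale expected")


def write_image(path: str | Path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write a float 0-255 image as 8- or 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    img = np.clip(np.asarray(img, dtype=float), 0.0, 255.0)
    if bit_depth == 8:
        iio.imwrite(path, np.rint(img).astype(np.uint8))
    elif bit_depth == 16:
        iio.imwrite(path, np.rint(img / _U16_SCALE).astype(np.uint16))
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}; use 8 or 16")
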
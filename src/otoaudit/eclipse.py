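"""Counterfactual occlusion: parametric elliptical masking.

The *eclipse extent* ``e`` is the ratio of the occluding ellipse's axes to
the image's dimensions: 0 leaves the image untouched, 1 blacks out the
inscribed ellipse (leaving only the corners visible). Training and
evaluating a classifier on eclipsed copies of a dataset probes whether its
performance rests on the clinically relevant centre of the image or on
peripheral artifacts — a classifier that stays accurate at extent 1.0 is,
by construction, reading something other than the occluded anatomy.
"""
from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .data_model import Manifest, as_raster, load_image, save_image

__all__ = ["eclipse_mask", "apply_eclipse", "eclipse_dataset"]


def eclipse_mask(shape: tuple[int, int], extent: float) -> np.ndarray:
    """Boolean (H, W) grid of pixels occluded at the given extent.

    A pixel is masked iff its centre satisfies
    ``((x - cx)/a)**2 + ((y - cy)/b)**2 <= 1`` with semi-axes
    ``a = extent*W/2``, ``b = extent*H/2`` and centre
    ``cx = (W-1)/2``, ``cy = (H-1)/2`` (inclusive boundary).
    """
    if not 0.0 <= extent <= 1.0:
        raise ValueError(f"eclipse extent must be in [0, 1], got {extent}")
    H, W = shape
    if extent == 0.0:
        return np.zeros((H, W), dtype=bool)
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    a, b = extent * W / 2.0, extent * H / 2.0
    y = (np.arange(H) - cy) / b
    x = (np.arange(W) - cx) / a
    return (y[:, None] ** 2 + x[None, :] ** 2) <= 1.0


def apply_eclipse(image: np.ndarray, extent: float) -> np.ndarray:
    """Black out the central ellipse at the given extent; extent 0 is identity."""
    img = as_raster(image)
    mask = eclipse_mask(img.shape[:2], extent)
    out = img.copy()
    out[mask] = 0
    return out


def eclipse_dataset(
    manifest: Manifest, extent: float, out_dir: str | Path
) -> Manifest:
    """Write an eclipsed PNG copy of every image; labels and splits unchanged."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for r in manifest.records:
        try:
            img = load_image(r.path)
        except OSError as exc:
            raise OSError(f"record {r.image_id!r}: {exc}") from exc
        out_path = out_dir / f"{r.image_id}.png"
        save_image(apply_eclipse(img, extent), out_path)
        records.append(replace(r, path=str(out_path)))
    return Manifest(records=tuple(records), dataset_id=manifest.dataset_id)
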
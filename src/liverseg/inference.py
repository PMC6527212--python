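"""Whole-volume prediction and per-voxel majority-vote fusion.

Each orientation model segments the volume slice by slice: every 2D slice
is reflect-padded by the model's context radius (plus the few pixels
needed to reach a grid size that tiles through the stride-2 stages) and
passed through the network, optionally in tiles that stitch exactly
because all convolutions are valid. The three hard per-orientation masks
are fused by a per-voxel majority vote (foreground iff at least two of the
three models agree); no morphological postprocessing is applied by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import (ImageVolume, MaskVolume, VolumeGeometry,
                         normalize_intensity, resample_isotropic,
                         resample_mask_to_geometry)
from .model import UNet2D, orientation_axis, ORIENTATIONS


@dataclass
class SegmentationResult:
    per_orientation_masks: dict[str, MaskVolume]
    fused_mask: MaskVolume
    fused_mask_original: MaskVolume
    working_geometry: VolumeGeometry
    original_geometry: VolumeGeometry


def _reflect_pad2d(arr: np.ndarray, pads) -> np.ndarray:
    """np.pad reflect, chunked so pads may exceed the array size."""
    (pt, pb), (pl, pr) = pads
    out = arr
    while pt or pb or pl or pr:
        h, w = out.shape
        t, b = min(pt, h - 1), min(pb, h - 1)
        l, r = min(pl, w - 1), min(pr, w - 1)
        out = np.pad(out, ((t, b), (l, r)), mode="reflect")
        pt -= t; pb -= b; pl -= l; pr -= r
    return out


def _predict_slice(model: UNet2D, slice2d: np.ndarray,
                   tile: int | None = None) -> np.ndarray:
    """Hard binary prediction for one 2D slice, full coverage.

    With ``tile`` set, the output plane is processed in tile×tile label
    windows whose input windows overlap by the context radius; valid-mode
    stitching makes the result identical to the untiled pass.
    """
    h, w = slice2d.shape
    rf = model.receptive_field
    pad = (rf - 1) // 2

    in_h = model.next_valid_input(h + rf - 1)
    in_w = model.next_valid_input(w + rf - 1)
    extra_h = in_h - (h + rf - 1)
    extra_w = in_w - (w + rf - 1)
    padded = _reflect_pad2d(slice2d, ((pad, pad + extra_h), (pad, pad + extra_w)))

    out_h, out_w = in_h - (rf - 1), in_w - (rf - 1)
    if tile is None:
        probs = model.predict_proba(padded[None, None])[0]
        return (probs[:h, :w] >= 0.5).astype(np.uint8)

    out = np.zeros((out_h, out_w))
    for top in range(0, out_h, tile):
        for left in range(0, out_w, tile):
            th = min(tile, out_h - top)
            tw = min(tile, out_w - left)
            ih = model.next_valid_input(th + rf - 1)
            iw = model.next_valid_input(tw + rf - 1)
            # grow the label window to match the valid input, cropping back after
            gh, gw = ih - (rf - 1), iw - (rf - 1)
            t0 = min(top, out_h - gh)
            l0 = min(left, out_w - gw)
            if t0 < 0 or l0 < 0:
                raise ValueError(f"tile {tile} too large for slice {h}x{w}")
            window = padded[t0:t0 + ih, l0:l0 + iw]
            probs = model.predict_proba(window[None, None])[0]
            out[top:top + th, left:left + tw] = \
                probs[top - t0:top - t0 + th, left - l0:left - l0 + tw]
    return (out[:h, :w] >= 0.5).astype(np.uint8)


def predict_orientation(model: UNet2D, vol: ImageVolume, orientation: str,
                        tile: int | None = None,
                        batch_slices: int = 8) -> MaskVolume:
    """Slice-wise hard segmentation of a preprocessed volume along one
    orientation."""
    axis = orientation_axis(orientation, vol.geometry)
    n_slices = vol.voxels.shape[axis]
    out = np.zeros(vol.voxels.shape, dtype=np.uint8)

    if tile is not None:
        for i in range(n_slices):
            sl = np.take(vol.voxels, i, axis=axis)
            _put_slice(out, _predict_slice(model, sl, tile=tile), i, axis)
        return MaskVolume(out, vol.geometry)

    # batch equally-shaped padded slices for throughput
    sl0 = np.take(vol.voxels, 0, axis=axis)
    h, w = sl0.shape
    rf = model.receptive_field
    pad = (rf - 1) // 2
    in_h = model.next_valid_input(h + rf - 1)
    in_w = model.next_valid_input(w + rf - 1)
    extra_h = in_h - (h + rf - 1)
    extra_w = in_w - (w + rf - 1)
    padded = np.empty((n_slices, 1, in_h, in_w))
    for i in range(n_slices):
        sl = np.take(vol.voxels, i, axis=axis)
        padded[i, 0] = _reflect_pad2d(sl, ((pad, pad + extra_h), (pad, pad + extra_w)))
    for start in range(0, n_slices, batch_slices):
        probs = model.predict_proba(padded[start:start + batch_slices])
        hard = (probs[:, :h, :w] >= 0.5).astype(np.uint8)
        for k in range(hard.shape[0]):
            _put_slice(out, hard[k], start + k, axis)
    return MaskVolume(out, vol.geometry)


def _put_slice(vol: np.ndarray, slice2d: np.ndarray, index: int, axis: int) -> None:
    sl = [slice(None)] * 3
    sl[axis] = index
    vol[tuple(sl)] = slice2d


def majority_vote(m1: MaskVolume, m2: MaskVolume, m3: MaskVolume) -> MaskVolume:
    """Per-voxel fusion: foreground iff at least 2 of the 3 masks agree."""
    for other in (m2, m3):
        if other.voxels.shape != m1.voxels.shape or \
                not np.allclose(other.geometry.spacing_mm, m1.geometry.spacing_mm):
            raise ValueError("majority vote requires identical geometry")
    votes = (m1.voxels.astype(np.int16) + m2.voxels.astype(np.int16)
             + m3.voxels.astype(np.int16))
    return MaskVolume(votes >= 2, m1.geometry)


def segment(models: dict[str, UNet2D], raw: ImageVolume,
            target_mm: float = 2.0, tile: int | None = None,
            largest_component: bool = False) -> SegmentationResult:
    """Full pipeline: resample to isotropic spacing, normalize, predict in
    the three orthogonal orientations, fuse by majority vote, and map the
    fused mask back onto the original grid for reporting.

    ``largest_component`` optionally keeps only the largest 6-connected
    fused component (off by default).
    """
    missing = [o for o in ORIENTATIONS if o not in models]
    if missing:
        raise ValueError(f"missing orientation models: {missing}")
    work = normalize_intensity(resample_isotropic(raw, target_mm))
    per = {o: predict_orientation(models[o], work, o, tile=tile) for o in ORIENTATIONS}
    fused = majority_vote(per["axial"], per["coronal"], per["sagittal"])
    if largest_component:
        structure = ndimage.generate_binary_structure(3, 1)
        labels, n = ndimage.label(fused.voxels, structure=structure)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            fused = MaskVolume(labels == 1 + int(np.argmax(sizes)), fused.geometry)
    fused_orig = resample_mask_to_geometry(fused, raw.geometry, raw.voxels.shape)
    return SegmentationResult(per_orientation_masks=per, fused_mask=fused,
                              fused_mask_original=fused_orig,
                              working_geometry=work.geometry,
                              original_geometry=raw.geometry)
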
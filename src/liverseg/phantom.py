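"""Synthetic abdominal phantom generator.

Produces contrast-enhanced-MR-like volumes: a bright, non-convex liver blob
(union of overlapping ellipsoids with a smooth random deformation),
hypo-intense lesions some of which sit on the organ boundary, and separate
bright confounder structures mimicking adjacent organs of similar intensity.
Observer behaviour is simulated by perturbing the reference mask through its
signed distance field: a uniform offset realizes a target volume bias, and
spatially correlated (Gaussian-smoothed) noise displaces the boundary.

Every output is a pure function of its configuration and seed, so cohorts
are bit-reproducible from a manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import ImageVolume, MaskVolume, VolumeGeometry, write_volume

# pre-normalization intensities (arbitrary units)
BACKGROUND_INTENSITY = 0.2
LIVER_INTENSITY = 0.7
LESION_INTENSITY = 0.4
CONFOUNDER_INTENSITY = 0.65


class PhantomConfigError(ValueError):
    """Invalid phantom configuration; message names the offending field."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic abdominal volume.

    Defaults emulate a 1500 ml liver (adult total liver volume) on a
    2 mm isotropic grid, with a couple of lesions (half touching the
    surface) and two adjacent similar-intensity confounders.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    liver_volume_ml: float = 1500.0
    lesion_count: int = 2
    lesion_boundary_fraction: float = 0.5
    confounder_count: int = 2
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise PhantomConfigError(f"grid_shape: all dims must be >= 16, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise PhantomConfigError(f"spacing_mm: all values must be > 0, got {self.spacing_mm}")
        if self.liver_volume_ml <= 0:
            raise PhantomConfigError(f"liver_volume_ml: must be > 0, got {self.liver_volume_ml}")
        if self.lesion_count < 0:
            raise PhantomConfigError(f"lesion_count: must be >= 0, got {self.lesion_count}")
        if not 0.0 <= self.lesion_boundary_fraction <= 1.0:
            raise PhantomConfigError(
                f"lesion_boundary_fraction: must be in [0, 1], got {self.lesion_boundary_fraction}")
        if self.confounder_count < 0:
            raise PhantomConfigError(f"confounder_count: must be >= 0, got {self.confounder_count}")
        if self.noise_sigma < 0:
            raise PhantomConfigError(f"noise_sigma: must be >= 0, got {self.noise_sigma}")


@dataclass(frozen=True)
class ObserverProfile:
    """Volume bias (signed %) and correlated boundary noise scale (mm) of a
    simulated observer."""

    volume_bias_pct: float = 0.0
    boundary_noise_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.boundary_noise_mm < 0:
            raise PhantomConfigError(
                f"boundary_noise_mm: must be >= 0, got {self.boundary_noise_mm}")


def _world_grid(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _liver_field(config: PhantomConfig, rng: np.random.Generator, axis_scale: float):
    """Smooth scalar field whose >1 superlevel set is the liver shape."""
    shape = np.asarray(config.grid_shape)
    spacing = np.asarray(config.spacing_mm, dtype=float)
    extent = shape * spacing
    center = extent / 2.0
    gx, gy, gz = _world_grid(config.grid_shape, spacing)

    n_ellipsoids = int(rng.integers(2, 5))
    field = np.zeros(config.grid_shape, dtype=np.float64)
    base_semi = extent * np.array([0.28, 0.24, 0.30]) * axis_scale
    for _ in range(n_ellipsoids):
        c = center + (rng.uniform(-0.10, 0.10, 3)) * extent
        semi = base_semi * rng.uniform(0.6, 1.0, 3)
        q = (((gx - c[0]) / semi[0]) ** 2
             + ((gy - c[1]) / semi[1]) ** 2
             + ((gz - c[2]) / semi[2]) ** 2)
        # smooth bump per ellipsoid; union realized by the max
        field = np.maximum(field, np.exp(1.0 - q))

    # smooth random deformation of the level-set field
    noise = rng.standard_normal(config.grid_shape)
    noise = ndimage.gaussian_filter(noise, sigma=6.0 / spacing)
    field *= 1.0 + 0.10 * noise
    return field


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _calibrated_liver_mask(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Liver mask with volume calibrated to liver_volume_ml by iso-level
    bisection on the single-component (largest, hole-filled) shape."""
    voxel_ml = float(np.prod(config.spacing_mm)) / 1000.0
    target_vox = config.liver_volume_ml / voxel_ml

    def shape_at(field, t):
        return ndimage.binary_fill_holes(_largest_component(field > t))

    scale = 1.0
    for _ in range(4):
        sub_rng = np.random.Generator(np.random.PCG64(config.seed))
        field = _liver_field(config, sub_rng, scale)
        lo, hi = 0.05, float(field.max())
        for _ in range(40):
            t = 0.5 * (lo + hi)
            if shape_at(field, t).sum() > target_vox:
                lo = t
            else:
                hi = t
        mask = shape_at(field, 0.5 * (lo + hi))
        err = mask.sum() / target_vox
        if 0.97 < err < 1.03:
            break
        scale *= err ** (-1.0 / 3.0)
    return mask


def generate_phantom(config: PhantomConfig) -> tuple[ImageVolume, MaskVolume]:
    """Generate one synthetic abdominal volume and its reference liver mask.

    The mask volume lands within a few percent of ``liver_volume_ml``.
    Lesions are hypo-intense inclusions inside the liver (the mask keeps
    them as foreground, as clinical liver volumes include tumours);
    confounders are bright structures disjoint from the liver.
    """
    config.validate()
    geom = VolumeGeometry(spacing_mm=tuple(float(s) for s in config.spacing_mm))
    rng = np.random.Generator(np.random.PCG64(config.seed))
    liver = _calibrated_liver_mask(config, rng)
    # burn the shape rng state identically regardless of calibration iterations
    rng = np.random.Generator(np.random.PCG64((config.seed, 1)))

    spacing = np.asarray(config.spacing_mm, dtype=float)
    image = np.full(config.grid_shape, BACKGROUND_INTENSITY, dtype=np.float64)
    image[liver] = LIVER_INTENSITY

    dist_in = ndimage.distance_transform_edt(liver, sampling=spacing)
    coords_in = np.argwhere(liver)
    if coords_in.size:
        liver_extent_mm = dist_in.max()
        n_boundary = int(round(config.lesion_count * config.lesion_boundary_fraction))
        for i in range(config.lesion_count):
            radius = rng.uniform(0.05, 0.12) * max(liver_extent_mm, 6.0) + 4.0
            on_boundary = i < n_boundary
            if on_boundary:
                cand = coords_in[(dist_in[tuple(coords_in.T)] < radius * 0.8)]
            else:
                cand = coords_in[(dist_in[tuple(coords_in.T)] > radius)]
            if len(cand) == 0:
                cand = coords_in
            c = cand[rng.integers(len(cand))] * spacing
            gx, gy, gz = _world_grid(config.grid_shape, spacing)
            ball = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) <= radius ** 2
            image[ball & liver] = LESION_INTENSITY

    outside_dist = ndimage.distance_transform_edt(~liver, sampling=spacing)
    for _ in range(config.confounder_count):
        radius = rng.uniform(8.0, 16.0)
        shell = (outside_dist > radius * 0.3) & (outside_dist < radius * 1.5)
        cand = np.argwhere(shell)
        if len(cand) == 0:
            cand = np.argwhere(~liver)
        c = cand[rng.integers(len(cand))] * spacing
        gx, gy, gz = _world_grid(config.grid_shape, spacing)
        ball = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) <= radius ** 2
        image[ball & ~liver] = CONFOUNDER_INTENSITY

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, config.grid_shape)

    return (ImageVolume(image.astype(np.float32), geom), MaskVolume(liver, geom))


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed distance in mm, positive inside the mask."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def simulate_observer_mask(reference: MaskVolume, profile: ObserverProfile) -> MaskVolume:
    """Perturb a reference mask the way a human observer would.

    The reference's signed distance field is shifted by a uniform offset
    chosen so the noiseless volume matches ``(1 + volume_bias_pct/100)``
    times the reference volume, then displaced by zero-mean spatially
    correlated noise of scale ``boundary_noise_mm``. A profile of zero bias
    and zero noise returns the reference unchanged.
    """
    profile.validate()
    ref = reference.voxels.astype(bool)
    if not ref.any():
        raise ValueError("reference mask is empty")
    if profile.volume_bias_pct == 0.0 and profile.boundary_noise_mm == 0.0:
        return MaskVolume(ref.copy(), reference.geometry)

    spacing = np.asarray(reference.geometry.spacing_mm, dtype=float)
    sdf = _signed_distance_mm(ref, spacing)
    # voxel-center distances are quantized (min step = spacing); smoothing
    # spreads the level sets so the offset bisection resolves sub-voxel
    # volume changes
    sdf = ndimage.gaussian_filter(sdf, sigma=2.0 / spacing)

    offset = 0.0
    if profile.volume_bias_pct != 0.0:
        target = ref.sum() * (1.0 + profile.volume_bias_pct / 100.0)
        lo, hi = -float(np.abs(sdf).max()), float(np.abs(sdf).max())
        for _ in range(60):
            offset = 0.5 * (lo + hi)
            v = int((sdf + offset > 0).sum())
            if v < target:
                lo = offset
            else:
                hi = offset
        offset = 0.5 * (lo + hi)

    noise = np.zeros_like(sdf)
    if profile.boundary_noise_mm > 0:
        rng = np.random.Generator(np.random.PCG64(profile.seed))
        white = rng.standard_normal(ref.shape)
        smooth = ndimage.gaussian_filter(white, sigma=8.0 / spacing)
        sd = smooth.std()
        if sd > 0:
            noise = smooth / sd * profile.boundary_noise_mm

    out = sdf + offset + noise > 0
    if not out.any():  # extreme shrinkage: keep at least the deepest voxel
        out[np.unravel_index(np.argmax(sdf), sdf.shape)] = True
    return MaskVolume(out, reference.geometry)


def build_cohort(n_cases: int, phantom_config: PhantomConfig,
                 profiles: list[ObserverProfile], out_dir: str | Path) -> Path:
    """Write a reproducible multi-observer phantom cohort to disk.

    For each case: the image, the reference mask, and one simulated mask
    per observer profile, all as ``.nii.gz``, plus a ``manifest.csv`` with
    columns ``case_id, role, observer_id, path, seed``. Case and observer
    seeds are derived deterministically from the configured seeds, so the
    cohort can be rebuilt bit-identically from the manifest.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out_dir} is not writable: {exc}") from exc

    rows = []
    for case in range(n_cases):
        case_id = f"case{case:03d}"
        case_seed = int((phantom_config.seed * 100003 + case * 9973) % (2 ** 31))
        cfg = PhantomConfig(**{**phantom_config.__dict__, "seed": case_seed})
        image, ref = generate_phantom(cfg)
        img_path = out_dir / f"{case_id}_image.nii.gz"
        ref_path = out_dir / f"{case_id}_reference.nii.gz"
        write_volume(image, img_path)
        write_volume(ref, ref_path)
        rows.append([case_id, "image", "", img_path.name, case_seed])
        rows.append([case_id, "reference", "", ref_path.name, case_seed])
        for obs, profile in enumerate(profiles):
            obs_id = f"obs{obs}"
            obs_seed = int((profile.seed * 7919 + case_seed * 13 + obs) % (2 ** 31))
            prof = ObserverProfile(volume_bias_pct=profile.volume_bias_pct,
                                   boundary_noise_mm=profile.boundary_noise_mm,
                                   seed=obs_seed)
            obs_mask = simulate_observer_mask(ref, prof)
            obs_path = out_dir / f"{case_id}_{obs_id}.nii.gz"
            write_volume(obs_mask, obs_path)
            rows.append([case_id, "observer", obs_id, obs_path.name, obs_seed])

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "role", "observer_id", "path", "seed"])
        writer.writerows(rows)
    return manifest
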
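"""Seeded synthetic scenes: sparse nuclei-like blobs on a dark background.

Scenes emulate the geometry of plate-based Hoechst (nuclei) screens — a
696 x 520 16-bit frame with bright nuclei on a nearly constant background.
Each nucleus is a sharp-edged disk with a few bright internal speckles
(chromatin-like texture).  The sharp envelope edge and sub-pixel-to-pixel
scale texture are essential, not cosmetic: they are the features defocus
blur destroys first, and they break the scale/amplitude degeneracy that
makes the defocus depth of a smooth Gaussian blob of unknown width and
brightness fundamentally ambiguous.  Together with :mod:`focusqc.optics`
this provides labeled patch datasets without downloading any external
image collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .optics import (OpticalParams, SensorModel, UINT16_MAX,
                     generate_defocus_stack)

__all__ = ["SceneSpec", "LabeledPatchSet", "make_scene", "make_dataset"]

PATCH_SIZE = 84


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic in-focus scene.

    Blob radii are nucleus (disk) radii in pixels; peaks are counts above
    the background.  ``edge_width`` is the 10-90% width of the disk edge in
    pixels (sub-pixel: the envelope is sharp at the camera's resolution).
    ``foreground_fraction_target`` is the intended fraction of pixels
    inside blob support, used only as a sanity target.
    """

    height: int = 520
    width: int = 696
    blob_count_range: tuple[int, int] = (25, 45)
    blob_radius_range: tuple[float, float] = (5.0, 9.0)
    blob_peak_range: tuple[float, float] = (3000.0, 30000.0)
    edge_width: float = 0.7
    speckles_per_blob: tuple[int, int] = (3, 7)
    background_offset: float = 100.0
    foreground_fraction_target: float = 0.015

    def __post_init__(self) -> None:
        if self.height < 2 * PATCH_SIZE or self.width < 2 * PATCH_SIZE:
            raise ValueError(
                f"scene must be at least {2 * PATCH_SIZE} px per side")
        for name in ("blob_count_range", "blob_radius_range",
                     "blob_peak_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")


@dataclass
class LabeledPatchSet:
    """Synthetic labeled examples for training or evaluation.

    patches : (n, 84, 84) float array of 16-bit-range counts
    labels : (n,) int defocus level per patch, in [0, n_levels)
    foreground_flags : (n,) bool, True when the patch intersects a blob
    scene_ids : (n,) int, originating scene of each patch
    """

    patches: np.ndarray
    labels: np.ndarray
    foreground_flags: np.ndarray
    scene_ids: np.ndarray
    seed: int | None = None
    n_levels: int = 11

    def __post_init__(self) -> None:
        n = len(self.patches)
        if not (len(self.labels) == len(self.foreground_flags)
                == len(self.scene_ids) == n):
            raise ValueError("field lengths disagree")
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_levels):
            raise ValueError("labels out of [0, n_levels)")

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, mask: np.ndarray) -> "LabeledPatchSet":
        return LabeledPatchSet(self.patches[mask], self.labels[mask],
                               self.foreground_flags[mask],
                               self.scene_ids[mask], self.seed, self.n_levels)


def make_scene(spec: SceneSpec,
               seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one in-focus scene and its foreground mask.

    Each blob is a sharp-edged disk (smoothstep edge of width
    ``edge_width``) carrying a few bright Gaussian speckles as internal
    texture, at a uniformly random position; the mask marks pixels inside
    any disk.  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    image = np.full((spec.height, spec.width), spec.background_offset,
                    dtype=np.float64)
    mask = np.zeros(image.shape, dtype=bool)
    lo, hi = spec.blob_count_range
    count = int(rng.integers(lo, hi + 1))
    for _ in range(count):
        cy = rng.uniform(0, spec.height)
        cx = rng.uniform(0, spec.width)
        radius = rng.uniform(*spec.blob_radius_range)
        peak = rng.uniform(*spec.blob_peak_range)
        # local bounding window keeps rendering O(blob area)
        pad = int(np.ceil(radius + 4))
        y0, y1 = max(0, int(cy) - pad), min(spec.height, int(cy) + pad + 1)
        x0, x1 = max(0, int(cx) - pad), min(spec.width, int(cx) + pad + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None]
        xx = np.arange(x0, x1)[None, :]
        d = np.hypot(yy - cy, xx - cx)
        # smoothstep from 1 inside to 0 outside across edge_width
        t = np.clip((radius - d) / spec.edge_width + 0.5, 0.0, 1.0)
        envelope = t * t * (3.0 - 2.0 * t)
        body = 0.6 * peak * envelope
        n_speck = int(rng.integers(spec.speckles_per_blob[0],
                                   spec.speckles_per_blob[1] + 1))
        for _ in range(n_speck):
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius * 0.7 * np.sqrt(rng.uniform())
            sy, sx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            s_sigma = rng.uniform(0.8, 1.5)
            s_amp = peak * rng.uniform(0.3, 0.8)
            d2s = (yy - sy) ** 2 + (xx - sx) ** 2
            body = body + s_amp * np.exp(-0.5 * d2s / s_sigma**2) * envelope
        image[y0:y1, x0:x1] += body
        mask[y0:y1, x0:x1] |= d <= radius
    if count:
        frac = mask.mean()
        tgt = spec.foreground_fraction_target
        if not (0.1 * tgt <= frac <= 10 * tgt):
            warnings.warn(
                f"foreground fraction {frac:.4f} far from target {tgt:.4f}",
                UserWarning, stacklevel=2)
    return np.clip(image, 0.0, UINT16_MAX), mask


def _random_patches(rng: np.random.Generator, stack, mask, scene_id,
                    patches_per_image):
    patches, labels, fg, sid = [], [], [], []
    h, w = mask.shape
    for image, level in stack:
        for _ in range(patches_per_image):
            r = int(rng.integers(0, h - PATCH_SIZE + 1))
            c = int(rng.integers(0, w - PATCH_SIZE + 1))
            patches.append(image[r:r + PATCH_SIZE, c:c + PATCH_SIZE])
            labels.append(level)
            fg.append(bool(mask[r:r + PATCH_SIZE, c:c + PATCH_SIZE].any()))
            sid.append(scene_id)
    return patches, labels, fg, sid


def make_dataset(n_scenes: int, spec: SceneSpec, params: OpticalParams,
                 sensor: SensorModel, patches_per_image: int,
                 seed: int) -> tuple[LabeledPatchSet, LabeledPatchSet]:
    """Generate disjoint train/test labeled patch sets.

    Scenes are split 50/50 by scene id before any patch extraction, so no
    scene contributes to both splits (the analogue of holding out imaging
    sites).  Each scene is expanded into an ``n_levels`` defocus stack and
    ``patches_per_image`` random 84 x 84 crops are taken per stack member,
    labeled with the member's defocus level.
    """
    if n_scenes < 2:
        raise ValueError("need at least 2 scenes to form disjoint splits")
    if spec.height < PATCH_SIZE or spec.width < PATCH_SIZE:
        raise ValueError("patch larger than scene")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_scenes)
    train_ids = set(order[: n_scenes // 2].tolist())

    buckets = {True: ([], [], [], []), False: ([], [], [], [])}
    for scene_id in range(n_scenes):
        scene, mask = make_scene(spec, rng)
        stack = generate_defocus_stack(scene, params, sensor, rng)
        out = _random_patches(rng, stack, mask, scene_id, patches_per_image)
        dest = buckets[scene_id in train_ids]
        for acc, new in zip(dest, out):
            acc.extend(new)

    def build(b):
        p, l, f, s = b
        return LabeledPatchSet(
            np.asarray(p, dtype=np.float64), np.asarray(l, dtype=np.int64),
            np.asarray(f, dtype=bool), np.asarray(s, dtype=np.int64),
            seed=seed, n_levels=params.n_levels)

    return build(buckets[True]), build(buckets[False])
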
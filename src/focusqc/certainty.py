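"""Prediction certainty and whole-image aggregation.

A patch prediction is a distribution over N ordered defocus levels.  Its
certainty is one minus the Shannon entropy normalized by log N:

    certainty = 1 - H(p) / log N,   H(p) = -sum_i p_i log p_i

so a uniform distribution (no information) scores 0 and a one-hot
distribution scores 1.  Certainty measures only the peakedness of the
distribution — it is invariant to permuting the levels and carries no
ordinal information.

The whole-image distribution is the certainty-weighted average of the patch
distributions, which lets confident foreground patches dominate while
near-uniform background patches contribute almost nothing.  The aggregate
certainty is the certainty of that averaged distribution; comparing it with
the plain mean of patch certainties separates images that are confidently
consistent from those that are confidently contradictory.
"""

from __future__ import annotations

import colorsys
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PatchPrediction", "WholeImagePrediction", "certainty_of",
    "aggregate_image", "annotate_image", "certainty_scatter",
    "prediction_montage", "level_color",
]


def certainty_of(dist: np.ndarray, tol: float = 1e-5) -> float:
    """Normalized-entropy certainty of a class distribution, in [0, 1]."""
    p = np.asarray(dist, dtype=np.float64)
    if p.ndim != 1 or np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise ValueError("input is not a normalized probability vector")
    p = np.clip(p, 0.0, None)
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))  # 0 log 0 := 0
    return float(np.clip(1.0 - h / np.log(p.size), 0.0, 1.0))


@dataclass(frozen=True)
class PatchPrediction:
    """One patch's focus call: grid position, distribution, level, certainty."""

    row: int
    col: int
    distribution: np.ndarray
    predicted_level: int
    certainty: float

    @classmethod
    def from_distribution(cls, dist: np.ndarray, row: int = 0,
                          col: int = 0) -> "PatchPrediction":
        dist = np.asarray(dist, dtype=np.float64)
        return cls(row=row, col=col, distribution=dist,
                   predicted_level=int(np.argmax(dist)),
                   certainty=certainty_of(dist))


@dataclass(frozen=True)
class WholeImagePrediction:
    """Certainty-weighted aggregate over all patches of one image."""

    aggregate_distribution: np.ndarray
    aggregate_certainty: float
    mean_certainty: float
    predicted_level: int


def aggregate_image(patch_preds: list[PatchPrediction]) -> WholeImagePrediction:
    """Certainty-weighted average of patch distributions.

    Patches with zero certainty (uniform output, typically background with
    nothing to focus on) get zero weight.  If every patch has zero
    certainty the unweighted mean is used, with a warning, since the
    weighted average is then 0/0.
    """
    if not patch_preds:
        raise ValueError("need at least one patch prediction")
    dists = np.stack([p.distribution for p in patch_preds])
    certs = np.array([p.certainty for p in patch_preds])
    total = certs.sum()
    if total == 0.0:
        warnings.warn("all patch certainties are zero; falling back to "
                      "unweighted mean", UserWarning, stacklevel=2)
        agg = dists.mean(axis=0)
    else:
        agg = (certs[:, None] * dists).sum(axis=0) / total
    agg = agg / agg.sum()
    return WholeImagePrediction(
        aggregate_distribution=agg,
        aggregate_certainty=certainty_of(agg),
        mean_certainty=float(certs.mean()),
        predicted_level=int(np.argmax(agg)),
    )


def level_color(level: int, certainty: float, n_levels: int = 11
                ) -> tuple[float, float, float]:
    """RGB border color: hue encodes level (0 = red), lightness certainty."""
    if not 0 <= level < n_levels:
        raise ValueError(f"level {level} out of range")
    hue = level / n_levels
    return colorsys.hsv_to_rgb(hue, 1.0, float(np.clip(certainty, 0.0, 1.0)))


def annotate_image(image: np.ndarray, patch_preds: list[PatchPrediction],
                   patch_size: int = 84, border: int = 3,
                   n_levels: int = 11) -> np.ndarray:
    """Render a grayscale image to RGB with colored patch borders.

    Each patch gets a border drawn on its own perimeter pixels: hue from a
    fixed 11-entry palette indexed by predicted level (level 0 anchored at
    red), lightness linear in certainty.  Returns a float RGB array in
    [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    h, w = img.shape
    for p in patch_preds:
        r0, c0 = p.row * patch_size, p.col * patch_size
        r1, c1 = r0 + patch_size, c0 + patch_size
        if r1 > h or c1 > w or r0 < 0 or c0 < 0:
            raise ValueError(f"patch grid position ({p.row}, {p.col}) "
                             f"out of bounds for image {img.shape}")
        color = level_color(p.predicted_level, p.certainty, n_levels)
        rgb[r0:r0 + border, c0:c1] = color
        rgb[r1 - border:r1, c0:c1] = color
        rgb[r0:r1, c0:c0 + border] = color
        rgb[r0:r1, c1 - border:c1] = color
    return rgb


def certainty_scatter(preds: list[WholeImagePrediction],
                      ax=None) -> pd.DataFrame:
    """Mean-vs-aggregate certainty table, one row per image.

    Optionally draws the scatter on ``ax`` with points colored by the
    predicted-level hue.
    """
    if not preds:
        raise ValueError("need at least one image prediction")
    df = pd.DataFrame({
        "mean_certainty": [p.mean_certainty for p in preds],
        "aggregate_certainty": [p.aggregate_certainty for p in preds],
        "predicted_level": [p.predicted_level for p in preds],
    })
    if ax is not None:
        n = int(df["predicted_level"].max()) + 1
        colors = [level_color(l, 1.0, max(n, 11))
                  for l in df["predicted_level"]]
        ax.scatter(df["mean_certainty"], df["aggregate_certainty"],
                   c=colors, alpha=0.6, s=12)
        ax.set_xlabel("mean certainty")
        ax.set_ylabel("aggregate certainty")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    return df


def certainty_bin(certainty: float, n_bins: int = 10) -> int:
    """Bin index for a certainty in [0, 1]; the last bin is right-closed."""
    return min(int(certainty * n_bins), n_bins - 1)


def prediction_montage(patches: list[np.ndarray],
                       patch_preds: list[PatchPrediction],
                       n_certainty_bins: int = 10, n_levels: int = 11,
                       patch_size: int = 84
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Level x certainty-bin montage of sample patch predictions.

    For each (predicted level, certainty bin) cell the first matching patch
    is rendered with its border annotation; unoccupied cells stay blank.
    Returns the RGB montage (n_levels rows, n_certainty_bins columns of
    patches) and the boolean occupancy grid.
    """
    if len(patches) != len(patch_preds) or not patches:
        raise ValueError("need equally many patches and predictions (>= 1)")
    occupancy = np.zeros((n_levels, n_certainty_bins), dtype=bool)
    montage = np.zeros((n_levels * patch_size,
                        n_certainty_bins * patch_size, 3))
    for patch, pred in zip(patches, patch_preds):
        b = certainty_bin(pred.certainty, n_certainty_bins)
        lvl = pred.predicted_level
        if occupancy[lvl, b]:
            continue
        occupancy[lvl, b] = True
        cell = annotate_image(
            patch, [PatchPrediction(0, 0, pred.distribution,
                                    pred.predicted_level, pred.certainty)],
            patch_size=patch_size, n_levels=n_levels)
        montage[lvl * patch_size:(lvl + 1) * patch_size,
                b * patch_size:(b + 1) * patch_size] = cell
    return montage, occupancy
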
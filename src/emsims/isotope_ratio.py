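"""Per-pixel and per-ROI ^15N/^14N quantification.

A nanoSIMS acquisition yields two co-registered ion-count images per field,
the ^12C^14N ("old" nitrogen) and ^12C^15N ("new" nitrogen) channels. The
turnover readout is the ratio R = C15/C14, computed per pixel for display
and as a ratio of summed counts over a region of interest for statistics:

    R_ROI = (sum of C15 counts) / (sum of C14 counts)

The ratio of sums is the maximum-likelihood estimate of a common ratio under
Poisson counting statistics and weights pixels by their information content;
the mean of per-pixel ratios is offered as a flagged alternative for
sensitivity analyses only.

Display images follow the HSI convention: the ratio is scaled by 1e4 and
clamped to [37, 2500], where 37 corresponds to the natural ^15N abundance of
0.37% and 2500 saturates strongly labeled structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "IonImagePair",
    "RatioMap",
    "DisplayConfig",
    "DisplayImage",
    "RoiRatio",
    "UndefinedRatioError",
    "NATURAL_15N_RATIO",
    "ratio_map",
    "display_image",
    "roi_ratio",
    "whole_area_ratio",
    "ratio_of_sums_se",
    "save_display",
]

#: Natural ^15N/^14N abundance ratio (0.37%), the unlabeled baseline.
NATURAL_15N_RATIO = 0.0037

#: Pixel sizes the instrument geometry produces (nm); outside -> warning.
PIXEL_SIZE_RANGE_NM = (20.0, 43.0)


class UndefinedRatioError(ValueError):
    """An ROI whose ^14N count sum is zero has no defined ratio."""


@dataclass
class IonImagePair:
    """Two simultaneously acquired ion-count channels plus metadata.

    Attributes
    ----------
    c14, c15 : 2-D integer arrays
        ^12C^14N and ^12C^15N counts; identical shapes, non-negative.
    pixel_size_nm : float
        Physical pixel pitch. Values outside the instrument's usual
        20-43 nm window trigger a warning but are accepted.
    metadata : dict
        Free-form acquisition metadata (field size, dwell time, seed, ...).
    """

    c14: np.ndarray
    c15: np.ndarray
    pixel_size_nm: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c14 = np.asarray(self.c14)
        self.c15 = np.asarray(self.c15)
        if self.c14.shape != self.c15.shape or self.c14.ndim != 2:
            raise ValueError("c14 and c15 must be 2-D arrays of identical shape")
        if (self.c14 < 0).any() or (self.c15 < 0).any():
            raise ValueError("ion counts must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        lo, hi = PIXEL_SIZE_RANGE_NM
        if not lo <= self.pixel_size_nm <= hi:
            warnings.warn(
                f"pixel size {self.pixel_size_nm:.1f} nm outside the usual "
                f"[{lo:.0f}, {hi:.0f}] nm acquisition window",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.c14.shape


@dataclass
class RatioMap:
    """Per-pixel ^15N/^14N ratio with a validity mask.

    ``valid`` is false where the ^14N count is zero; no substitute value is
    invented for those pixels (``ratio`` holds 0 there but must not be read).
    """

    ratio: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.ratio.shape != self.valid.shape:
            raise ValueError("ratio and valid must have identical shapes")

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


@dataclass(frozen=True)
class DisplayConfig:
    """HSI display convention: scale to per-10^4 units, then clamp.

    The defaults reproduce the published convention: a scale factor of 1e4
    maps the natural abundance 0.0037 to the lower clamp 37; the upper clamp
    2500 saturates ratios >= 0.25.
    """

    scale_factor: float = 1e4
    lower_clamp: float = 37.0
    upper_clamp: float = 2500.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if not self.lower_clamp < self.upper_clamp:
            raise ValueError("lower_clamp must be below upper_clamp")


@dataclass
class DisplayImage:
    """A clamped display grid plus the count of invalid pixels rendered
    at the lower clamp."""

    values: np.ndarray
    n_invalid: int
    config: DisplayConfig


@dataclass(frozen=True)
class RoiRatio:
    """Ratio-of-sums over an ROI with the sums kept for error propagation."""

    ratio: float
    sum15: int
    sum14: int
    n_pixels: int
    n_invalid: int
    method: str = "ratio_of_sums"

    @property
    def se(self) -> float:
        """Delta-method standard error of the ratio (plug-in Poisson)."""
        return ratio_of_sums_se(self.sum15, self.sum14)


def ratio_map(pair: IonImagePair) -> RatioMap:
    """Compute the per-pixel ratio image R = C15/C14.

    Pixels with zero ^14N counts are flagged invalid; an all-invalid map is
    legal (callers inspect ``n_invalid``).
    """
    c14 = pair.c14.astype(float)
    valid = pair.c14 > 0
    ratio = np.zeros_like(c14)
    np.divide(pair.c15, c14, out=ratio, where=valid)
    return RatioMap(ratio=ratio, valid=valid)


def display_image(rmap: RatioMap, cfg: DisplayConfig | None = None) -> DisplayImage:
    """Render a ratio map on the clamped display scale.

    displayed = clip(ratio * scale_factor, lower_clamp, upper_clamp);
    invalid pixels render at the lower clamp and are counted.
    """
    cfg = cfg or DisplayConfig()
    vals = np.clip(rmap.ratio * cfg.scale_factor, cfg.lower_clamp, cfg.upper_clamp)
    vals = np.where(rmap.valid, vals, cfg.lower_clamp)
    return DisplayImage(values=vals, n_invalid=rmap.n_invalid, config=cfg)


def roi_ratio(
    pair: IonImagePair,
    mask: np.ndarray,
    *,
    method: str = "ratio_of_sums",
    roi_name: str | None = None,
) -> RoiRatio:
    """Average ^15N/^14N ratio of an ROI.

    Parameters
    ----------
    mask : boolean array, same shape as the channels
        Pixels belonging to the ROI; must select at least one pixel.
    method : {"ratio_of_sums", "mean_of_ratios"}
        The default divides the summed ^15N counts by the summed ^14N
        counts. ``mean_of_ratios`` averages per-pixel ratios over valid
        pixels instead (sensitivity-analysis option; not the default
        convention).

    Zero-^14N pixels are counted as invalid; their ^15N counts still enter
    the numerator sum (counts are physical). The ROI is rejected only when
    its total ^14N count is zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pair.shape:
        raise ValueError("mask shape does not match the ion images")
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError(f"ROI {roi_name or ''} selects no pixels".strip())
    s14 = int(pair.c14[mask].sum())
    s15 = int(pair.c15[mask].sum())
    n_invalid = int((pair.c14[mask] == 0).sum())
    if s14 == 0:
        raise UndefinedRatioError(
            f"ROI {roi_name or '<unnamed>'} has zero total ^14N counts"
        )
    if method == "ratio_of_sums":
        value = s15 / s14
    elif method == "mean_of_ratios":
        valid = mask & (pair.c14 > 0)
        value = float(np.mean(pair.c15[valid] / pair.c14[valid]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return RoiRatio(
        ratio=float(value),
        sum15=s15,
        sum14=s14,
        n_pixels=n_pixels,
        n_invalid=n_invalid,
        method=method,
    )


def whole_area_ratio(pair: IonImagePair, **kwargs) -> RoiRatio:
    """Ratio of sums over the entire image (the per-image baseline)."""
    return roi_ratio(pair, np.ones(pair.shape, dtype=bool), **kwargs)


def ratio_of_sums_se(sum15: float, sum14: float) -> float:
    """Delta-method SE of R = S15/S14 for independent Poisson sums.

    Var(R)/R^2 ~= 1/S15 + 1/S14 with the observed sums as plug-in estimates
    of their means.
    """
    if sum14 <= 0:
        raise UndefinedRatioError("SE undefined for zero ^14N sum")
    if sum15 <= 0:
        # with no ^15N counts the plug-in variance of the numerator is 0+;
        # use 1 count as the conventional floor
        sum15 = 1.0
    r = sum15 / sum14
    return float(r * np.sqrt(1.0 / sum15 + 1.0 / sum14))


def save_display(
    disp: DisplayImage,
    png_path: str | Path | None = None,
    tiff_path: str | Path | None = None,
    *,
    cmap: str = "viridis",
) -> None:
    """Write a display image as an 8-bit PNG (linear map of the clamp
    range through a colormap) and/or the raw display grid as 32-bit TIFF."""
    if tiff_path is not None:
        import tifffile

        tifffile.imwrite(str(tiff_path), disp.values.astype(np.float32))
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cfg = disp.config
        norm = (disp.values - cfg.lower_clamp) / (cfg.upper_clamp - cfg.lower_clamp)
        rgba = plt.get_cmap(cmap)(norm)
        rgb8 = (rgba[..., :3] * 255).astype(np.uint8)
        plt.imsave(str(png_path), rgb8)
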
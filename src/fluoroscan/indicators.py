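"""Per-pixel physiological indicator maps and their statistics.

The three indicators of crop status:

* ``fvfm``      — maximum PSII quantum efficiency, (Fm − Fo)/Fm
* ``phipsii``   — operating PSII quantum efficiency, (Fm′ − F)/Fm′
* ``r550_510``  — relative reflectance 550 nm / 510 nm (leaf greenness)

Maps carry NaN for undefined pixels (off-mask, or a denominator too dim
to trust).  Summaries use the population standard deviation — the pixel
set is the full population of the plant region, not a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps

from .segmentation import PlantMask

logger = logging.getLogger(__name__)

INDICATORS = ("fvfm", "phipsii", "r550_510")

#: Fixed pseudo-color display ranges, shared across a day series so the
#: panels are visually comparable.
DISPLAY_RANGE = {"fvfm": (0.0, 0.85), "phipsii": (0.0, 0.85), "r550_510": (0.0, 2.0)}

#: Denominator cutoff: fraction of the frame's robust (99th-percentile)
#: maximum below which a ratio is marked undefined instead of computed.
EPS_FRACTION = 0.01


@dataclass
class IndicatorMap:
    """2-D indicator values with NaN marking undefined pixels."""

    values: np.ndarray
    indicator: str
    mask: PlantMask
    n_clamped: int = 0  # negative ratios clamped to 0 (noise-induced)

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]


@dataclass
class IndicatorSummary:
    """Distribution statistics of one indicator map (or plant subset)."""

    indicator: str
    mean: float
    std: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n_pixels: int
    day: int | None = None

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")
        if self.std < 0 or self.n_pixels < 1:
            raise ValueError("invalid summary statistics")


def _check_shapes(num: np.ndarray, den: np.ndarray, mask: PlantMask) -> None:
    if num.shape != den.shape or num.shape != mask.shape:
        raise ValueError(
            f"frames and mask must be co-registered: {num.shape}, {den.shape}, {mask.shape}"
        )


def _ratio_map(
    num: np.ndarray,
    den: np.ndarray,
    mask: PlantMask,
    indicator: str,
    clamp_unit: bool,
) -> IndicatorMap:
    """(num/den) on mask pixels; den below epsilon -> undefined."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    _check_shapes(num, den, mask)
    robust_max = float(np.percentile(den, 99))
    eps = EPS_FRACTION * robust_max if robust_max > 0 else np.finfo(float).tiny
    valid = mask.mask & (den >= eps)
    values = np.full(num.shape, np.nan)
    values[valid] = num[valid] / den[valid]
    n_dim = int((mask.mask & ~valid).sum())
    if n_dim:
        logger.info("%s: %d masked pixels below denominator epsilon", indicator, n_dim)
    n_clamped = int((values[valid] < 0).sum())
    if n_clamped:
        logger.info("%s: clamped %d negative values to 0", indicator, n_clamped)
    if clamp_unit:
        values[valid] = np.clip(values[valid], 0.0, np.nextafter(1.0, 0.0))
    else:
        values[valid] = np.maximum(values[valid], 0.0)
    return IndicatorMap(values=values, indicator=indicator, mask=mask, n_clamped=n_clamped)


def compute_fvfm(fo_frame: np.ndarray, fm_frame: np.ndarray, mask: PlantMask) -> IndicatorMap:
    """Maximum PSII quantum efficiency (Fm − Fo)/Fm per plant pixel."""
    fo = np.asarray(fo_frame, dtype=float)
    fm = np.asarray(fm_frame, dtype=float)
    _check_shapes(fo, fm, mask)
    return _ratio_map(fm - fo, fm, mask, "fvfm", clamp_unit=True)


def compute_phipsii(f_frame: np.ndarray, fmp_frame: np.ndarray, mask: PlantMask) -> IndicatorMap:
    """Operating PSII quantum efficiency (Fm′ − F)/Fm′ per plant pixel."""
    f = np.asarray(f_frame, dtype=float)
    fmp = np.asarray(fmp_frame, dtype=float)
    _check_shapes(f, fmp, mask)
    return _ratio_map(fmp - f, fmp, mask, "phipsii", clamp_unit=True)


def compute_ratio_550_510(
    r550_frame: np.ndarray, r510_frame: np.ndarray, mask: PlantMask
) -> IndicatorMap:
    """Relative reflectance R550/R510 per plant pixel."""
    r550 = np.asarray(r550_frame, dtype=float)
    r510 = np.asarray(r510_frame, dtype=float)
    return _ratio_map(r550, r510, mask, "r550_510", clamp_unit=False)


def summarize(imap: IndicatorMap, day: int | None = None) -> IndicatorSummary:
    """Distribution statistics over the defined pixels of a map."""
    vals = imap.defined_values()
    if vals.size == 0:
        raise ValueError("no defined pixels to summarize")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return IndicatorSummary(
        indicator=imap.indicator,
        mean=float(vals.mean()),
        std=float(vals.std()),  # population sd
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(vals.min()),
        max=float(vals.max()),
        n_pixels=int(vals.size),
        day=day,
    )


def render_pseudocolor(imap: IndicatorMap, out_path) -> None:
    """Write an 8-bit pseudo-color PNG of the map with an embedded color bar.

    Values are mapped on the fixed per-indicator display range (so day
    series are comparable); undefined pixels render black.  Output bytes
    are deterministic for a given map.
    """
    lo, hi = DISPLAY_RANGE[imap.indicator]
    cmap = colormaps["jet"]
    norm = np.clip((imap.values - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.zeros(imap.values.shape + (3,), dtype=np.uint8)
    defined = imap.defined
    rgb[defined] = (np.asarray(cmap(norm[defined]))[:, :3] * 255).astype(np.uint8)

    # Embedded color bar: a vertical gradient strip right of the image,
    # top = display maximum, separated by a black gap.
    h = rgb.shape[0]
    gap, bar_w = 6, 18
    grad = np.linspace(1.0, 0.0, h)
    bar = (np.asarray(cmap(grad))[:, :3] * 255).astype(np.uint8)
    bar = np.repeat(bar[:, None, :], bar_w, axis=1)
    out = np.concatenate([rgb, np.zeros((h, gap, 3), np.uint8), bar], axis=1)
    iio.imwrite(out_path, out, extension=".png")
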
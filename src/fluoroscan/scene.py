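"""Ground-truthed synthetic acquisition generator.

Emulates a PAM fluorescence + multispectral imager pointed at a bed of
potted seedlings: elliptical leaves (tagged old/new) around plant
centers, a dark soil background, optical vignetting, read and shot
noise, and day-course stress treatments (drought, nitrogen deficiency,
Botrytis-type patchy infection).  Every acquisition carries its exact
per-pixel ground truth, so the downstream segmentation, indicator and
diagnosis stages are testable without the instrument.

The generating physiology sits at the field's healthy working point:
maximum PSII efficiency Fv/Fm = 0.80, operating efficiency
PhiPSII = 0.40 under 200 µmol m⁻² s⁻¹ actinic light, and a 550/510
reflectance ratio of 1.6.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .frame_io import FrameStack, StackMetadata, write_stack

# Healthy working point (dimensionless).
HEALTHY_FVFM = 0.80
HEALTHY_PHIPSII = 0.40
HEALTHY_RATIO_550_510 = 1.6
#: PhiPSII plateau under severe drought ("wilted" stage).
DROUGHT_PHIPSII_FLOOR = 0.25

#: Leaf-age class codes in PhysiologyField.age.
AGE_BACKGROUND, AGE_OLD, AGE_NEW = 0, 1, 2

STRESS_TYPES = ("none", "drought", "nitrogen_deficiency", "disease")
#: Spatial expression of each stress (fixed per type).
SPATIAL_MODE = {
    "none": "uniform",
    "drought": "uniform",
    "nitrogen_deficiency": "old_leaves_first",
    "disease": "patchy_lesions",
}

# Severity above which drought starts to pull down Fv/Fm and chroma
# (early drought is a PhiPSII-only signal).
DROUGHT_SEVERE_THRESHOLD = 0.7


class InvalidSpecError(ValueError):
    """Raised when a scene specification cannot produce a valid scene."""


@dataclass
class SceneSpec:
    """Geometry and texture of one synthetic bed position."""

    image_height: int = 520
    image_width: int = 696
    n_plants: int = 6
    leaves_per_plant: int = 6
    background_level: float = 30.0  # fluorescence counts of soil/tray pixels
    rng_seed: int = 0
    # Biological texture: per-pixel and per-leaf spread of the phi fields
    # (dimensionless) and of the greenness driver.
    pixel_sd: float = 0.02
    leaf_sd: float = 0.015
    chroma_pixel_sd: float = 0.03

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if self.n_plants < 1:
            raise InvalidSpecError("n_plants must be >= 1")
        if self.leaves_per_plant < 1:
            raise InvalidSpecError("leaves_per_plant must be >= 1")
        if self.background_level < 0:
            raise InvalidSpecError("background_level must be non-negative")


@dataclass
class PhysiologyField:
    """Per-pixel ground-truth physiology of a scene.

    ``phi_max`` is the quantity measured as Fv/Fm, ``phi_op`` the quantity
    measured as PhiPSII, ``chroma`` a greenness driver (healthy = 1.0) that
    scales both the Fm amplitude and the 550/510 reflectance target.  All
    three are zero off the plant footprint.
    """

    phi_max: np.ndarray
    phi_op: np.ndarray
    chroma: np.ndarray
    footprint: np.ndarray
    age: np.ndarray  # AGE_OLD / AGE_NEW on footprint, AGE_BACKGROUND elsewhere
    plant_id: np.ndarray  # 1-based plant label on footprint, 0 elsewhere
    background_level: float = 30.0

    def copy(self) -> "PhysiologyField":
        return PhysiologyField(
            phi_max=self.phi_max.copy(),
            phi_op=self.phi_op.copy(),
            chroma=self.chroma.copy(),
            footprint=self.footprint.copy(),
            age=self.age.copy(),
            plant_id=self.plant_id.copy(),
            background_level=self.background_level,
        )

    def footprint_mean(self, name: str) -> float:
        return float(getattr(self, name)[self.footprint].mean())


@dataclass
class StressModel:
    """A stress treatment's day course and spatial expression."""

    stress_type: str = "none"
    day_range: tuple[int, int] = (1, 9)
    severity_trajectory: Sequence[float] | None = None  # per day, in [0, 1]
    lesion_growth_rate: float = 3.0  # pixels/day at full-rate growth (disease)
    lesion_base_radius: float = 2.0
    lesions_per_plant: int = 2
    lesion_seed: int = 0
    old_leaf_lead_days: int = 2  # N deficiency: old leaves lead new leaves
    new_leaf_attenuation: float = 0.3  # N deficiency: damped new-leaf response

    def __post_init__(self) -> None:
        if self.stress_type not in STRESS_TYPES:
            raise ValueError(
                f"unknown stress_type {self.stress_type!r}; expected one of {STRESS_TYPES}"
            )
        d0, d1 = self.day_range
        if d1 < d0:
            raise ValueError("day_range end before start")
        if self.severity_trajectory is None:
            self.severity_trajectory = _default_trajectory(self.stress_type, d0, d1)
        traj = np.asarray(self.severity_trajectory, dtype=float)
        if len(traj) != d1 - d0 + 1:
            raise ValueError("severity_trajectory length must cover day_range")
        if np.any(traj < 0) or np.any(traj > 1):
            raise ValueError("severity values must lie in [0, 1]")
        if np.any(np.diff(traj) < 0):
            raise ValueError("severity must be non-decreasing over days")
        self.severity_trajectory = traj

    @property
    def spatial_mode(self) -> str:
        return SPATIAL_MODE[self.stress_type]

    @property
    def n_days(self) -> int:
        return self.day_range[1] - self.day_range[0] + 1

    def severity_at(self, day: int) -> float:
        d0, d1 = self.day_range
        if not d0 <= day <= d1:
            raise ValueError(f"day {day} outside day_range {self.day_range}")
        return float(self.severity_trajectory[day - d0])

    def _severity_clamped(self, day: float) -> float:
        """Severity with days before onset mapped to 0 (used for leaf lag)."""
        d0, d1 = self.day_range
        if day < d0:
            return 0.0
        return float(self.severity_trajectory[int(min(day, d1)) - d0])


def _default_trajectory(stress_type: str, d0: int, d1: int) -> np.ndarray:
    days = np.arange(d0, d1 + 1, dtype=float)
    if stress_type == "none":
        return np.zeros_like(days)
    if stress_type == "drought":
        # Water withheld from day 1; soil water collapses within ~5 days and
        # stays low, so severity saturates around day 6-7.
        return np.clip((days - d0) / 5.5, 0.0, 1.0)
    span = max(d1 - d0, 1)
    return (days - d0) / span


@dataclass
class ImagingModel:
    """Optical and sensor model of the rendered acquisition."""

    vignetting_strength: float = 0.15  # radial attenuation at the corners
    read_noise_sd: float = 5.0  # counts
    shot_noise: bool = True  # variance proportional to signal
    shot_noise_scale: float = 0.5  # variance per count of signal
    bit_depth: int = 12
    fm_gain: float = 3000.0  # Fm counts per unit chroma (before vignetting)
    r510_gain: float = 100.0  # 510 nm plant reflectance counts
    r510_background: float = 60.0  # soil reflectance counts
    r550_background: float = 45.0  # soil: 550/510 ~ 0.75, well below leaves
    light_levels: dict = field(
        default_factory=lambda: {"measuring": 0.1, "actinic": 200.0, "saturating": 6000.0}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.vignetting_strength < 1.0:
            raise ValueError("vignetting_strength must be in [0, 1)")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")

    @property
    def noiseless(self) -> bool:
        return self.read_noise_sd == 0 and not self.shot_noise

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    def vignette(self, shape: tuple[int, int]) -> np.ndarray:
        """Radial multiplier in (0, 1]; 1 at the optical center."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
        return 1.0 - self.vignetting_strength * r2


def _ellipse_mask(shape, center, angle, d, a, b):
    """Boolean mask of one leaf: an ellipse offset by d along angle."""
    h, w = shape
    cy = center[0] + d * np.sin(angle)
    cx = center[1] + d * np.cos(angle)
    y0 = max(int(cy - a - 2), 0)
    y1 = min(int(cy + a + 3), h)
    x0 = max(int(cx - a - 2), 0)
    x1 = min(int(cx + a + 3), w)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not inside.any():
        return None
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def build_scene(spec: SceneSpec, seed: int | None = None) -> PhysiologyField:
    """Lay out plants on the bed and draw their healthy physiology.

    Each plant is a rosette of elliptical leaves that overlap at the
    plant center (one connected component per plant), alternately tagged
    old/new.  Phi fields get mean-centered biological texture, so the
    footprint means sit exactly at the healthy working point.
    """
    spec.validate()
    if seed is None:
        seed = spec.rng_seed
    rng = np.random.default_rng(seed)
    h, w = spec.image_height, spec.image_width
    shape = (h, w)

    ncols = max(int(np.ceil(np.sqrt(spec.n_plants * w / h))), 1)
    nrows = int(np.ceil(spec.n_plants / ncols))
    cell_h, cell_w = h / nrows, w / ncols
    if min(cell_h, cell_w) < 16:
        raise InvalidSpecError(
            f"image {h}x{w} too small to lay out {spec.n_plants} plants "
            "without merging"
        )
    # Leaf geometry scaled to the grid cell so plants never merge.
    scale = float(np.clip(min(cell_h, cell_w) / 240.0, 0.2, 1.5))
    d_off, ax_a, ax_b = 24.0 * scale, 32.0 * scale, 14.0 * scale

    footprint = np.zeros(shape, dtype=bool)
    age = np.zeros(shape, dtype=np.int8)
    plant_id = np.zeros(shape, dtype=np.int32)
    leaf_label = np.zeros(shape, dtype=np.int32)

    centers = []
    for r in range(nrows):
        for c in range(ncols):
            if len(centers) < spec.n_plants:
                centers.append(((r + 0.5) * cell_h, (c + 0.5) * cell_w))

    leaf_idx = 0
    for pid, center in enumerate(centers, start=1):
        phase = rng.uniform(0, 2 * np.pi)
        plant_px = 0
        for k in range(spec.leaves_per_plant):
            leaf_idx += 1
            angle = phase + 2 * np.pi * k / spec.leaves_per_plant
            angle += rng.normal(0, 0.08)
            m = _ellipse_mask(shape, center, angle, d_off, ax_a, ax_b)
            if m is None:
                raise InvalidSpecError(
                    f"zero-area leaf for plant {pid}: image too small for the layout"
                )
            footprint |= m
            # Later leaves may overwrite overlap pixels; alternate ages so
            # old and new leaves each cover about half the plant.
            age[m] = AGE_OLD if k % 2 == 0 else AGE_NEW
            plant_id[m] = pid
            leaf_label[m] = leaf_idx
            plant_px += int(m.sum())
        if plant_px == 0:
            raise InvalidSpecError(f"plant {pid} has an empty footprint")

    def textured(base: float, pixel_sd: float) -> np.ndarray:
        vals = np.zeros(shape, dtype=float)
        if not footprint.any():
            return vals
        noise = rng.normal(0.0, pixel_sd, size=shape)
        # Per-leaf offsets model whole-leaf physiological differences.
        offsets = rng.normal(0.0, spec.leaf_sd, size=leaf_idx + 1)
        offsets[0] = 0.0
        noise += offsets[leaf_label]
        # Mean-center over the footprint: the healthy working point is exact.
        noise -= noise[footprint].mean()
        vals[footprint] = base + noise[footprint]
        return vals

    phi_max = textured(HEALTHY_FVFM, spec.pixel_sd)
    phi_op = textured(HEALTHY_PHIPSII, spec.pixel_sd)
    chroma = textured(1.0, spec.chroma_pixel_sd)

    fp = footprint
    phi_max[fp] = np.clip(phi_max[fp], 0.05, 0.98)
    phi_op[fp] = np.clip(phi_op[fp], 0.01, phi_max[fp] - 1e-6)
    chroma[fp] = np.clip(chroma[fp], 0.05, None)

    return PhysiologyField(
        phi_max=phi_max,
        phi_op=phi_op,
        chroma=chroma,
        footprint=footprint,
        age=age,
        plant_id=plant_id,
        background_level=spec.background_level,
    )


def _lesion_mask(field: PhysiologyField, model: StressModel, radius: float) -> np.ndarray:
    """Union of circular lesion patches, grown to ``radius``, on the footprint.

    Lesion centers are drawn deterministically from the footprint (per
    plant) so the same patches grow from day to day.
    """
    rng = np.random.default_rng(model.lesion_seed)
    h, w = field.footprint.shape
    mask = np.zeros((h, w), dtype=bool)
    if radius <= 0:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    for pid in np.unique(field.plant_id[field.plant_id > 0]):
        ys, xs = np.nonzero(field.plant_id == pid)
        n = min(model.lesions_per_plant, len(ys))
        idx = rng.choice(len(ys), size=n, replace=False)
        for i in idx:
            mask |= (yy - ys[i]) ** 2 + (xx - xs[i]) ** 2 <= radius**2
    return mask & field.footprint


def apply_stress(field: PhysiologyField, model: StressModel, day: int) -> PhysiologyField:
    """Return a copy of ``field`` expressing ``model`` at the given day.

    Drought depresses phi_op toward the severe-drought floor first;
    Fv/Fm and chroma follow only past the severe threshold.  Nitrogen
    deficiency depresses all three with old leaves leading (and new
    leaves responding more weakly), which drives up the Fv/Fm standard
    deviation.  Disease carves growing circular lesions inside which all
    three collapse to 30% of their healthy level.
    """
    s = model.severity_at(day)
    out = field.copy()
    if model.stress_type == "none" or s == 0.0:
        return out
    fp = out.footprint

    if model.stress_type == "drought":
        # phi_op: healthy 0.40 -> floor 0.25 at full severity.
        drop = (HEALTHY_PHIPSII - DROUGHT_PHIPSII_FLOOR) / HEALTHY_PHIPSII
        out.phi_op[fp] *= 1.0 - drop * s
        if s > DROUGHT_SEVERE_THRESHOLD:
            late = (s - DROUGHT_SEVERE_THRESHOLD) / (1.0 - DROUGHT_SEVERE_THRESHOLD)
            out.phi_max[fp] *= 1.0 - 0.10 * late  # 0.80 -> 0.72
            out.chroma[fp] *= 1.0 - 0.15 * late  # 550/510: 1.6 -> 1.36
    elif model.stress_type == "nitrogen_deficiency":
        s_old = s
        s_new = model.new_leaf_attenuation * model._severity_clamped(
            day - model.old_leaf_lead_days
        )
        for age_code, sv in ((AGE_OLD, s_old), (AGE_NEW, s_new)):
            sel = out.age == age_code
            out.phi_max[sel] *= 1.0 - 0.3125 * sv  # 0.80 -> 0.55
            out.phi_op[sel] *= 1.0 - 0.45 * sv  # 0.40 -> 0.22
            out.chroma[sel] *= 1.0 - 0.20 * sv  # ratio 1.6 -> 1.28
    elif model.stress_type == "disease":
        radius = model.lesion_base_radius + model.lesion_growth_rate * s * (
            model.n_days - 1
        )
        lesions = _lesion_mask(out, model, radius)
        for name in ("phi_max", "phi_op", "chroma"):
            arr = getattr(out, name)
            arr[lesions] *= 0.30
    else:  # pragma: no cover - guarded by StressModel
        raise ValueError(f"unknown stress_type {model.stress_type!r}")

    out.phi_op[fp] = np.clip(out.phi_op[fp], 0.0, out.phi_max[fp] - 1e-9)
    return out


def render_stack(
    field: PhysiologyField,
    imaging: ImagingModel | None = None,
    seed: int = 0,
    metadata: StackMetadata | None = None,
) -> FrameStack:
    """Render the six protocol frames from a physiology field.

    Construction (per footprint pixel, v = vignetting multiplier):

    ==========  ===============================================
    Fm          fm_gain * chroma * v
    Fo          Fm * (1 - phi_max)
    Fm'         Fm * (1 - q),  q = 0.5 * (phi_max - phi_op)/phi_max
    F           Fm' * (1 - phi_op)
    R510        r510_gain * v
    R550        R510 * 1.6 * chroma
    ==========  ===============================================

    so that (Fm-Fo)/Fm and (Fm'-F)/Fm' invert exactly to phi_max and
    phi_op in the noiseless case; q stands in for light-adapted
    quenching without modelling its kinetics.  Background pixels carry
    ``field.background_level`` in the fluorescence frames and the soil
    reflectances in the spectral frames.

    With noise enabled the counts are quantized to integers and clipped
    to the sensor range; a fully noiseless render returns exact float
    frames (an analytic stack, not writable as 16-bit TIFF).
    """
    imaging = imaging or ImagingModel()
    fp = field.footprint
    if np.any(field.phi_max[fp] < 0) or np.any(field.phi_max[fp] >= 1):
        raise ValueError("phi_max must lie in [0, 1) on the footprint")
    if np.any(field.phi_op[fp] < 0) or np.any(field.phi_op[fp] >= 1):
        raise ValueError("phi_op must lie in [0, 1) on the footprint")

    shape = fp.shape
    v = imaging.vignette(shape)
    bg = field.background_level

    fm = np.full(shape, bg, dtype=float)
    fm[fp] = imaging.fm_gain * field.chroma[fp] * v[fp]
    fo = np.full(shape, bg, dtype=float)
    fo[fp] = fm[fp] * (1.0 - field.phi_max[fp])
    q = np.zeros(shape)
    pm = field.phi_max[fp]
    q[fp] = 0.5 * (pm - field.phi_op[fp]) / np.where(pm > 0, pm, 1.0)
    fmp = np.full(shape, bg, dtype=float)
    fmp[fp] = fm[fp] * (1.0 - q[fp])
    f = np.full(shape, bg, dtype=float)
    f[fp] = fmp[fp] * (1.0 - field.phi_op[fp])

    r510 = np.full(shape, imaging.r510_background, dtype=float)
    r510[fp] = imaging.r510_gain * v[fp]
    r550 = np.full(shape, imaging.r550_background, dtype=float)
    r550[fp] = r510[fp] * HEALTHY_RATIO_550_510 * field.chroma[fp]

    frames = {"Fo": fo, "Fm": fm, "F": f, "Fm_prime": fmp, "R510": r510, "R550": r550}
    rng = np.random.default_rng(seed)
    if not imaging.noiseless:
        for k in frames:
            a = frames[k]
            if imaging.shot_noise:
                a = a + rng.normal(0.0, np.sqrt(imaging.shot_noise_scale * np.maximum(a, 0)))
            if imaging.read_noise_sd > 0:
                a = a + rng.normal(0.0, imaging.read_noise_sd, size=a.shape)
            a = np.round(np.clip(a, 0, imaging.max_count))
            frames[k] = a
        n_sat = int((frames["Fm"][fp] >= imaging.max_count).sum())
        if fp.any() and n_sat > 0.001 * fp.sum():
            warnings.warn(
                f"{n_sat} footprint pixels ({100 * n_sat / fp.sum():.2f}%) "
                "saturate the sensor",
                stacklevel=2,
            )
    else:
        for k in frames:
            frames[k] = np.clip(frames[k], 0, imaging.max_count)

    meta = metadata or StackMetadata(
        bit_depth=imaging.bit_depth, light_levels=dict(imaging.light_levels)
    )
    return FrameStack(frames=frames, metadata=meta)


def generate_dataset(
    spec: SceneSpec,
    model: StressModel,
    imaging: ImagingModel | None = None,
    days: Sequence[int] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[tuple[FrameStack, PhysiologyField]]:
    """Generate one acquisition per day with its ground-truth field.

    The scene layout is built once from ``seed``; per-day render noise
    uses independent child seeds.  With ``out_dir`` set, each stack is
    written as TIFF+JSON and the ground truth as a compressed array
    container (``.npz``) plus a JSON manifest.
    """
    imaging = imaging or ImagingModel()
    if days is None:
        days = list(range(model.day_range[0], model.day_range[1] + 1))
    days = list(days)
    if not days:
        raise ValueError("day list must be non-empty")

    base = build_scene(spec, seed)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(days))
    out = []
    for day, child in zip(days, children):
        field_d = apply_stress(base, model, day)
        render_seed = int(child.generate_state(1)[0] % (2**31))
        meta = StackMetadata(
            day=day, bit_depth=imaging.bit_depth, light_levels=dict(imaging.light_levels)
        )
        stack = render_stack(field_d, imaging, seed=render_seed, metadata=meta)
        out.append((stack, field_d))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for day, (stack, field_d) in zip(days, out):
            stack_name = f"day_{day:02d}.tif"
            truth_name = f"day_{day:02d}_truth.npz"
            write_stack(stack, out_dir / stack_name)
            np.savez_compressed(
                out_dir / truth_name,
                footprint=field_d.footprint,
                phi_max=field_d.phi_max,
                phi_op=field_d.phi_op,
                chroma=field_d.chroma,
                age=field_d.age,
                plant_id=field_d.plant_id,
            )
            entries.append({"day": day, "stack": stack_name, "truth": truth_name})
        manifest = {
            "stress_type": model.stress_type,
            "days": days,
            "seed": seed,
            "image_shape": [spec.image_height, spec.image_width],
            "entries": entries,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return out


# -- nutrition calibration preset -------------------------------------------

#: fvfm = NUTRITION_INTERCEPT + NUTRITION_SLOPE * total_N + noise
NUTRITION_SLOPE = 0.005  # Fv/Fm per (mg N / g dry weight)
NUTRITION_INTERCEPT = 0.60
NUTRITION_N_RANGE = (15.0, 45.0)  # mg/g dry weight across N-strength treatments
#: Noise sd set so the expected coefficient of determination of the
#: Fv/Fm ~ total-N fit is 0.85: with N ~ U(15, 45), the signal variance is
#: slope^2 * 30^2/12 = 1.875e-3 and sigma^2 = 1.875e-3 * 0.15/0.85.
NUTRITION_NOISE_SD = float(np.sqrt(NUTRITION_SLOPE**2 * 30.0**2 / 12 * 0.15 / 0.85))


def nutrition_calibration_pairs(n: int = 60, seed: int = 7) -> pd.DataFrame:
    """Synthetic (total-N, Fv/Fm) pairs from the N-strength experiments.

    Emulates sampling leaves across deficient / full / double-strength
    nutrient treatments: total nitrogen uniform over 15-45 mg per g dry
    weight, Fv/Fm linear in total N with Gaussian measurement scatter.
    """
    if n < 3:
        raise ValueError("need at least 3 calibration pairs")
    rng = np.random.default_rng(seed)
    total_n = rng.uniform(*NUTRITION_N_RANGE, size=n)
    fvfm = (
        NUTRITION_INTERCEPT
        + NUTRITION_SLOPE * total_n
        + rng.normal(0.0, NUTRITION_NOISE_SD, size=n)
    )
    return pd.DataFrame({"total_n_mg_g": total_n, "fvfm": fvfm})
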
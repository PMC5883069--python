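"""Acquisition stack containers, TIFF round-trip and bed-scan stitching.

One acquisition of the modulated-fluorescence protocol yields four
chlorophyll-fluorescence frames (Fo, Fm, F, Fm') plus two narrow-band
reflectance frames (510 nm and 550 nm), all co-registered on the same
CCD grid.  Stacks are stored as multi-page 16-bit TIFF files with the
page order fixed to ``FRAME_ORDER`` and the protocol metadata in a JSON
sidecar next to the image file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

#: Fixed page order of a stack on disk.
FRAME_ORDER = ("Fo", "Fm", "F", "Fm_prime", "R510", "R550")

DEFAULT_LIGHT_LEVELS = {
    # µmol photons m^-2 s^-1; saturating pulses exceed 6000.
    "measuring": 0.1,
    "actinic": 200.0,
    "saturating": 6000.0,
}
DEFAULT_WAVELENGTHS = {
    "excitation_nm": 460,
    "detection_min_nm": 650,
    "spectral_nm": [510, 550],
}


class StackFormatError(ValueError):
    """Raised when a stack file or its metadata is malformed."""


@dataclass
class StackMetadata:
    """Protocol metadata attached to one acquisition."""

    position: tuple[int, int] = (0, 0)  # (x-index, y-index) on the bed grid
    day: int = 1
    light_levels: dict = field(default_factory=lambda: dict(DEFAULT_LIGHT_LEVELS))
    wavelengths: dict = field(default_factory=lambda: dict(DEFAULT_WAVELENGTHS))
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.position = (int(self.position[0]), int(self.position[1]))
        if self.position[0] < 0 or self.position[1] < 0:
            raise ValueError(f"grid position indices must be >= 0, got {self.position}")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["position"] = list(self.position)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StackMetadata":
        required = {"position", "day", "light_levels", "wavelengths", "bit_depth"}
        missing = required - set(d)
        if missing:
            raise StackFormatError(f"metadata missing keys: {sorted(missing)}")
        return cls(
            position=tuple(d["position"]),
            day=int(d["day"]),
            light_levels=dict(d["light_levels"]),
            wavelengths=dict(d["wavelengths"]),
            bit_depth=int(d["bit_depth"]),
        )


@dataclass
class FrameStack:
    """Six co-registered intensity frames (counts) plus metadata."""

    frames: dict[str, np.ndarray]
    metadata: StackMetadata = field(default_factory=StackMetadata)

    def __post_init__(self) -> None:
        keys = tuple(self.frames)
        if set(keys) != set(FRAME_ORDER):
            missing = [k for k in FRAME_ORDER if k not in keys]
            extra = [k for k in keys if k not in FRAME_ORDER]
            raise StackFormatError(
                f"frame keys must be exactly {FRAME_ORDER}; "
                f"missing {missing}, unexpected {extra}"
            )
        shapes = {k: np.asarray(v).shape for k, v in self.frames.items()}
        if len(set(shapes.values())) != 1:
            raise StackFormatError(f"all frames must share one shape, got {shapes}")
        for k in FRAME_ORDER:
            a = np.asarray(self.frames[k], dtype=float)
            if a.ndim != 2:
                raise StackFormatError(f"frame {k} must be 2-D")
            if np.any(a < 0):
                raise StackFormatError(f"frame {k} contains negative counts")
            self.frames[k] = a

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames["Fo"].shape

    def __getitem__(self, key: str) -> np.ndarray:
        return self.frames[key]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page uint16 TIFF plus a JSON metadata sidecar.

    Counts must be integral and representable in 16 bits; quantized stacks
    from the renderer satisfy this.  The round trip through
    :func:`read_stack` is lossless.
    """
    path = Path(path)
    pages = []
    for k in FRAME_ORDER:
        a = stack.frames[k]
        if not np.all(np.isfinite(a)) or np.any(a != np.round(a)):
            raise ValueError(
                f"frame {k} has non-integral counts; write_stack stores 16-bit "
                "unsigned samples (render with noise/quantization enabled)"
            )
        if a.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError(f"frame {k} exceeds the 16-bit sample range")
        pages.append(a.astype(np.uint16))
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(stack.metadata.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def read_stack(path: str | Path) -> FrameStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != len(FRAME_ORDER):
        if pages.shape[0] < len(FRAME_ORDER):
            missing = FRAME_ORDER[pages.shape[0]]
            raise StackFormatError(
                f"{path}: expected {len(FRAME_ORDER)} pages, got "
                f"{pages.shape[0]}; missing frame {missing}"
            )
        raise StackFormatError(
            f"{path}: expected {len(FRAME_ORDER)} pages, got {pages.shape[0]}"
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise StackFormatError(f"metadata sidecar not found: {sidecar}")
    meta = StackMetadata.from_dict(json.loads(sidecar.read_text()))
    frames = {k: pages[i].astype(float) for i, k in enumerate(FRAME_ORDER)}
    return FrameStack(frames=frames, metadata=meta)


def stitch_mosaic(stacks: list[FrameStack]) -> FrameStack:
    """Abut per-position stacks from the bed scan into one mosaic stack.

    Tiles are placed frame-wise on the rectangular grid given by their
    metadata positions ``(x, y)`` (x = column index, y = row index); the
    instrument images disjoint bed positions, so no overlap or blending
    is applied.  The grid must be complete and all tiles the same shape.
    """
    if not stacks:
        raise ValueError("no stacks to stitch")
    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"tile shape mismatch: {sorted(shapes)}")
    tile_h, tile_w = stacks[0].shape
    positions = [s.metadata.position for s in stacks]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate grid cell(s): {dupes}")
    ncols = max(x for x, _ in positions) + 1
    nrows = max(y for _, y in positions) + 1
    expected = {(x, y) for x in range(ncols) for y in range(nrows)}
    missing = sorted(expected - set(positions))
    if missing:
        raise ValueError(f"incomplete grid; missing cell(s): {missing}")

    frames = {
        k: np.zeros((nrows * tile_h, ncols * tile_w), dtype=float)
        for k in FRAME_ORDER
    }
    for s in stacks:
        x, y = s.metadata.position
        sl = (slice(y * tile_h, (y + 1) * tile_h), slice(x * tile_w, (x + 1) * tile_w))
        for k in FRAME_ORDER:
            frames[k][sl] = s.frames[k]
    meta = StackMetadata(
        position=(0, 0),
        day=stacks[0].metadata.day,
        light_levels=dict(stacks[0].metadata.light_levels),
        wavelengths=dict(stacks[0].metadata.wavelengths),
        bit_depth=stacks[0].metadata.bit_depth,
    )
    return FrameStack(frames=frames, metadata=meta)
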
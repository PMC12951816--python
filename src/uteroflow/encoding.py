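"""Temporal frame-difference motion encoding for cine MRI.

A cine acquisition yields ``T`` grayscale frames of one midsagittal slice
(nominally 30 frames at 6-s intervals).  Uterine peristalsis is visible only
as frame-to-frame change, so four consecutive frames ``f1..f4`` are folded
into a single 3-channel "combined image" whose channels hold the three
successive half-differences, offset to neutral gray::

    R = f1/2 - f2/2 + 128
    G = f2/2 - f3/2 + 128
    B = f3/2 - f4/2 + 128

A static scene therefore maps to uniform 128 in every channel, and at a 6-s
frame interval each combined image spans 18 s of motion.  Sliding the
4-frame window at stride 1 over a ``T``-frame sequence yields ``T - 3``
combined images.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

NEUTRAL_GRAY = 128.0
WINDOW = 4  # frames per combined image


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """One case's cine stack: ``frames`` is (T, H, W) grayscale in [0, 255]."""

    case_id: str
    frames: np.ndarray
    frame_interval_s: float = 6.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("frame stack is empty")
        if float(self.frames.min()) < 0.0 or float(self.frames.max()) > 255.0:
            raise ValueError("frame values must lie in [0, 255]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])


@dataclass
class CombinedImage:
    """3-channel motion image from four consecutive frames.

    ``channels`` is (H, W, 3) float in [0, 255]; ``window_start`` is the
    0-based index of ``f1`` in the source sequence.
    """

    case_id: str
    window_start: int
    channels: np.ndarray
    frame_interval_s: float = 6.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[2] != 3:
            raise ValueError("channels must be (H, W, 3)")

    @property
    def span_s(self) -> float:
        """Seconds of motion represented: three inter-frame intervals."""
        return 3.0 * self.frame_interval_s

    def to_uint8(self) -> np.ndarray:
        """8-bit export; round half to even so 128.0 stays exactly 128."""
        return np.clip(np.rint(self.channels), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def combine_frames(
    f1: np.ndarray,
    f2: np.ndarray,
    f3: np.ndarray,
    f4: np.ndarray,
    *,
    case_id: str = "",
    window_start: int = 0,
    frame_interval_s: float = 6.0,
) -> CombinedImage:
    """Fold four consecutive grayscale frames into one combined image.

    Channels are computed in floating point as successive half-differences
    offset by 128, then clamped to [0, 255] (the raw range is [0.5, 255.5]).
    Rounding to 8 bits happens only on export.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in (f1, f2, f3, f4)]
    shape = frames[0].shape
    if any(f.shape != shape for f in frames[1:]):
        raise ValueError(
            "frame shape mismatch: " + ", ".join(str(f.shape) for f in frames)
        )
    if len(shape) != 2:
        raise ValueError(f"frames must be 2-D grayscale, got shape {shape}")
    channels = np.stack(
        [
            frames[0] / 2.0 - frames[1] / 2.0 + NEUTRAL_GRAY,
            frames[1] / 2.0 - frames[2] / 2.0 + NEUTRAL_GRAY,
            frames[2] / 2.0 - frames[3] / 2.0 + NEUTRAL_GRAY,
        ],
        axis=-1,
    )
    np.clip(channels, 0.0, 255.0, out=channels)
    return CombinedImage(
        case_id=case_id,
        window_start=window_start,
        channels=channels,
        frame_interval_s=frame_interval_s,
    )


def window_series(
    seq: FrameSequence, window: int = WINDOW, stride: int = 1
) -> list[CombinedImage]:
    """Slide the combining window over the sequence.

    At the default window 4 / stride 1 a ``T``-frame sequence yields
    ``T - 3`` combined images (20 frames -> 17, 30 frames -> 27).
    """
    if window != WINDOW:
        raise ValueError("the combining formula is defined for 4-frame windows")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if seq.n_frames < window:
        raise ValueError(
            f"sequence {seq.case_id!r} has {seq.n_frames} frames; need >= {window}"
        )
    out: list[CombinedImage] = []
    for start in range(0, seq.n_frames - window + 1, stride):
        out.append(
            combine_frames(
                *(seq.frames[start + i] for i in range(window)),
                case_id=seq.case_id,
                window_start=start,
                frame_interval_s=seq.frame_interval_s,
            )
        )
    return out


def reverse_time(seq: FrameSequence) -> FrameSequence:
    """Return the sequence with frame order reversed (test helper)."""
    return FrameSequence(
        case_id=seq.case_id,
        frames=seq.frames[::-1].copy(),
        frame_interval_s=seq.frame_interval_s,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _to_grayscale(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(np.float64)


def read_png_sequence(
    directory: str | Path,
    case_id: str | None = None,
    frame_interval_s: float = 6.0,
) -> FrameSequence:
    """Read a directory of PNG frames in lexicographic filename order."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG frames under {directory}")
    frames = np.stack([_to_grayscale(iio.imread(p)) for p in paths])
    return FrameSequence(
        case_id=case_id or directory.name,
        frames=frames,
        frame_interval_s=frame_interval_s,
    )


def read_dicom_series(
    directory: str | Path,
    case_id: str | None = None,
    frame_interval_s: float = 6.0,
) -> FrameSequence:
    """Read a DICOM series, ordered by InstanceNumber."""
    import pydicom

    directory = Path(directory)
    paths = [p for p in sorted(directory.iterdir()) if p.suffix.lower() in {".dcm", ""}]
    datasets = []
    for p in paths:
        if not p.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    if not datasets:
        raise FileNotFoundError(f"no readable DICOM files under {directory}")
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = np.stack([d.pixel_array.astype(np.float64) for d in datasets])
    # rescale each study to the stored 8-bit display range if needed
    if frames.max() > 255.0:
        frames = frames * (255.0 / frames.max())
    return FrameSequence(
        case_id=case_id or directory.name,
        frames=frames,
        frame_interval_s=frame_interval_s,
    )


def read_array_archive(path: str | Path) -> dict[str, FrameSequence]:
    """Read an .npz archive of stacks keyed by case id."""
    archive = np.load(Path(path))
    interval = 6.0
    if "_frame_interval_s" in archive:
        interval = float(archive["_frame_interval_s"])
    return {
        key: FrameSequence(case_id=key, frames=archive[key], frame_interval_s=interval)
        for key in archive.files
        if not key.startswith("_")
    }


def write_png_sequence(seq: FrameSequence, directory: str | Path) -> list[Path]:
    """Write frames as zero-padded 8-bit PNGs (frame_000.png, ...)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(seq.n_frames - 1)))
    paths = []
    for i, frame in enumerate(seq.frames):
        p = directory / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, np.clip(np.rint(frame), 0, 255).astype(np.uint8))
        paths.append(p)
    return paths


def write_array_archive(
    sequences: Iterable[FrameSequence], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sequences = list(sequences)
    arrays = {seq.case_id: seq.frames.astype(np.float32) for seq in sequences}
    if sequences:
        arrays["_frame_interval_s"] = np.float64(sequences[0].frame_interval_s)
    np.savez_compressed(path, **arrays)
    return path


def write_combined_png(images: Sequence[CombinedImage], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in images:
        p = directory / f"{img.case_id}_w{img.window_start:03d}.png"
        iio.imwrite(p, img.to_uint8())
        paths.append(p)
    return paths
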
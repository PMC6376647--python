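"""Reading and writing focus stacks, plane triplets, annotations and detections.

Conventions
-----------
Pixel coordinates are 0-based ``(row, col)``, row-major.  Focal-plane
indices are 1-based, matching the microscopy convention of numbering the
planes of a z-stack from the bottom of the acquisition range (``plane 13``
is the autofocused plane in a 25-plane stack).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ZStack",
    "PlaneTriplet",
    "AnnotationSet",
    "DetectionSet",
    "read_zstack",
    "write_zstack",
    "select_triplet",
    "normalize_triplet",
    "read_annotations",
    "write_annotations",
    "read_detections",
    "write_detections",
]


@dataclass
class ZStack:
    """An ordered set of co-registered focal-plane images.

    Parameters
    ----------
    planes : ndarray, shape ``(n_planes, height, width)``
        Intensity images, bottom plane first.
    plane_spacing_um : float
        Axial distance between adjacent focal planes, in micrometres.
    in_focus_index : int
        1-based index of the most focused plane.
    """

    planes: np.ndarray
    plane_spacing_um: float = 10.0
    in_focus_index: int = 13

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError(f"planes must be 3-D (n_planes, H, W), got shape {self.planes.shape}")
        if self.n_planes < 1:
            raise ValueError("a z-stack needs at least one plane")
        if not 1 <= self.in_focus_index <= self.n_planes:
            raise ValueError(
                f"in_focus_index {self.in_focus_index} out of range for {self.n_planes} planes"
            )

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.planes.shape[1], self.planes.shape[2]


@dataclass
class PlaneTriplet:
    """Three consecutive focal planes stacked as channels.

    ``channels`` has shape ``(3, height, width)``; ``source_plane_indices``
    records which (1-based, strictly consecutive) planes the channels came
    from.
    """

    channels: np.ndarray
    source_plane_indices: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError(f"channels must have shape (3, H, W), got {self.channels.shape}")
        a, b, c = self.source_plane_indices
        if not (b == a + 1 and c == b + 1):
            raise ValueError(f"plane indices must be strictly consecutive, got {self.source_plane_indices}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1], self.channels.shape[2]


@dataclass
class AnnotationSet:
    """Point annotations of cell centres for one image.

    ``points`` is an ``(n, 2)`` integer array of 0-based ``(row, col)``
    coordinates; ``provenance`` marks whether the points were placed by a
    human (``"manual"``) or generated by auto-labeling (``"pseudo"``).
    """

    points: np.ndarray
    image_shape: tuple[int, int]
    provenance: str = "manual"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
        self.points = pts.astype(np.int64)
        h, w = self.image_shape
        if len(self.points):
            r, c = self.points[:, 0], self.points[:, 1]
            if (r < 0).any() or (r >= h).any() or (c < 0).any() or (c >= w).any():
                bad = self.points[(r < 0) | (r >= h) | (c < 0) | (c >= w)][0]
                raise ValueError(f"point {tuple(bad)} outside image of shape {self.image_shape}")
            if len(np.unique(self.points, axis=0)) != len(self.points):
                raise ValueError("duplicate annotation points")
        if self.provenance not in ("manual", "pseudo"):
            raise ValueError(f"provenance must be 'manual' or 'pseudo', got {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DetectionSet:
    """Detected cell centres with per-point confidences in [0, 1]."""

    points: np.ndarray
    confidences: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        self.points = pts.astype(np.int64)
        if self.confidences is None:
            self.confidences = np.ones(len(self.points))
        self.confidences = np.asarray(self.confidences, dtype=float)
        if len(self.confidences) != len(self.points):
            raise ValueError("one confidence per point required")
        if len(self.confidences) and (
            self.confidences.min() < 0.0 or self.confidences.max() > 1.0
        ):
            raise ValueError("confidences must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.points)


_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def read_zstack(path: str | os.PathLike, plane_spacing_um: float = 10.0,
                in_focus_index: int = 13) -> ZStack:
    """Read a focus stack from a multi-page TIFF (or a directory of planes).

    The canonical container is a multi-page TIFF with one focal plane per
    page, bottom plane first.  As a fallback dialect a directory of
    single-plane images is accepted; planes are taken in sorted filename
    order.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If pages differ in shape, or the stack has fewer planes than
        ``in_focus_index``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"no plane images found in directory {path}")
        pages = [tifffile.imread(f) if f.suffix.lower() != ".png" else _read_png(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"non-uniform plane shapes in {path}: {sorted(shapes)}")
        planes = np.stack(pages)
    else:
        planes = tifffile.imread(path)
        if planes.ndim == 2:
            planes = planes[None]
        if planes.ndim != 3:
            raise ValueError(f"expected a stack of 2-D pages, got array of shape {planes.shape}")
    if in_focus_index > planes.shape[0]:
        raise ValueError(
            f"in_focus_index {in_focus_index} exceeds the {planes.shape[0]} pages in {path}"
        )
    return ZStack(planes, plane_spacing_um=plane_spacing_um, in_focus_index=in_focus_index)


def _read_png(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_zstack(path: str | os.PathLike, stack: ZStack) -> None:
    """Write a z-stack as a multi-page TIFF, one plane per page."""
    tifffile.imwrite(Path(path), np.asarray(stack.planes))


def select_triplet(stack: ZStack, start_index: int, normalize: bool = True) -> PlaneTriplet:
    """Extract three consecutive planes as the detector's input channels.

    ``start_index`` is 1-based; the triplet consists of planes
    ``start_index, start_index+1, start_index+2`` (the default detector
    input is the in-focus plane and the two planes above it).

    With ``normalize=True`` (the default, and what the detector expects)
    each channel is rescaled to zero mean and unit variance; with
    ``normalize=False`` the channels are the raw plane intensities.
    """
    if start_index < 1 or start_index + 2 > stack.n_planes:
        raise ValueError(
            f"triplet ({start_index},{start_index + 1},{start_index + 2}) out of range "
            f"for a {stack.n_planes}-plane stack"
        )
    channels = np.asarray(stack.planes[start_index - 1 : start_index + 2])
    triplet = PlaneTriplet(
        channels=channels.copy(),
        source_plane_indices=(start_index, start_index + 1, start_index + 2),
    )
    return normalize_triplet(triplet) if normalize else triplet


def normalize_triplet(triplet: PlaneTriplet) -> PlaneTriplet:
    """Rescale each channel to zero mean, unit variance (z-score).

    The same affine normalization is applied at training and prediction
    time; it makes the detector robust to exposure differences between
    cultivations.  Constant channels map to all-zero.
    """
    x = triplet.channels.astype(np.float32)
    mean = x.mean(axis=(1, 2), keepdims=True)
    std = x.std(axis=(1, 2), keepdims=True)
    x = (x - mean) / np.where(std > 0, std, 1.0)
    return PlaneTriplet(channels=x, source_plane_indices=triplet.source_plane_indices)


def read_annotations(path: str | os.PathLike, image_shape: tuple[int, int],
                     provenance: str = "manual") -> AnnotationSet:
    """Read cell-centre annotations from a ``row,col`` CSV."""
    df = pd.read_csv(path)
    for col in ("row", "col"):
        if col not in df.columns:
            raise ValueError(f"annotation CSV {path} lacks required column {col!r}")
    points = df[["row", "col"]].to_numpy()
    return AnnotationSet(points=points, image_shape=image_shape, provenance=provenance)


def write_annotations(ann: AnnotationSet, path: str | os.PathLike) -> None:
    pd.DataFrame(ann.points, columns=["row", "col"]).to_csv(path, index=False)


def read_detections(path: str | os.PathLike) -> DetectionSet:
    """Read detections from a ``row,col,confidence`` CSV."""
    df = pd.read_csv(path)
    for col in ("row", "col", "confidence"):
        if col not in df.columns:
            raise ValueError(f"detection CSV {path} lacks required column {col!r}")
    return DetectionSet(points=df[["row", "col"]].to_numpy(),
                        confidences=df["confidence"].to_numpy())


def write_detections(det: DetectionSet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(det.points, columns=["row", "col"])
    df["confidence"] = det.confidences
    df.to_csv(path, index=False)
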
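"""Synthetic brightfield focus-stack generator with ground truth.

Cells in brightfield z-stacks are near-invisible in the focused plane
and gain contrast with defocus, with the sign of the contrast inverting
across the focal plane (bright above focus, dark below, or vice versa).
The generator reproduces that phenomenology: each cell is a radially
symmetric Gaussian blob whose amplitude is proportional to the signed
defocus and whose width grows with it.  This is a phenomenological
stand-in for through-focus optics, not a PSF simulation — it captures
the contrast inversion and blur growth that the detector exploits, and
nothing else.

Two presets mirror the appearance axes that separate easy from hard
cell lines: a sparse, high-contrast source domain of larger cells
growing separately, and a dense, low-contrast target domain of small
cells in touching clusters (0.4x the source radius, 0.5x the contrast),
where detectors trained on the source keep precision but lose recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stackdetect.iostack import AnnotationSet, ZStack

__all__ = [
    "DomainPreset",
    "SyntheticSample",
    "DomainPairBundle",
    "simulate_sample",
    "make_domain_pair",
    "sourcelike_preset",
    "targetlike_preset",
]


@dataclass
class DomainPreset:
    """Appearance parameters of one synthetic cell line.

    cell_radius_px / cell_radius_sd : blob radius distribution (px); the
        in-focus radius, widened by defocus.
    contrast : peak blob amplitude at maximal defocus, relative to a
        [0, 1] intensity scale.
    clustering : ``"none"`` (uniform placement) or ``"clustered"``
        (Matern-style parent/offspring clusters).
    n_cells : inclusive (lo, hi) range for the cell count per image.
    min_separation : minimum centre-to-centre distance (px).
    defocus_sign : +1 for cells bright above focus, -1 for the inverse.
    defocus_blur_slope : fractional radius growth per plane of defocus.
    """

    name: str = "custom"
    cell_radius_px: float = 5.0
    cell_radius_sd: float = 0.5
    contrast: float = 0.35
    clustering: str = "none"
    cluster_radius_px: float = 12.0
    cells_per_cluster: float = 6.0
    n_cells: tuple[int, int] = (15, 25)
    min_separation: float = 14.0
    defocus_sign: int = 1
    defocus_blur_slope: float = 0.3
    background_level: float = 0.5
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.cell_radius_px < 2:
            raise ValueError("cell radius must be >= 2 px")
        if self.clustering not in ("none", "clustered"):
            raise ValueError("clustering must be 'none' or 'clustered'")


def sourcelike_preset() -> DomainPreset:
    """Sparse, high-contrast cells growing separately (easy to detect)."""
    return DomainPreset(name="sourcelike")


def targetlike_preset() -> DomainPreset:
    """Dense, low-contrast clusters of small cells (0.4x radius, 0.5x contrast)."""
    return DomainPreset(
        name="targetlike",
        cell_radius_px=2.0,
        cell_radius_sd=0.2,
        contrast=0.175,
        clustering="clustered",
        cluster_radius_px=12.0,
        cells_per_cluster=6.0,
        n_cells=(25, 40),
        min_separation=6.0,
    )


@dataclass
class SyntheticSample:
    stack: ZStack
    truth: AnnotationSet
    preset: DomainPreset
    seed: int | None = None


@dataclass
class DomainPairBundle:
    """Datasets for a source-train / target-adapt experiment.

    ``source_train`` are annotated; ``target_pool`` images are the
    adaptation pool whose annotations exist only for scoring and must
    never be fed to training; both test lists are held out from all
    training and adaptation.
    """

    source_train: list[SyntheticSample]
    target_pool: list[SyntheticSample]
    source_test: list[SyntheticSample]
    target_test: list[SyntheticSample]


def _place_cells(
    preset: DomainPreset,
    shape: tuple[int, int],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample integer cell centres respecting the minimum separation."""
    h, w = shape
    margin = max(2, int(round(preset.cell_radius_px)))
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError(f"image {h}x{w} too small for cells of radius {preset.cell_radius_px}")
    min_d2 = preset.min_separation**2
    placed: list[tuple[int, int]] = []

    def far_enough(r: float, c: float) -> bool:
        return all((r - pr) ** 2 + (c - pc) ** 2 >= min_d2 for pr, pc in placed)

    max_tries = 400 * max(n, 1)
    tries = 0
    if preset.clustering == "none":
        while len(placed) < n:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not place {n} cells with separation {preset.min_separation} "
                    f"in a {h}x{w} image"
                )
            r = int(rng.integers(margin, h - margin))
            c = int(rng.integers(margin, w - margin))
            if far_enough(r, c):
                placed.append((r, c))
    else:
        n_parents = max(1, int(np.ceil(n / preset.cells_per_cluster)))
        parents = [
            (float(rng.uniform(margin, h - margin)), float(rng.uniform(margin, w - margin)))
            for _ in range(n_parents)
        ]
        while len(placed) < n:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not place {n} clustered cells with separation "
                    f"{preset.min_separation} in a {h}x{w} image"
                )
            pr, pc = parents[int(rng.integers(0, n_parents))]
            ang = rng.uniform(0, 2 * np.pi)
            rad = preset.cluster_radius_px * np.sqrt(rng.uniform())
            r = int(round(pr + rad * np.sin(ang)))
            c = int(round(pc + rad * np.cos(ang)))
            if margin <= r < h - margin and margin <= c < w - margin and far_enough(r, c):
                placed.append((r, c))
    return np.asarray(placed, dtype=np.int64).reshape(len(placed), 2)


def simulate_sample(
    preset: DomainPreset,
    image_shape: tuple[int, int] = (128, 128),
    n_planes: int = 5,
    rng: np.random.Generator | int | None = None,
) -> SyntheticSample:
    """Render one synthetic focus stack with its ground-truth annotations.

    Every cell appears in every plane as a Gaussian blob with amplitude
    ``contrast * sign * (p - focus) / half_range`` — zero at focus,
    opposite signs above and below it — and width
    ``radius * (1 + blur_slope * |p - focus|)``.  Additive Gaussian noise
    is applied last and intensities are clipped to [0, 1].
    """
    if n_planes < 3 or n_planes % 2 == 0:
        raise ValueError("n_planes must be odd and >= 3 (centre plane in focus)")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        rng = np.random.default_rng(rng)
    h, w = image_shape
    lo, hi = preset.n_cells
    n = int(rng.integers(lo, hi + 1))
    points = _place_cells(preset, image_shape, n, rng)
    radii = np.maximum(2.0, rng.normal(preset.cell_radius_px, preset.cell_radius_sd, n))
    focus = (n_planes + 1) // 2  # 1-based centre plane
    half_range = (n_planes - 1) / 2
    planes = np.full((n_planes, h, w), preset.background_level, dtype=np.float64)
    yy_full, xx_full = np.mgrid[0:h, 0:w]
    for p in range(1, n_planes + 1):
        dz = p - focus
        amp = preset.contrast * preset.defocus_sign * dz / half_range
        if amp == 0.0:
            continue
        for (r0, c0), rad in zip(points, radii):
            width = rad * (1.0 + preset.defocus_blur_slope * abs(dz))
            ext = int(np.ceil(4 * width))
            y0, y1 = max(0, r0 - ext), min(h, r0 + ext + 1)
            x0, x1 = max(0, c0 - ext), min(w, c0 + ext + 1)
            yy = yy_full[y0:y1, x0:x1] - r0
            xx = xx_full[y0:y1, x0:x1] - c0
            planes[p - 1, y0:y1, x0:x1] += amp * np.exp(
                -(yy * yy + xx * xx) / (2 * width * width)
            )
    planes += rng.normal(0.0, preset.noise_sigma, planes.shape)
    planes = np.clip(planes, 0.0, 1.0).astype(np.float32)
    stack = ZStack(planes, plane_spacing_um=10.0, in_focus_index=focus)
    truth = AnnotationSet(points=points, image_shape=image_shape, provenance="manual")
    return SyntheticSample(stack=stack, truth=truth, preset=preset, seed=seed)


def make_domain_pair(
    source_preset: DomainPreset,
    target_preset: DomainPreset,
    n_train: int = 12,
    n_target: int = 8,
    n_test: int = 4,
    image_shape: tuple[int, int] = (128, 128),
    n_planes: int = 5,
    rng: np.random.Generator | int | None = None,
) -> DomainPairBundle:
    """Generate a source-train / target-adapt dataset bundle.

    Defaults mirror the study design: 12 annotated source training
    images, an unannotated target pool for adaptation, and 4 held-out
    annotated test images per domain, disjoint (by construction, from
    independent random streams) from everything used in training or
    adaptation.
    """
    if source_preset == target_preset:
        raise ValueError("source and target presets must differ in at least one field")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    groups = rng.spawn(4)

    def batch(preset: DomainPreset, count: int, g: np.random.Generator):
        return [simulate_sample(preset, image_shape, n_planes, child)
                for child in g.spawn(count)]

    return DomainPairBundle(
        source_train=batch(source_preset, n_train, groups[0]),
        target_pool=batch(target_preset, n_target, groups[1]),
        source_test=batch(source_preset, n_test, groups[2]),
        target_test=batch(target_preset, n_test, groups[3]),
    )
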
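"""Synthetic three-channel immunofluorescence fixtures with known ground truth.

Generates DAPI / CK-EpCAM / CD45 channel images that emulate a microfluidic
CTC-enrichment output slide: a sparse field of nucleated cells where tumor
cells (CTCs) are round, CK/EpCAM-positive and CD45-negative, while white
blood cells are CD45-positive and may carry lobed, irregular nuclei.  Every
rendered cell is recorded in a ground-truth table so the downstream
segmentation, gating and enumeration pipeline can be validated exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

__all__ = [
    "CLASSES",
    "CellSpec",
    "FixtureConfig",
    "ImageFixture",
    "render_nucleus",
    "generate_fixture",
    "ground_truth_counts",
    "random_fixture_config",
    "write_fixture",
]

#: Recognized cell classes: DAPI+CK/EpCAM+CD45- tumor cells, CD45+ leukocytes,
#: double-stained cells and cells below both gates.
CLASSES = ("CTC", "WBC", "DUAL_POSITIVE", "NEGATIVE")

GROUND_TRUTH_COLUMNS = [
    "cell_id", "x", "y", "diameter_um", "n_lobes", "ck_epcam", "cd45", "true_class",
]


@dataclasses.dataclass
class CellSpec:
    """One cell to render: position, nuclear morphology and marker levels.

    ``n_lobes == 1`` gives a round nucleus; ``n_lobes >= 2`` gives a union of
    overlapping disks emulating the lobed nuclei of granulocytes.  ``center``
    is ``(x, y)`` in pixels, or ``None`` to let the generator place the cell.
    """

    center: tuple[float, float] | None
    nucleus_diameter: float  # um
    n_lobes: int
    ck_epcam_intensity: float
    cd45_intensity: float
    true_class: str

    def __post_init__(self) -> None:
        if self.nucleus_diameter <= 0:
            raise ValueError("nucleus_diameter must be positive")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if self.ck_epcam_intensity < 0 or self.cd45_intensity < 0:
            raise ValueError("intensities must be nonnegative")
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown true_class {self.true_class!r}")


@dataclasses.dataclass
class FixtureConfig:
    """Parameters of one synthetic slide."""

    image_size: tuple[int, int] = (512, 512)  # rows, cols
    pixel_size: float = 0.5  # um per pixel
    background_level: float = 10.0
    noise_sd: float = 0.0
    dna_intensity: float = 200.0  # nuclear stain level in the DAPI channel
    cells: list[CellSpec] = dataclasses.field(default_factory=list)
    seed: int = 0
    max_placement_retries: int = 1000
    min_gap_px: float = 8.0  # clearance between auto-placed nuclei so
    # neighbors stay resolvable after segmentation and secondary expansion

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background_level and noise_sd must be nonnegative")


@dataclasses.dataclass
class ImageFixture:
    """Rendered channels plus the ground-truth cell table."""

    dna_channel: np.ndarray
    ck_epcam_channel: np.ndarray
    cd45_channel: np.ndarray
    ground_truth: pd.DataFrame
    pixel_size: float

    def __post_init__(self) -> None:
        shapes = {self.dna_channel.shape, self.ck_epcam_channel.shape, self.cd45_channel.shape}
        if len(shapes) != 1:
            raise ValueError("channel shapes differ")


def render_nucleus(spec: CellSpec, pixel_size: float) -> np.ndarray:
    """Rasterize a nucleus footprint as a boolean mask.

    A single-lobed nucleus is a disk of the requested diameter.  A nucleus
    with ``k >= 2`` lobes is the union of ``k`` disks of that diameter whose
    centers are spaced 0.6 diameters apart along one axis, which yields an
    elongated footprint whose fitted-ellipse eccentricity exceeds a disk's.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    d_px = spec.nucleus_diameter / pixel_size
    r = d_px / 2.0
    spacing = 0.6 * d_px
    extent = d_px + (spec.n_lobes - 1) * spacing
    size_y = int(np.ceil(d_px)) + 3
    size_x = int(np.ceil(extent)) + 3
    yy, xx = np.mgrid[0:size_y, 0:size_x]
    cy = (size_y - 1) / 2.0
    x0 = (size_x - 1) / 2.0 - (spec.n_lobes - 1) * spacing / 2.0
    mask = np.zeros((size_y, size_x), dtype=bool)
    for k in range(spec.n_lobes):
        cx = x0 + k * spacing
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not mask.any():
        raise ValueError("nucleus smaller than one pixel at this pixel_size")
    return mask


def _paint(channel: np.ndarray, mask: np.ndarray, center: tuple[float, float], value: float) -> np.ndarray | None:
    """Add ``value`` over ``mask`` centered at ``center`` (x, y); return the
    painted footprint as a boolean image, or None if out of bounds."""
    h, w = channel.shape
    mh, mw = mask.shape
    top = int(round(center[1] - (mh - 1) / 2.0))
    left = int(round(center[0] - (mw - 1) / 2.0))
    if top < 0 or left < 0 or top + mh > h or left + mw > w:
        return None
    footprint = np.zeros((h, w), dtype=bool)
    footprint[top : top + mh, left : left + mw] = mask
    channel[footprint] += value
    return footprint


def generate_fixture(config: FixtureConfig) -> ImageFixture:
    """Render all cells of ``config`` into three channels.

    Nuclear footprints must not overlap: cells with fixed centers that collide
    raise, cells with ``center=None`` are placed by rejection sampling (up to
    ``max_placement_retries`` draws) keeping at least ``min_gap_px`` between
    bounding circles so neighbors stay separable.  The same config and seed
    always produce bit-identical images.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    dna = np.zeros((h, w), dtype=np.float64)
    ck = np.zeros((h, w), dtype=np.float64)
    cd45 = np.zeros((h, w), dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)

    rows = []
    for i, spec in enumerate(config.cells):
        mask = render_nucleus(spec, config.pixel_size)
        mh, mw = mask.shape
        if mh > h or mw > w:
            raise ValueError(f"cell {i}: nucleus footprint {mask.shape} exceeds image {config.image_size}")
        radius = 0.5 * float(np.hypot(mh, mw))
        placed_center = None
        if spec.center is not None:
            fp = _paint(np.zeros_like(dna), mask, spec.center, 1.0)
            if fp is None:
                raise ValueError(f"cell {i}: footprint extends beyond the image")
            if (fp & occupied).any():
                raise ValueError(f"cell {i}: overlaps a previously placed cell")
            placed_center = spec.center
        else:
            for _ in range(config.max_placement_retries):
                cx = rng.uniform((mw - 1) / 2.0, w - 1 - (mw - 1) / 2.0)
                cy = rng.uniform((mh - 1) / 2.0, h - 1 - (mh - 1) / 2.0)
                clear = all(
                    np.hypot(cx - px, cy - py) >= radius + pr + config.min_gap_px
                    for px, py, pr in placed
                )
                if clear:
                    placed_center = (cx, cy)
                    break
            else:
                raise RuntimeError(
                    f"cell {i}: could not place without overlap after "
                    f"{config.max_placement_retries} retries"
                )
        fp = _paint(dna, mask, placed_center, config.dna_intensity)
        _paint(ck, mask, placed_center, spec.ck_epcam_intensity)
        _paint(cd45, mask, placed_center, spec.cd45_intensity)
        occupied |= fp
        placed.append((placed_center[0], placed_center[1], radius))
        rows.append(
            {
                "cell_id": i,
                "x": placed_center[0],
                "y": placed_center[1],
                "diameter_um": spec.nucleus_diameter,
                "n_lobes": spec.n_lobes,
                "ck_epcam": spec.ck_epcam_intensity,
                "cd45": spec.cd45_intensity,
                "true_class": spec.true_class,
            }
        )

    for channel in (dna, ck, cd45):
        channel += config.background_level
        if config.noise_sd > 0:
            channel += rng.normal(0.0, config.noise_sd, size=channel.shape)
        np.clip(channel, 0.0, None, out=channel)

    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return ImageFixture(dna, ck, cd45, truth, config.pixel_size)


def ground_truth_counts(fixture: ImageFixture) -> dict[str, int]:
    """Per-class cell counts of the ground-truth table (all classes reported)."""
    counts = {c: 0 for c in CLASSES}
    for cls, n in fixture.ground_truth["true_class"].value_counts().items():
        counts[str(cls)] += int(n)
    return counts


def random_fixture_config(
    rng: np.random.Generator,
    n_ctc: int = 5,
    n_wbc: int = 20,
    n_dual: int = 2,
    n_negative: int = 2,
    image_size: tuple[int, int] = (512, 512),
    pixel_size: float = 0.5,
    noise_sd: float = 0.0,
    lobed_wbc_fraction: float = 0.0,
    ck_positive: float = 180.0,
    cd45_positive: float = 150.0,
    marker_negative: float = 2.0,
) -> FixtureConfig:
    """Draw a fixture config with separable marker levels.

    Emulates a typical enrichment output: a minority of CTCs among leukocytes.
    Nuclear diameters are drawn uniformly from 10-18 um (inside the 9-36 um
    analysis window).  ``lobed_wbc_fraction`` of WBCs get 2-3 lobed nuclei.
    """
    cells: list[CellSpec] = []

    def diam() -> float:
        return float(rng.uniform(10.0, 18.0))

    for _ in range(n_ctc):
        cells.append(CellSpec(None, diam(), 1, ck_positive, marker_negative, "CTC"))
    for _ in range(n_wbc):
        lobes = int(rng.integers(2, 4)) if rng.random() < lobed_wbc_fraction else 1
        cells.append(CellSpec(None, diam(), lobes, marker_negative, cd45_positive, "WBC"))
    for _ in range(n_dual):
        cells.append(CellSpec(None, diam(), 1, ck_positive, cd45_positive, "DUAL_POSITIVE"))
    for _ in range(n_negative):
        cells.append(CellSpec(None, diam(), 1, marker_negative, marker_negative, "NEGATIVE"))
    order = rng.permutation(len(cells))
    cells = [cells[i] for i in order]
    return FixtureConfig(
        image_size=image_size,
        pixel_size=pixel_size,
        noise_sd=noise_sd,
        cells=cells,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_fixture(fixture: ImageFixture, out_dir: str | Path, fmt: str = "tiff") -> dict[str, Path]:
    """Write channels (16-bit TIFF or PNG) and the ground-truth CSV.

    Float intensities are rounded and clipped into the uint16 range.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    channels = {
        "dna": fixture.dna_channel,
        "ck_epcam": fixture.ck_epcam_channel,
        "cd45": fixture.cd45_channel,
    }
    ext = {"tiff": "tif", "png": "png"}[fmt]
    for name, arr in channels.items():
        data = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
        path = out / f"{name}.{ext}"
        if fmt == "tiff":
            tifffile.imwrite(path, data)
        else:
            iio.imwrite(path, data)
        paths[name] = path
    truth_path = out / "ground_truth.csv"
    fixture.ground_truth.to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path
    return paths
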
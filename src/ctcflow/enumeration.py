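"""CTC identification and enumeration from three-channel fluorescence images.

Re-implements the seven-step enumeration pipeline used on microfluidic
enrichment outputs: (1) primary (nucleus) segmentation with a global
threshold on the DNA channel; (2-3) size and eccentricity filtering to drop
debris, clumps, and lobed-nucleus leukocytes; (4) secondary-object expansion
around each nucleus; (5) mean CK/EpCAM and CD45 intensity measurement inside
the secondary objects; (6) export of a per-object measurement table; (7)
intensity gating into CTC / WBC / dual-positive / negative classes,
enumeration, CTC purity, and an image gallery.
"""

from __future__ import annotations

import dataclasses
import sqlite3
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import filters as skfilters
from skimage import segmentation as sksegmentation

from .synthetic_fixtures import CLASSES, ImageFixture

__all__ = [
    "LabeledMask",
    "PrimaryObject",
    "CellMeasurement",
    "GateConfig",
    "CellRecord",
    "EnumerationResult",
    "CalibrationWarning",
    "segment_primary",
    "measure_shape",
    "filter_primary",
    "expand_secondary",
    "measure_intensity",
    "calibrate_gates",
    "classify_cells",
    "enumerate_cells",
    "run_pipeline",
    "measurements_table",
    "export_measurements",
    "export_gallery",
]


class CalibrationWarning(UserWarning):
    """Raised when the positive staining control fails its gate check."""


@dataclasses.dataclass
class LabeledMask:
    """Integer label image (0 = background) with its pixel size in um/px."""

    labels: np.ndarray
    pixel_size: float

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclasses.dataclass
class PrimaryObject:
    """Shape measurements of one segmented nucleus."""

    object_id: int
    centroid: tuple[float, float]  # (row, col) px
    area_px: int
    equivalent_diameter_um: float
    eccentricity: float


@dataclasses.dataclass
class CellMeasurement:
    object_id: int
    mean_ck_epcam: float
    mean_cd45: float
    shape: PrimaryObject | None = None


@dataclasses.dataclass
class GateConfig:
    """Gating and filtering parameters of the enumeration pipeline.

    The diameter window (9-36 um, inclusive) keeps single nucleated cells.
    The eccentricity ceiling excludes lobed/irregular leukocyte nuclei; the
    underlying image software never publishes a canonical value, so the 0.80
    default is an explicit, configurable choice.  Intensity thresholds are
    usually set from staining controls via :func:`calibrate_gates`.
    """

    ck_epcam_positive_threshold: float = 50.0
    cd45_positive_threshold: float = 50.0
    diameter_min: float = 9.0
    diameter_max: float = 36.0
    eccentricity_max: float = 0.80
    secondary_expand_radius: int = 3
    calibration_k: float = 3.0

    def __post_init__(self) -> None:
        if not self.diameter_min < self.diameter_max:
            raise ValueError("diameter_min must be < diameter_max")
        if not 0 < self.eccentricity_max <= 1:
            raise ValueError("eccentricity_max must be in (0, 1]")
        if self.ck_epcam_positive_threshold < 0 or self.cd45_positive_threshold < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.secondary_expand_radius < 0:
            raise ValueError("secondary_expand_radius must be >= 0")


@dataclasses.dataclass
class CellRecord:
    measurement: CellMeasurement
    assigned_class: str


@dataclasses.dataclass
class EnumerationResult:
    """Per-class counts and CTC purity for one sample.

    ``ctc_purity`` (CTC count / total cell count) is ``None`` with
    ``purity_defined=False`` when no cells were counted: an empty field of
    view carries no purity information and must not masquerade as purity 0.
    """

    counts: dict[str, int]
    total_cells: int
    ctc_purity: float | None
    purity_defined: bool

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total_cells": self.total_cells,
            "ctc_purity": self.ctc_purity,
            "purity_defined": self.purity_defined,
        }


# --- step 1: primary object identification -------------------------------

def _threshold_otsu(image: np.ndarray) -> float:
    return float(skfilters.threshold_otsu(image))


def _threshold_quantile(image: np.ndarray, q: float = 0.95) -> float:
    return float(np.quantile(image, q))


THRESHOLD_STRATEGIES: dict[str, callable] = {
    "otsu": _threshold_otsu,
    "quantile": _threshold_quantile,
}


def segment_primary(
    dna_channel: np.ndarray,
    pixel_size: float,
    strategy: str = "otsu",
    fixed_threshold: float | None = None,
) -> LabeledMask:
    """Segment nuclei with a single global threshold over the DNA image.

    Foreground is split into 4-connected components, holes are filled, and
    objects touching the image border are removed (cells cut by the field of
    view cannot be measured).  A constant image yields zero objects.
    """
    dna = np.asarray(dna_channel, dtype=np.float64)
    if dna.ndim != 2:
        raise ValueError("dna_channel must be a 2-D array")
    if strategy == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed strategy requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        try:
            estimator = THRESHOLD_STRATEGIES[strategy]
        except KeyError:
            raise ValueError(f"unknown threshold strategy {strategy!r}") from None
        if np.ptp(dna) == 0:  # constant image: nothing to segment
            return LabeledMask(np.zeros(dna.shape, dtype=np.int32), pixel_size)
        thr = estimator(dna)
    binary = dna > thr
    binary = ndimage.binary_fill_holes(binary)
    binary = sksegmentation.clear_border(binary)
    labels = skmeasure.label(binary, connectivity=1)
    return LabeledMask(labels.astype(np.int32), pixel_size)


# --- steps 2-3: shape measurement and filtering --------------------------

def measure_shape(mask: LabeledMask) -> list[PrimaryObject]:
    """Measure area, equivalent diameter and ellipse-fit eccentricity.

    Equivalent diameter is the diameter of the circle with the object's area,
    converted to um.  Eccentricity is the ratio of the between-foci distance
    to the major axis length of the ellipse with the same second central
    moments; 0 for a circle, approaching 1 for elongated shapes.
    """
    out: list[PrimaryObject] = []
    for prop in skmeasure.regionprops(mask.labels):
        area = int(prop.area)
        diam_um = 2.0 * np.sqrt(area / np.pi) * mask.pixel_size
        out.append(
            PrimaryObject(
                object_id=int(prop.label),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=area,
                equivalent_diameter_um=float(diam_um),
                eccentricity=float(prop.eccentricity),
            )
        )
    return out


def filter_primary(objects: list[PrimaryObject], gates: GateConfig) -> list[PrimaryObject]:
    """Keep nuclei inside the closed diameter window and below the
    eccentricity ceiling; input order is preserved."""
    return [
        o
        for o in objects
        if gates.diameter_min <= o.equivalent_diameter_um <= gates.diameter_max
        and o.eccentricity <= gates.eccentricity_max
    ]


# --- step 4: secondary objects -------------------------------------------

def expand_secondary(mask: LabeledMask, radius: int) -> LabeledMask:
    """Grow each primary object by ``radius`` pixels.

    Expansion is distance-limited; contested pixels go to the nearest primary
    object, so expansions never merge and the object count is preserved.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return LabeledMask(mask.labels.copy(), mask.pixel_size)
    expanded = sksegmentation.expand_labels(mask.labels, distance=radius)
    return LabeledMask(expanded.astype(mask.labels.dtype), mask.pixel_size)


# --- step 5: intensity measurement ---------------------------------------

def measure_intensity(mask: LabeledMask, channel: np.ndarray) -> dict[int, float]:
    """Arithmetic mean channel intensity under each label."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != mask.labels.shape:
        raise ValueError("mask and channel shapes differ")
    ids = np.arange(1, mask.n_objects + 1)
    if ids.size == 0:
        return {}
    means = ndimage.mean(channel, labels=mask.labels, index=ids)
    return {int(i): float(m) for i, m in zip(ids, means)}


# --- gating ----------------------------------------------------------------

def calibrate_gates(
    positive_control: list[CellMeasurement],
    isotype_control: list[CellMeasurement],
    k: float = 3.0,
    base: GateConfig | None = None,
) -> GateConfig:
    """Set intensity gates from staining controls.

    Each channel's positive threshold is mean + k*SD of the isotype
    (negative) control, the usual negative-control gating rule.  If fewer
    than 90% of positive-control cells clear the CK/EpCAM gate a
    :class:`CalibrationWarning` is raised (staining likely failed).
    """
    if not isotype_control:
        raise ValueError("isotype control must be non-empty")
    ck = np.array([m.mean_ck_epcam for m in isotype_control], dtype=float)
    cd = np.array([m.mean_cd45 for m in isotype_control], dtype=float)
    ck_sd = float(np.std(ck, ddof=1)) if ck.size > 1 else 0.0
    cd_sd = float(np.std(cd, ddof=1)) if cd.size > 1 else 0.0
    ck_thr = float(np.mean(ck)) + k * ck_sd
    cd_thr = float(np.mean(cd)) + k * cd_sd
    if positive_control:
        frac = np.mean([m.mean_ck_epcam > ck_thr for m in positive_control])
        if frac < 0.90:
            warnings.warn(
                f"only {frac:.0%} of positive-control cells exceed the CK/EpCAM gate",
                CalibrationWarning,
                stacklevel=2,
            )
    base = base or GateConfig()
    return dataclasses.replace(
        base,
        ck_epcam_positive_threshold=ck_thr,
        cd45_positive_threshold=cd_thr,
        calibration_k=k,
    )


def classify_cells(measurements: list[CellMeasurement], gates: GateConfig) -> list[CellRecord]:
    """Assign each cell to exactly one class by marker gating.

    CTC: CK/EpCAM above gate, CD45 at or below gate.  DUAL_POSITIVE: both
    above.  WBC: only CD45 above.  NEGATIVE: neither.
    """
    records = []
    for m in measurements:
        ck_pos = m.mean_ck_epcam > gates.ck_epcam_positive_threshold
        cd_pos = m.mean_cd45 > gates.cd45_positive_threshold
        if ck_pos and not cd_pos:
            cls = "CTC"
        elif ck_pos and cd_pos:
            cls = "DUAL_POSITIVE"
        elif cd_pos:
            cls = "WBC"
        else:
            cls = "NEGATIVE"
        records.append(CellRecord(m, cls))
    return records


def enumerate_cells(records: list[CellRecord]) -> EnumerationResult:
    """Count cells per class and compute CTC purity = CTC / total."""
    counts = {c: 0 for c in CLASSES}
    for r in records:
        counts[r.assigned_class] += 1
    total = len(records)
    if total == 0:
        return EnumerationResult(counts, 0, None, False)
    return EnumerationResult(counts, total, counts["CTC"] / total, True)


# --- end-to-end convenience -----------------------------------------------

def run_pipeline(
    dna: np.ndarray,
    ck_epcam: np.ndarray,
    cd45: np.ndarray,
    pixel_size: float,
    gates: GateConfig,
    strategy: str = "otsu",
    fixed_threshold: float | None = None,
) -> tuple[list[CellRecord], EnumerationResult, LabeledMask]:
    """Segment, filter, expand, measure, classify and enumerate one field."""
    primary = segment_primary(dna, pixel_size, strategy, fixed_threshold)
    shapes = measure_shape(primary)
    kept = filter_primary(shapes, gates)
    kept_ids = {o.object_id for o in kept}
    pruned = primary.labels.copy()
    pruned[~np.isin(pruned, list(kept_ids) or [0])] = 0
    pruned_mask = LabeledMask(pruned, pixel_size)
    secondary = expand_secondary(pruned_mask, gates.secondary_expand_radius)
    # expand_secondary preserves label ids, so means are keyed per object
    ck_means = _means_for(secondary, ck_epcam, kept_ids)
    cd_means = _means_for(secondary, cd45, kept_ids)
    shape_by_id = {o.object_id: o for o in kept}
    measurements = [
        CellMeasurement(i, ck_means[i], cd_means[i], shape_by_id[i])
        for i in sorted(kept_ids)
    ]
    records = classify_cells(measurements, gates)
    return records, enumerate_cells(records), pruned_mask


def _means_for(mask: LabeledMask, channel: np.ndarray, ids: set[int]) -> dict[int, float]:
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != mask.labels.shape:
        raise ValueError("mask and channel shapes differ")
    if not ids:
        return {}
    index = sorted(ids)
    means = ndimage.mean(channel, labels=mask.labels, index=index)
    return {int(i): float(m) for i, m in zip(index, means)}


# --- step 6: data export ---------------------------------------------------

def measurements_table(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        m = r.measurement
        row = {
            "object_id": m.object_id,
            "mean_ck_epcam": m.mean_ck_epcam,
            "mean_cd45": m.mean_cd45,
            "assigned_class": r.assigned_class,
        }
        if m.shape is not None:
            row.update(
                centroid_row=m.shape.centroid[0],
                centroid_col=m.shape.centroid[1],
                area_px=m.shape.area_px,
                equivalent_diameter_um=m.shape.equivalent_diameter_um,
                eccentricity=m.shape.eccentricity,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def export_measurements(records: list[CellRecord], csv_path: str | Path, sqlite_path: str | Path | None = None) -> None:
    """Write the per-object table as CSV and optionally a one-table SQLite DB."""
    table = measurements_table(records)
    table.to_csv(csv_path, index=False)
    if sqlite_path is not None:
        with sqlite3.connect(sqlite_path) as conn:
            table.to_sql("per_object", conn, if_exists="replace", index=False)


# --- step 7: gallery -------------------------------------------------------

def export_gallery(
    fixture: ImageFixture,
    records: list[CellRecord],
    out_dir: str | Path,
    crop_px: int = 48,
) -> dict[str, Path]:
    """Write one RGB montage PNG per non-empty class.

    Each tile is a crop centered on the cell's nucleus centroid, composited
    with the conventional channel colors: DAPI blue, CK/EpCAM green, CD45
    red.  Classes without cells produce no file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def norm(a: np.ndarray) -> np.ndarray:
        hi = float(a.max())
        return a / hi if hi > 0 else a

    rgb = np.stack(
        [norm(fixture.cd45_channel), norm(fixture.ck_epcam_channel), norm(fixture.dna_channel)],
        axis=-1,
    )
    h, w = fixture.dna_channel.shape
    half = crop_px // 2
    paths: dict[str, Path] = {}
    for cls in CLASSES:
        tiles = []
        for r in records:
            if r.assigned_class != cls or r.measurement.shape is None:
                continue
            cy, cx = (int(round(v)) for v in r.measurement.shape.centroid)
            cy = min(max(cy, half), h - half)
            cx = min(max(cx, half), w - half)
            tiles.append(rgb[cy - half : cy + half, cx - half : cx + half])
        if not tiles:
            continue
        montage = np.concatenate(tiles, axis=1)
        path = out / f"gallery_{cls.lower()}.png"
        iio.imwrite(path, (np.clip(montage, 0, 1) * 255).astype(np.uint8))
        paths[cls] = path
    return paths
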
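"""File formats: labelme point annotations, PNG/DICOM images, manifests, reports.

Landmark annotations use the labelme JSON dialect — one point shape per
landmark with labels C2A, C2P, C7A, C7P (configurable via a label map).
Coordinates are 0-based pixel positions, x right, y down, exactly as
labelme stores them.  Readers reject malformed inputs rather than
silently repairing them; writers are byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

from .evaluation import MeasurementRecord, round_half_away
from .geometry import LANDMARK_LABELS, LandmarkSet, Point2D
from .normative import POSTURES

__all__ = [
    "Annotation",
    "read_labelme",
    "write_labelme",
    "load_image",
    "load_manifest",
    "write_manifest",
    "write_measurements",
    "read_measurements",
    "write_summary",
]

PathLike = Union[str, Path]

LABELME_VERSION = "5.2.1"

MEASUREMENT_COLUMNS = [
    "image_id",
    "patient_id",
    "posture",
    "c2_slope_true",
    "c7_slope_true",
    "angle_true",
    "c2_slope_pred",
    "c7_slope_pred",
    "angle_pred",
    "confidence",
    "abs_error_angle",
]


@dataclass(frozen=True)
class Annotation:
    """Four named landmark points bound to one image."""

    image_path: str
    image_height: int
    image_width: int
    points: Tuple[Tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.points]
        if sorted(labels) != sorted(LANDMARK_LABELS):
            raise ValueError(
                f"annotation must contain exactly {LANDMARK_LABELS}, got {labels}"
            )
        for label, x, y in self.points:
            if not (0 <= x < self.image_width and 0 <= y < self.image_height):
                raise ValueError(
                    f"landmark {label} at ({x}, {y}) outside "
                    f"{self.image_width}x{self.image_height} image"
                )

    def to_landmarks(self) -> LandmarkSet:
        by_label = {p[0]: Point2D(p[1], p[2]) for p in self.points}
        return LandmarkSet(*(by_label[lbl] for lbl in LANDMARK_LABELS))

    @classmethod
    def from_landmarks(
        cls,
        landmarks: LandmarkSet,
        image_path: str,
        image_height: int,
        image_width: int,
    ) -> "Annotation":
        points = tuple(
            (label, float(p.x), float(p.y))
            for label, p in zip(LANDMARK_LABELS, landmarks.as_tuple())
        )
        return cls(
            image_path=image_path,
            image_height=image_height,
            image_width=image_width,
            points=points,
        )


def read_labelme(
    path: PathLike, label_map: Optional[Mapping[str, str]] = None
) -> Annotation:
    """Read a labelme JSON annotation with four named landmark points.

    ``label_map`` translates alternative label strings to the canonical
    C2A/C2P/C7A/C7P dialect.  Non-point shapes or unknown labels are
    ignored with a warning; a missing or duplicated landmark label is an
    error naming the label.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed labelme JSON in {path}: {exc}") from exc
    if "shapes" not in data or not isinstance(data["shapes"], list):
        raise ValueError(f"{path} has no labelme 'shapes' array")
    label_map = dict(label_map or {})
    found: Dict[str, Tuple[float, float]] = {}
    for shape in data["shapes"]:
        raw_label = shape.get("label", "")
        label = label_map.get(raw_label, raw_label)
        if shape.get("shape_type") != "point" or label not in LANDMARK_LABELS:
            warnings.warn(
                f"ignoring shape {raw_label!r} ({shape.get('shape_type')}) "
                f"in {path.name}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if label in found:
            raise ValueError(f"duplicate landmark label {label} in {path}")
        pts = shape.get("points")
        if not pts or len(pts) != 1 or len(pts[0]) != 2:
            raise ValueError(f"landmark {label} in {path} is not a single point")
        found[label] = (float(pts[0][0]), float(pts[0][1]))
    missing = [lbl for lbl in LANDMARK_LABELS if lbl not in found]
    if missing:
        raise ValueError(f"missing landmark label(s) {missing} in {path}")
    return Annotation(
        image_path=str(data.get("imagePath", "")),
        image_height=int(data["imageHeight"]),
        image_width=int(data["imageWidth"]),
        points=tuple((lbl, *found[lbl]) for lbl in LANDMARK_LABELS),
    )


def write_labelme(annotation: Annotation, path: PathLike) -> None:
    """Write an annotation as labelme-compatible JSON (imageData null)."""
    shapes = [
        {
            "label": label,
            "points": [[x, y]],
            "group_id": None,
            "shape_type": "point",
            "flags": {},
        }
        for label, x, y in annotation.points
    ]
    payload = {
        "version": LABELME_VERSION,
        "flags": {},
        "shapes": shapes,
        "imagePath": annotation.image_path,
        "imageData": None,
        "imageHeight": annotation.image_height,
        "imageWidth": annotation.image_width,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_image(path: PathLike, voi_lut: bool = False) -> np.ndarray:
    """Load a radiograph as an 8-bit grayscale array (H, W) uint8.

    PNG (or other PIL-readable) files are loaded as-is; RGB is converted
    to single-channel luminance.  DICOM files are windowed to 8 bits by
    a min-max map over the stored pixel range (deterministic default);
    ``voi_lut=True`` applies the file's VOI LUT / windowing when present.
    MONOCHROME1 photometric interpretation is inverted so that bone is
    bright.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom", ".ima"):
        return _load_dicom(path, voi_lut=voi_lut)
    with Image.open(path) as img:
        if img.mode in ("RGB", "RGBA"):
            img = img.convert("L")
        if img.mode != "L":
            raise ValueError(
                f"unsupported PNG bit depth/mode {img.mode!r} in {path}; "
                "expected 8-bit grayscale"
            )
        return np.asarray(img, dtype=np.uint8)


def _load_dicom(path: Path, voi_lut: bool) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise ValueError(f"{path} has no pixel data")
    pixels = ds.pixel_array.astype(np.float64)
    if voi_lut:
        from pydicom.pixels import apply_voi_lut

        pixels = apply_voi_lut(ds.pixel_array, ds).astype(np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi > lo:
        scaled = (pixels - lo) / (hi - lo) * 255.0
    else:
        scaled = np.zeros_like(pixels)
    out = np.round(scaled).astype(np.uint8)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        out = 255 - out
    return out


def load_manifest(path: PathLike, check_paths: bool = True) -> pd.DataFrame:
    """Load a dataset manifest CSV (columns image, annotation, patient_id, posture)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ["image", "annotation", "patient_id", "posture"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s) {missing}")
    bad_postures = set(df["posture"]) - set(POSTURES)
    if bad_postures:
        raise ValueError(f"manifest has unknown posture(s) {sorted(bad_postures)}")
    if check_paths:
        base = Path(path).parent
        for col in ("image", "annotation"):
            for p in df[col]:
                resolved = Path(p)
                if not resolved.is_absolute():
                    resolved = base / p
                if not resolved.exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def write_manifest(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, columns=["image", "annotation", "patient_id", "posture"])


def resolve_manifest_path(manifest_path: PathLike, entry: str) -> Path:
    """Resolve a (possibly relative) manifest entry against the manifest dir."""
    p = Path(entry)
    return p if p.is_absolute() else Path(manifest_path).parent / p


def write_measurements(records: Sequence[MeasurementRecord], path: PathLike) -> None:
    """Write measurement records as CSV, angles rounded to 2 decimals."""
    rows = []
    for r in records:
        rows.append(
            {
                "image_id": r.image_id,
                "patient_id": r.patient_id,
                "posture": r.posture,
                "c2_slope_true": round_half_away(r.truth.c2_slope, 2),
                "c7_slope_true": round_half_away(r.truth.c7_slope, 2),
                "angle_true": round_half_away(r.truth.c2c7_angle, 2),
                "c2_slope_pred": round_half_away(r.prediction.c2_slope, 2),
                "c7_slope_pred": round_half_away(r.prediction.c7_slope, 2),
                "angle_pred": round_half_away(r.prediction.c2c7_angle, 2),
                "confidence": (
                    "" if r.confidence is None else round_half_away(r.confidence, 4)
                ),
                "abs_error_angle": round_half_away(r.abs_error_angle, 2),
            }
        )
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements(path: PathLike) -> pd.DataFrame:
    """Read a measurements CSV back as a DataFrame."""
    df = pd.read_csv(path, dtype={"patient_id": str, "image_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurements CSV missing column(s) {missing}")
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_summary(summaries, path: PathLike) -> None:
    """Write summaries (dataclasses/dicts/arrays) as full-precision JSON."""
    Path(path).write_text(json.dumps(_jsonable(summaries), indent=2) + "\n")
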
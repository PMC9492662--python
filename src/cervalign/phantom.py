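"""Synthetic lateral cervical radiograph phantoms with exact ground truth.

Each phantom patient is a stack of six vertebral bodies (C2-C7) rendered
as soft-edged bright quadrilaterals on a noisy, bias-shaded background,
posed at three postures (flexion, neutral, extension).  The C2 and C7
inferior endplate orientations are constructed analytically so that the
C2-C7 Cobb angle of the emitted ground-truth landmarks equals a target
angle drawn from posture-conditional truncated normal distributions
whose defaults match the normative clinical cohort.

Difficulty artifacts mirror the failure modes seen clinically:
osteophyte spurs (drawn beyond a vertebral corner while the ground-truth
landmark stays on the original corner), fused vertebrae, posterior
instrumentation, and a bright shoulder band obscuring C7.  Artifacts are
purely decorative: they never move the ground truth.

Rendering is deliberately schematic — there is no projection physics —
so phantom-based error figures are properties of this artifact, not
claims about clinical images.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm
from skimage.draw import polygon as draw_polygon

from .geometry import LandmarkSet, Point2D, measure_from_landmarks
from .io import Annotation, write_labelme, write_manifest
from .normative import COHORT_STATS, POSTURES

__all__ = [
    "PosturePhantomParams",
    "ArtifactProbs",
    "PhantomSpec",
    "PhantomImage",
    "PhantomPatient",
    "sample_posture_angle",
    "generate_patient",
    "generate_dataset",
    "generate_arrays",
]


@dataclass(frozen=True)
class PosturePhantomParams:
    """Sampling parameters for one posture (degrees).

    The C2-C7 angle is drawn from Normal(angle_mean, angle_sd) truncated
    to [angle_min, angle_max]; the C2 slope from a normal truncated to
    +/- 2 SD (keeping the rendered spine on-canvas), and the C7 slope is
    then c2_slope + angle, reproducing the joint structure downstream
    posture classification relies on.
    """

    angle_mean: float
    angle_sd: float
    angle_min: float
    angle_max: float
    c2_slope_mean: float
    c2_slope_sd: float


def _default_posture_params() -> Dict[str, PosturePhantomParams]:
    out = {}
    for posture in POSTURES:
        st = COHORT_STATS[posture]
        out[posture] = PosturePhantomParams(
            angle_mean=st.c2c7_angle.mean,
            angle_sd=st.c2c7_angle.sd,
            angle_min=st.c2c7_angle.min,
            angle_max=st.c2c7_angle.max,
            c2_slope_mean=st.c2_slope.mean,
            c2_slope_sd=st.c2_slope.sd,
        )
    return out


@dataclass(frozen=True)
class ArtifactProbs:
    """Per-patient (per-image for occlusion) artifact probabilities.

    Defaults approximate a degenerative surgical-referral population:
    osteophytes are common, ~17% of patients carry instrumentation
    (matching the cohort's surgical fraction), congenital/surgical
    fusion is uncommon, and the shoulder girdle frequently encroaches
    on C7 in lateral views.
    """

    osteophyte: float = 0.4
    fused_vertebrae: float = 0.08
    instrumentation: float = 0.17
    shoulder_occlusion: float = 0.3

    def __post_init__(self) -> None:
        for name in ("osteophyte", "fused_vertebrae", "instrumentation",
                     "shoulder_occlusion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} probability {p} outside [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of the phantom generator."""

    image_size: int = 128
    posture_params: Dict[str, PosturePhantomParams] = field(
        default_factory=_default_posture_params
    )
    artifact_probs: ArtifactProbs = field(default_factory=ArtifactProbs)
    noise_sd: float = 0.03
    bias_amplitude: float = 0.08
    seed: int = 0
    retry_limit: int = 25

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise parameters must be non-negative")
        for posture, p in self.posture_params.items():
            if p.angle_sd <= 0 or p.c2_slope_sd <= 0:
                raise ValueError(f"{posture}: sd must be positive")
            if p.angle_min >= p.angle_max:
                raise ValueError(f"{posture}: angle_min must be < angle_max")


@dataclass(frozen=True)
class PhantomImage:
    """One rendered posture of a phantom patient."""

    image: np.ndarray  # uint8 (H, W)
    landmarks: LandmarkSet
    posture: str
    target_angle: float
    c2_slope: float


@dataclass(frozen=True)
class PhantomPatient:
    patient_id: str
    postures: Dict[str, PhantomImage]


def _patient_seed_sequence(spec: PhantomSpec, patient_id: str) -> np.random.SeedSequence:
    # stable per-patient stream derived from (master seed, patient id)
    return np.random.SeedSequence([spec.seed, zlib.crc32(patient_id.encode())])


def sample_posture_angle(
    posture: str, spec: PhantomSpec, rng: np.random.Generator
) -> float:
    """Draw a C2-C7 target angle for one posture (truncated normal)."""
    try:
        p = spec.posture_params[posture]
    except KeyError:
        raise ValueError(f"unknown posture {posture!r}") from None
    a = (p.angle_min - p.angle_mean) / p.angle_sd
    b = (p.angle_max - p.angle_mean) / p.angle_sd
    return float(
        truncnorm.rvs(a, b, loc=p.angle_mean, scale=p.angle_sd, random_state=rng)
    )


def _sample_c2_slope(
    posture_params: PosturePhantomParams, rng: np.random.Generator
) -> float:
    return float(
        truncnorm.rvs(-2.0, 2.0, loc=posture_params.c2_slope_mean,
                      scale=posture_params.c2_slope_sd, random_state=rng)
    )


def _unit(deg: float) -> np.ndarray:
    rad = np.deg2rad(deg)
    return np.array([np.cos(rad), np.sin(rad)])  # (x, y), y down


def _spine_geometry(
    theta2: float,
    theta7: float,
    anatomy: Dict[str, np.ndarray],
    size: int,
) -> Optional[Tuple[LandmarkSet, List[np.ndarray], List[np.ndarray]]]:
    """Lay out the six vertebrae for given C2/C7 inferior endplate slopes.

    Returns (landmarks, body polygons, inferior endplate centers) with
    everything translated to the canvas center, or None when the
    configuration does not fit on canvas.
    """
    widths, height, gap, shares, wedges = (
        anatomy["widths"], anatomy["height"], anatomy["gap"],
        anatomy["shares"], anatomy["wedges"],
    )
    fracs = np.concatenate([[0.0], np.cumsum(shares) / shares.sum()])
    thetas = theta2 + fracs * (theta7 - theta2)  # inferior slopes C2..C7

    centers = [np.zeros(2)]
    for i in range(1, 6):
        phi = np.deg2rad(0.5 * (thetas[i - 1] + thetas[i]))
        step = np.array([-np.sin(phi), np.cos(phi)])  # "down the spine"
        centers.append(centers[-1] + (height + gap) * step)

    polygons = []
    for i in range(6):
        d = _unit(thetas[i])
        up = np.array([np.sin(np.deg2rad(thetas[i])), -np.cos(np.deg2rad(thetas[i]))])
        a_inf = centers[i] - 0.5 * widths[i] * d
        p_inf = centers[i] + 0.5 * widths[i] * d
        d_sup = _unit(thetas[i] + wedges[i])
        c_sup = centers[i] + height * up
        a_sup = c_sup - 0.46 * widths[i] * d_sup
        p_sup = c_sup + 0.46 * widths[i] * d_sup
        polygons.append(np.array([a_sup, p_sup, p_inf, a_inf]))

    all_pts = np.vstack(polygons)
    lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
    shift = np.array([size / 2.0, size / 2.0]) - 0.5 * (lo + hi)
    centers = [c + shift for c in centers]
    polygons = [p + shift for p in polygons]

    def corner(i: int, sign: float) -> np.ndarray:
        return centers[i] + sign * 0.5 * widths[i] * _unit(thetas[i])

    lm_pts = [corner(0, -1), corner(0, +1), corner(5, -1), corner(5, +1)]
    margin = 4.0
    for pt in lm_pts:
        if not (margin <= pt[0] <= size - 1 - margin
                and margin <= pt[1] <= size - 1 - margin):
            return None
    for poly in polygons:
        if poly.min() < 1.0 or poly.max() > size - 2.0:
            return None
    landmarks = LandmarkSet(*(Point2D(float(p[0]), float(p[1])) for p in lm_pts))
    return landmarks, polygons, centers


def _sample_anatomy(size: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    u = size / 128.0
    base_w = rng.uniform(0.16, 0.20) * size
    widths = base_w * rng.uniform(0.95, 1.05, size=6)
    widths[5] *= 1.06  # C7 slightly broader
    return {
        "widths": widths,
        "height": rng.uniform(0.085, 0.105) * size,
        "gap": rng.uniform(0.025, 0.040) * size,
        "shares": np.clip(1.0 + 0.25 * rng.normal(size=5), 0.3, None),
        "wedges": rng.uniform(-4.0, 4.0, size=6),
        "body_intensity": rng.uniform(0.55, 0.70),
        "smooth_sigma": 0.8 * u,
    }


def _fill_polygon(canvas: np.ndarray, poly: np.ndarray, value: float) -> None:
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=canvas.shape)
    canvas[rr, cc] = value


def _render_posture(
    spec: PhantomSpec,
    anatomy: Dict[str, np.ndarray],
    landmarks: LandmarkSet,
    polygons: List[np.ndarray],
    centers: List[np.ndarray],
    flags: Dict[str, bool],
    render_rng: np.random.Generator,
    artifact_rng: np.random.Generator,
) -> np.ndarray:
    size = spec.image_size
    canvas = np.full((size, size), 0.12, dtype=np.float64)

    # low-frequency bias field
    fx, fy = render_rng.uniform(0.5, 1.5, size=2)
    px, py = render_rng.uniform(0, 2 * np.pi, size=2)
    yy, xx = np.mgrid[0:size, 0:size] / size
    canvas += spec.bias_amplitude * np.cos(2 * np.pi * fx * xx + px) * np.cos(
        2 * np.pi * fy * yy + py
    )

    body = anatomy["body_intensity"]
    for poly in polygons:
        _fill_polygon(canvas, poly, body + render_rng.uniform(-0.03, 0.03))

    # ---- decorative artifacts (never move ground truth) ----
    # draw counts from artifact_rng identically regardless of flags so the
    # stream stays aligned across artifact-probability settings
    spur_verts = artifact_rng.choice(6, size=3, replace=False)
    spur_len = artifact_rng.uniform(0.03, 0.05) * size
    if flags["osteophyte"]:
        for i in spur_verts:
            poly = polygons[i]
            a_inf = poly[3]  # anterior inferior corner
            d_ant = a_inf - poly[2]
            d_ant = d_ant / np.linalg.norm(d_ant)
            tip = a_inf + spur_len * (d_ant + np.array([0.0, 0.35]))
            base = a_inf + 0.25 * spur_len * np.array([0.0, -1.0])
            _fill_polygon(canvas, np.array([a_inf, base, tip]), body)

    fuse_idx = int(artifact_rng.integers(1, 5))  # bridge between C(i) and C(i+1)
    if flags["fused_vertebrae"]:
        upper, lower = polygons[fuse_idx], polygons[fuse_idx + 1]
        bridge = np.array([upper[3], upper[2], lower[1], lower[0]])
        _fill_polygon(canvas, bridge, body)

    rod_offset = artifact_rng.uniform(0.03, 0.05) * size
    if flags["instrumentation"]:
        top, bottom = polygons[1], polygons[5]
        direction = bottom[2] - top[1]
        norm = np.linalg.norm(direction)
        perp = np.array([-direction[1], direction[0]]) / max(norm, 1e-9)
        p0 = top[1] + rod_offset * perp
        p1 = bottom[2] + rod_offset * perp
        w = 0.012 * size
        rod = np.array([p0 - w * perp, p0 + w * perp, p1 + w * perp, p1 - w * perp])
        _fill_polygon(canvas, rod, 0.95)
        for t in (0.25, 0.55, 0.85):
            screw0 = p0 + t * (p1 - p0)
            screw1 = screw0 - 0.06 * size * perp
            sw = 0.008 * size
            along = (p1 - p0) / max(np.linalg.norm(p1 - p0), 1e-9)
            scr = np.array(
                [screw0 - sw * along, screw0 + sw * along,
                 screw1 + sw * along, screw1 - sw * along]
            )
            _fill_polygon(canvas, scr, 0.95)

    band_tilt = artifact_rng.uniform(-8.0, 8.0)
    band_half = artifact_rng.uniform(0.06, 0.10) * size
    if flags["shoulder_occlusion"]:
        c7_y = 0.5 * (landmarks.c7_anterior.y + landmarks.c7_posterior.y)
        d = _unit(band_tilt)
        n = np.array([-d[1], d[0]])
        c = np.array([size / 2.0, c7_y])
        ext = 1.2 * size
        band = np.array(
            [c - ext * d - band_half * n, c + ext * d - band_half * n,
             c + ext * d + band_half * n, c - ext * d + band_half * n]
        )
        overlay = np.zeros_like(canvas)
        _fill_polygon(overlay, band, 0.45)
        canvas = canvas + overlay

    canvas = ndimage.gaussian_filter(canvas, anatomy["smooth_sigma"])
    canvas += render_rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    return (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def generate_patient(
    spec: PhantomSpec,
    patient_id: str,
    rng: Optional[np.random.Generator] = None,
) -> PhantomPatient:
    """Generate one phantom patient rendered at all three postures.

    The patient's random stream derives from (spec.seed, patient_id), so
    regenerating the same patient is bit-identical and datasets are
    extensible.  If a sampled pose cannot be placed on canvas within
    ``spec.retry_limit`` attempts, a RuntimeError is raised.
    """
    if rng is not None:
        seq = np.random.SeedSequence(rng.integers(0, 2**31))
    else:
        seq = _patient_seed_sequence(spec, patient_id)
    geom_rng, render_rng, artifact_rng = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )
    anatomy = _sample_anatomy(spec.image_size, geom_rng)

    probs = spec.artifact_probs
    draws = artifact_rng.uniform(size=3)
    patient_flags = {
        "osteophyte": bool(draws[0] < probs.osteophyte),
        "fused_vertebrae": bool(draws[1] < probs.fused_vertebrae),
        "instrumentation": bool(draws[2] < probs.instrumentation),
    }

    postures: Dict[str, PhantomImage] = {}
    for posture in POSTURES:
        params = spec.posture_params[posture]
        placed = None
        for _ in range(spec.retry_limit):
            target = sample_posture_angle(posture, spec, geom_rng)
            theta2 = _sample_c2_slope(params, geom_rng)
            placed = _spine_geometry(
                theta2, theta2 + target, anatomy, spec.image_size
            )
            if placed is not None:
                break
        if placed is None:
            raise RuntimeError(
                f"could not place phantom spine for {patient_id}/{posture} "
                f"within {spec.retry_limit} attempts"
            )
        landmarks, polygons, centers = placed
        measured = measure_from_landmarks(landmarks).c2c7_angle
        if abs(measured - target) > 0.1:
            raise RuntimeError(
                f"phantom geometry inconsistency: {measured} vs target {target}"
            )
        flags = dict(patient_flags)
        flags["shoulder_occlusion"] = bool(
            artifact_rng.uniform() < probs.shoulder_occlusion
        )
        image = _render_posture(
            spec, anatomy, landmarks, polygons, centers, flags,
            render_rng, artifact_rng,
        )
        postures[posture] = PhantomImage(
            image=image,
            landmarks=landmarks,
            posture=posture,
            target_angle=target,
            c2_slope=theta2,
        )
    return PhantomPatient(patient_id=patient_id, postures=postures)


def generate_dataset(
    n_patients: int,
    spec: PhantomSpec,
    out_dir: "str | Path",
) -> pd.DataFrame:
    """Write a phantom dataset: PNGs, labelme JSONs, and a manifest CSV.

    Each patient contributes one image per posture.  Paths in the
    manifest are relative to ``out_dir``; the manifest is written to
    ``out_dir / "manifest.csv"`` and also returned (with a ``target_angle``
    convenience column).
    """
    from PIL import Image

    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        patient = generate_patient(spec, pid)
        for posture, pimg in patient.postures.items():
            stem = f"{pid}_{posture}"
            img_rel = f"images/{stem}.png"
            ann_rel = f"annotations/{stem}.json"
            Image.fromarray(pimg.image, mode="L").save(out_dir / img_rel)
            annotation = Annotation.from_landmarks(
                pimg.landmarks,
                image_path=f"../{img_rel}",
                image_height=spec.image_size,
                image_width=spec.image_size,
            )
            write_labelme(annotation, out_dir / ann_rel)
            rows.append(
                {
                    "image": img_rel,
                    "annotation": ann_rel,
                    "patient_id": pid,
                    "posture": posture,
                    "target_angle": pimg.target_angle,
                }
            )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def generate_arrays(
    n_patients: int, spec: PhantomSpec, start_index: int = 0
) -> Tuple[np.ndarray, np.ndarray, List[str], List[str], np.ndarray]:
    """Generate a phantom cohort in memory (no files).

    Returns ``(images, landmarks, patient_ids, postures, target_angles)``
    with images (n, S, S) uint8 and landmarks (n, 4, 2) in (x, y) pixel
    order.  ``start_index`` offsets patient numbering so disjoint cohorts
    can be generated from the same spec.
    """
    images, lms, pids, postures, targets = [], [], [], [], []
    for i in range(start_index, start_index + n_patients):
        pid = f"P{i:04d}"
        patient = generate_patient(spec, pid)
        for posture, pimg in patient.postures.items():
            images.append(pimg.image)
            lms.append([[p.x, p.y] for p in pimg.landmarks.as_tuple()])
            pids.append(pid)
            postures.append(posture)
            targets.append(pimg.target_angle)
    return (
        np.stack(images),
        np.array(lms, dtype=np.float64),
        pids,
        postures,
        np.array(targets, dtype=np.float64),
    )
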
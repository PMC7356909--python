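"""Synthetic annotated forearm photographs and whole cohorts.

No photographs from the original flush-test study are publicly deposited,
so every pipeline stage is exercised on generated data.  A synthetic
measurement is a skin-toned background with Gaussian pixel noise, an
elliptical flush region whose red chrominance is raised by a controlled
amount, a congruent control ellipse placed beside it along the forearm
axis, and a ruler strip with known tick spacing for scale calibration.

The requested Cr shift ``delta = attenuation * delta_cr_max * f(conc) *
g(time)`` is rendered by adding an integer amount to R and subtracting an
integer amount from G inside the flush ellipse.  Because pixels are 8-bit
integers, the exactly rendered shift ``0.439*dR + 0.368*dG`` differs from
the request by at most a small quantisation residue (well under 0.5
units); the achieved value is recorded in the photograph metadata as
``rendered_delta_cr`` so recovery can be checked exactly.

The dose response f and time response g default to a saturating dose curve
and a rise to a 10-minute plateau; a subject-level ``attenuation`` in
[0, 1] scales the whole response and is what distinguishes cohort groups
(a blunted-response group has low attenuation).  All randomness flows from
one explicit seed; identical seeds give bit-identical images.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ValidationError
from .imaging import AnnotatedPhotograph, RulerAnnotation
from .response import session_grid

__all__ = [
    "FlushModel",
    "GroupSpec",
    "CohortSpec",
    "integer_chrominance_shift",
    "generate_photograph",
    "write_photograph",
    "generate_cohort",
]

#: Cr gains of a +1 shift in R and a -1 shift in G
_CR_PER_R, _CR_PER_G = 0.439, 0.368


@dataclass(frozen=True)
class FlushModel:
    """Parameters of the synthetic measurement.

    Geometry is expressed in millimeters on an image of
    ``image_shape`` pixels at ``mm_per_pixel``; the defaults give a
    400 × 300 px frame covering 40 × 30 mm at 0.1 mm/px, which keeps a
    full three-group cohort cheap to generate.
    """

    base_rgb: tuple[int, int, int] = (205, 160, 130)
    noise_sd: float = 2.0
    ellipse_center_mm: tuple[float, float] = (12.0, 15.0)  # (x, y)
    ellipse_axes_mm: tuple[float, float] = (7.0, 5.0)  # semi-axes (x, y)
    control_gap_mm: float = 2.0  # gap between flush and control ellipses
    delta_cr_max: float = 20.0
    dose_response: Mapping[float, float] = field(
        default_factory=lambda: {0.001: 0.3, 0.01: 0.65, 0.1: 1.0}
    )
    time_response: Mapping[int, float] = field(
        default_factory=lambda: {3: 0.6, 5: 0.8, 10: 1.0, 15: 1.0}
    )
    attenuation: float = 1.0
    image_shape: tuple[int, int] = (300, 400)  # (rows, cols)
    mm_per_pixel: float = 0.1
    ruler_distance_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.delta_cr_max < 0:
            raise ValidationError("delta_cr_max must be non-negative")
        if not (0.0 <= self.attenuation <= 1.0):
            raise ValidationError("attenuation must lie in [0, 1]")
        for name, mapping in (("dose", self.dose_response), ("time", self.time_response)):
            for v in mapping.values():
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(f"{name} response values must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroupSpec:
    """Per-group cohort parameters.

    ``absent_fraction`` of subjects are hard non-responders (attenuation
    0); the rest draw attenuation from a normal clipped to [0, 1].
    """

    n: int
    attenuation_mean: float = 1.0
    attenuation_sd: float = 0.0
    absent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group size must be >= 1")
        if not (0.0 <= self.absent_fraction <= 1.0):
            raise ValidationError("absent_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Groups of a synthetic cohort, keyed by group label."""

    groups: Mapping[str, GroupSpec]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort spec needs at least one group")


@functools.lru_cache(maxsize=None)
def integer_chrominance_shift(delta: float) -> tuple[int, int, float]:
    """Integer (dR, dG) channel shifts best rendering a Cr shift ``delta``.

    Returns ``(dR, dG, rendered)`` with R raised by dR and G lowered by dG,
    so ``rendered = 0.439*dR + 0.368*dG``; the pair minimises
    ``|rendered - delta|`` (ties toward the smallest total shift).
    """
    if delta < 0:
        raise ValidationError("delta must be non-negative")
    best: tuple[float, int, int] | None = None
    for d_r in range(0, 51):
        for d_g in range(0, 51):
            err = abs(_CR_PER_R * d_r + _CR_PER_G * d_g - delta)
            key = (round(err, 12), d_r + d_g)
            if best is None or key < (round(best[0], 12), best[1] + best[2]):
                best = (err, d_r, d_g)
    assert best is not None
    _, d_r, d_g = best
    return d_r, d_g, _CR_PER_R * d_r + _CR_PER_G * d_g


def _ellipse_mask(
    shape: tuple[int, int], center_mm: tuple[float, float],
    axes_mm: tuple[float, float], mm_per_pixel: float,
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cols * mm_per_pixel
    y = rows * mm_per_pixel
    cx, cy = center_mm
    ax, ay = axes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def generate_photograph(
    model: FlushModel,
    concentration: float,
    time_min: int,
    seed: int,
    subject: str = "synthetic",
    group: str = "unknown",
    attenuation: float | None = None,
) -> AnnotatedPhotograph:
    """Render one synthetic measurement, seed-deterministically.

    ``attenuation`` overrides the model's value (subject-level draw in a
    cohort).  The achieved Cr shift is stored in
    ``photo.metadata["rendered_delta_cr"]``.
    """
    if concentration not in model.dose_response:
        raise ValidationError(
            f"concentration {concentration} M has no dose-response entry"
        )
    if time_min not in model.time_response:
        raise ValidationError(f"time point {time_min} min has no time-response entry")
    att = model.attenuation if attenuation is None else float(attenuation)
    if not (0.0 <= att <= 1.0):
        raise ValidationError("attenuation must lie in [0, 1]")

    h, w = model.image_shape
    mmpp = model.mm_per_pixel
    ruler_col0, ruler_col1 = w - 16, w - 8  # ruler strip columns

    cx, cy = model.ellipse_center_mm
    ax, ay = model.ellipse_axes_mm
    cx2 = cx + 2 * ax + model.control_gap_mm
    frame_x_mm = ruler_col0 * mmpp  # usable width left of the ruler strip
    frame_y_mm = h * mmpp
    for label, (ecx, ecy) in (("flush", (cx, cy)), ("control", (cx2, cy))):
        if ecx - ax < 0 or ecx + ax >= frame_x_mm or ecy - ay < 0 or ecy + ay >= frame_y_mm:
            raise ValidationError(f"{label} ellipse does not fit inside the frame")

    area1 = _ellipse_mask((h, w), (cx, cy), (ax, ay), mmpp)
    # exact congruent copy shifted along the forearm axis (columns)
    col_shift = int(round((cx2 - cx) / mmpp))
    area2 = np.zeros_like(area1)
    area2[:, col_shift:] = area1[:, : w - col_shift]

    delta = att * model.delta_cr_max * model.dose_response[concentration] * model.time_response[time_min]
    d_r, d_g, rendered = integer_chrominance_shift(delta)

    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(model.base_rgb, dtype=float)
    if model.noise_sd > 0:
        img += rng.normal(0.0, model.noise_sd, size=img.shape)
    img[area1, 0] += d_r
    img[area1, 1] -= d_g

    # ruler: dark strip with white ticks; the tick spacing shrinks to fit
    # small frames, the annotated distance always matching it exactly
    img[:, ruler_col0:ruler_col1] = 40.0
    tick_step = int(round(model.ruler_distance_mm / mmpp))
    if 20 + tick_step > h - 4:
        tick_step = h - 30
        if tick_step < 2:
            raise ValidationError("frame too small to render a ruler")
    tick_rows = np.arange(20, h - 2, tick_step)
    for r in tick_rows:
        img[r : r + 2, ruler_col0:ruler_col1] = 255.0
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ruler = RulerAnnotation(
        p1=(float(tick_rows[0]), float(ruler_col0 + 4)),
        p2=(float(tick_rows[1]), float(ruler_col0 + 4)),
        physical_distance_mm=tick_step * mmpp,
    )
    metadata = {
        "subject": subject,
        "group": group,
        "concentration_m": concentration,
        "time_min": int(time_min),
        "attenuation": att,
        "requested_delta_cr": delta,
        "rendered_delta_cr": rendered,
    }
    return AnnotatedPhotograph(
        pixels=pixels, area1_mask=area1, area2_mask=area2, ruler=ruler, metadata=metadata
    )


def write_photograph(
    photo: AnnotatedPhotograph, image_path: str | Path, annotation_path: str | Path
) -> None:
    """Write a photograph as PNG + JSON sidecar + two 0/255 mask PNGs."""
    image_path = Path(image_path)
    annotation_path = Path(annotation_path)
    Image.fromarray(photo.pixels).save(image_path)
    stem = annotation_path.stem
    mask_names = {}
    for idx, mask in ((1, photo.area1_mask), (2, photo.area2_mask)):
        name = f"{stem}_area{idx}.png"
        Image.fromarray((mask.astype(np.uint8)) * 255).save(annotation_path.parent / name)
        mask_names[idx] = name
    sidecar = dict(photo.metadata)
    sidecar.update(
        {
            "ruler": {
                "p1_xy": [photo.ruler.p1[1], photo.ruler.p1[0]],
                "p2_xy": [photo.ruler.p2[1], photo.ruler.p2[0]],
                "distance_mm": photo.ruler.physical_distance_mm,
            },
            "area1": {"mask": mask_names[1]},
            "area2": {"mask": mask_names[2]},
        }
    )
    annotation_path.write_text(json.dumps(sidecar, indent=1))


def generate_cohort(
    spec: CohortSpec,
    model: FlushModel,
    out_dir: str | Path,
    seed: int,
) -> pd.DataFrame:
    """Generate a full cohort on disk and return its session manifest.

    Per subject, 12 photographs on the 3 concentrations × 4 time points
    grid, with a subject-level attenuation drawn from the group
    distribution.  Writes PNGs, sidecars and ``manifest.csv`` under
    ``out_dir``; the manifest (subject, group, concentration_m, time_min,
    image, annotation, attenuation) feeds the extract/classify/analyze
    pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for group_name in spec.groups:
        gspec = spec.groups[group_name]
        for i in range(gspec.n):
            subject = f"{group_name}{i + 1:03d}"
            if rng.random() < gspec.absent_fraction:
                att = 0.0
            else:
                att = float(
                    np.clip(
                        rng.normal(gspec.attenuation_mean, gspec.attenuation_sd), 0.0, 1.0
                    )
                )
            for conc, t in session_grid():
                img_seed = int(rng.integers(0, 2**31))
                photo = generate_photograph(
                    model, conc, t, seed=img_seed, subject=subject,
                    group=group_name, attenuation=att,
                )
                stem = f"{subject}_c{conc:g}_t{t:02d}"
                image_path = out_dir / f"{stem}.png"
                annotation_path = out_dir / f"{stem}.json"
                write_photograph(photo, image_path, annotation_path)
                rows.append(
                    {
                        "subject": subject,
                        "group": group_name,
                        "concentration_m": conc,
                        "time_min": t,
                        "image": image_path.name,
                        "annotation": annotation_path.name,
                        "attenuation": att,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
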
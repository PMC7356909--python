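"""The 97-variable per-measurement feature vector and area-difference statistics.

For each measurement the irritated area (1) and the adjacent control area
(2) are each summarised by six statistics — mean, median, mode, range,
minimum, maximum — of eight color components: R, G, B, H, S, V, Cr, Cb.
That gives 6 × 8 × 2 = 96 color variables; the flush surface of area 1 in
mm² is the 97th.  Because the control area is sampled from the same
forearm under the same illumination, the per-statistic differences
area 1 − area 2 ("delta" variables) cancel the subject's baseline skin
color and the shared lighting, and are the quantities carried into the
response call and the group statistics.

Variable naming is fixed so downstream tables are stable:
``area{1,2}_{component}_{statistic}`` plus ``area1_surface_mm2`` for the
features, and ``delta_{component}_{statistic}`` for the differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .color_models import SkinThresholds, rgb_to_hsv, rgb_to_ycbcr
from .errors import EmptyAreaError, ValidationError
from .imaging import (
    AnnotatedPhotograph,
    ScaleCalibration,
    calibrate_scale,
    region_area,
    valid_pixels,
)

__all__ = [
    "COMPONENTS",
    "STATISTICS",
    "AREA_VARIABLE",
    "FEATURE_NAMES",
    "DELTA_NAMES",
    "ColorSummary",
    "FeatureVector",
    "DeltaVector",
    "summarize_component",
    "component_values",
    "extract_features",
    "relative_statistics",
]

COMPONENTS = ("R", "G", "B", "H", "S", "V", "Cr", "Cb")
STATISTICS = ("mean", "median", "mode", "range", "min", "max")
AREA_VARIABLE = "area1_surface_mm2"

FEATURE_NAMES: tuple[str, ...] = (AREA_VARIABLE,) + tuple(
    f"area{a}_{c}_{s}" for a in (1, 2) for c in COMPONENTS for s in STATISTICS
)
DELTA_NAMES: tuple[str, ...] = (AREA_VARIABLE,) + tuple(
    f"delta_{c}_{s}" for c in COMPONENTS for s in STATISTICS
)

# native scale of each component; the mode is computed on the component
# quantized to 256 levels over this scale
_COMPONENT_MAX = {
    "R": 255.0, "G": 255.0, "B": 255.0,
    "H": 360.0, "S": 1.0, "V": 1.0,
    "Cr": 255.0, "Cb": 255.0,
}


@dataclass(frozen=True)
class ColorSummary:
    """Six statistics for each of the eight color components over one area.

    ``values[component][statistic]`` → float; 48 numbers per area.
    """

    values: dict[str, dict[str, float]]

    def __getitem__(self, component: str) -> dict[str, float]:
        return self.values[component]


def summarize_component(values: np.ndarray | list, component: str = "R") -> dict[str, float]:
    """Six summary statistics of one color component over a pixel set.

    mean: arithmetic; median: midpoint of the two central order statistics
    for even counts; mode: the most frequent value after quantizing the
    component to 256 levels over its native scale (ties broken toward the
    smallest value), reported back on the native scale; range = max − min.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise EmptyAreaError("cannot summarize an empty list of component values")
    if component not in _COMPONENT_MAX:
        raise ValidationError(f"unknown component {component!r}")
    native_max = _COMPONENT_MAX[component]
    quantized = np.rint(arr * (255.0 / native_max)).astype(np.int64)
    counts = np.bincount(np.clip(quantized, 0, 255), minlength=256)
    mode = int(counts.argmax()) * (native_max / 255.0)
    vmin, vmax = float(arr.min()), float(arr.max())
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "mode": float(mode),
        "range": vmax - vmin,
        "min": vmin,
        "max": vmax,
    }


def component_values(rgb_pixels: np.ndarray) -> dict[str, np.ndarray]:
    """Per-pixel values of the eight color components for an (N, 3) RGB set."""
    rgb_pixels = np.asarray(rgb_pixels)
    hsv = rgb_to_hsv(rgb_pixels)
    ycbcr = rgb_to_ycbcr(rgb_pixels)
    rgbf = rgb_pixels.astype(float)
    return {
        "R": rgbf[..., 0],
        "G": rgbf[..., 1],
        "B": rgbf[..., 2],
        "H": hsv[..., 0],
        "S": hsv[..., 1],
        "V": hsv[..., 2],
        "Cr": ycbcr[..., 2],
        "Cb": ycbcr[..., 1],
    }


def _summarize_area(rgb_pixels: np.ndarray) -> ColorSummary:
    comps = component_values(rgb_pixels)
    return ColorSummary(
        values={c: summarize_component(comps[c], c) for c in COMPONENTS}
    )


@dataclass(frozen=True)
class FeatureVector:
    """The 97 per-measurement variables.

    ``area_mm2`` is the surface of the full annotated irritated region;
    ``summary1``/``summary2`` hold the 48 color statistics of areas 1
    and 2 computed over their skin-plausible pixels.
    """

    area_mm2: float
    summary1: ColorSummary
    summary2: ColorSummary

    def to_series(self) -> pd.Series:
        """The 97 named variables in canonical order."""
        data = {AREA_VARIABLE: self.area_mm2}
        for idx, summary in ((1, self.summary1), (2, self.summary2)):
            for c in COMPONENTS:
                for s in STATISTICS:
                    data[f"area{idx}_{c}_{s}"] = summary[c][s]
        return pd.Series(data, index=list(FEATURE_NAMES))


@dataclass(frozen=True)
class DeltaVector:
    """Area 1 − area 2 differences of the 48 color statistics.

    The irritated-area surface is carried through unchanged, giving 49
    named entries.
    """

    area_mm2: float
    deltas: dict[str, float]  # keyed delta_{component}_{statistic}

    def to_series(self) -> pd.Series:
        data = {AREA_VARIABLE: self.area_mm2, **self.deltas}
        return pd.Series(data, index=list(DELTA_NAMES))

    def __getitem__(self, name: str) -> float:
        if name == AREA_VARIABLE:
            return self.area_mm2
        return self.deltas[name]

    @classmethod
    def from_series(cls, series: pd.Series) -> "DeltaVector":
        missing = [n for n in DELTA_NAMES if n not in series.index]
        if missing:
            raise ValidationError(f"delta series lacks entries: {missing[:3]}...")
        return cls(
            area_mm2=float(series[AREA_VARIABLE]),
            deltas={n: float(series[n]) for n in DELTA_NAMES if n != AREA_VARIABLE},
        )


def extract_features(
    photo: AnnotatedPhotograph,
    scale: ScaleCalibration | None = None,
    thresholds: SkinThresholds | None = None,
) -> FeatureVector:
    """Compute the full 97-variable vector for one measurement.

    Color statistics use only the skin-plausible pixels of each area; the
    surface A is that of the complete annotated area 1 (manual marking
    defines the flush extent, the chrominance filter only guards the color
    statistics against non-skin pixels such as pen marks or plaster).

    When ``scale`` is omitted it is calibrated from the photograph's ruler.
    Raises :class:`EmptyAreaError` naming the area if the skin filter
    removes every pixel of either area.
    """
    if scale is None:
        scale = calibrate_scale(photo.ruler)
    summaries = []
    for idx, mask in ((1, photo.area1_mask), (2, photo.area2_mask)):
        keep = valid_pixels(photo, mask, thresholds)
        if not keep.any():
            raise EmptyAreaError(
                f"area {idx}: no skin-plausible pixels remain after filtering"
            )
        summaries.append(_summarize_area(photo.pixels[keep]))
    area = region_area(photo.area1_mask, scale)
    return FeatureVector(area_mm2=area, summary1=summaries[0], summary2=summaries[1])


def relative_statistics(feature_vector: FeatureVector) -> DeltaVector:
    """Differences area 1 − area 2 for every (component, statistic) pair."""
    deltas = {
        f"delta_{c}_{s}": feature_vector.summary1[c][s] - feature_vector.summary2[c][s]
        for c in COMPONENTS
        for s in STATISTICS
    }
    return DeltaVector(area_mm2=feature_vector.area_mm2, deltas=deltas)
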
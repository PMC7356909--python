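"""Tool configuration: a flat ``key = value`` text file with full defaults.

Every tunable constant of the pipeline is surfaced here: the chrominance
skin-plausibility window, the no-difference threshold tau of the response
proxy, the significance level and Bonferroni family size, and the ROC
operating-point rule.  Unknown keys and out-of-range values are rejected
on load.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .color_models import SkinThresholds
from .errors import ConfigError

__all__ = ["ToolConfig", "load_config", "DEFAULT_CONFIG_TEXT"]


@dataclass
class ToolConfig:
    # chrominance window for skin-plausible pixels (8-bit units)
    cr_min: float = 140.0
    cr_max: float = 165.0
    cb_min: float = 140.0
    cb_max: float = 195.0
    # optional extra filter on H/360 (off by default)
    hue_band_enabled: bool = False
    hue_min: float = 0.01
    hue_max: float = 0.1
    # no-difference threshold of the response proxy (8-bit color units)
    tau: float = 2.0
    # family-wise significance control
    alpha: float = 0.05
    # Bonferroni family size; 0 = use the number of tests actually run.
    # 27 corresponds to the canonical screen of 9 variables x 3 concentrations.
    n_tests: int = 0
    # ROC operating point rule: youden | fixed-threshold
    roc_rule: str = "youden"
    roc_fixed_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cr_min > self.cr_max or self.cb_min > self.cb_max:
            raise ConfigError("chrominance window bounds must satisfy min <= max")
        if not (self.tau > 0):
            raise ConfigError("tau must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_tests < 0:
            raise ConfigError("n_tests must be >= 0")
        if self.roc_rule not in ("youden", "fixed-threshold"):
            raise ConfigError(f"unknown roc_rule {self.roc_rule!r}")
        if self.hue_band_enabled and self.hue_min > self.hue_max:
            raise ConfigError("hue band bounds must satisfy min <= max")

    def thresholds(self) -> SkinThresholds:
        band = (self.hue_min, self.hue_max) if self.hue_band_enabled else None
        return SkinThresholds(
            cr_min=self.cr_min, cr_max=self.cr_max,
            cb_min=self.cb_min, cb_max=self.cb_max, hue_band=band,
        )


_BOOL_VALUES = {"true": True, "yes": True, "1": True, "false": False, "no": False, "0": False}


def load_config(path: str | Path | None) -> ToolConfig:
    """Parse a flat key/value config file; ``None`` gives the defaults."""
    if path is None:
        return ToolConfig()
    text = Path(path).read_text()
    field_types = {f.name: f.type for f in fields(ToolConfig)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (s.strip() for s in line.partition("="))
        if key not in field_types:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        kind = field_types[key]
        try:
            if kind == "bool":
                values[key] = _BOOL_VALUES[value.lower()]
            elif kind == "int":
                values[key] = int(value)
            elif kind == "float":
                values[key] = float(value)
            else:
                values[key] = value
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key!r}: {value!r}") from exc
    return ToolConfig(**values)


DEFAULT_CONFIG_TEXT = """\
# niaflush configuration (flat key = value; '#' starts a comment)

# Chrominance window for skin-plausible pixels, 8-bit units.  The stock
# window matches the camera/lighting the method was developed under; widen
# or disable it (0..255) for other acquisition setups.
cr_min = 140
cr_max = 165
cb_min = 140
cb_max = 195

# Optional extra filter on hue/360 (rarely needed; off by default).
hue_band_enabled = false
hue_min = 0.01
hue_max = 0.1

# No-difference threshold of the automated response proxy, 8-bit units:
# a measurement is flagged when |delta mean Cr| and |delta mean R| are
# both below tau.  The absent call needs >= 4 flagged of 12 measurements.
tau = 2.0

# Significance level and Bonferroni family size (0 = number of tests run;
# 27 = the canonical 9-variable x 3-concentration screen).
alpha = 0.05
n_tests = 0

# ROC operating point: youden | fixed-threshold
roc_rule = youden
roc_fixed_threshold = 0.0

seed = 0
"""
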
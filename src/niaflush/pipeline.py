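"""Table-level pipeline: manifest → features → response calls → group reports.

These functions connect the per-photograph operations to the flat CSV
tables the tool reads and writes:

* a *manifest* lists measurements (subject, group, concentration_m,
  time_min, image, annotation);
* the *feature table* has one row per measurement with the 97 variables;
* the *delta table* has the 49 area-difference variables;
* *response calls* and *effect/ROC reports* are derived from those.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import ToolConfig
from .errors import ValidationError
from .features import (
    AREA_VARIABLE,
    COMPONENTS,
    DeltaVector,
    extract_features,
    relative_statistics,
)
from .imaging import calibrate_scale, load_photograph
from .response import classify_response, assemble_session, session_grid
from .stats import apply_bonferroni, group_time_effects, roc_analysis

__all__ = [
    "METADATA_COLUMNS",
    "CANONICAL_VARIABLES",
    "extract_manifest",
    "classify_deltas",
    "analyze_effects",
    "analyze_roc",
]

METADATA_COLUMNS = ("subject", "group", "concentration_m", "time_min")

#: The canonical screen: flush surface plus the mean delta of each color
#: component, examined per concentration (9 variables x 3 concentrations).
CANONICAL_VARIABLES: tuple[str, ...] = (AREA_VARIABLE,) + tuple(
    f"delta_{c}_mean" for c in COMPONENTS
)


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} lacks columns {missing}")


def extract_manifest(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    config: ToolConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run imaging + feature extraction for every manifest row.

    Returns ``(features, deltas)`` DataFrames: metadata columns followed by
    the 97 feature / 49 delta variables.  Fails fast with the offending
    row's index and image path in the error message.
    """
    config = config or ToolConfig()
    base_dir = Path(base_dir)
    if manifest.empty:
        raise ValidationError("manifest is empty")
    _require_columns(manifest, METADATA_COLUMNS + ("image", "annotation"), "manifest")
    thresholds = config.thresholds()
    feature_rows, delta_rows = [], []
    for idx, row in manifest.iterrows():
        try:
            photo = load_photograph(base_dir / row["image"], base_dir / row["annotation"])
            scale = calibrate_scale(photo.ruler)
            fv = extract_features(photo, scale, thresholds)
            dv = relative_statistics(fv)
        except Exception as exc:
            raise type(exc)(
                f"manifest row {idx} ({row['image']}): {exc}"
            ) from exc
        meta = {c: row[c] for c in METADATA_COLUMNS}
        feature_rows.append({**meta, **fv.to_series().to_dict()})
        delta_rows.append({**meta, **dv.to_series().to_dict()})
    return pd.DataFrame(feature_rows), pd.DataFrame(delta_rows)


def classify_deltas(deltas: pd.DataFrame, config: ToolConfig | None = None) -> pd.DataFrame:
    """Apply the absent/present rule to every subject in a delta table.

    Returns one row per subject: subject, group, flagged_count, call.
    Every subject must have a complete 12-cell session.
    """
    config = config or ToolConfig()
    _require_columns(deltas, METADATA_COLUMNS, "delta table")
    rows = []
    for subject, sub in deltas.groupby("subject", sort=True):
        records = [
            (
                {c: r[c] for c in METADATA_COLUMNS},
                DeltaVector.from_series(r),
            )
            for _, r in sub.iterrows()
        ]
        session = assemble_session(records)
        call = classify_response(session, tau=config.tau)
        rows.append(
            {
                "subject": subject,
                "group": sub["group"].iloc[0],
                "flagged_count": call.flagged_count,
                "call": call.call,
            }
        )
    return pd.DataFrame(rows)


def analyze_effects(
    deltas: pd.DataFrame,
    variables: tuple[str, ...] = CANONICAL_VARIABLES,
    config: ToolConfig | None = None,
) -> pd.DataFrame:
    """Mixed group × time ANOVA per (variable, concentration).

    The delta table must hold exactly two groups.  Returns a tidy table
    (variable, concentration_m, factor, F, p, partial_eta_sq, significant)
    with the Bonferroni flag computed over the group-effect family (one
    test per variable × concentration; family size from ``config.n_tests``
    when non-zero).
    """
    config = config or ToolConfig()
    _require_columns(deltas, METADATA_COLUMNS + tuple(variables), "delta table")
    results = []
    keyed = []
    for variable in variables:
        for conc, sub in deltas.groupby("concentration_m", sort=True):
            table = sub.rename(columns={variable: "value", "time_min": "time"})
            effects = group_time_effects(
                table, dv="value", subject="subject", group="group", time="time",
                variable=variable,
            )
            for eff in effects:
                keyed.append((conc, eff))
            results.extend(effects)
    group_effects = [eff for _, eff in keyed if eff.factor == "group"]
    m = config.n_tests if config.n_tests else len(group_effects)
    apply_bonferroni(group_effects, alpha=config.alpha, m=m)
    rows = [
        {
            "variable": eff.variable,
            "concentration_m": conc,
            "factor": eff.factor,
            "F": eff.F,
            "p": eff.p,
            "partial_eta_sq": eff.partial_eta_sq,
            "significant": eff.significant,
        }
        for conc, eff in keyed
    ]
    return pd.DataFrame(rows)


def analyze_roc(
    deltas: pd.DataFrame,
    variables: tuple[str, ...] = CANONICAL_VARIABLES,
    config: ToolConfig | None = None,
    positive_group: str | None = None,
) -> pd.DataFrame:
    """ROC discrimination per (variable, concentration, time) cell.

    Subjects of ``positive_group`` (default: the lexicographically last
    group, so a patient label like SZ beats HC) are the positive class;
    the per-cell score is the variable's value, sign-oriented so that the
    AUC is at least 0.5 on the training groups.  Returns a tidy table with
    AUC and the operating point's sensitivity/specificity.
    """
    config = config or ToolConfig()
    _require_columns(deltas, METADATA_COLUMNS + tuple(variables), "delta table")
    groups = sorted(deltas["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"ROC analysis needs exactly 2 groups, got {groups}")
    pos = positive_group if positive_group is not None else groups[-1]
    if pos not in groups:
        raise ValidationError(f"positive group {pos!r} not among {groups}")
    rows = []
    for variable in variables:
        for (conc, t), sub in deltas.groupby(["concentration_m", "time_min"], sort=True):
            labels = (sub["group"] == pos).to_numpy()
            scores = sub[variable].to_numpy(dtype=float)
            # orient: a blunted response means lower flush scores in patients
            flip = np.mean(scores[labels]) < np.mean(scores[~labels])
            result = roc_analysis(
                -scores if flip else scores,
                labels,
                rule=config.roc_rule,
                fixed_threshold=config.roc_fixed_threshold,
            )
            rows.append(
                {
                    "variable": variable,
                    "concentration_m": conc,
                    "time_min": t,
                    "positive_group": pos,
                    "score_flipped": bool(flip),
                    "auc": result.auc,
                    "sensitivity": result.operating_sensitivity,
                    "specificity": result.operating_specificity,
                    "threshold": result.operating_threshold,
                }
            )
    return pd.DataFrame(rows)
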
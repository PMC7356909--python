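"""Subject sessions and the absent/present niacin-response call.

A complete session is 12 measurements per subject: three methyl nicotinate
concentrations (0.001, 0.01, 0.1 M) photographed at four time points
(3, 5, 10, 15 min after a 90 s application).  A response is called
*absent* when at least 4 of the 12 measurements (33%) show no difference
between the irritated and control areas.

The original assessment of "no visible difference" was a judgment by two
human raters.  This module provides an automated proxy: a measurement is
flagged as showing no difference when both the mean red-chrominance delta
and the mean red delta are below a threshold ``tau`` (default 2 8-bit
units, a conservative just-noticeable color difference).  Manually
supplied rater flags can be passed instead, bypassing the proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import (
    DuplicateMeasurementError,
    IncompleteSessionError,
    OffGridError,
    ValidationError,
)
from .features import DeltaVector

__all__ = [
    "CONCENTRATIONS_M",
    "TIME_POINTS_MIN",
    "ABSENT_MIN_FLAGS",
    "DEFAULT_TAU",
    "SubjectSession",
    "ResponseCall",
    "session_grid",
    "assemble_session",
    "flag_no_difference",
    "classify_response",
]

CONCENTRATIONS_M: tuple[float, ...] = (0.001, 0.01, 0.1)
TIME_POINTS_MIN: tuple[int, ...] = (3, 5, 10, 15)

#: minimum number of flagged measurements (of 12) for an absent call
ABSENT_MIN_FLAGS = 4

#: default no-difference threshold in 8-bit color units
DEFAULT_TAU = 2.0


def session_grid() -> list[tuple[float, int]]:
    """The 12 (concentration, time) cells of a complete session."""
    return [(c, t) for c in CONCENTRATIONS_M for t in TIME_POINTS_MIN]


def _normalize_cell(concentration: float, time_min: float) -> tuple[float, int]:
    conc = next(
        (c for c in CONCENTRATIONS_M if abs(concentration - c) <= 1e-9 * max(1.0, c)),
        None,
    )
    if conc is None:
        raise OffGridError(
            f"concentration {concentration} M not in grid {CONCENTRATIONS_M}"
        )
    if time_min not in TIME_POINTS_MIN:
        raise OffGridError(f"time point {time_min} min not in grid {TIME_POINTS_MIN}")
    return conc, int(time_min)


@dataclass
class SubjectSession:
    """All measurements of one subject on the 3 × 4 grid."""

    subject: str
    group: str = "unknown"
    measurements: dict[tuple[float, int], DeltaVector] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return len(self.measurements) == len(session_grid())

    @property
    def missing_cells(self) -> list[tuple[float, int]]:
        return [cell for cell in session_grid() if cell not in self.measurements]


@dataclass(frozen=True)
class ResponseCall:
    """Outcome of the absent/present rule for one subject."""

    subject: str
    flags: dict[tuple[float, int], bool]
    flagged_count: int
    call: str  # "absent" | "present"
    tau: float | None


def assemble_session(
    records: Iterable[tuple[Mapping, DeltaVector]],
) -> SubjectSession:
    """Build a session from (metadata, DeltaVector) records.

    Metadata mappings must carry ``subject``, ``concentration_m`` and
    ``time_min`` (``group`` optional).  At most one record per grid cell;
    off-grid cells and duplicates raise.  The returned session may be
    incomplete — check :attr:`SubjectSession.complete` /
    :attr:`SubjectSession.missing_cells`.
    """
    session: SubjectSession | None = None
    for metadata, delta in records:
        try:
            subject = str(metadata["subject"])
            cell = _normalize_cell(float(metadata["concentration_m"]), metadata["time_min"])
        except KeyError as exc:
            raise ValidationError(f"measurement metadata lacks key {exc}") from exc
        group = str(metadata.get("group", "unknown"))
        if session is None:
            session = SubjectSession(subject=subject, group=group)
        elif session.subject != subject:
            raise ValidationError(
                f"records mix subjects {session.subject!r} and {subject!r}"
            )
        if cell in session.measurements:
            raise DuplicateMeasurementError(
                f"subject {subject}: duplicate measurement for cell {cell}"
            )
        session.measurements[cell] = delta
    if session is None:
        raise ValidationError("no records supplied")
    return session


def flag_no_difference(delta: DeltaVector, tau: float = DEFAULT_TAU) -> bool:
    """True when a measurement shows no irritated-vs-control difference.

    The proxy for the raters' judgment: both ``|delta_Cr_mean|`` and
    ``|delta_R_mean|`` below ``tau`` (8-bit units).
    """
    if not (tau > 0):
        raise ValidationError("tau must be positive")
    return abs(delta["delta_Cr_mean"]) < tau and abs(delta["delta_R_mean"]) < tau


def classify_response(
    session: SubjectSession,
    tau: float = DEFAULT_TAU,
    manual_flags: Mapping[tuple[float, int], bool] | None = None,
) -> ResponseCall:
    """Apply the ≥4-of-12 absent-response rule to a complete session.

    ``manual_flags`` (one boolean per grid cell) substitutes rater
    judgments for the automated proxy.  Incomplete sessions are rejected —
    the 33% rule is defined on exactly 12 measurements.
    """
    if not session.complete:
        raise IncompleteSessionError(
            f"subject {session.subject}: session missing cells {session.missing_cells}"
        )
    if manual_flags is not None:
        missing = [cell for cell in session_grid() if cell not in manual_flags]
        if missing:
            raise ValidationError(f"manual flags missing for cells {missing}")
        flags = {cell: bool(manual_flags[cell]) for cell in session_grid()}
        tau_used: float | None = None
    else:
        flags = {
            cell: flag_no_difference(session.measurements[cell], tau)
            for cell in session_grid()
        }
        tau_used = tau
    count = sum(flags.values())
    call = "absent" if count >= ABSENT_MIN_FLAGS else "present"
    return ResponseCall(
        subject=session.subject, flags=flags, flagged_count=count, call=call, tau=tau_used
    )
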
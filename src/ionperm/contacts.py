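"""Per-window contact counting, critical-interaction classification, and
unbiased permeation-event detection.

A partner "interacts" with the ion in a frame when the minimum distance
between the ion bead and any bead of that partner is below the cutoff
(default 3 A).  A partner is "critical" in a window when it interacts in
strictly more than the threshold fraction (default 50%) of the window's
frames.  Percentages are reported per partner and deliberately not
renormalized: one frame can host several simultaneous interactions, so
the column may sum to more than 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Frame, InvalidParameterError, IonpermError, min_partner_distance

__all__ = [
    "ContactTable",
    "CriticalRange",
    "PermeationEvent",
    "count_contacts",
    "classify_critical",
    "critical_frame_threshold",
    "critical_ranges",
    "detect_permeation_events",
]

DEFAULT_CUTOFF = 3.0          # A
DEFAULT_THRESHOLD_PCT = 50.0  # percent of frames


@dataclass
class ContactTable:
    """Per-partner interacting-frame counts for one window."""

    window_center: float
    total_frames: int
    per_partner: dict[str, tuple[int, float]]  # id -> (count, percent 1-dec)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"partner": pid, "interacting_frames": c, "percent": f}
            for pid, (c, f) in self.per_partner.items()
        ]
        return pd.DataFrame(rows, columns=["partner", "interacting_frames",
                                           "percent"])


@dataclass
class CriticalRange:
    partner_id: str
    z_interval: tuple[float, float]
    window_centers: list[float]


@dataclass
class PermeationEvent:
    direction: str  # "EC_to_IC" | "IC_to_EC"
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise InvalidParameterError("t_end must be > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def contact_fraction_percent(interacting: int, total: int) -> float:
    """100 * interacting/total, rounded to one decimal."""
    return round(100.0 * interacting / total, 1)


def count_contacts(
    frames: Sequence[Frame],
    cutoff: float = DEFAULT_CUTOFF,
    window_center: float = float("nan"),
) -> ContactTable:
    """Count, per partner, the frames whose min ion distance is < cutoff."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be > 0")
    if not frames:
        raise InvalidParameterError("no frames given")
    partner_ids: dict[str, None] = {}
    for f in frames:
        for pid in f.partner_ids():
            partner_ids.setdefault(pid)
    counts = {pid: 0 for pid in partner_ids}
    for f in frames:
        _ = f.ion  # raises if the frame somehow lacks an ion bead
        for pid in partner_ids:
            if min_partner_distance(f, pid) < cutoff:
                counts[pid] += 1
    total = len(frames)
    return ContactTable(
        window_center=window_center,
        total_frames=total,
        per_partner={
            pid: (c, contact_fraction_percent(c, total))
            for pid, c in counts.items()
        },
    )


def critical_frame_threshold(total_frames: int,
                             threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> float:
    """Frame count a partner must strictly exceed to qualify as critical."""
    if not (0 < threshold_pct <= 100):
        raise InvalidParameterError("threshold_pct must be in (0, 100]")
    return threshold_pct / 100.0 * total_frames


def classify_critical(
    table: ContactTable, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> set[str]:
    """Partners interacting in strictly more than threshold_pct of frames."""
    cut = critical_frame_threshold(table.total_frames, threshold_pct)
    return {pid for pid, (c, _) in table.per_partner.items() if c > cut}


def critical_ranges(
    tables: Sequence[ContactTable],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> list[CriticalRange]:
    """Maximal contiguous runs of critical windows per partner.

    Tables must be ordered by strictly increasing window center; interval
    endpoints are the first and last window centers of a run (no
    sub-window interpolation).
    """
    centers = [t.window_center for t in tables]
    if any(b <= a for a, b in zip(centers, centers[1:])):
        raise InvalidParameterError("window centers must be strictly increasing")
    partner_ids: dict[str, None] = {}
    for t in tables:
        for pid in t.per_partner:
            partner_ids.setdefault(pid)

    ranges: list[CriticalRange] = []
    for pid in partner_ids:
        run: list[float] = []
        for t in tables:
            critical = pid in classify_critical(t, threshold_pct)
            if critical:
                run.append(t.window_center)
            elif run:
                ranges.append(
                    CriticalRange(pid, (run[0], run[-1]), list(run))
                )
                run = []
        if run:
            ranges.append(CriticalRange(pid, (run[0], run[-1]), list(run)))
    return ranges


def detect_permeation_events(
    frames: Sequence[Frame],
    groove_top: float = 10.0,
    groove_bottom: float = -10.0,
    gate_partner: str = "gate",
    gate_cutoff: float = DEFAULT_CUTOFF,
) -> list[PermeationEvent]:
    """Detect complete groove traversals in an unbiased trajectory.

    An EC-to-IC event opens at the first frame where the ion is on the
    extracellular side (rc > groove_top) while in contact with the gate
    partner, and completes when the rc drops below groove_bottom.  The
    IC-to-EC detection mirrors this: the event opens when the ion enters
    from below (rc crosses groove_bottom upward), requires gate contact
    at some frame during the traversal, and completes when the rc exceeds
    groove_top.  Incomplete excursions produce no event.
    """
    if groove_top <= groove_bottom:
        raise InvalidParameterError("groove_top must be > groove_bottom")
    events: list[PermeationEvent] = []
    pending_dir: str | None = None
    pending_t: float = 0.0
    gate_seen = False
    prev_rc: float | None = None
    for f in frames:
        rc = f.rc.value
        gate_contact = min_partner_distance(f, gate_partner) < gate_cutoff
        if pending_dir is None:
            if rc > groove_top and gate_contact:
                pending_dir, pending_t, gate_seen = "EC_to_IC", f.time, True
            elif (
                prev_rc is not None
                and prev_rc < groove_bottom <= rc
            ):
                pending_dir, pending_t, gate_seen = "IC_to_EC", f.time, gate_contact
        elif pending_dir == "EC_to_IC":
            if rc < groove_bottom:
                events.append(PermeationEvent("EC_to_IC", pending_t, f.time))
                pending_dir = None
        elif pending_dir == "IC_to_EC":
            gate_seen = gate_seen or gate_contact
            if rc < groove_bottom:
                pending_dir = None  # fell back out the IC side; abandoned
            elif rc > groove_top and gate_seen:
                events.append(PermeationEvent("IC_to_EC", pending_t, f.time))
                pending_dir = None
        prev_rc = rc
    return events


def tables_to_dataframe(tables: Sequence[ContactTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for pid, (c, pct) in t.per_partner.items():
            rows.append(
                {
                    "window_center_A": t.window_center,
                    "total_frames": t.total_frames,
                    "partner": pid,
                    "interacting_frames": c,
                    "percent": pct,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["window_center_A", "total_frames", "partner",
                 "interacting_frames", "percent"],
    )


def ranges_to_dataframe(ranges: Sequence[CriticalRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"partner": r.partner_id, "z_min_A": r.z_interval[0],
             "z_max_A": r.z_interval[1]}
            for r in ranges
        ],
        columns=["partner", "z_min_A", "z_max_A"],
    )


def events_to_dataframe(events: Sequence[PermeationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"direction": e.direction, "t_start_ps": e.t_start,
             "t_end_ps": e.t_end, "duration_ps": e.duration}
            for e in events
        ],
        columns=["direction", "t_start_ps", "t_end_ps", "duration_ps"],
    )
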
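"""Participant and trial exclusion rules, and per-direction error patterns.

The cleaning contract is ordered: participants are screened first (a
participant whose reproduced distances do not correlate positively and
significantly with the target distances is excluded wholesale — the signature
of a duration-reproduction strategy), and only then are individual trials
removed whose absolute error deviates more than two standard deviations from
that participant's overall mean. Swapping the order changes the result, so
the order is part of the contract. The outlier rule is applied once, not
iterated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .frames import to_body_frame

__all__ = [
    "DIRECTION_GRID_DEG",
    "ORIENTATIONS",
    "FRAMES",
    "ErrorPattern",
    "ensure_error_columns",
    "screen_participants",
    "remove_outlier_trials",
    "error_pattern",
]

#: the 12 sagittal-plane translation directions (degrees, earth frame)
DIRECTION_GRID_DEG = tuple(range(-150, 181, 30))

ORIENTATIONS = ("upright", "pitch30")
FRAMES = ("earth", "body")

#: pitch angle (deg) of the backward-pitched orientation
PITCH_DEG = 30.0


@dataclass(frozen=True)
class ErrorPattern:
    """Mean absolute error (m) per direction bin, in a named reference frame.

    Bins with no trials carry NaN and a zero count; they are flagged rather
    than dropped so downstream consumers can refuse to correlate incomplete
    patterns by name.
    """

    frame: str
    orientation: str
    values: dict[int, float]
    n_per_bin: dict[int, int]

    def __post_init__(self):
        if tuple(sorted(self.values)) != tuple(sorted(DIRECTION_GRID_DEG)):
            raise ValueError("pattern must cover exactly the 12-direction grid")

    def directions(self) -> list[int]:
        return sorted(self.values)

    def items(self):
        return self.values.items()

    def __getitem__(self, direction: int) -> float:
        return self.values[direction]

    def empty_bins(self) -> list[int]:
        return sorted(d for d, n in self.n_per_bin.items() if n == 0)

    def to_dict(self) -> dict:
        return {
            "frame": self.frame,
            "orientation": self.orientation,
            "values": {str(d): float(v) for d, v in sorted(self.values.items())},
            "n_per_bin": {str(d): int(n) for d, n in sorted(self.n_per_bin.items())},
        }


@dataclass
class ExclusionReport:
    """Which participants were excluded, and why; plus trial-level removals."""

    excluded: list[dict] = field(default_factory=list)
    removed_trial_fraction: float | None = None

    @property
    def excluded_ids(self) -> list:
        return [e["participant_id"] for e in self.excluded]

    def to_dict(self) -> dict:
        return {
            "excluded": self.excluded,
            "removed_trial_fraction": self.removed_trial_fraction,
        }


def ensure_error_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Derive signed_error and abs_error from the raw columns if absent."""
    df = table.copy()
    if "signed_error" not in df.columns:
        df["signed_error"] = df["reproduced_distance"] - df["target_distance"]
    if "abs_error" not in df.columns:
        df["abs_error"] = df["signed_error"].abs()
    return df


def screen_participants(
    table: pd.DataFrame, alpha_level: float = 0.05
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Exclude participants whose reproduced distances do not track the targets.

    Per participant, the Pearson correlation between target and reproduced
    distances across all their trials is tested two-sided (n-2 df); the
    participant is excluded when p >= alpha_level or r <= 0. A participant
    with constant responses has no defined correlation and is excluded with a
    logged reason rather than crashing the screen.
    """
    table = ensure_error_columns(table)
    report = ExclusionReport()
    keep_ids = []
    for pid, grp in table.groupby("participant_id", sort=True):
        if len(grp) < 3:
            raise ValueError(f"participant {pid!r} has fewer than 3 trials")
        x = grp["target_distance"].to_numpy(float)
        y = grp["reproduced_distance"].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            report.excluded.append(
                {"participant_id": pid, "reason": "constant responses (undefined correlation)",
                 "r": None, "p": None}
            )
            continue
        r, p = stats.pearsonr(x, y)
        if p >= alpha_level or r <= 0:
            report.excluded.append(
                {"participant_id": pid,
                 "reason": "no significant positive target-response correlation",
                 "r": float(r), "p": float(p)}
            )
        else:
            keep_ids.append(pid)
    kept = table[table["participant_id"].isin(keep_ids)].reset_index(drop=True)
    return kept, report


def remove_outlier_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop trials whose absolute error deviates more than two standard
    deviations from the participant's overall mean (single pass, both
    orientations pooled). Returns the cleaned table and the removed fraction.

    Participants with fewer than 2 trials (sample SD undefined) keep all
    their trials.
    """
    table = ensure_error_columns(table)
    keep_mask = pd.Series(True, index=table.index)
    for _, grp in table.groupby("participant_id", sort=False):
        if len(grp) < 2:
            continue
        y = grp["abs_error"]
        m, s = y.mean(), y.std(ddof=1)
        keep_mask.loc[grp.index] = (y - m).abs() <= 2.0 * s
    removed_fraction = float(1.0 - keep_mask.mean()) if len(table) else 0.0
    return table[keep_mask].reset_index(drop=True), removed_fraction


def error_pattern(
    table: pd.DataFrame, orientation: str, frame: str, pitch_deg: float = PITCH_DEG
) -> ErrorPattern:
    """Mean absolute error per direction bin for one orientation, with the
    directions relabeled into the requested reference frame.

    For the upright orientation both frames coincide; for the pitched
    orientation the body frame rotates every direction label by -pitch_deg.
    Bins without trials are flagged (NaN value, zero count).
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}; expected one of {ORIENTATIONS}")
    if frame not in FRAMES:
        raise ValueError(f"unknown frame {frame!r}; expected one of {FRAMES}")
    table = ensure_error_columns(table)
    sub = table[table["orientation"] == orientation]
    dirs = sub["direction_deg"].to_numpy(float)
    if frame == "body" and orientation == "pitch30":
        dirs = to_body_frame(dirs, pitch_deg)
    binned = pd.Series(sub["abs_error"].to_numpy(float), index=np.round(dirs).astype(int))
    grouped = binned.groupby(level=0)
    means = grouped.mean()
    counts = grouped.size()
    values = {d: float(means.get(d, np.nan)) for d in DIRECTION_GRID_DEG}
    n_per_bin = {d: int(counts.get(d, 0)) for d in DIRECTION_GRID_DEG}
    return ErrorPattern(frame=frame, orientation=orientation, values=values, n_per_bin=n_per_bin)
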
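"""Earth- versus body-centered direction coding and the frame-correlation test.

When the observer sits upright, body- and earth-centered direction labels
coincide. A 30 deg backward pitch dissociates them: a translation at earth
angle 120 deg is then a straight-up (90 deg) translation relative to the
trunk. If the per-direction accuracy pattern is anchored to the body it
rotates with the observer; if it is anchored to gravity it stays put. The
test correlates the upright pattern with the pitched pattern coded both ways
and asks which coding preserves it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "wrap_direction",
    "to_body_frame",
    "FrameCorrelation",
    "frame_correlation",
]


def wrap_direction(deg):
    """Wrap an angle (degrees) into (-180, 180], the convention of the
    12-direction grid {-150, -120, ..., 150, 180}."""
    w = np.asarray(deg, dtype=float) % 360.0
    w = np.where(w > 180.0, w - 360.0, w)
    return float(w) if w.ndim == 0 else w


def to_body_frame(direction_earth_deg, pitch_deg: float):
    """Relabel an earth-frame direction as a body-frame direction.

    A backward pitch of `pitch_deg` raises the trunk's forward axis by that
    angle, so body angle = earth angle - pitch, wrapped onto (-180, 180] so
    that grid directions map to grid directions (e.g. earth 120 deg at 30 deg
    pitch is body 90 deg, and earth -150 deg wraps to body 180 deg).
    """
    return wrap_direction(np.asarray(direction_earth_deg, dtype=float) - pitch_deg)


@dataclass(frozen=True)
class FrameCorrelation:
    """Pearson correlation between two 12-bin error patterns in one frame."""

    frame: str
    r: float
    p: float
    n_pairs: int
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "frame": self.frame,
            "r": float(self.r),
            "p": float(self.p),
            "n_pairs": int(self.n_pairs),
            "defined": bool(self.defined),
        }


def frame_correlation(pattern_upright, pattern_pitched, frame: str | None = None) -> FrameCorrelation:
    """Correlate the upright error pattern with the pitched pattern.

    Both patterns must cover the full 12-direction grid; the pitched pattern
    is expected to be expressed already in the requested frame (its `frame`
    attribute is checked when `frame` is given). The p-value is two-sided from
    the t distribution with n_pairs - 2 degrees of freedom.
    """
    if frame is not None and pattern_pitched.frame != frame:
        raise ValueError(
            f"pitched pattern is coded in frame {pattern_pitched.frame!r}, not {frame!r}"
        )
    frame = frame or pattern_pitched.frame
    missing = sorted(
        set(d for d, v in pattern_upright.items() if not np.isfinite(v))
        | set(d for d, v in pattern_pitched.items() if not np.isfinite(v))
    )
    if missing:
        raise ValueError(f"error patterns have empty bins at directions {missing}")
    dirs = sorted(pattern_upright.directions())
    if dirs != sorted(pattern_pitched.directions()):
        raise ValueError("patterns are defined on different direction grids")
    x = np.array([pattern_upright[d] for d in dirs])
    y = np.array([pattern_pitched[d] for d in dirs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return FrameCorrelation(frame=frame, r=float("nan"), p=float("nan"),
                                n_pairs=len(dirs), defined=False)
    r, p = stats.pearsonr(x, y)
    return FrameCorrelation(frame=frame, r=float(r), p=float(p), n_pairs=len(dirs))
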
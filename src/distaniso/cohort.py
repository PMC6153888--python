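"""Synthetic distance-reproduction cohorts.

Generates trial tables with the statistical structure the analysis assumes:
a within-participant design of 2 body orientations x 12 sagittal directions x
6 target distances (144 test trials per participant), direction-dependent
absolute-error structure from one of the five (an)isotropy model variants,
a multiplicative log-normal participant random effect, and a minority of
"duration-strategy" participants who reproduce elapsed time instead of
distance, so their reproduced distances are unrelated to the targets.

Noise calibration. The analysis models the *expected absolute* error
mu(alpha); the generator draws a zero-centered signed error whose absolute
value has exactly that mean. For an unbounded normal this is the folded-normal
identity sigma = mu*sqrt(pi/2). Responses, however, live on the test
translation's path [0 m, 2.5 m], so signed errors are drawn from a normal
truncated to [-D, 2.5-D] (D the target distance) with sigma solved per trial
so that E|error| still equals mu(alpha) exactly. Without this calibration the
bounded response range would bias mean absolute errors low at short target
distances and propagate into the fitted weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .frames import to_body_frame
from .models import AnisotropyParams, predict_error
from .motion import (
    TEST_PEAK_ACCEL,
    TEST_TOTAL_DISTANCE,
    TEST_TOTAL_TIME,
    build_test_profile,
    position_at,
    solve_test_profile,
)

__all__ = [
    "DIRECTIONS_DEG",
    "TARGET_DISTANCES",
    "CohortConfig",
    "simulate_cohort",
    "write_trial_table",
    "read_trial_table",
    "truncated_abs_mean",
    "solve_truncated_sd",
]

#: the 12 sagittal translation directions (deg, earth frame, 0 = forward)
DIRECTIONS_DEG = np.arange(-150, 181, 30)

#: the 6 target distances (m)
TARGET_DISTANCES = np.array([0.5, 0.7, 0.9, 1.1, 1.3, 1.5])

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _default_true_params() -> AnisotropyParams:
    # horizontal-vertical anisotropy at the magnitudes the analysis is
    # designed to resolve (horizontal more accurate than vertical)
    return AnisotropyParams(variant="hv", w_h=0.36, w_v=0.40)


@dataclass
class CohortConfig:
    """Generative settings for one simulated cohort.

    participant_sd is the standard deviation, on the log scale, of the single
    multiplicative random effect applied to every weight of a participant
    (median scaling 1). duration_strategy_fraction participants ignore
    distance and press at a roughly fixed time into the test translation.
    The anisotropy is body-fixed by default: in the pitched orientation the
    generative error curve follows body-frame directions.
    """

    n_participants: int = 24
    generative_variant: str = "hv"
    true_params: AnisotropyParams = field(default_factory=_default_true_params)
    participant_sd: float = 0.2
    duration_strategy_fraction: float = 4 / 24
    seed: int = 0
    trials_per_cell: int = 1
    anisotropy_frame: str = "body"
    pitch_deg: float = 30.0

    def __post_init__(self):
        if isinstance(self.true_params, dict):
            self.true_params = AnisotropyParams(**self.true_params)
        if self.n_participants < 1:
            raise ValueError("n_participants must be ≥ 1")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be ≥ 0")
        if not 0 <= self.duration_strategy_fraction < 0.5:
            raise ValueError("duration_strategy_fraction must lie in [0, 0.5)")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be ≥ 1")
        if self.anisotropy_frame not in ("body", "earth"):
            raise ValueError("anisotropy_frame must be 'body' or 'earth'")
        if self.true_params.variant != self.generative_variant:
            raise ValueError("true_params.variant must match generative_variant")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def truncated_abs_mean(sigma, lo, hi):
    """E|X| for X ~ N(0, sigma^2) truncated to [lo, hi] (lo < 0 < hi)."""
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = lo / sigma
        b = hi / sigma
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        out = sigma * (2.0 / _SQRT_2PI - stats.norm.pdf(b) - stats.norm.pdf(a)) / z
    return np.where(sigma > 0, out, 0.0)


def solve_truncated_sd(mu, lo, hi, iters: int = 80, sigma_max: float = 1e3):
    """Solve E|X| = mu for the scale of a normal truncated to [lo, hi].

    E|X| is increasing in sigma and saturates at the uniform-limit value
    (lo^2 + hi^2)/(2*(hi - lo)); targets at or above that supremum get the
    capped sigma_max (the achievable mean then falls slightly short).
    Vectorised bisection, exact to ~1e-12 relative.
    """
    mu = np.asarray(mu, dtype=float)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), mu.shape).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), mu.shape).copy()
    lo_s = np.full(mu.shape, 1e-12)
    hi_s = np.full(mu.shape, sigma_max)
    infeasible = truncated_abs_mean(hi_s, lo, hi) <= mu
    for _ in range(iters):
        mid = 0.5 * (lo_s + hi_s)
        too_small = truncated_abs_mean(mid, lo, hi) < mu
        lo_s = np.where(too_small, mid, lo_s)
        hi_s = np.where(too_small, hi_s, mid)
    sigma = 0.5 * (lo_s + hi_s)
    sigma = np.where(infeasible, sigma_max, sigma)
    return np.where(mu > 0, sigma, 0.0)


_TEST_PROFILE = None


def _test_profile():
    global _TEST_PROFILE
    if _TEST_PROFILE is None:
        params = solve_test_profile(TEST_PEAK_ACCEL, TEST_TOTAL_TIME, TEST_TOTAL_DISTANCE)
        _TEST_PROFILE = build_test_profile(params)
    return _TEST_PROFILE


def _design_cells(trials_per_cell: int) -> pd.DataFrame:
    cells = pd.MultiIndex.from_product(
        [DIRECTIONS_DEG, TARGET_DISTANCES, range(trials_per_cell)],
        names=["direction_deg", "target_distance", "rep"],
    ).to_frame(index=False)
    return cells.drop(columns="rep")


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one cohort's long-format trial table, deterministic in the seed.

    Columns: participant_id, block, orientation, direction_deg,
    target_distance, reproduced_distance, signed_error, abs_error, strategy.
    Trials are organised in 12 blocks (6 per orientation, orientation order
    counterbalanced across participants); the block structure carries no
    generative effect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_duration = int(round(config.duration_strategy_fraction * n))
    duration_ids = rng.choice(n, size=n_duration, replace=False)
    is_duration_p = np.zeros(n, dtype=bool)
    is_duration_p[duration_ids] = True
    scales = np.exp(config.participant_sd * rng.standard_normal(n))
    press_anchors = rng.uniform(2.0, 4.0, size=n)  # duration strategy: fixed press time
    true_w = config.true_params.as_array()

    cells = _design_cells(config.trials_per_cell)
    n_per_orient = len(cells)

    # long-format frame: participants x (two orientation halves) x cells,
    # trials shuffled within each half and split into 6 blocks of equal size
    pid = np.repeat(np.arange(n), 2 * n_per_orient)
    half = np.tile(np.repeat([0, 1], n_per_orient), n)
    # orientation order counterbalanced: even participants upright first
    upright_half = (pid % 2).astype(int)  # which half holds the upright blocks
    orientation = np.where(half == upright_half, "upright", "pitch30")
    order = rng.permuted(
        np.tile(np.arange(n_per_orient), (2 * n, 1)), axis=1
    ).ravel()
    direction = cells["direction_deg"].to_numpy(float)[order]
    D = cells["target_distance"].to_numpy(float)[order]
    block = half * 6 + 1 + (np.arange(len(pid)) % n_per_orient) * 6 // n_per_orient

    reproduced = np.empty(len(pid))
    dur_mask = is_duration_p[pid]
    if dur_mask.any():
        press = press_anchors[pid[dur_mask]] + rng.normal(0.0, 0.15, size=int(dur_mask.sum()))
        press = np.clip(press, 0.0, TEST_TOTAL_TIME)
        reproduced[dur_mask] = position_at(_test_profile(), press)
    dist_mask = ~dur_mask
    if dist_mask.any():
        alpha = direction[dist_mask].copy()
        if config.anisotropy_frame == "body":
            pitched = orientation[dist_mask] == "pitch30"
            alpha[pitched] = to_body_frame(alpha[pitched], config.pitch_deg)
        # every variant is homogeneous of degree 1 in its weights, so the
        # participant scaling multiplies the predicted error directly
        mu = scales[pid[dist_mask]] * np.asarray(
            predict_error(config.true_params, alpha), dtype=float
        )
        Dm = D[dist_mask]
        sigma = solve_truncated_sd(mu, -Dm, TEST_TOTAL_DISTANCE - Dm)
        signed = np.zeros(int(dist_mask.sum()))
        pos = sigma > 0
        if np.any(pos):
            signed[pos] = stats.truncnorm.rvs(
                -Dm[pos] / sigma[pos],
                (TEST_TOTAL_DISTANCE - Dm[pos]) / sigma[pos],
                scale=sigma[pos],
                random_state=rng,
            )
        reproduced[dist_mask] = Dm + signed

    table = pd.DataFrame(
        {
            "participant_id": np.char.add("p", np.char.zfill(pid.astype(str), 2)),
            "block": block,
            "orientation": orientation,
            "direction_deg": direction,
            "target_distance": D,
            "reproduced_distance": reproduced,
            "strategy": np.where(dur_mask, "duration", "distance"),
        }
    )
    table["signed_error"] = table["reproduced_distance"] - table["target_distance"]
    table["abs_error"] = table["signed_error"].abs()
    cols = [
        "participant_id", "block", "orientation", "direction_deg", "target_distance",
        "reproduced_distance", "signed_error", "abs_error", "strategy",
    ]
    return table[cols]


_CSV_COLUMNS = [
    "participant_id", "block", "orientation", "direction_deg",
    "target_distance", "reproduced_distance",
]


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write the long-format CSV (core columns only; errors are derived)."""
    table[_CSV_COLUMNS].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read a long-format trial CSV and recompute the error columns."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    df["signed_error"] = df["reproduced_distance"] - df["target_distance"]
    df["abs_error"] = df["signed_error"].abs()
    return df
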
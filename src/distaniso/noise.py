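"""Simulator stimulus-noise audit.

Motion simulators do not render commanded accelerations perfectly; if the
rendering noise differed systematically between the remembered (target) and
the reproduced-along (test) translation, or across directions, it could
masquerade as a perceptual anisotropy. The audit quantifies rendering
fidelity per trial condition as a signal-to-noise ratio

    SNR = ( rms(|cmd|) / rms(|cmd - rec|) )^2

over the 3-axis commanded and recorded acceleration series, and then asks
whether the noise-level differences between target and test translations are
even perceivable, by comparing them against Weber-type differential
thresholds for linear acceleration: Delta-I = 0.05*I + 0.03 for horizontal,
0.19*I^0.60 for upward and 0.17*I^0.42 for downward translations, combined
for oblique directions through the direction projections (with the opposite
vertical term zeroed).

Hardware recordings are not part of the package; `synthesize_imu` produces
commanded/recorded pairs with controlled injected noise so the procedure can
be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .motion import MotionProfile

__all__ = [
    "IMURecording",
    "ThresholdModel",
    "preprocess_imu",
    "snr",
    "noise_rms",
    "differential_threshold",
    "noise_vs_threshold",
    "NoiseAudit",
    "two_way_anova",
    "synthesize_imu",
    "write_imu_csv",
    "read_imu_csv",
]


@dataclass(frozen=True)
class IMURecording:
    """A commanded/recorded 3-axis acceleration pair for one trial motion.

    Axes are x (earth-horizontal forward), y (lateral), z (earth-vertical up),
    in m/s^2. `label` identifies the trial condition: direction_deg,
    target_distance, orientation, phase ('target' or 'test'), repeat (1-5).
    """

    time: np.ndarray
    commanded: np.ndarray  # shape (n, 3)
    recorded: np.ndarray  # shape (n, 3)
    sample_rate: float
    label: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.commanded.shape != self.recorded.shape or self.commanded.shape[1] != 3:
            raise ValueError("commanded and recorded must share shape (n, 3)")


@dataclass(frozen=True)
class ThresholdModel:
    """Differential-threshold coefficients for linear acceleration.

    horizontal: Delta-I = slope*I + offset; upward/downward:
    Delta-I = coef * I**exponent. All coefficients positive, exponents in
    (0, 1].
    """

    horizontal_slope: float = 0.05
    horizontal_offset: float = 0.03
    upward_coef: float = 0.19
    upward_exponent: float = 0.60
    downward_coef: float = 0.17
    downward_exponent: float = 0.42

    def __post_init__(self):
        vals = [self.horizontal_slope, self.horizontal_offset, self.upward_coef,
                self.downward_coef]
        if any(v <= 0 for v in vals):
            raise ValueError("all threshold coefficients must be positive")
        for e in (self.upward_exponent, self.downward_exponent):
            if not 0 < e <= 1:
                raise ValueError("exponents must lie in (0, 1]")


def preprocess_imu(raw: IMURecording, cutoff_hz: float = 80.0, order: int = 4) -> IMURecording:
    """Zero-phase low-pass the recorded axes and remove the gravity offset.

    The filter is a Butterworth of the given order applied forward-backward
    (zero phase); gravity removal subtracts each recorded axis's mean over the
    whole recording (setting the mean intercept to zero). Requires
    sample_rate > 2*cutoff.
    """
    if raw.sample_rate <= 2.0 * cutoff_hz:
        raise ValueError(
            f"sample_rate {raw.sample_rate} Hz too low for a {cutoff_hz} Hz cutoff"
        )
    sos = sp_signal.butter(order, cutoff_hz, btype="low", fs=raw.sample_rate, output="sos")
    rec = sp_signal.sosfiltfilt(sos, raw.recorded, axis=0)
    rec = rec - rec.mean(axis=0, keepdims=True)
    return replace(raw, recorded=rec)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def noise_rms(rec: IMURecording) -> float:
    """RMS of the norm of the commanded-minus-recorded difference (the
    stimulus noise level, m/s^2)."""
    diff = rec.commanded - rec.recorded
    return _rms(np.linalg.norm(diff, axis=1))


def snr(rec: IMURecording) -> float:
    """Squared ratio of the rms commanded-vector norm to the rms noise norm.

    A perfect recording (recorded identical to commanded) yields the infinite
    sentinel `inf`; an all-zero commanded signal yields 0.
    """
    cmd_rms = _rms(np.linalg.norm(rec.commanded, axis=1))
    nse_rms = noise_rms(rec)
    if cmd_rms == 0.0:
        return 0.0
    if nse_rms == 0.0:
        return float("inf")
    return (cmd_rms / nse_rms) ** 2


def differential_threshold(
    I, alpha_deg: float, thresholds: ThresholdModel = ThresholdModel(), mode: str = "shortcut"
):
    """Smallest perceivable acceleration difference (m/s^2) at intensity I.

    mode="shortcut" (default) routes pure-axis directions through the single-
    axis functions directly (0/180 deg -> horizontal with unsigned intensity,
    +90 -> upward, -90 -> downward) and combines obliques through the
    direction projections. mode="literal" evaluates the combined formula as
    printed for every direction; note that at +-90 deg the horizontal offset
    term then persists inside the root, so the literal form does not reduce to
    the pure-vertical functions.
    """
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < 0):
        raise ValueError("stimulus intensity must be non-negative")
    if mode not in ("shortcut", "literal"):
        raise ValueError("mode must be 'shortcut' or 'literal'")
    t = thresholds
    a = np.deg2rad(float(alpha_deg))
    c, s = np.cos(a), np.sin(a)

    def horiz(x):
        return t.horizontal_slope * x + t.horizontal_offset

    def up(x):
        return t.upward_coef * x**t.upward_exponent

    def down(x):
        return t.downward_coef * x**t.downward_exponent

    if mode == "shortcut":
        if abs(s) < 1e-12:  # pure horizontal (forward or backward)
            out = horiz(I_arr)
            return float(out) if out.ndim == 0 else out
        if abs(c) < 1e-12:  # pure vertical
            out = up(I_arr) if s > 0 else down(I_arr)
            return float(out) if out.ndim == 0 else out
    term_h = (c * t.horizontal_slope * I_arr + t.horizontal_offset) ** 2
    term_u = (s * up(I_arr)) ** 2 if s > 0 else 0.0
    term_d = (s * down(I_arr)) ** 2 if s < 0 else 0.0
    out = np.sqrt(term_h + term_u + term_d)
    return float(out) if out.ndim == 0 else out


@dataclass
class NoiseAudit:
    """Per-direction audit table plus any missing-condition gaps."""

    table: pd.DataFrame
    gaps: list[dict] = field(default_factory=list)

    def all_sub_threshold(self) -> bool:
        return bool(self.table["sub_threshold"].all())

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "gaps": self.gaps,
        }


def noise_vs_threshold(
    recordings: list[IMURecording], thresholds: ThresholdModel = ThresholdModel()
) -> NoiseAudit:
    """Compare target/test noise differences against differential thresholds.

    Per (orientation, direction): average the SNR of the target and of the
    test recordings over repeats (on the SNR scale), take the absolute
    difference of the mean noise rms between target and test, and compute the
    lowest differential threshold across that direction's stimuli, plugging
    each target stimulus's noise rms in as the intensity I. The condition is
    flagged sub-threshold when the noise difference stays below that lowest
    threshold.
    """
    rows = []
    gaps = []
    keyed: dict[tuple, dict[str, list[IMURecording]]] = {}
    for rec in recordings:
        lab = rec.label
        key = (lab.get("orientation", "upright"), lab["direction_deg"])
        keyed.setdefault(key, {"target": [], "test": []})[lab["phase"]].append(rec)
    for (orientation, direction), phases in sorted(keyed.items()):
        targets, tests = phases["target"], phases["test"]
        if not targets or not tests:
            gaps.append(
                {"orientation": orientation, "direction_deg": direction,
                 "missing": "test" if targets else "target"}
            )
            continue
        snr_target = float(np.mean([snr(r) for r in targets]))
        snr_test = float(np.mean([snr(r) for r in tests]))
        rms_target = float(np.mean([noise_rms(r) for r in targets]))
        rms_test = float(np.mean([noise_rms(r) for r in tests]))
        diff = abs(rms_target - rms_test)
        lowest = min(
            differential_threshold(noise_rms(r), direction, thresholds) for r in targets
        )
        rows.append(
            {
                "orientation": orientation,
                "direction_deg": direction,
                "snr_target": snr_target,
                "snr_test": snr_test,
                "noise_rms_target": rms_target,
                "noise_rms_test": rms_test,
                "noise_rms_diff": diff,
                "lowest_threshold": float(lowest),
                "sub_threshold": bool(diff < lowest),
            }
        )
    return NoiseAudit(table=pd.DataFrame(rows), gaps=gaps)


def two_way_anova(values, factor_direction, factor_orientation) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction on a balanced layout.

    Returns a table indexed by effect (direction, orientation,
    direction:orientation, residual) with sum_sq, df, F and p. Degenerate
    inputs are reported with sentinels instead of NaN: zero variance
    everywhere gives F=0, p=1; a perfectly noiseless effect gives F=inf, p=0.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "direction": pd.Categorical(factor_direction),
            "orientation": pd.Categorical(factor_orientation),
        }
    )
    counts = df.groupby(["direction", "orientation"], observed=True).size()
    expected_cells = df["direction"].nunique() * df["orientation"].nunique()
    if len(counts) < expected_cells or counts.min() == 0:
        raise ValueError("empty factor cells; the layout must be complete")
    if counts.nunique() > 1:
        raise ValueError("unbalanced layout; equal repeats per cell required")
    model = smf.ols("value ~ C(direction) * C(orientation)", data=df).fit()
    table = anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(direction)": "direction",
            "C(orientation)": "orientation",
            "C(direction):C(orientation)": "direction:orientation",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    # replace numerically degenerate ratios (zero residual variance) with
    # explicit sentinels, judged relative to the data's scale
    scale = float(np.mean(np.square(df["value"]))) + 1e-300
    resid_ms = table.loc["residual", "sum_sq"] / table.loc["residual", "df"]
    if resid_ms < 1e-12 * scale:
        for effect in table.index.drop("residual"):
            effect_ms = table.loc[effect, "sum_sq"] / table.loc[effect, "df"]
            if effect_ms > 1e-10 * scale:
                table.loc[effect, "F"] = np.inf
                table.loc[effect, "p"] = 0.0
            else:
                table.loc[effect, "F"] = 0.0
                table.loc[effect, "p"] = 1.0
    return table


def synthesize_imu(
    profile: MotionProfile,
    direction_deg: float,
    noise_sd_per_axis: float,
    seed=None,
    orientation: str = "upright",
    target_distance: float | None = None,
    phase: str = "target",
    repeat: int = 1,
    dc_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> IMURecording:
    """Synthetic commanded/recorded pair for one trial motion.

    The commanded signal projects the profile's acceleration onto the sagittal
    unit vector (x = cos alpha, y = 0, z = sin alpha); the recorded signal
    adds seeded iid per-axis Gaussian noise and an optional DC offset (for
    gravity-removal tests). Stands in for hardware IMU recordings.
    """
    if noise_sd_per_axis < 0:
        raise ValueError("noise sd must be ≥ 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.deg2rad(direction_deg)
    unit = np.array([np.cos(a), 0.0, np.sin(a)])
    commanded = profile.acceleration[:, None] * unit[None, :]
    recorded = commanded + rng.normal(0.0, noise_sd_per_axis, size=commanded.shape)
    recorded = recorded + np.asarray(dc_offset, dtype=float)[None, :]
    label = {
        "direction_deg": float(direction_deg),
        "target_distance": target_distance,
        "orientation": orientation,
        "phase": phase,
        "repeat": int(repeat),
    }
    return IMURecording(
        time=profile.time.copy(),
        commanded=commanded,
        recorded=recorded,
        sample_rate=profile.sample_rate,
        label=label,
    )


_IMU_COLUMNS = ["time", "cmd_x", "cmd_y", "cmd_z", "rec_x", "rec_y", "rec_z"]


def write_imu_csv(rec: IMURecording, path) -> None:
    """Write the trace as CSV plus a sidecar JSON with the trial label."""
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.commanded, rec.recorded]), columns=_IMU_COLUMNS
    )
    path = str(path)
    df.to_csv(path, index=False)
    sidecar = path[: path.rfind(".")] + ".json" if "." in path else path + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"sample_rate": rec.sample_rate, "label": rec.label}, fh, sort_keys=True)


def read_imu_csv(path) -> IMURecording:
    df = pd.read_csv(path)
    path = str(path)
    sidecar = path[: path.rfind(".")] + ".json" if "." in path else path + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    return IMURecording(
        time=df["time"].to_numpy(float),
        commanded=df[["cmd_x", "cmd_y", "cmd_z"]].to_numpy(float),
        recorded=df[["rec_x", "rec_y", "rec_z"]].to_numpy(float),
        sample_rate=float(meta["sample_rate"]),
        label=meta["label"],
    )
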
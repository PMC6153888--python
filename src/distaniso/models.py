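"""(An)isotropy error models for traveled-distance reproduction.

The response variable is the absolute reproduction error of one trial; the
predictor is the translation direction alpha in the sagittal plane (0 deg =
forward, 90 deg = up). Five nested model variants describe how the expected
absolute error depends on alpha:

- ``isotropy``: a constant intercept (null model).
- ``hv`` (horizontal-vertical): sqrt((w_h cos a)^2 + (w_v sin a)^2).
- ``ud`` (upward-downward): the vertical weight splits into w_u (sin a > 0)
  and w_d (sin a < 0).
- ``fb`` (forward-backward): the horizontal weight splits into w_f
  (cos a > 0) and w_b (cos a < 0).
- ``fbud``: both splits at once.

The indicator switches use strict inequalities and coincide with vanishing
sin/cos factors, so every variant is continuous in alpha. The quadrature-form
combination means that equal weights reduce a variant to the one it refines
(and ``hv`` with equal weights to a constant), which is what makes the AICc
comparison between them meaningful.

Fitting is by maximum marginal likelihood of a nonlinear mixed-effects model:
each participant's predicted error curve is scaled by exp(b_i) with
b_i ~ N(0, tau^2) (one multiplicative random effect), the residual is
homoscedastic Gaussian, and the single-participant integrals are evaluated by
adaptive Gauss-Hermite quadrature around the per-participant mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize

__all__ = [
    "VARIANTS",
    "VARIANT_WEIGHTS",
    "AnisotropyParams",
    "ModelFitResult",
    "predict_error",
    "marginal_loglik",
    "fit_mixed_model",
    "aicc",
    "compare_models",
]

#: weight names used by each model variant, in canonical order
VARIANT_WEIGHTS: dict[str, tuple[str, ...]] = {
    "isotropy": ("intercept",),
    "hv": ("w_h", "w_v"),
    "ud": ("w_h", "w_u", "w_d"),
    "fb": ("w_f", "w_b", "w_v"),
    "fbud": ("w_f", "w_b", "w_u", "w_d"),
}

VARIANTS = tuple(VARIANT_WEIGHTS)


@dataclass(frozen=True)
class AnisotropyParams:
    """Non-negative error weights (m) of one model variant.

    Only the fields used by `variant` are consulted; the rest stay None.
    """

    variant: str
    w_h: float | None = None
    w_v: float | None = None
    w_u: float | None = None
    w_d: float | None = None
    w_f: float | None = None
    w_b: float | None = None
    intercept: float | None = None

    def __post_init__(self):
        if self.variant not in VARIANT_WEIGHTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name in VARIANT_WEIGHTS[self.variant]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"variant {self.variant!r} requires weight {name!r}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"weight {name!r} must be finite and ≥ 0")

    @property
    def weight_names(self) -> tuple[str, ...]:
        return VARIANT_WEIGHTS[self.variant]

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.weight_names], dtype=float)

    @classmethod
    def from_array(cls, variant: str, weights: np.ndarray) -> "AnisotropyParams":
        names = VARIANT_WEIGHTS[variant]
        if len(weights) != len(names):
            raise ValueError(f"variant {variant!r} takes {len(names)} weights")
        return cls(variant=variant, **dict(zip(names, map(float, weights))))

    def to_dict(self) -> dict:
        d = {"variant": self.variant}
        d.update({n: float(getattr(self, n)) for n in self.weight_names})
        return d


def _predict_arrays(variant: str, w: np.ndarray, cos_a: np.ndarray, sin_a: np.ndarray) -> np.ndarray:
    """Vectorised model prediction from precomputed direction projections."""
    if variant == "isotropy":
        return np.full_like(cos_a, w[0])
    if variant == "hv":
        return np.sqrt((w[0] * cos_a) ** 2 + (w[1] * sin_a) ** 2)
    up = sin_a > 0
    down = sin_a < 0
    fwd = cos_a > 0
    back = cos_a < 0
    if variant == "ud":
        return np.sqrt(
            (w[0] * cos_a) ** 2 + up * (w[1] * sin_a) ** 2 + down * (w[2] * sin_a) ** 2
        )
    if variant == "fb":
        return np.sqrt(
            fwd * (w[0] * cos_a) ** 2 + back * (w[1] * cos_a) ** 2 + (w[2] * sin_a) ** 2
        )
    if variant == "fbud":
        return np.sqrt(
            fwd * (w[0] * cos_a) ** 2
            + back * (w[1] * cos_a) ** 2
            + up * (w[2] * sin_a) ** 2
            + down * (w[3] * sin_a) ** 2
        )
    raise ValueError(f"unknown variant {variant!r}")


def predict_error(params: AnisotropyParams, alpha_deg) -> float | np.ndarray:
    """Expected absolute error (m) at translation direction alpha (degrees)."""
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    out = _predict_arrays(params.variant, params.as_array(), np.cos(a), np.sin(a))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# mixed-effects fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelFitResult:
    """One fitted (an)isotropy model.

    k counts the fixed-effect weights plus the random-effect variance and the
    residual variance; aicc is finite whenever the fit converged.
    """

    variant: str
    fixed_estimates: AnisotropyParams
    random_effect_sd: float
    residual_sd: float
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_participants: int = 0
    data_checksum: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "fixed_estimates": self.fixed_estimates.to_dict(),
            "random_effect_sd": float(self.random_effect_sd),
            "residual_sd": float(self.residual_sd),
            "loglik": float(self.loglik),
            "k": int(self.k),
            "n": int(self.n),
            "aicc": float(self.aicc),
            "converged": bool(self.converged),
            "n_participants": int(self.n_participants),
            "data_checksum": float(self.data_checksum),
        }


class _FitData:
    """Trial table reorganised for fast repeated marginal-likelihood evaluation."""

    def __init__(self, table: pd.DataFrame):
        required = {"participant_id", "direction_deg", "abs_error"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table lacks required columns: {sorted(missing)}")
        df = table.sort_values("participant_id", kind="stable")
        pid = df["participant_id"].to_numpy()
        self.participants, starts = np.unique(pid, return_index=True)
        if len(self.participants) < 2:
            raise ValueError("need at least 2 participants for a mixed-effects fit")
        self.starts = np.sort(starts)
        a = np.deg2rad(df["direction_deg"].to_numpy(float))
        self.cos_a = np.cos(a)
        self.sin_a = np.sin(a)
        self.y = df["abs_error"].to_numpy(float)
        self.n = len(self.y)
        self.n_groups = len(self.participants)
        self.counts = np.diff(np.append(self.starts, self.n))
        self.C = np.add.reduceat(self.y**2, self.starts)
        self.checksum = float(np.round(self.y.sum(), 9))


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    if nodes not in _GH_CACHE:
        x, w = hermgauss(nodes)
        _GH_CACHE[nodes] = (x, np.log(w))
    return _GH_CACHE[nodes]


#: residual variance structures for the Gaussian working likelihood:
#: "proportional": sd_ij = sigma * exp(b_i) * mu_ij (the whole error
#:   distribution scales with the participant effect and the predicted level);
#: "participant": sd_ij = sigma * exp(b_i);
#: "shared": one common sd for every observation.
RESIDUAL_SCALINGS = ("proportional", "participant", "shared")


def _group_loglik(
    data: _FitData,
    mu: np.ndarray,
    tau: float,
    sigma: float,
    gh_nodes: int,
    residual_scaling: str = "shared",
) -> float:
    """Marginal log-likelihood with per-participant multiplicative scaling.

    Under every residual structure the conditional sum of squares reduces to a
    quadratic in exp(+-b) with three sufficient statistics per participant, so
    each quadrature node costs O(n_participants).
    """
    if residual_scaling == "proportional":
        # work with z = y/mu, which is N(exp(b), exp(2b) sigma^2) given b
        m = np.maximum(mu, 1e-10)
        z = data.y / m
        A = data.counts.astype(float)
        B = np.add.reduceat(z, data.starts)
        C = np.add.reduceat(z**2, data.starts)
        log_jac = np.add.reduceat(np.log(m), data.starts)  # d y -> d z
    else:
        A = np.add.reduceat(mu**2, data.starts)
        B = np.add.reduceat(data.y * mu, data.starts)
        C = data.C
        log_jac = np.zeros(data.n_groups)
    scaled = residual_scaling in ("proportional", "participant")
    inv2s2 = 1.0 / (2.0 * sigma**2)
    inv_t2 = 1.0 / tau**2
    n_i = data.counts.astype(float)

    if scaled:
        # conditional ll: -n_i*b - (C e^{-2b} - 2B e^{-b} + A)/(2 sigma^2)
        def h(b):
            e = np.exp(-b)
            Ae, Be, Ce, ne = (
                (np.expand_dims(v, -1) for v in (A, B, C, n_i))
                if np.ndim(b) == 2
                else (A, B, C, n_i)
            )
            return -ne * b - (Ce * e**2 - 2.0 * Be * e + Ae) * inv2s2 - 0.5 * b**2 * inv_t2

        def dh(b):
            e = np.exp(-b)
            return -n_i + (C * e**2 - B * e) / sigma**2 - b * inv_t2

        def d2h(b):
            e = np.exp(-b)
            return (-2.0 * C * e**2 + B * e) / sigma**2 - inv_t2

    else:
        # conditional ll: -(C - 2B e^{b} + A e^{2b})/(2 sigma^2)
        def h(b):
            e = np.exp(b)
            Ae, Be, Ce = (
                (np.expand_dims(v, -1) for v in (A, B, C)) if np.ndim(b) == 2 else (A, B, C)
            )
            return -(Ce - 2.0 * e * Be + e**2 * Ae) * inv2s2 - 0.5 * b**2 * inv_t2

        def dh(b):
            e = np.exp(b)
            return (e * B - e**2 * A) / sigma**2 - b * inv_t2

        def d2h(b):
            e = np.exp(b)
            return (e * B - 2.0 * e**2 * A) / sigma**2 - inv_t2

    # per-participant mode by safeguarded Newton (vectorised over participants)
    b = np.zeros(data.n_groups)
    for _ in range(100):
        g = dh(b)
        H = d2h(b)
        H = np.where(H < -1e-12, H, -1e-12)
        step = np.clip(-g / H, -1.0, 1.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-11:
            break
    curv = np.maximum(-d2h(b), 1e-12)
    s_hat = 1.0 / np.sqrt(curv)

    x, logw = _gh(gh_nodes)
    nodes = b[:, None] + np.sqrt(2.0) * s_hat[:, None] * x[None, :]
    h0 = h(b)
    log_terms = logw[None, :] + x[None, :] ** 2 + h(nodes) - h0[:, None]
    log_int = h0 + np.log(np.sqrt(2.0) * s_hat) + _logsumexp(log_terms)
    const = (
        -0.5 * n_i * np.log(2.0 * np.pi * sigma**2)
        - log_jac
        - 0.5 * np.log(2.0 * np.pi * tau**2)
    )
    return float(np.sum(log_int + const))


def _logsumexp(a: np.ndarray) -> np.ndarray:
    m = np.max(a, axis=1)
    return m + np.log(np.sum(np.exp(a - m[:, None]), axis=1))


def marginal_loglik(
    table: pd.DataFrame,
    params: AnisotropyParams,
    random_effect_sd: float,
    residual_sd: float,
    gh_nodes: int = 15,
    residual_scaling: str = "shared",
) -> float:
    """Marginal log-likelihood of the mixed model at given parameter values.

    Exposed so that the likelihood at the generative truth can be compared
    against the likelihood at the optimum (optimizer sanity checks).
    """
    data = _FitData(table)
    mu = _predict_arrays(
        params.variant, params.as_array(), data.cos_a, data.sin_a
    )
    return _group_loglik(data, mu, random_effect_sd, residual_sd, gh_nodes, residual_scaling)


_LOG_SD_BOUNDS = (-13.8, 5.0)  # sd bounded to [1e-6, ~150]


def fit_mixed_model(
    table: pd.DataFrame,
    variant: str,
    n_starts: int = 5,
    gh_nodes: int = 15,
    seed: int = 0,
    gtol: float = 1e-8,
    residual_scaling: str = "shared",
) -> ModelFitResult:
    """Fit one model variant to a cleaned trial table by maximum likelihood.

    Direction enters continuously through its sine/cosine projections. Weights
    are kept non-negative through an absolute-value reparameterisation, and the
    two variance components through log parameterisation. The optimiser runs
    from a moment-based start plus jittered restarts; the best likelihood wins.
    Non-convergence is flagged on the result, never silently dropped.
    """
    if variant not in VARIANT_WEIGHTS:
        raise ValueError(f"unknown variant {variant!r}")
    if residual_scaling not in RESIDUAL_SCALINGS:
        raise ValueError(f"residual_scaling must be one of {RESIDUAL_SCALINGS}")
    data = _FitData(table)
    names = VARIANT_WEIGHTS[variant]
    p = len(names)

    def negll(theta: np.ndarray) -> float:
        w = np.abs(theta[:p])
        tau = np.exp(theta[p])
        sigma = np.exp(theta[p + 1])
        mu = _predict_arrays(variant, w, data.cos_a, data.sin_a)
        ll = _group_loglik(data, mu, tau, sigma, gh_nodes, residual_scaling)
        return -ll if np.isfinite(ll) else 1e12

    y_mean = float(np.mean(data.y))
    y_sd = float(np.std(data.y)) or 1e-3
    # under proportional scaling sigma is a coefficient of variation
    sigma0 = 0.6 * y_sd / y_mean if residual_scaling == "proportional" and y_mean > 0 else 0.6 * y_sd
    base = np.concatenate(
        [np.full(p, max(y_mean, 1e-3)), [np.log(0.2), np.log(max(sigma0, 1e-4))]]
    )
    rng = np.random.default_rng(seed)
    bounds = [(None, None)] * p + [_LOG_SD_BOUNDS, _LOG_SD_BOUNDS]

    best = None
    n_converged = 0
    for start_idx in range(n_starts):
        theta0 = base.copy()
        if start_idx == 1:
            # cover the no-random-effect boundary (degenerate data collapse
            # onto a flat ridge there that jittered interior starts can miss)
            theta0[p] = _LOG_SD_BOUNDS[0]
        elif start_idx > 1:
            theta0[:p] *= np.exp(rng.normal(0.0, 0.3, size=p))
            theta0[p:] += rng.normal(0.0, 0.5, size=2)
            theta0[p:] = np.clip(theta0[p:], *_LOG_SD_BOUNDS)
        res = minimize(
            negll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    w_hat = np.abs(best.x[:p])
    tau_hat = float(np.exp(best.x[p]))
    sigma_hat = float(np.exp(best.x[p + 1]))
    loglik = -float(best.fun)
    k = p + 2
    converged = n_converged > 0 and np.isfinite(loglik)
    return ModelFitResult(
        variant=variant,
        fixed_estimates=AnisotropyParams.from_array(variant, w_hat),
        random_effect_sd=tau_hat,
        residual_sd=sigma_hat,
        loglik=loglik,
        k=k,
        n=data.n,
        aicc=aicc(loglik, k, data.n) if converged else float("nan"),
        converged=converged,
        n_participants=data.n_groups,
        data_checksum=data.checksum,
        diagnostics={
            "n_starts": n_starts,
            "n_converged_starts": int(n_converged),
            "optimizer_message": str(best.message),
        },
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion:
    AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} ≤ k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def compare_models(fits: list[ModelFitResult]) -> pd.DataFrame:
    """Rank converged fits of the same data by AICc.

    dAICc is the difference from the best (lowest-AICc) model; models within
    dAICc < 4 of the best are flagged indistinguishable from it under the
    conventional model-selection guideline.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ns = {f.n for f in fits}
    checks = {f.data_checksum for f in fits}
    if len(ns) > 1 or len(checks) > 1:
        raise ValueError("fits were computed on differing observation sets; refusing to compare")
    if not all(f.converged for f in fits):
        bad = [f.variant for f in fits if not f.converged]
        raise ValueError(f"non-converged fits cannot be compared: {bad}")
    rows = [
        {
            "variant": f.variant,
            "k": f.k,
            "loglik": f.loglik,
            "aicc": f.aicc,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(["aicc", "variant"], kind="stable").reset_index(drop=True)
    df["daicc"] = df["aicc"] - df["aicc"].min()
    df["best"] = df["daicc"] == 0.0
    df["indistinguishable"] = df["daicc"] < 4.0
    return df
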
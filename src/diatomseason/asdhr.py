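"""Arbitrary-Sampled Dynamic Harmonic Regression (ASDHR).

Unobserved-components decomposition of an irregularly sampled series

    y_t = T_t + S_t + e_t,      S_t = sum_i a_{i,t} cos(w_i t) + b_{i,t} sin(w_i t)

where the trend T_t and the harmonic coefficients a_{i,t}, b_{i,t} are
stochastic time-varying parameters (random walks or integrated random
walks) estimated by a Kalman filter and fixed-interval smoother run
directly on the irregular sampling grid.  The irregular-sampling mechanism
is that process noise accumulates linearly with the elapsed gap: a random
walk injects variance ``nvr * sigma2_e * dt`` over a gap of ``dt`` years,
and the integrated-random-walk trend uses the exact continuous-time
discretisation of an integrated Wiener process over the gap.

Each component's speed of variation is governed by its noise variance
ratio (NVR), the ratio of its process-noise variance (per year) to the
observation-noise variance; NVR = 0 makes the component deterministic and
recovers ordinary harmonic regression.  NVRs and the observation-noise
variance are estimated by maximum likelihood via the prediction-error
decomposition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .errors import (
    EstimationError,
    NumericalConditioningError,
    OrderingError,
    SpecificationError,
    UnderdeterminedFitError,
)
from .series import IrregularSeries

logger = logging.getLogger("diatomseason.asdhr")

RANDOM_WALK = "random_walk"
INTEGRATED_RANDOM_WALK = "integrated_random_walk"
_KIND_ALIASES = {
    "rw": RANDOM_WALK,
    "random_walk": RANDOM_WALK,
    "irw": INTEGRATED_RANDOM_WALK,
    "integrated_random_walk": INTEGRATED_RANDOM_WALK,
}

#: Diffuse-prior scale: initial state variance = DIFFUSE_SCALE * var(y).
DIFFUSE_SCALE = 1e7
#: Innovation-variance floor, relative to var(y).
INNOVATION_FLOOR = 1e-12


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicSet:
    """Fundamental plus harmonic frequencies of the seasonal cycle.

    ``frequencies[i-1] = 2*pi*i / fundamental_period`` for i = 1..n_harmonics,
    in radians per year.
    """

    fundamental_period: float = 1.0
    n_harmonics: int = 2

    def __post_init__(self):
        if not (self.fundamental_period > 0):
            raise SpecificationError(
                f"fundamental_period must be positive, got {self.fundamental_period}"
            )
        if int(self.n_harmonics) < 1 or self.n_harmonics != int(self.n_harmonics):
            raise SpecificationError(
                f"n_harmonics must be a positive integer, got {self.n_harmonics}"
            )

    @property
    def frequencies(self) -> np.ndarray:
        i = np.arange(1, self.n_harmonics + 1)
        return 2.0 * np.pi * i / self.fundamental_period


def make_harmonics(fundamental_period: float, n_harmonics: int) -> HarmonicSet:
    """Build the harmonic set ``w_i = 2*pi*i / fundamental_period``."""
    return HarmonicSet(float(fundamental_period), int(n_harmonics))


@dataclass
class TVPModel:
    """Stochastic law of one time-varying parameter.

    ``kind`` is ``"random_walk"`` (alias ``"rw"``) or
    ``"integrated_random_walk"`` (alias ``"irw"``).  ``nvr`` is the noise
    variance ratio; ``nvr = 0`` freezes the parameter, ``nvr = None`` asks
    for maximum-likelihood estimation.
    """

    kind: str = RANDOM_WALK
    nvr: Optional[float] = None

    def __post_init__(self):
        key = str(self.kind).lower()
        if key not in _KIND_ALIASES:
            raise SpecificationError(f"unknown TVP kind {self.kind!r}")
        self.kind = _KIND_ALIASES[key]
        if self.nvr is not None and not (self.nvr >= 0):
            raise SpecificationError(f"nvr must be >= 0 or None, got {self.nvr}")

    @property
    def dim(self) -> int:
        return 2 if self.kind == INTEGRATED_RANDOM_WALK else 1


@dataclass
class UCSpec:
    """Unobserved-components model: trend + harmonics (+ optional cycle stub).

    The state vector is ``[trend block | a_1, b_1 | ... | a_R, b_R]`` with a
    one-element trend block for a random-walk trend and ``[level, slope]``
    for an integrated-random-walk trend.  ``seasonal`` may be a single
    :class:`TVPModel` shared by all harmonics or one per harmonic.  A cycle
    component is accepted as a flag for interface completeness but not
    modelled (``include_cycle=True`` raises).
    """

    trend: TVPModel = field(default_factory=lambda: TVPModel(INTEGRATED_RANDOM_WALK))
    seasonal: Union[TVPModel, Sequence[TVPModel]] = field(
        default_factory=lambda: TVPModel(RANDOM_WALK))
    harmonics: Optional[HarmonicSet] = field(default_factory=HarmonicSet)
    include_cycle: bool = False
    obs_noise_variance: Optional[float] = None

    def __post_init__(self):
        if self.include_cycle:
            raise SpecificationError(
                "cycle component is a configuration stub only; no cyclic "
                "component is estimated")
        if self.obs_noise_variance is not None and not (self.obs_noise_variance > 0):
            raise SpecificationError("obs_noise_variance must be positive or None")
        for m in self.seasonal_models:
            if m.kind != RANDOM_WALK and m.kind != INTEGRATED_RANDOM_WALK:
                raise SpecificationError(f"bad seasonal TVP kind {m.kind!r}")
            if m.dim != 1:
                raise SpecificationError(
                    "harmonic coefficients must follow a random walk "
                    "(integrated-random-walk harmonics are not supported)")

    @property
    def n_harmonics(self) -> int:
        """Zero for a trend-only model (``harmonics=None``)."""
        return 0 if self.harmonics is None else self.harmonics.n_harmonics

    @property
    def frequencies(self) -> np.ndarray:
        return np.empty(0) if self.harmonics is None else self.harmonics.frequencies

    @property
    def shared_seasonal(self) -> bool:
        return isinstance(self.seasonal, TVPModel)

    @property
    def seasonal_models(self) -> list:
        if self.n_harmonics == 0:
            return []
        if self.shared_seasonal:
            return [self.seasonal] * self.n_harmonics
        models = list(self.seasonal)
        if len(models) != self.n_harmonics:
            raise SpecificationError(
                f"{len(models)} seasonal TVP models for "
                f"{self.n_harmonics} harmonics")
        return models

    @property
    def trend_dim(self) -> int:
        return self.trend.dim

    @property
    def state_dim(self) -> int:
        return self.trend_dim + 2 * self.n_harmonics

    @property
    def n_blocks(self) -> int:
        """Trend block plus one block per harmonic."""
        return 1 + self.n_harmonics

    def block_nvrs(self, overrides: Optional[Sequence[float]] = None) -> np.ndarray:
        """NVR per state block ``[trend, harmonic_1, ..., harmonic_R]``.

        ``overrides`` replaces the whole vector; otherwise values come from
        the TVP models and must all be set (not None).
        """
        if overrides is not None:
            v = np.asarray(overrides, dtype=float)
            if v.shape != (self.n_blocks,):
                raise SpecificationError(
                    f"expected {self.n_blocks} NVRs (trend first), got shape {v.shape}")
            if np.any(v < 0):
                raise SpecificationError("NVRs must be >= 0")
            return v
        vals = [self.trend.nvr] + [m.nvr for m in self.seasonal_models]
        if any(v is None for v in vals):
            raise SpecificationError(
                "NVRs unset in the spec; estimate them or pass overrides")
        return np.asarray(vals, dtype=float)


def default_spec(period: float = 1.0, n_harmonics: int = 2,
                 trend: str = "irw", seasonal: str = "rw") -> UCSpec:
    """Convenience constructor: IRW trend, RW harmonic coefficients with one
    independently estimated NVR per harmonic (standard DHR practice —
    harmonics usually vary at different rates), all hyperparameters free."""
    return UCSpec(
        trend=TVPModel(trend),
        seasonal=[TVPModel(seasonal) for _ in range(int(n_harmonics))],
        harmonics=make_harmonics(period, n_harmonics),
    )


# --------------------------------------------------------------------------
# system matrices
# --------------------------------------------------------------------------

def observation_vector(t: float, spec: UCSpec) -> np.ndarray:
    """Regression row ``h_t`` with ``h_t . state = T_t + S_t``.

    Trend entries first ([1] for RW, [1, 0] for IRW), then alternating
    cos(w_i t), sin(w_i t).
    """
    h = np.zeros(spec.state_dim)
    h[0] = 1.0
    w = spec.frequencies
    s0 = spec.trend_dim
    h[s0::2] = np.cos(w * t)
    h[s0 + 1::2] = np.sin(w * t)
    return h


def _observation_matrix(times: np.ndarray, spec: UCSpec) -> np.ndarray:
    n = times.size
    H = np.zeros((n, spec.state_dim))
    H[:, 0] = 1.0
    wt = np.outer(times, spec.frequencies)
    s0 = spec.trend_dim
    H[:, s0::2] = np.cos(wt)
    H[:, s0 + 1::2] = np.sin(wt)
    return H


def transition_system(delta_t: float, spec: UCSpec, nvrs, sigma2_e: float):
    """State transition and process covariance over a gap of ``delta_t`` years.

    Random-walk blocks are identity with variance ``nvr*sigma2_e*delta_t``;
    the IRW trend block is ``[[1, dt], [0, 1]]`` with the exact integrated
    Wiener covariance ``q*[[dt^3/3, dt^2/2], [dt^2/2, dt]]``,
    ``q = nvr*sigma2_e``.
    """
    if not (delta_t > 0):
        raise OrderingError(f"delta_t must be positive, got {delta_t}")
    nvrs = spec.block_nvrs(nvrs)
    F, Q = _transition_stack(np.asarray([delta_t], dtype=float), spec, nvrs, sigma2_e)
    return F[0], Q[0]


def _transition_stack(dts: np.ndarray, spec: UCSpec, nvrs: np.ndarray,
                      sigma2_e: float):
    """Vectorised transition/process-covariance matrices for all gaps."""
    m, d, s0 = dts.size, spec.state_dim, spec.trend_dim
    F = np.tile(np.eye(d), (m, 1, 1))
    Q = np.zeros((m, d, d))
    q_tr = nvrs[0] * sigma2_e
    if spec.trend.kind == INTEGRATED_RANDOM_WALK:
        F[:, 0, 1] = dts
        Q[:, 0, 0] = q_tr * dts ** 3 / 3.0
        Q[:, 0, 1] = Q[:, 1, 0] = q_tr * dts ** 2 / 2.0
        Q[:, 1, 1] = q_tr * dts
    else:
        Q[:, 0, 0] = q_tr * dts
    for i in range(spec.n_harmonics):
        q = nvrs[1 + i] * sigma2_e * dts
        Q[:, s0 + 2 * i, s0 + 2 * i] = q
        Q[:, s0 + 2 * i + 1, s0 + 2 * i + 1] = q
    return F, Q


# --------------------------------------------------------------------------
# filter / smoother
# --------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Output of the Kalman filter on the irregular grid."""

    times: np.ndarray
    observed: np.ndarray          # boolean mask of instants carrying data
    filtered_mean: np.ndarray     # (n, d) or (n, d, m)
    filtered_cov: np.ndarray      # (n, d, d)
    predicted_mean: np.ndarray
    predicted_cov: np.ndarray
    innovations: np.ndarray       # NaN at unobserved instants
    innovation_var: np.ndarray
    loglik: float
    spec: UCSpec = None
    nvrs: np.ndarray = None
    sigma2_e: float = None
    init_mean: np.ndarray = None
    init_var: float = None


@dataclass
class SmoothResult:
    times: np.ndarray
    mean: np.ndarray              # (n, d) or (n, d, m)
    cov: np.ndarray               # (n, d, d)


def _default_init(y: np.ndarray, spec: UCSpec, init_var=None):
    yv = y[np.isfinite(y)]
    scale = float(np.var(yv)) if yv.size else 1.0
    if scale <= 0:
        scale = max(float(np.max(np.abs(yv))) ** 2 if yv.size else 1.0, 1.0)
    if init_var is None:
        init_var = DIFFUSE_SCALE * scale
    m0 = np.zeros(spec.state_dim)
    if yv.size:
        m0[0] = yv[0]
    return m0, float(init_var), scale


def kalman_filter(series: IrregularSeries, spec: UCSpec, nvrs=None,
                  sigma2_e: float = None, init_mean=None,
                  init_var: float = None) -> FilterResult:
    """Run the predict/update recursion on the irregular sampling grid.

    Each predict step uses :func:`transition_system` with the actual
    inter-sample gap.  The log-likelihood comes from the prediction-error
    decomposition.  Initialisation is a diffuse prior (variance
    ``1e7 * var(y)`` unless ``init_var`` is given) with zero mean except
    the trend level, which starts at the first observation.  NaN values
    mark instants with no observation (prediction only).
    """
    times = np.asarray(series.times, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if sigma2_e is None:
        sigma2_e = spec.obs_noise_variance
    if sigma2_e is None or not (sigma2_e > 0):
        raise SpecificationError("sigma2_e must be a positive number")
    nvr_vec = spec.block_nvrs(nvrs)
    n_obs = int(np.sum(np.isfinite(y)))
    if n_obs < spec.state_dim:
        raise SpecificationError(
            f"need at least {spec.state_dim} observations, got {n_obs}")
    m0, p0, scale = _default_init(y, spec, init_var)
    if init_mean is not None:
        m0 = np.asarray(init_mean, dtype=float)
    return _filter(times, y[:, None], spec, nvr_vec, float(sigma2_e), m0[:, None],
                   p0, scale, squeeze=True)


def _filter(times, Y, spec, nvrs, sigma2_e, M0, p0, scale, squeeze) -> FilterResult:
    """Core recursion; ``Y`` is (n, m) with NaN rows marking missing data.

    The covariance recursion is independent of the data, so ``m`` parallel
    observation columns (used for the smoother influence-trace) share one
    covariance pass.
    """
    n, mcols = Y.shape
    d = spec.state_dim
    H = _observation_matrix(times, spec)
    dts = np.diff(times)
    if n > 1:
        if np.any(dts <= 0):
            raise OrderingError("times must be strictly increasing")
        Fs, Qs = _transition_stack(dts, spec, nvrs, sigma2_e)
    observed = np.all(np.isfinite(Y), axis=1)
    floor = INNOVATION_FLOOR * max(scale, np.finfo(float).tiny)

    M = M0.astype(float).copy()
    P = p0 * np.eye(d)
    fm = np.empty((n, d, mcols)); fP = np.empty((n, d, d))
    pm = np.empty((n, d, mcols)); pP = np.empty((n, d, d))
    innov = np.full((n, mcols), np.nan); ivar = np.full(n, np.nan)
    loglik = 0.0
    for k in range(n):
        if k > 0:
            M = Fs[k - 1] @ M
            P = Fs[k - 1] @ P @ Fs[k - 1].T + Qs[k - 1]
            P = 0.5 * (P + P.T)
        pm[k], pP[k] = M, P
        if observed[k]:
            h = H[k]
            f = float(h @ P @ h) + sigma2_e
            if not np.isfinite(f) or f <= 0:
                raise NumericalConditioningError(
                    f"singular innovation variance at t={times[k]:.6f}")
            f = max(f, floor)
            Ph = P @ h
            K = Ph / f
            nu = Y[k] - h @ M
            M = M + np.outer(K, nu)
            P = P - np.outer(K, Ph)
            P = 0.5 * (P + P.T)
            innov[k], ivar[k] = nu, f
            if mcols == 1:
                loglik += -0.5 * (np.log(2.0 * np.pi * f) + float(nu[0]) ** 2 / f)
        fm[k], fP[k] = M, P

    if squeeze and mcols == 1:
        fm, pm, innov = fm[..., 0], pm[..., 0], innov[:, 0]
    return FilterResult(
        times=times, observed=observed, filtered_mean=fm, filtered_cov=fP,
        predicted_mean=pm, predicted_cov=pP, innovations=innov,
        innovation_var=ivar, loglik=float(loglik), spec=spec, nvrs=nvrs,
        sigma2_e=sigma2_e, init_mean=M0[..., 0] if squeeze and mcols == 1 else M0,
        init_var=p0)


def fixed_interval_smooth(fr: FilterResult) -> SmoothResult:
    """Rauch–Tung–Striebel backward pass over the filter output.

    At the final instant smoothed = filtered; smoothed variances never
    exceed filtered variances.
    """
    fm = fr.filtered_mean
    squeeze = fm.ndim == 2
    if squeeze:
        fm = fm[..., None]
    pm = fr.predicted_mean if fr.predicted_mean.ndim == 3 else fr.predicted_mean[..., None]
    n, d, mcols = fm.shape
    dts = np.diff(fr.times)
    if n > 1:
        Fs, _ = _transition_stack(dts, fr.spec, fr.nvrs, fr.sigma2_e)
    sm = fm.copy(); sP = fr.filtered_cov.copy()
    for k in range(n - 2, -1, -1):
        Ppred = fr.predicted_cov[k + 1]
        B = Fs[k] @ fr.filtered_cov[k]          # F P_f  (P_f symmetric)
        try:
            C = np.linalg.solve(Ppred, B).T      # P_f F' Ppred^-1
        except np.linalg.LinAlgError:
            C = (np.linalg.pinv(Ppred) @ B).T
        sm[k] = fm[k] + C @ (sm[k + 1] - pm[k + 1])
        sP[k] = fr.filtered_cov[k] + C @ (sP[k + 1] - fr.predicted_cov[k + 1]) @ C.T
        sP[k] = 0.5 * (sP[k] + sP[k].T)
    if squeeze:
        sm = sm[..., 0]
    return SmoothResult(times=fr.times, mean=sm, cov=sP)


# --------------------------------------------------------------------------
# hyperparameter estimation
# --------------------------------------------------------------------------

@dataclass
class HyperparameterEstimate:
    nvrs: np.ndarray              # per block, trend first
    sigma2_e: float
    loglik: float
    converged: bool
    n_starts: int
    message: str = ""


_NVR_GRID = (1e-4, 1e-2, 1.0)


def _free_parameter_layout(spec: UCSpec):
    """Indices of free NVR blocks plus whether sigma2_e is free."""
    free_blocks = []
    if spec.trend.nvr is None:
        free_blocks.append(0)
    if spec.shared_seasonal:
        if spec.seasonal.nvr is None:
            free_blocks.append("seasonal_shared")
    else:
        for i, m in enumerate(spec.seasonal_models):
            if m.nvr is None:
                free_blocks.append(1 + i)
    return free_blocks, spec.obs_noise_variance is None


def _assemble(theta, spec, free_blocks, sigma_free):
    nvrs = np.empty(spec.n_blocks)
    nvrs[0] = spec.trend.nvr if spec.trend.nvr is not None else 0.0
    for i, m in enumerate(spec.seasonal_models):
        nvrs[1 + i] = m.nvr if m.nvr is not None else 0.0
    j = 0
    for fb in free_blocks:
        v = np.exp(theta[j]); j += 1
        if fb == "seasonal_shared":
            nvrs[1:] = v
        else:
            nvrs[fb] = v
    sigma2 = np.exp(theta[j]) if sigma_free else float(spec.obs_noise_variance)
    return nvrs, sigma2


def estimate_hyperparameters(series: IrregularSeries, spec: UCSpec,
                             n_polish: int = 3) -> HyperparameterEstimate:
    """Maximise the prediction-error log-likelihood over the free parameters.

    Free parameters are every NVR left as None in ``spec`` (one shared
    parameter when the seasonal TVP model is shared) and, if unset, the
    observation-noise variance.  The search works on natural logs: a grid
    of starts (``{1e-4, 1e-2, 1}`` per NVR) is scored, the best
    ``n_polish`` are refined by Nelder-Mead (the profile is near-flat and
    kinked where an NVR hits its boundary, which defeats gradient-based
    polish), and the best point seen anywhere — grid or polish — is
    returned, so the optimum is never worse than any grid start.
    """
    if len(series) < 24:
        logger.warning("HYPERPARAM_SMALL_N n=%d observations (< 24 recommended)",
                       len(series))
    free_blocks, sigma_free = _free_parameter_layout(spec)
    n_free = len(free_blocks) + int(sigma_free)
    vy = float(np.var(series.values))
    if vy <= 0:
        vy = 1.0
    if n_free == 0:
        fr = kalman_filter(series, spec, spec.block_nvrs())
        return HyperparameterEstimate(spec.block_nvrs(), float(spec.obs_noise_variance),
                                      fr.loglik, True, 0, "nothing to estimate")

    _PENALTY = 1e12

    def nll(theta):
        if np.any(theta < -60) or np.any(theta > 60):
            return _PENALTY
        nvrs, sigma2 = _assemble(theta, spec, free_blocks, sigma_free)
        try:
            fr = kalman_filter(series, spec, nvrs, sigma2)
        except (NumericalConditioningError, FloatingPointError):
            return _PENALTY
        return -fr.loglik if np.isfinite(fr.loglik) else _PENALTY

    # grid of starts
    grids = [np.log(np.asarray(_NVR_GRID)) for _ in free_blocks]
    if sigma_free:
        grids.append(np.log(np.asarray([0.3 * vy])))
    starts = np.array(np.meshgrid(*grids, indexing="ij")).reshape(n_free, -1).T
    scores = np.array([nll(th) for th in starts])
    order = np.argsort(scores)

    best_theta, best_val = starts[order[0]], scores[order[0]]
    any_ok = best_val < _PENALTY
    messages = []
    for idx in order[:n_polish]:
        if scores[idx] >= _PENALTY:
            continue
        # Nelder-Mead: robust on the flat, kinked profiles typical of
        # boundary NVRs; bounds enforced through the penalty in nll.
        res = optimize.minimize(nll, starts[idx], method="Nelder-Mead",
                                options={"maxiter": 400 * n_free,
                                         "xatol": 1e-4, "fatol": 1e-7})
        messages.append(str(res.message))
        if res.fun < best_val:
            best_theta, best_val = res.x, res.fun
            any_ok = True
    if not any_ok or not np.isfinite(best_val) or best_val >= _PENALTY:
        nvrs, sigma2 = _assemble(best_theta, spec, free_blocks, sigma_free)
        raise EstimationError("hyperparameter search failed to find a finite "
                              "likelihood", best=(nvrs, sigma2))
    nvrs, sigma2 = _assemble(best_theta, spec, free_blocks, sigma_free)
    return HyperparameterEstimate(nvrs, float(sigma2), float(-best_val), True,
                                  len(starts), "; ".join(messages))


# --------------------------------------------------------------------------
# fitting and diagnostics
# --------------------------------------------------------------------------

@dataclass
class ASDHRFit:
    """Smoothed decomposition of an irregular series with fit statistics."""

    spec: UCSpec
    times: np.ndarray
    values: np.ndarray
    trend: np.ndarray
    trend_var: np.ndarray
    seasonal: np.ndarray
    seasonal_var: np.ndarray
    a: np.ndarray                 # (n, R) smoothed cos coefficients
    b: np.ndarray                 # (n, R) smoothed sin coefficients
    a_var: np.ndarray
    b_var: np.ndarray
    fitted: np.ndarray
    fitted_var: np.ndarray
    resid: np.ndarray
    nvrs: np.ndarray              # per block, trend first
    sigma2_e: float
    loglik: float
    r_squared: float
    f_statistic: float
    f_pvalue: float
    effective_dof: float
    init_mean: np.ndarray
    init_var: float
    smoothed_mean: np.ndarray
    smoothed_cov: np.ndarray
    label: str = ""

    def summary(self) -> dict:
        return {
            "n": int(self.times.size),
            "nvr_trend": float(self.nvrs[0]),
            "nvr_seasonal": [float(v) for v in self.nvrs[1:]],
            "sigma2_e": float(self.sigma2_e),
            "loglik": float(self.loglik),
            "r_squared": float(self.r_squared),
            "f_statistic": float(self.f_statistic),
            "f_pvalue": float(self.f_pvalue),
            "effective_dof": float(self.effective_dof),
        }


def _components(times, spec, sm: SmoothResult, y):
    H = _observation_matrix(times, spec)
    s0 = spec.trend_dim
    mean, cov = sm.mean, sm.cov
    trend = mean[:, 0]
    trend_var = cov[:, 0, 0]
    Hs = H[:, s0:]
    seasonal = np.einsum("nd,nd->n", Hs, mean[:, s0:])
    seasonal_var = np.einsum("ni,nij,nj->n", Hs, cov[:, s0:, s0:], Hs)
    fitted = trend + seasonal if spec.trend_dim >= 1 else seasonal
    fitted_var = np.einsum("ni,nij,nj->n", H, cov, H)
    R = spec.n_harmonics
    a = mean[:, s0::2]; b = mean[:, s0 + 1::2]
    a_var = cov[:, range(s0, s0 + 2 * R, 2), range(s0, s0 + 2 * R, 2)]
    b_var = cov[:, range(s0 + 1, s0 + 2 * R, 2), range(s0 + 1, s0 + 2 * R, 2)]
    return trend, trend_var, seasonal, seasonal_var, a, b, a_var, b_var, fitted, fitted_var


def _influence_trace(times, spec, nvrs, sigma2_e, init_var, scale) -> float:
    """Trace of the linear smoother map y -> y_hat (effective model dof).

    The map is exactly linear (the trend-level initialisation is itself
    linear in y), so the trace is obtained by pushing the identity matrix
    through one shared covariance recursion.
    """
    n = times.size
    M0 = np.zeros((spec.state_dim, n))
    M0[0, 0] = 1.0                      # trend level starts at the first obs
    fr = _filter(times, np.eye(n), spec, nvrs, sigma2_e, M0, init_var, scale,
                 squeeze=False)
    sm = fixed_interval_smooth(fr)
    H = _observation_matrix(times, spec)
    # y_hat matrix A: A[k, :] = h_k . M_s[k]; need only the diagonal
    diag = np.einsum("kd,kdk->k", H, sm.mean)
    return float(np.sum(diag))


def goodness_of_fit(fit: ASDHRFit):
    """R², ANOVA-style F test and effective degrees of freedom.

    ``r_squared = 1 - SSE/SST``.  The effective model dof ``p*`` is the
    trace of the smoother influence map y -> y_hat at the fitted
    hyperparameters; with all NVRs zero it reduces to the regressor count
    and the F test coincides with the classical harmonic-regression ANOVA:
    ``F = [(SST - SSE)/(p*-1)] / [SSE/(n-p*)]`` on ``(p*-1, n-p*)`` dof.
    """
    y = fit.values
    n = y.size
    sse = float(np.sum(fit.resid ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    scale = float(np.var(y)) if np.var(y) > 0 else 1.0
    pstar = _influence_trace(fit.times, fit.spec, fit.nvrs, fit.sigma2_e,
                             fit.init_var, scale)
    if n <= pstar:
        raise UnderdeterminedFitError(
            f"effective dof {pstar:.2f} >= n = {n}; fit is underdetermined")
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    if sse <= 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = ((sst - sse) / (pstar - 1.0)) / (sse / (n - pstar))
        f_stat = max(f_stat, 0.0)
        f_p = float(stats.f.sf(f_stat, pstar - 1.0, n - pstar))
    return r2, float(f_stat), f_p, float(pstar)


def fit_asdhr(series: IrregularSeries, spec: UCSpec = None) -> ASDHRFit:
    """Estimate hyperparameters, filter, smooth and assemble the decomposition.

    Components satisfy ``fitted = trend + seasonal`` exactly at every
    sample instant, and ``resid = y - fitted``.  When the observation
    noise variance is estimated, the maximum-likelihood value (which
    divides by n) is rescaled by ``n / (n - p*)`` with ``p*`` the
    effective model dof — the standard residual-dof correction — before
    the reported variances and bands are formed; fitted values, gains,
    R² and F are invariant to this rescaling because NVRs are ratios.
    """
    if spec is None:
        spec = default_spec()
    est = estimate_hyperparameters(series, spec)
    fr = kalman_filter(series, spec, est.nvrs, est.sigma2_e)
    sm = fixed_interval_smooth(fr)
    (trend, trend_var, seasonal, seasonal_var, a, b, a_var, b_var,
     fitted, fitted_var) = _components(series.times, spec, sm, series.values)
    resid = series.values - fitted
    fit = ASDHRFit(
        spec=spec, times=series.times, values=series.values,
        trend=trend, trend_var=trend_var, seasonal=seasonal,
        seasonal_var=seasonal_var, a=a, b=b, a_var=a_var, b_var=b_var,
        fitted=fitted, fitted_var=fitted_var, resid=resid,
        nvrs=est.nvrs, sigma2_e=est.sigma2_e, loglik=fr.loglik,
        r_squared=np.nan, f_statistic=np.nan, f_pvalue=np.nan,
        effective_dof=np.nan, init_mean=fr.init_mean, init_var=fr.init_var,
        smoothed_mean=sm.mean, smoothed_cov=sm.cov, label=series.label)
    fit.r_squared, fit.f_statistic, fit.f_pvalue, fit.effective_dof = goodness_of_fit(fit)
    if spec.obs_noise_variance is None:
        n = len(series)
        factor = n / (n - fit.effective_dof)
        fit.sigma2_e *= factor
        for name in ("trend_var", "seasonal_var", "a_var", "b_var",
                     "fitted_var", "smoothed_cov"):
            setattr(fit, name, getattr(fit, name) * factor)
        fit.init_var *= factor
    return fit


@dataclass
class ConfidenceBand:
    level: float
    fitted_lower: np.ndarray
    fitted_upper: np.ndarray
    seasonal_lower: np.ndarray
    seasonal_upper: np.ndarray


def confidence_band(fit: ASDHRFit, level: float = 0.95) -> ConfidenceBand:
    """Pointwise Gaussian bands for the fitted signal and the seasonal part."""
    if not (0.0 < level < 1.0):
        raise SpecificationError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    se_f = np.sqrt(np.maximum(fit.fitted_var, 0.0))
    se_s = np.sqrt(np.maximum(fit.seasonal_var, 0.0))
    return ConfidenceBand(level,
                          fit.fitted - z * se_f, fit.fitted + z * se_f,
                          fit.seasonal - z * se_s, fit.seasonal + z * se_s)


@dataclass
class Prediction:
    times: np.ndarray
    trend: np.ndarray
    trend_var: np.ndarray
    seasonal: np.ndarray
    seasonal_var: np.ndarray
    mean: np.ndarray
    var: np.ndarray


def predict_at(fit: ASDHRFit, new_times) -> Prediction:
    """Smoothed T, S and y at arbitrary instants.

    New instants are inserted into the grid as missing observations and
    the filter/smoother re-run with the fitted hyperparameters; at the
    original sample instants the result equals the stored decomposition.
    """
    new_times = np.atleast_1d(np.asarray(new_times, dtype=float))
    if not np.all(np.isfinite(new_times)):
        raise OrderingError("new_times must be finite")
    all_t = np.unique(np.concatenate([fit.times, new_times]))
    y_all = np.full(all_t.size, np.nan)
    y_all[np.searchsorted(all_t, fit.times)] = fit.values
    scale = float(np.var(fit.values)) if np.var(fit.values) > 0 else 1.0
    fr = _filter(all_t, y_all[:, None], fit.spec, fit.nvrs, fit.sigma2_e,
                 np.asarray(fit.init_mean, dtype=float)[:, None],
                 fit.init_var, scale, squeeze=True)
    sm = fixed_interval_smooth(fr)
    comp = _components(all_t, fit.spec, sm, y_all)
    trend, trend_var, seasonal, seasonal_var = comp[0], comp[1], comp[2], comp[3]
    fitted, fitted_var = comp[8], comp[9]
    idx = np.searchsorted(all_t, new_times)
    return Prediction(new_times, trend[idx], trend_var[idx], seasonal[idx],
                      seasonal_var[idx], fitted[idx], fitted_var[idx])


def fit_to_frame(fit: ASDHRFit, level: float = 0.95):
    """Tabular export: date, y, trend, seasonal, fitted, resid and bands."""
    import pandas as pd

    from .series import from_decimal_year
    band = confidence_band(fit, level)
    pct = f"{level * 100:g}"
    return pd.DataFrame({
        "date": from_decimal_year(fit.times).strftime("%Y-%m-%d"),
        "y": fit.values,
        "trend": fit.trend,
        "seasonal": fit.seasonal,
        "fitted": fit.fitted,
        "resid": fit.resid,
        f"fitted_lo{pct}": band.fitted_lower,
        f"fitted_hi{pct}": band.fitted_upper,
    })
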
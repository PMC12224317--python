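"""Exponential fitting of stopped-flow traces and rate-constant extraction.

Single-phase traces (O2 reactions) are fit to

    Y = dA * exp(-k_obs * t) + A_inf

and biphasic traces (CytC reactions, two sequential one-electron transfers)
to

    Y = dA1 * exp(-k_obs1 * t) + dA2 * exp(-k_obs2 * t) + A_inf

with the convention k_obs1 > k_obs2 (phase 1 is the faster phase).  Observed
rate constants regressed linearly against oxidant concentration give the
bimolecular constant k_ox as the slope.

The module also quantifies the bias the pseudo-first-order approximation
incurs when the oxidant is in limited excess: simulating exact second-order
traces and pushing them through the same fit-and-regress pipeline shows the
regressed slope underestimates the true bimolecular constant at low
oxidant/enzyme ratios, vanishing as the excess grows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .kinetic_core import (
    KineticScheme,
    MixState,
    SpectralModel,
    Trace,
    absorbance_trace,
    simulate_mechanism,
)

__all__ = [
    "Trace",
    "FitResult",
    "BimolecularFit",
    "FitError",
    "fit_exponential",
    "select_phase_count",
    "fit_bimolecular",
    "pseudo_first_order_bias",
]


class FitError(RuntimeError):
    """Raised when a fit cannot be attempted or every attempt failed."""


@dataclass
class FitResult:
    """Parameters of a single- or double-exponential least-squares fit.

    ``amplitudes`` and ``k_obs`` are parallel tuples ordered fastest phase
    first; ``k_obs[0] > k_obs[1]`` when two phases are present.
    """

    n_phases: int
    amplitudes: tuple[float, ...]
    k_obs: tuple[float, ...]
    a_inf: float
    residual_norm: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.n_phases not in (1, 2):
            raise ValueError("n_phases must be 1 or 2")
        if len(self.amplitudes) != self.n_phases or len(self.k_obs) != self.n_phases:
            raise ValueError("amplitudes/k_obs length must match n_phases")

    @property
    def dA(self) -> float:
        return self.amplitudes[0]

    @property
    def noise_estimate(self) -> float:
        # residual standard deviation with dof correction
        return self.residual_norm  # set by fit_exponential as residual std


def _model(t: np.ndarray, params: np.ndarray, n_phases: int) -> np.ndarray:
    # log-rates are clipped so pathological steps cannot overflow exp()
    if n_phases == 1:
        dA, logk, a_inf = params
        return dA * np.exp(-np.exp(np.clip(logk, -200, 200)) * t) + a_inf
    dA1, logk1, dA2, logk2, a_inf = params
    return (dA1 * np.exp(-np.exp(np.clip(logk1, -200, 200)) * t)
            + dA2 * np.exp(-np.exp(np.clip(logk2, -200, 200)) * t) + a_inf)


def _single_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Crude (dA, k, a_inf) from endpoint and a log-linear rate estimate."""
    a_inf = float(y[-1])
    dA = float(y[0] - a_inf)
    span = t[-1] - t[0]
    k = 1.0 / max(span / 5.0, 1e-30)
    resid = y - a_inf
    mask = np.abs(resid) > 0.05 * max(abs(dA), 1e-30)
    if mask.sum() >= 3 and dA != 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.log(np.abs(resid[mask] / dA))
        tt = t[mask]
        ok = np.isfinite(logr)
        if ok.sum() >= 3:
            slope, _, _, _, _ = stats.linregress(tt[ok], logr[ok])
            if slope < 0:
                k = -float(slope)
    return dA, k, a_inf


def _peel_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Initialize a biphasic fit by peeling the slow tail off the trace."""
    n = len(t)
    tail = slice(int(0.6 * n), n)
    dA2, k2, a_inf = _single_guess(t[tail], y[tail])
    resid = y - (dA2 * np.exp(-k2 * t) + a_inf)
    head = slice(0, max(int(0.5 * n), 8))
    dA1, k1, _ = _single_guess(t[head], resid[head] + 0.0)
    if k1 <= k2:
        k1 = 10.0 * k2
    return dA1, k1, dA2, k2, a_inf


def _biphasic_starts(t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Multistart grid for the biexponential fit.

    Anchored on a single-exponential fit of the whole trace (whose rate is a
    mixture of the two true rates) with log-spaced fast/slow rate splits
    around it, plus a tail-peeling start.
    """
    dA, k, a_inf = _single_guess(t, y)
    try:
        res = least_squares(
            lambda p: _model(t, p, 1) - y,
            np.array([dA, math.log(k), a_inf]),
            method="lm", max_nfev=5000,
        )
        if np.all(np.isfinite(res.x)) and abs(res.x[1]) < 200:
            dA, k, a_inf = res.x[0], float(np.exp(res.x[1])), res.x[2]
    except Exception:
        pass
    starts = []
    for f_fast, f_slow in ((3, 1), (10, 1), (30, 1), (100, 1),
                           (3, 0.3), (10, 0.3), (30, 0.1)):
        starts.append(np.array([dA / 2, math.log(k * f_fast),
                                dA / 2, math.log(k * f_slow), a_inf]))
    dA1, k1, dA2, k2, a_inf2 = _peel_guess(t, y)
    starts.append(np.array([dA1, math.log(k1), dA2, math.log(k2), a_inf2]))
    return starts


def fit_exponential(trace: Trace, n_phases: int) -> FitResult:
    """Least-squares fit of one or two exponential phases plus an endpoint.

    Initialization uses tail-peeling plus a log-spaced multistart on the
    rates; rates are optimized on a log scale so they stay positive.  On
    noiseless synthetic data the recovery is exact to <=1e-6 relative.
    Non-convergence is reported in the returned ``converged`` flag (and a
    warning), never silently.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t = trace.time
    y = trace.absorbance
    n_params = 3 if n_phases == 1 else 5
    if len(t) < n_params + 2:
        raise FitError(
            f"trace has {len(t)} points; need at least {n_params + 2} "
            f"for a {n_phases}-phase fit"
        )

    starts: list[np.ndarray] = []
    if n_phases == 1:
        dA, k, a_inf = _single_guess(t, y)
        for f in (0.04, 0.2, 1.0, 5.0, 25.0):
            starts.append(np.array([dA, math.log(k * f), a_inf]))
    else:
        starts = _biphasic_starts(t, y)

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda p: _model(t, p, n_phases) - y,
                x0,
                method="lm",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=20000,
            )
        except Exception:
            continue
        if not (np.all(np.isfinite(res.x)) and np.isfinite(res.cost)):
            continue
        # a rate clipped at the parameterization boundary is degenerate
        if np.any(np.abs(res.x[1::2][: n_phases]) >= 200):
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        warnings.warn("exponential fit failed to converge from every start")
        return FitResult(n_phases, (math.nan,) * n_phases, (math.nan,) * n_phases,
                         math.nan, math.nan, converged=False,
                         message="no start converged")

    p = best.x
    dof = max(len(t) - n_params, 1)
    resid_std = float(np.sqrt(2 * best.cost / dof))
    if n_phases == 1:
        amps = (float(p[0]),)
        ks = (float(np.exp(p[1])),)
    else:
        pairs = sorted(
            [(float(np.exp(p[1])), float(p[0])), (float(np.exp(p[3])), float(p[2]))],
            key=lambda kv: -kv[0],
        )
        ks = (pairs[0][0], pairs[1][0])
        amps = (pairs[0][1], pairs[1][1])
    converged = bool(best.status > 0)
    if not converged:
        warnings.warn(f"exponential fit did not converge: {best.status}")
    return FitResult(n_phases, amps, ks, float(p[-1]), resid_std,
                     converged=converged, message=str(best.status))


def _aicc(rss: float, n: int, p: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * p
    denom = n - p - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * p * (p + 1) / denom


def select_phase_count(trace: Trace, ic_margin: float = 10.0,
                       amplitude_floor_sigma: float = 3.0) -> int:
    """Choose one vs two exponential phases for a trace.

    Returns 2 only if the two-phase fit improves the small-sample corrected
    information criterion by more than ``ic_margin`` AND both fitted
    amplitudes exceed ``amplitude_floor_sigma`` times the residual noise of
    the two-phase fit; otherwise 1.  Slow cross-species CytC reactions, for
    example, display only a single exponential.
    """
    results = {}
    errors = {}
    for n in (1, 2):
        try:
            r = fit_exponential(trace, n)
            if r.converged:
                results[n] = r
            else:
                errors[n] = r.message
        except FitError as exc:
            errors[n] = str(exc)
    if not results:
        raise FitError(f"both fits failed: {errors}")
    if 2 not in results:
        return 1
    if 1 not in results:
        return 2
    # a single phase that already explains the trace to numerical precision
    # leaves nothing for a second phase to model
    scale = float(np.ptp(trace.absorbance))
    if results[1].residual_norm <= max(1e-10 * scale, 1e-14):
        return 1
    n_pts = len(trace)
    rss1 = results[1].residual_norm ** 2 * max(n_pts - 3, 1)
    rss2 = results[2].residual_norm ** 2 * max(n_pts - 5, 1)
    delta = _aicc(rss1, n_pts, 3) - _aicc(rss2, n_pts, 5)
    noise = results[2].residual_norm
    floor = amplitude_floor_sigma * noise
    amps_ok = all(abs(a) > floor for a in results[2].amplitudes)
    return 2 if (delta > ic_margin and amps_ok) else 1


@dataclass
class BimolecularFit:
    """Ordinary least-squares line through (oxidant concentration, k_obs).

    The slope is the bimolecular rate constant k_ox (M^-1 s^-1); the
    intercept (s^-1) is retained rather than forced through zero.
    """

    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def k_ox(self) -> float:
        return self.slope


def fit_bimolecular(points: list[tuple[float, float]]) -> BimolecularFit:
    """OLS regression of k_obs against oxidant concentration."""
    if len(points) < 2:
        raise ValueError("need at least 2 (concentration, k_obs) points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all oxidant concentrations are identical")
    res = stats.linregress(x, y)
    return BimolecularFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=float(res.stderr) if np.isfinite(res.stderr) else math.nan,
        intercept_stderr=(float(res.intercept_stderr)
                          if np.isfinite(res.intercept_stderr) else math.nan),
        points=list(points),
    )


def _cytc_time_grid(scheme: KineticScheme, conc: float, n: int = 400) -> np.ndarray:
    k_slow = scheme.k2f if scheme.k2f > 0 else scheme.k1f
    t_end = 10.0 / (k_slow * conc)
    grid = np.geomspace(t_end * 1e-5, t_end, n - 1)
    return np.concatenate([[0.0], grid])


def pseudo_first_order_bias(
    scheme: KineticScheme,
    enzyme_conc: float,
    oxidant_concs: list[float],
    spec: SpectralModel | None = None,
) -> float:
    """Relative bias of the regressed slope under limited oxidant excess.

    Simulates exact second-order CytC traces at the given post-mix
    concentrations, fits each to the biexponential model, regresses the
    fast-phase k_obs against concentration, and returns
    ``(slope - k1f) / k1f``.  Negative values mean the pipeline
    underestimates the true bimolecular constant, which is the expected
    outcome whenever the oxidant is not in overwhelming excess.
    """
    if any(c <= 0 for c in oxidant_concs):
        raise ValueError("oxidant concentrations must be positive")
    if scheme.k1f <= 0:
        raise ValueError("scheme must have k1f > 0")
    if spec is None:
        spec = SpectralModel()
    points = []
    for conc in sorted(oxidant_concs):
        init = MixState(e_flh2=enzyme_conc, c_ox=conc)
        traj = simulate_mechanism(scheme, init, _cytc_time_grid(scheme, conc))
        trace = absorbance_trace(traj, spec, 550)
        fit = fit_exponential(trace, 2)
        if not fit.converged:
            raise FitError(f"biexponential fit failed at [CytC]={conc}")
        points.append((conc, fit.k_obs[0]))
    slope = fit_bimolecular(points).slope
    return (slope - scheme.k1f) / scheme.k1f
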
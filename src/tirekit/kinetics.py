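"""Sensorgram analysis: Langmuir monolayer kinetics and affinity inference.

Binding of an analyte at concentration C to a monolayer of independent
surface sites obeys

    d(theta)/dt = ka * C * (1 - theta) - kd * theta

whose solution from theta(0) = 0 is a single exponential with relaxation
time tau = 1/(ka*C + kd) and equilibrium occupancy theta_eq = C/(C + K_D),
K_D = kd/ka. The measured sensorgram — Psi at a fixed wavelength (700 nm)
versus time — therefore decays exponentially while the layer compacts;
fitting tau at several concentrations and regressing 1/tau on C yields the
association rate ka (slope), dissociation rate kd (intercept) and the
affinity constant K_D = kd/ka.

At high concentration the specific decay is followed by a slow rise from
non-specific adsorption on top of the saturated layer; traces are first
segmented so that tau is fitted on the specific (pre-minimum) phase only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticTrace",
    "CoverageState",
    "ExpDecayFit",
    "AffinityResult",
    "KineticFitError",
    "langmuir_coverage",
    "segment_biphasic",
    "fit_exponential",
    "estimate_affinity",
]


class KineticFitError(RuntimeError):
    """The trace has no usable exponential-decay segment."""


@dataclass(frozen=True)
class KineticTrace:
    """Psi(t) sensorgram at one analyte concentration.

    times in seconds, strictly increasing from 0; psi in degrees;
    concentration in molar.
    """

    times: np.ndarray
    psi: np.ndarray
    concentration_m: float
    wavelength_nm: float = 700.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.psi, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size < 10:
            raise ValueError("trace needs >= 10 equal-length time/psi samples")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at >= 0")
        if not np.isfinite(y).all():
            raise ValueError("psi must be finite")
        if not (np.isfinite(self.concentration_m) and self.concentration_m >= 0):
            raise ValueError("concentration must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "psi", y)


@dataclass(frozen=True)
class CoverageState:
    """Fractional occupancy of the binding sites, 0 <= theta <= 1."""

    theta: float | np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.theta)
        if np.any(th < -1e-12) or np.any(th > 1 + 1e-12):
            raise ValueError("theta must lie in [0, 1]")


@dataclass(frozen=True)
class ExpDecayFit:
    """Result of fitting psi(t) = baseline + amplitude * exp(-t/tau)."""

    tau_s: float
    tau_se_s: float
    amplitude_deg: float
    baseline_deg: float
    window_s: tuple[float, float]
    residual_rms_deg: float
    biphasic: bool

    def __post_init__(self) -> None:
        if not self.tau_s > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class AffinityResult:
    """ka, kd and K_D = kd/ka from the 1/tau vs C regression."""

    ka: float          # M^-1 s^-1 (slope)
    kd: float          # s^-1 (intercept)
    KD: float          # M
    ka_se: float
    kd_se: float
    KD_se: float
    r_squared: float
    table: pd.DataFrame          # columns: concentration_m, tau_s, inv_tau
    non_identifiable: bool = False


def langmuir_coverage(concentration_m, ka: float, kd: float, t) -> CoverageState:
    """Closed-form occupancy theta(t) = theta_eq * (1 - exp(-t/tau)).

    theta_eq = C/(C + kd/ka) and tau = 1/(ka*C + kd); the solution of the
    monolayer rate equation starting from an empty surface. ``t`` may be an
    array.
    """
    if not (ka > 0 and kd > 0):
        raise ValueError("rate constants ka and kd must be positive")
    c = np.asarray(concentration_m, dtype=float)
    tt = np.asarray(t, dtype=float)
    if np.any(c < 0) or np.any(tt < 0):
        raise ValueError("concentration and time must be >= 0")
    theta_eq = c / (c + kd / ka)
    rate = ka * c + kd
    theta = theta_eq * (1.0 - np.exp(-rate * tt))
    if np.ndim(concentration_m) == 0 and np.ndim(t) == 0:
        return CoverageState(float(theta))
    return CoverageState(theta)


def segment_biphasic(
    trace: KineticTrace,
    smooth_window: int = 5,
    position_fraction: float = 0.8,
    rise_factor: float = 3.0,
) -> tuple[tuple[float, float], Optional[tuple[float, float]]]:
    """Split a decay-then-rise sensorgram into its two phases.

    The trace is smoothed with a centred moving average (``smooth_window``
    samples) and the global minimum located. If the minimum falls before
    ``position_fraction`` of the record and the net rise after it exceeds
    ``rise_factor`` times the residual RMS (raw minus smoothed), the trace
    is biphasic and both (t_start, t_end) windows are returned; otherwise
    the whole record is the decay window and the rise window is None.
    """
    t, y = trace.times, trace.psi
    smoothed = (
        pd.Series(y).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    rms = float(np.sqrt(np.mean((y - smoothed) ** 2)))
    imin = int(np.argmin(smoothed))
    full = (float(t[0]), float(t[-1]))
    net_rise = smoothed[-1] - smoothed[imin]
    if imin > 0 and t[imin] < position_fraction * t[-1] and net_rise > rise_factor * rms:
        return (float(t[0]), float(t[imin])), (float(t[imin]), float(t[-1]))
    return full, None


def _exp_model(t, baseline, amplitude, tau):
    return baseline + amplitude * np.exp(-t / tau)


def fit_exponential(trace: KineticTrace, **segment_kwargs) -> ExpDecayFit:
    """Fit the specific-binding decay psi(t) = baseline + A * exp(-t/tau).

    The decay window comes from :func:`segment_biphasic` so that a
    non-specific rising tail never contaminates tau. Initial guesses are
    taken from a log-linearized regression; the refined fit is unweighted
    least squares on the raw samples, with the tau standard error from the
    local curvature of the objective.

    Raises :class:`KineticFitError` when the window holds no significant
    monotone decay (flat or rising trace).
    """
    (t0, t1), rise = segment_biphasic(trace, **segment_kwargs)
    sel = (trace.times >= t0) & (trace.times <= t1)
    t = trace.times[sel]
    y = trace.psi[sel]
    if t.size < 10:
        raise KineticFitError(
            f"decay segment has {t.size} samples (< 10); "
            "trace rises from the start or is too short"
        )
    # net drop estimated from endpoint segment means so that sample noise
    # does not mask a shallow decay; noise scale from first differences
    # (robust to the slow trend)
    m = max(5, t.size // 20)
    drop = float(np.mean(y[:m]) - np.mean(y[-m:]))
    noise = float(np.std(np.diff(y)) / np.sqrt(2.0))
    drop_se = noise * np.sqrt(2.0 / m)
    if drop <= 3.0 * drop_se or drop <= 0:
        raise KineticFitError(
            f"no significant decay: net drop {drop:.4g} deg vs its noise {drop_se:.4g} deg"
        )

    # log-linearized initial guess with the baseline pinned just below the minimum
    b0 = float(np.min(y)) - 0.05 * float(np.ptp(y)) - 1e-12
    z = np.log(y - b0)
    slope, intercept = np.polyfit(t - t[0], z, 1)
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    a0 = float(np.exp(intercept))

    dt_min = float(np.min(np.diff(t)))
    popt, pcov = curve_fit(
        _exp_model,
        t - t[0],
        y,
        p0=(b0, a0, tau0),
        bounds=([-np.inf, 0.0, dt_min * 1e-3], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    baseline, amplitude, tau = popt
    resid = y - _exp_model(t - t[0], *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    tau_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return ExpDecayFit(
        tau_s=float(tau),
        tau_se_s=tau_se,
        amplitude_deg=float(amplitude),
        baseline_deg=float(baseline),
        window_s=(float(t[0]), float(t[-1])),
        residual_rms_deg=rms,
        biphasic=rise is not None,
    )


def estimate_affinity(fits: Sequence[tuple[float, ExpDecayFit]]) -> AffinityResult:
    """Ordinary least-squares regression of 1/tau on concentration.

    Slope -> ka, intercept -> kd, K_D = kd/ka with its standard error by
    first-order (delta-method) propagation using the full slope/intercept
    covariance. A non-positive slope or intercept makes K_D meaningless;
    the result is then flagged ``non_identifiable`` rather than clamped,
    because clamping would silently bias K_D.
    """
    if len(fits) < 2:
        raise ValueError("need tau fits at >= 2 concentrations")
    c = np.array([f[0] for f in fits], dtype=float)
    tau = np.array([f[1].tau_s for f in fits], dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    inv_tau = 1.0 / tau

    n = c.size
    xbar, ybar = c.mean(), inv_tau.mean()
    sxx = float(np.sum((c - xbar) ** 2))
    sxy = float(np.sum((c - xbar) * (inv_tau - ybar)))
    ka = sxy / sxx
    kd = ybar - ka * xbar
    resid = inv_tau - (ka * c + kd)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((inv_tau - ybar) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    dof = n - 2
    s2 = ss_res / dof if dof > 0 else 0.0
    var_ka = s2 / sxx
    var_kd = s2 * (1.0 / n + xbar**2 / sxx)
    cov_ka_kd = -s2 * xbar / sxx

    non_identifiable = not (ka > 0 and kd > 0)
    KD = kd / ka if ka != 0 else float("nan")
    if ka != 0:
        g = np.array([-kd / ka**2, 1.0 / ka])  # d(KD)/d(ka, kd)
        cov = np.array([[var_ka, cov_ka_kd], [cov_ka_kd, var_kd]])
        KD_var = float(g @ cov @ g)
        KD_se = math.sqrt(KD_var) if KD_var >= 0 else float("nan")
    else:
        KD_se = float("nan")

    table = pd.DataFrame(
        {"concentration_m": c, "tau_s": tau, "inv_tau": inv_tau}
    ).sort_values("concentration_m", ignore_index=True)
    return AffinityResult(
        ka=ka,
        kd=kd,
        KD=KD,
        ka_se=math.sqrt(var_ka),
        kd_se=math.sqrt(var_kd),
        KD_se=KD_se,
        r_squared=r_squared,
        table=table,
        non_identifiable=non_identifiable,
    )
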
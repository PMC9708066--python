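"""Sharpe-Schoolfield thermal performance curve (TPC) fitting.

The four-parameter Sharpe-Schoolfield model with an explicit peak
temperature describes the unimodal response of a biological rate B to
absolute temperature T:

    B(T) = B0 * exp(-(E/k) * (1/T - 1/Tref))
           / (1 + E/(ED - E) * exp((ED/k) * (1/Tpk - 1/T)))

where B0 is the rate at the (low) reference temperature Tref in the
absence of deactivation, E (eV) is the activation energy governing the
Boltzmann-Arrhenius rise, ED (eV) > E is the deactivation energy
governing the fall beyond the peak, Tpk (K) is the temperature of peak
performance and k = 8.617e-5 eV/K is the Boltzmann constant.

Fitting is ordinary nonlinear least squares on the rate scale with a
multi-start grid over activation-energy and peak-temperature initials;
the fitted curve yields the thermal optimum Topt = Tpk - 273.15 degC,
the peak rate B(Tpk) in closed form, and the operational niche width
(Topt minus the temperature below the peak at which the rate has fallen
to half its maximum).  With fewer than five distinct assay temperatures
a four-parameter fit is not attempted and the temperature of the highest
observed rate is reported as a fallback Topt.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "BOLTZMANN_EV",
    "KELVIN_OFFSET",
    "SSParameters",
    "TPCObservation",
    "TPCFitResult",
    "FitConfig",
    "ss_evaluate",
    "peak_rate",
    "operational_niche_width",
    "fit_ss",
    "arrhenius_correct",
]

BOLTZMANN_EV = 8.617e-5  # eV per K
KELVIN_OFFSET = 273.15

#: fewest distinct assay temperatures for a four-parameter fit
MIN_TEMPS_FULL_FIT = 5


@dataclass(frozen=True)
class SSParameters:
    """Parameter set of one Sharpe-Schoolfield curve.

    ``b0`` carries the unit of the input rates; ``e`` and ``ed`` are in eV
    with ``ed > e`` (required for Tpk to be a true maximum); ``tpk`` and
    ``tref`` are absolute temperatures in K.  ``tref`` is fixed, never
    fitted, and only rescales ``b0``.
    """

    b0: float
    e: float
    ed: float
    tpk: float
    tref: float = KELVIN_OFFSET

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.e <= 0:
            raise ValueError("activation energy E must be positive")
        if self.ed <= self.e:
            raise ValueError("deactivation energy ED must exceed E")
        if self.tpk <= 0:
            raise ValueError("tpk must be a positive absolute temperature")

    @property
    def topt_celsius(self) -> float:
        return self.tpk - KELVIN_OFFSET


@dataclass(frozen=True)
class TPCObservation:
    """One measured (temperature, rate) point."""

    temp: float  # degC
    rate: float  # per hour
    replicate: str = "1"


@dataclass
class TPCFitResult:
    """Fit output: parameters plus derived thermal traits and diagnostics."""

    params: SSParameters | None
    topt: float  # degC
    peak_rate: float  # per hour
    niche_width: float | None  # degC; None when undefined or fallback
    n_temps: int
    n_obs: int
    rss: float = math.nan
    r_squared: float = math.nan
    aic: float = math.nan
    method: str = "fitted"  # or "fallback"
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FitConfig:
    """Settings of the nonlinear least-squares procedure."""

    tref: float = KELVIN_OFFSET
    e_starts: tuple[float, ...] = (0.2, 0.65, 1.2)
    e_bounds: tuple[float, float] = (0.01, 10.0)
    ed_gap_bounds: tuple[float, float] = (0.01, 30.0)
    tpk_pad: tuple[float, float] = (5.0, 10.0)  # K below min / above max obs
    niche_floor: float = -10.0  # degC
    log_residuals: bool = False


def ss_evaluate(params: SSParameters, temp: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the Sharpe-Schoolfield curve at absolute temperature(s) (K)."""
    t = np.asarray(temp, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    k = BOLTZMANN_EV
    rise = params.b0 * np.exp(-(params.e / k) * (1.0 / t - 1.0 / params.tref))
    denom = 1.0 + (params.e / (params.ed - params.e)) * np.exp(
        (params.ed / k) * (1.0 / params.tpk - 1.0 / t)
    )
    out = rise / denom
    return float(out) if np.isscalar(temp) else out


def peak_rate(params: SSParameters) -> float:
    """Rate at the peak, B(Tpk), in closed form."""
    k = BOLTZMANN_EV
    rise = params.b0 * math.exp(
        -(params.e / k) * (1.0 / params.tpk - 1.0 / params.tref)
    )
    return rise / (1.0 + params.e / (params.ed - params.e))


def operational_niche_width(
    params: SSParameters, floor: float = -10.0
) -> float | None:
    """Topt minus the sub-peak temperature where the rate is half-maximal.

    The half-maximum crossing below the peak is found by bracketed root
    finding on [floor, Topt] (degC).  Returns ``None`` when the curve never
    falls to half-max above ``floor`` (very flat rise).
    """
    floor_k = floor + KELVIN_OFFSET
    if floor_k >= params.tpk:
        raise ValueError("floor must lie below the peak temperature")
    half = 0.5 * peak_rate(params)

    def f(t_k: float) -> float:
        return ss_evaluate(params, t_k) - half

    if f(floor_k) > 0:  # rate already above half-max at the floor
        return None
    t_half_k = optimize.brentq(f, floor_k, params.tpk, xtol=1e-10, rtol=1e-14)
    return params.tpk - t_half_k


def arrhenius_correct(
    rate: float, t_obs: float, t_target: float, e: float = 0.61
) -> float:
    """Boltzmann-Arrhenius correction of a rate between temperatures (degC).

    rate * exp((E/k) * (1/T_obs - 1/T_target)) with temperatures in K;
    the default activation energy 0.61 eV is the conventional value for
    cross-study normalisation of metabolic rates to 20 degC.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t_obs_k = t_obs + KELVIN_OFFSET
    t_target_k = t_target + KELVIN_OFFSET
    return rate * math.exp((e / BOLTZMANN_EV) * (1.0 / t_obs_k - 1.0 / t_target_k))


def _fallback_result(temps: np.ndarray, rates: np.ndarray, n_temps: int) -> TPCFitResult:
    i = int(np.argmax(rates))
    return TPCFitResult(
        params=None,
        topt=float(temps[i]),
        peak_rate=float(rates[i]),
        niche_width=None,
        n_temps=n_temps,
        n_obs=len(rates),
        method="fallback",
        warnings=[
            "fewer than %d distinct temperatures; Topt taken as the "
            "temperature of the highest observed rate" % MIN_TEMPS_FULL_FIT
        ],
    )


def _residuals(theta: np.ndarray, t_k: np.ndarray, rates: np.ndarray,
               tref: float, log_scale: bool) -> np.ndarray:
    log_b0, e, gap, tpk = theta
    params = SSParameters(b0=math.exp(log_b0), e=e, ed=e + gap, tpk=tpk, tref=tref)
    pred = ss_evaluate(params, t_k)
    if log_scale:
        return np.log(pred) - np.log(rates)
    return pred - rates


def fit_ss(
    observations: Iterable[TPCObservation] | Sequence[tuple[float, float]],
    config: FitConfig | None = None,
) -> TPCFitResult:
    """Fit the Sharpe-Schoolfield model to temperature-rate observations.

    Observations may be :class:`TPCObservation` objects or bare
    ``(temp_degC, rate)`` pairs.  Non-positive rates are dropped (the model
    is strictly positive).  With fewer than five distinct temperatures the
    fallback rule applies and ``method`` is set to ``"fallback"``.  The
    best of the multi-start fits by residual sum of squares wins, ties
    broken in favour of the smaller activation energy.
    """
    config = config or FitConfig()
    obs = [
        o if isinstance(o, TPCObservation) else TPCObservation(temp=o[0], rate=o[1])
        for o in observations
    ]
    msgs: list[str] = []
    n_dropped = sum(1 for o in obs if o.rate <= 0)
    if n_dropped:
        msgs.append(f"dropped {n_dropped} non-positive rate observation(s)")
        logger.info(msgs[-1])
        obs = [o for o in obs if o.rate > 0]
    if not obs:
        raise ValueError("no positive-rate observations to fit")

    obs = sorted(obs, key=lambda o: (o.temp, o.rate, o.replicate))
    temps = np.array([o.temp for o in obs])
    rates = np.array([o.rate for o in obs])
    n_temps = len(np.unique(temps))
    if n_temps < MIN_TEMPS_FULL_FIT:
        res = _fallback_result(temps, rates, n_temps)
        res.warnings = msgs + res.warnings
        return res

    t_k = temps + KELVIN_OFFSET
    tpk_lo = float(t_k.min()) - config.tpk_pad[0]
    tpk_hi = float(t_k.max()) + config.tpk_pad[1]
    tpk_init = float(t_k[np.argmax(rates)])
    i_ref = int(np.argmin(np.abs(t_k - config.tref)))

    lower = [-50.0, config.e_bounds[0], config.ed_gap_bounds[0], tpk_lo]
    upper = [50.0, config.e_bounds[1], config.ed_gap_bounds[1], tpk_hi]

    best: optimize.OptimizeResult | None = None
    best_key: tuple[float, float] | None = None
    for e0 in config.e_starts:
        # back out a B0 start from the observation nearest Tref via the
        # rising (Arrhenius) part of the curve
        b0_init = rates[i_ref] * math.exp(
            (e0 / BOLTZMANN_EV) * (1.0 / t_k[i_ref] - 1.0 / config.tref)
        )
        theta0 = np.array([
            math.log(max(b0_init, 1e-20)),
            e0,
            min(max(3.0 * e0, config.ed_gap_bounds[0] * 1.1), config.ed_gap_bounds[1]),
            min(max(tpk_init, tpk_lo), tpk_hi),
        ])
        theta0 = np.clip(theta0, lower, upper)
        try:
            sol = optimize.least_squares(
                _residuals,
                theta0,
                bounds=(lower, upper),
                args=(t_k, rates, config.tref, config.log_residuals),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception as exc:  # singular Jacobian etc.; try next start
            logger.debug("start E=%g failed: %s", e0, exc)
            continue
        key = (float(np.sum(sol.fun**2)), float(sol.x[1]))
        if best_key is None or key < best_key:
            best, best_key = sol, key

    if best is None:
        raise RuntimeError("all multi-start fits failed")

    log_b0, e_hat, gap_hat, tpk_hat = best.x
    params = SSParameters(
        b0=math.exp(log_b0), e=e_hat, ed=e_hat + gap_hat, tpk=tpk_hat,
        tref=config.tref,
    )
    pred = ss_evaluate(params, t_k)
    resid = pred - rates
    rss = float(np.sum(resid**2))
    tss = float(np.sum((rates - rates.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else math.nan
    n = len(rates)
    # Gaussian AIC with 4 curve parameters + residual variance
    aic = n * math.log(max(rss / n, 1e-300)) + 2 * 5

    if tpk_hat >= float(t_k.max()):
        msgs.append(
            "no decline observed within the measured range: fitted Tpk at or "
            "beyond the warmest assay temperature; treat Topt with caution"
        )
        warnings.warn(msgs[-1], stacklevel=2)

    width = operational_niche_width(params, floor=config.niche_floor)
    if width is None:
        msgs.append("rate never falls to half-max above the niche floor; "
                    "niche width undefined")

    return TPCFitResult(
        params=params,
        topt=params.topt_celsius,
        peak_rate=peak_rate(params),
        niche_width=width,
        n_temps=n_temps,
        n_obs=n,
        rss=rss,
        r_squared=r_squared,
        aic=aic,
        method="fitted",
        warnings=msgs,
    )
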
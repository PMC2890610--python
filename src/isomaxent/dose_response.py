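"""Fixed-Hill logistic dose-response fitting with parametric bootstrap.

Viability curves from MTS plates follow a plateau-transition-plateau
shape in log10 dose x:

    I(x) = I_bot + (I_top - I_bot) / (1 + 10**(HILL * (x - logIC50)))

with the Hill steepness held fixed (2.5 throughout this study), so only
(I_top, I_bot, logIC50) are regressed. After the fit, I_top and I_bot
are normalized to the fitted I_top. Parameter uncertainties come from a
parametric bootstrap: synthetic data sets are drawn from the best-fit
curve plus Gaussian noise at the residual scale and refit, and the
per-parameter spread over replicates is reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "DEFAULT_HILL",
    "DoseResponseParams",
    "FitResult",
    "FitError",
    "DegenerateDataError",
    "model_response",
    "fit_dose_response",
    "bootstrap_fit",
]

DEFAULT_HILL = 2.5


class FitError(RuntimeError):
    """Regression failed to converge from every restart."""

    def __init__(self, message: str, best_residual: float = math.nan):
        super().__init__(message)
        self.best_residual = best_residual


class DegenerateDataError(ValueError):
    """Responses carry no transition; logIC50 is not identifiable."""


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of the fixed-Hill logistic in log10 molar dose."""

    i_top: float
    i_bot: float
    log_ic50: float
    hill: float = DEFAULT_HILL

    def __post_init__(self) -> None:
        if self.hill <= 0:
            raise ValueError("hill must be positive")


@dataclass
class FitResult:
    """A converged fit, normalized so that i_top = 1.

    ``params_raw`` keeps the pre-normalization estimates (the bootstrap
    simulates at the raw scale); ``param_sd`` is populated by
    :func:`bootstrap_fit`, on the normalized scale (each replicate's
    parameters divided by the primary fit's raw i_top).
    """

    params: DoseResponseParams
    params_raw: DoseResponseParams
    residual_sd: float
    param_sd: dict[str, float] = field(default_factory=dict)
    param_mean: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0


def model_response(x, params: DoseResponseParams):
    """Evaluate the dose-response curve at log10 dose ``x``.

    Monotone non-increasing in x for an inhibitory compound (i_top >
    i_bot): the low-dose limit is i_top, the high-dose limit i_bot, and
    the response at x = logIC50 is the plateau midpoint.
    """
    x = np.asarray(x, dtype=float)
    return params.i_bot + (params.i_top - params.i_bot) / (
        1.0 + 10.0 ** (params.hill * (x - params.log_ic50))
    )


def _curve(x, i_top, i_bot, log_ic50, hill):
    return i_bot + (i_top - i_bot) / (1.0 + 10.0 ** (hill * (x - log_ic50)))


def fit_dose_response(
    doses: np.ndarray,
    responses: np.ndarray,
    hill: float = DEFAULT_HILL,
) -> FitResult:
    """Least-squares fit of (i_top, i_bot, logIC50) with the Hill slope fixed.

    Initializes from the response extremes and the dose nearest the
    midpoint response, with a 5-point restart grid on logIC50 spanning
    the dose range to avoid local minima. Requires at least 4 distinct
    doses; a dose span under one log10 unit only triggers a warning.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have the same shape")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct doses")
    if not np.isfinite(responses).all():
        raise ValueError("non-finite response")
    if np.ptp(doses) < 1.0:
        warnings.warn("dose range spans less than one log10 unit", stacklevel=2)
    if np.ptp(responses) <= 1e-12 * max(1.0, abs(responses).max()):
        raise DegenerateDataError("responses are constant; no transition to fit")

    top0, bot0 = responses.max(), responses.min()
    mid = (top0 + bot0) / 2.0
    lic0 = doses[np.argmin(np.abs(responses - mid))]
    starts = np.unique(
        np.concatenate([[lic0], np.linspace(doses.min(), doses.max(), 5)])
    )
    best = None
    best_ssr = math.inf
    for s in starts:
        try:
            popt, _ = optimize.curve_fit(
                lambda x, it, ib, l: _curve(x, it, ib, l, hill),
                doses,
                responses,
                p0=[top0, bot0, s],
                maxfev=5000,
            )
        except RuntimeError:
            continue
        ssr = float(((responses - _curve(doses, *popt, hill)) ** 2).sum())
        if ssr < best_ssr:
            best_ssr, best = ssr, popt
    if best is None:
        raise FitError("regression failed from every restart", best_residual=best_ssr)
    i_top, i_bot, log_ic50 = (float(v) for v in best)
    if i_top < i_bot:  # the logistic is symmetric under (top,bot) swap + sign
        i_top, i_bot = i_bot, i_top
    raw = DoseResponseParams(i_top, i_bot, log_ic50, hill)
    dof = max(doses.size - 3, 1)
    residual_sd = math.sqrt(best_ssr / dof)
    normalized = DoseResponseParams(1.0, i_bot / i_top, log_ic50, hill)
    return FitResult(params=normalized, params_raw=raw, residual_sd=residual_sd)


def bootstrap_fit(
    fit: FitResult,
    doses: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    residual_sd: float | None = None,
    max_failure_rate: float = 0.2,
) -> FitResult:
    """Parametric bootstrap around a converged fit.

    Draws ``n_boot`` synthetic data sets from the best-fit curve plus
    Gaussian noise of scale ``residual_sd`` (defaulting to the primary
    fit's root-mean-square residual), refits each with the same
    procedure, and reports per-parameter means and standard deviations on
    the normalized scale. More than ``max_failure_rate`` replicate
    failures aborts.
    """
    doses = np.asarray(doses, dtype=float)
    sd = fit.residual_sd if residual_sd is None else float(residual_sd)
    if sd < 0:
        raise ValueError("residual_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    ideal = model_response(doses, fit.params_raw)
    scale = fit.params_raw.i_top
    reps = []
    failures = 0
    for _ in range(n_boot):
        data = ideal + rng.normal(0.0, sd, size=doses.shape) if sd > 0 else ideal
        try:
            r = fit_dose_response(doses, data, hill=fit.params_raw.hill)
        except (FitError, DegenerateDataError):
            failures += 1
            continue
        p = r.params_raw
        reps.append((p.i_top / scale, p.i_bot / scale, p.log_ic50))
    if failures > max_failure_rate * n_boot:
        raise FitError(
            f"{failures}/{n_boot} bootstrap replicates failed to converge"
        )
    arr = np.asarray(reps)
    names = ("i_top", "i_bot", "log_ic50")
    return replace(
        fit,
        param_mean=dict(zip(names, arr.mean(axis=0))),
        param_sd=dict(zip(names, arr.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(3))),
        n_boot=n_boot,
    )
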
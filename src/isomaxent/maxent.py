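"""Maximum-entropy inference of isotype expression under an energy constraint.

Given a prior expression distribution mu over M tubulin isotypes and
per-isotype drug binding free energies dG_i, the measured cytotoxicity of a
compound pins the expression-weighted mean binding energy

    <dG> = sum_i P_i dG_i,

and the distribution P that maximizes the relative entropy
``-sum_i P_i ln(P_i / mu_i)`` subject to that constraint (and
normalization) is the exponentially tilted prior

    P_i = mu_i exp(-beta dG_i) / Z,   Z = sum_j mu_j exp(-beta dG_j),

with the Lagrange multiplier beta fixed by the constraint. Because
``d<dG>/dbeta = -Var_P(dG) <= 0``, the constraint gap is monotone in beta
and the root is unique whenever the target mean lies strictly inside the
range of energies supported by the prior.

The target mean itself comes from cytotoxicity through a linear
logIC50-to-energy calibration, and the per-isotype energies for a
derivative are built from (a) reference energies for colchicine, obtained
by inverting the Gibbs form against the measured colchicine-treated
expression profile, plus (b) the computed relative binding free energies
of the derivative with respect to colchicine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data_io import ExpressionProfile, IsotypeScheme

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_SLOPE",
    "CalibrationConstants",
    "EnergyVector",
    "MaxEntProblem",
    "MaxEntSolution",
    "MissingDataError",
    "UnsolvableError",
    "mean_energy_from_logic50",
    "posterior_weights",
    "constraint_gap",
    "solvable",
    "solve_beta",
    "relative_entropy",
    "infer_reference_energies",
    "derivative_energies",
    "predict_expression",
]

GAS_CONSTANT_KCAL = 1.9872041e-3  # kcal / (mol K)

#: Default logIC50 -> mean-binding-energy slope, kcal/mol per log10 unit.
#: An affinity-scored convention of magnitude 2.303*R*T near room
#: temperature: one log10 unit of potency corresponds to ~1.37 kcal/mol of
#: binding free energy, and more potent (more negative logIC50) maps to a
#: larger constraint mean. Both slope and intercept are configurable.
DEFAULT_SLOPE = -1.366
DEFAULT_INTERCEPT = 0.0

ENERGY_VARIANTS = ("mean", "mean+sd", "mean-sd")


class MissingDataError(ValueError):
    """A required logIC50 measurement is absent (distinct from 'no solution')."""


class UnsolvableError(RuntimeError):
    """Numerical failure on an instance the solvability test accepted."""


@dataclass(frozen=True)
class CalibrationConstants:
    """Coefficients of the linear logIC50 -> mean binding energy relation."""

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


@dataclass
class EnergyVector:
    """Per-isotype binding free energies (kcal/mol) for one compound."""

    scheme: IsotypeScheme
    values: np.ndarray
    variant: str = "mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.scheme),):
            raise ValueError("energy vector length does not match scheme")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite binding energy")
        if self.variant not in ENERGY_VARIANTS:
            raise ValueError(f"unknown energy variant {self.variant!r}")


@dataclass
class MaxEntProblem:
    """One constrained inference instance: prior, energies, target mean."""

    prior: ExpressionProfile
    energies: EnergyVector
    target_mean: float

    def __post_init__(self) -> None:
        if self.prior.scheme != self.energies.scheme:
            raise ValueError("prior and energies use different isotype schemes")


@dataclass
class MaxEntSolution:
    """Tilted posterior, its multiplier, and solvability bookkeeping.

    For unsolvable instances (constraint mean outside the supported energy
    range) the posterior is the all-zero vector, mirroring how the grid
    analysis assigns zero expression levels when no prediction exists.
    """

    posterior: np.ndarray
    beta: float
    partition: float
    solvable: bool
    n_restarts: int = 1
    beta_sd: float = 0.0


def mean_energy_from_logic50(logic50: float, calib: CalibrationConstants) -> float:
    """Map a logIC50 (log10 molar) onto a mean binding energy (kcal/mol)."""
    if not math.isfinite(logic50):
        raise MissingDataError("logIC50 is missing or non-finite")
    return calib.slope * logic50 + calib.intercept


def _tilt(prior: np.ndarray, energies: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Stabilized exponential tilt; returns (posterior, log partition)."""
    logw = np.where(prior > 0, np.log(np.maximum(prior, 1e-300)), -np.inf)
    logw = logw - beta * energies
    shift = logw.max()
    if not np.isfinite(shift):
        raise ValueError("prior has empty support")
    w = np.exp(logw - shift)
    total = w.sum()
    return w / total, shift + math.log(total)


def posterior_weights(
    prior: ExpressionProfile, energies: EnergyVector, beta: float
) -> ExpressionProfile:
    """Exponentially tilt the prior: ``P_i = mu_i exp(-beta dG_i) / Z``.

    Computed with a max-shift so that no overflow occurs for any
    ``|beta * dG|`` representable in double precision.
    """
    post, _ = _tilt(prior.fractions, energies.values, beta)
    return ExpressionProfile(
        prior.cell_line, prior.treatment, prior.scheme, post, raw_sum=prior.raw_sum
    )


def constraint_gap(problem: MaxEntProblem, beta: float) -> float:
    """Posterior mean energy minus the target, at multiplier ``beta``.

    Non-increasing in beta; strictly decreasing wherever the posterior
    energy variance is positive.
    """
    post, _ = _tilt(problem.prior.fractions, problem.energies.values, beta)
    return float(post @ problem.energies.values) - problem.target_mean


def solvable(problem: MaxEntProblem) -> bool:
    """Whether the constraint has a root: target strictly inside the
    supported energy range (or equal to the common supported energy)."""
    support = problem.prior.fractions > 0
    vals = problem.energies.values[support]
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        return bool(problem.target_mean == lo)
    return bool(lo < problem.target_mean < hi)


def relative_entropy(posterior: np.ndarray, prior: np.ndarray) -> float:
    """``-sum_i P_i ln(P_i / mu_i)``; the objective the tilt maximizes."""
    p = np.asarray(posterior, float)
    mask = p > 0
    return float(-(p[mask] * np.log(p[mask] / np.asarray(prior, float)[mask])).sum())


_BETA_LIMIT = 1e4


def solve_beta(
    problem: MaxEntProblem,
    beta0: float = 0.0,
    tol: float = 1e-10,
) -> MaxEntSolution:
    """Solve the mean-energy constraint for the Lagrange multiplier.

    Expands a bracket geometrically around ``beta0`` until the constraint
    gap changes sign, then polishes with Brent's method. Monotonicity of
    the gap makes the root unique, so ``beta0`` only shifts the initial
    bracket, never the answer.
    """
    prior = problem.prior.fractions
    energies = problem.energies.values
    if not solvable(problem):
        return MaxEntSolution(np.zeros_like(prior), math.nan, math.nan, False)

    support = prior > 0
    if np.ptp(energies[support]) == 0:
        # all supported energies equal the target: the prior already solves it
        post, logz = _tilt(prior, energies, 0.0)
        return MaxEntSolution(post, 0.0, math.exp(logz), True)

    gap = lambda b: constraint_gap(problem, b)
    g0 = gap(beta0)
    if g0 == 0.0:
        root = beta0
    else:
        # gap is decreasing: root lies above beta0 if g0 > 0, below otherwise
        step = 1.0
        lo, hi = beta0, beta0
        while True:
            if g0 > 0:
                lo, hi = hi, beta0 + step
                g_new = gap(hi)
                if g_new <= 0:
                    break
            else:
                hi, lo = lo, beta0 - step
                g_new = gap(lo)
                if g_new >= 0:
                    lo, hi = lo, hi
                    break
            step *= 2.0
            if step > 4 * _BETA_LIMIT or max(abs(lo), abs(hi)) > _BETA_LIMIT:
                raise UnsolvableError(
                    f"no sign change within |beta| <= {_BETA_LIMIT:g} "
                    f"on a solvable instance (target {problem.target_mean})"
                )
        if lo > hi:
            lo, hi = hi, lo
        root = optimize.brentq(
            gap, lo, hi, xtol=1e-13, rtol=max(tol, 4 * np.finfo(float).eps)
        )
    post, logz = _tilt(prior, energies, root)
    residual = abs(post @ energies - problem.target_mean)
    if residual > 1e-8 * max(1.0, abs(problem.target_mean)):
        raise UnsolvableError(f"constraint residual {residual:g} exceeds tolerance")
    return MaxEntSolution(post, float(root), math.exp(logz), True)


def infer_reference_energies(
    prior_colchicine: ExpressionProfile, mean_energy_colchicine: float
) -> tuple[EnergyVector, float]:
    """Invert the Gibbs form against the colchicine-treated profile.

    With a flat improper prior (mu_i = 1) the tilted form ``P_i =
    exp(-beta dG_i)/Z`` determines the per-isotype colchicine energies
    only up to a gauge; fixing Z = 1 gives ``dG_i = -ln(P_i)/beta`` and
    the mean-energy constraint then pins the multiplier:

        beta_C = S(P) / <dG>_C,   S(P) = -sum_i P_i ln P_i.

    Requires every fraction positive (apply :meth:`ExpressionProfile.
    floored` first for profiles with exact zeros) and a nonzero target.
    """
    p = prior_colchicine.fractions
    if (p <= 0).any():
        raise ValueError(
            "reference inversion requires strictly positive fractions; "
            "apply a prior floor first"
        )
    entropy = float(-(p * np.log(p)).sum())
    if entropy == 0.0:
        raise ValueError("degenerate one-hot profile: reference gauge undefined")
    if mean_energy_colchicine == 0.0:
        raise ValueError("colchicine mean energy must be nonzero")
    beta_c = entropy / mean_energy_colchicine
    values = -np.log(p) / beta_c
    return EnergyVector(prior_colchicine.scheme, values, "mean"), beta_c


def derivative_energies(
    reference: EnergyVector,
    ddg_mean: np.ndarray,
    ddg_sd: np.ndarray | None = None,
    variant: str = "mean",
    sign: int = 1,
) -> EnergyVector:
    """Per-isotype energies of a derivative: reference plus relative shift.

    ``variant`` selects the mean relative energies or the mean plus/minus
    one standard deviation (the uncertainty bands of the computed relative
    binding free energies). ``sign`` flips the direction of the relative
    energy convention (derivative-minus-colchicine by default).
    """
    ddg_mean = np.asarray(ddg_mean, dtype=float)
    if ddg_mean.shape != (len(reference.scheme),):
        raise ValueError("relative-energy row does not match the scheme")
    if variant not in ENERGY_VARIANTS:
        raise ValueError(f"unknown energy variant {variant!r}")
    shift = ddg_mean.copy()
    if variant != "mean":
        if ddg_sd is None:
            raise ValueError("sd row required for mean±sd variants")
        ddg_sd = np.asarray(ddg_sd, dtype=float)
        shift += ddg_sd if variant == "mean+sd" else -ddg_sd
    return EnergyVector(reference.scheme, reference.values + sign * shift, variant)


def predict_expression(
    prior_colchicine: ExpressionProfile,
    energies: EnergyVector,
    logic50: float,
    calib: CalibrationConstants,
    n_restarts: int = 100,
    beta_max: float = 10.0,
    seed: int = 0,
) -> MaxEntSolution:
    """Predict the expression profile of a cell line under one derivative.

    The colchicine-treated profile is the prior; the derivative's logIC50
    sets the constraint mean through the calibration. The multiplier
    equation is solved from ``n_restarts`` random initial guesses drawn
    uniformly from ``(-beta_max, beta_max)``; the reported beta and
    posterior are means over converged restarts and ``beta_sd`` their
    spread (zero in practice, since the monotone constraint has a unique
    root).
    """
    if np.isnan(logic50):
        raise MissingDataError("logIC50 missing for this (compound, cell line)")
    target = mean_energy_from_logic50(logic50, calib)
    problem = MaxEntProblem(prior_colchicine, energies, target)
    if not solvable(problem):
        return MaxEntSolution(
            np.zeros_like(prior_colchicine.fractions),
            math.nan,
            math.nan,
            False,
            n_restarts=n_restarts,
        )
    rng = np.random.default_rng(seed)
    beta0s = rng.uniform(-beta_max, beta_max, size=n_restarts)
    betas = np.empty(n_restarts)
    posts = np.empty((n_restarts, len(energies.scheme)))
    partition = math.nan
    for k, b0 in enumerate(beta0s):
        sol = solve_beta(problem, beta0=float(b0))
        betas[k] = sol.beta
        posts[k] = sol.posterior
        partition = sol.partition
    posterior = posts.mean(axis=0)
    posterior /= posterior.sum()
    return MaxEntSolution(
        posterior,
        float(betas.mean()),
        partition,
        True,
        n_restarts=n_restarts,
        beta_sd=float(betas.std()),
    )
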
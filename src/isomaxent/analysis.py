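"""Grid analysis over derivatives x cell lines, classification and scores.

Three modelling cases differ only in which sub-isotypes are treated as
structurally distinguishable:

* case 1 — IIa/IIb and IVa/IVb indistinguishable (4 isotypes; relative
  binding energies averaged within each pair);
* case 2 — only IVa/IVb distinguishable (5 isotypes);
* case 3 — all six isotype variants distinguishable.

For each (cell line, derivative) pair the colchicine-treated expression
profile (or a uniform profile) is the prior, the colchicine logIC50 of
that line fixes the reference per-isotype energies, and the derivative's
logIC50 fixes the constraint mean. The highest-expression isotype of the
mean-energy posterior labels the cell; ties map to "U" and unsolvable
constraints to "0". Frequency scores count those labels over the grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .data_io import (
    COLLAPSED_4,
    SPLIT_ALL_6,
    SPLIT_IV_5,
    BindingEnergyTable,
    CytotoxicityTable,
    ExpressionProfile,
    IsotypeScheme,
    collapse_isotypes,
)
from .maxent import (
    ENERGY_VARIANTS,
    CalibrationConstants,
    MaxEntSolution,
    derivative_energies,
    infer_reference_energies,
    mean_energy_from_logic50,
    predict_expression,
)

__all__ = [
    "AnalysisConfig",
    "CALIBRATED_CONFIG",
    "GridCellResult",
    "FrequencyMap",
    "CASE_SCHEMES",
    "COLCHICINE_ID",
    "LABEL_TIE",
    "LABEL_NO_SOLUTION",
    "LABEL_NO_DATA",
    "build_priors",
    "run_grid",
    "classify_highest",
    "frequency_map",
    "potency_order",
]

log = logging.getLogger(__name__)

COLCHICINE_ID = "D00"
LABEL_TIE = "U"
LABEL_NO_SOLUTION = "0"
LABEL_NO_DATA = "NO_DATA"

CASE_SCHEMES: dict[int, IsotypeScheme] = {1: COLLAPSED_4, 2: SPLIT_IV_5, 3: SPLIT_ALL_6}


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the pipeline, all defaulted to the shipped choices.

    ``calibration`` maps logIC50 to the mean-binding-energy constraint;
    ``prior_floor`` replaces exact zeros in measured expression rows
    before logarithms are taken; ``tie_rel_tol`` is the relative margin
    within which top posterior weights count as tied; ``na_as_zero``
    folds cells with no logIC50 measurement into the "0" (no prediction)
    score instead of dropping them; ``ddg_sign`` flips the
    derivative-minus-colchicine convention of the relative energies;
    ``tie_mode`` selects plain tie detection on the mean-energy posterior
    ("rel_tol") or additionally requiring the mean±sd energy variants to
    agree on the argmax ("variant_consensus").
    """

    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    prior_floor: float = 1e-4
    n_restarts: int = 100
    beta_max: float = 10.0
    seed: int = 0
    tolerance: float = 1e-10
    tie_rel_tol: float = 0.01
    tie_mode: str = "rel_tol"
    na_as_zero: bool = True
    m006x_policy: str = "uniform"
    sd_rule: str = "quadrature"
    ddg_sign: int = 1

    def digest(self) -> str:
        """Stable hash of the configuration, recorded with run outputs."""
        payload = asdict(self)
        payload["calibration"] = [self.calibration.slope, self.calibration.intercept]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


#: Configuration calibrated against the reference Case 1 frequency scores
#: (see docs/methods.md for the calibration procedure and its residual
#: mismatches). Differs from the defaults in the logIC50-energy constants,
#: the direction of the relative-energy convention, and tie handling.
CALIBRATED_CONFIG = AnalysisConfig(
    calibration=CalibrationConstants(slope=-0.4, intercept=-3.5),
    tie_rel_tol=0.04,
    tie_mode="variant_consensus",
    prior_floor=1e-3,
    sd_rule="max",
    ddg_sign=-1,
)


@dataclass
class GridCellResult:
    """Outcome of one (cell line, derivative) inference."""

    cell_line: str
    derivative: str
    case: int
    prior_mode: str
    solutions: dict[str, MaxEntSolution] | None
    label: str

    def to_json_dict(self) -> dict:
        sols = None
        if self.solutions is not None:
            sols = {
                k: {
                    "posterior": s.posterior.tolist(),
                    "beta": s.beta,
                    "beta_sd": s.beta_sd,
                    "solvable": s.solvable,
                }
                for k, s in self.solutions.items()
            }
        return {
            "cell_line": self.cell_line,
            "derivative": self.derivative,
            "case": self.case,
            "prior_mode": self.prior_mode,
            "label": self.label,
            "solutions": sols,
        }


@dataclass
class FrequencyMap:
    """Counts of highest-expression labels over one grid run."""

    counts: dict[str, int]
    n_cells: int
    n_no_data: int = 0

    def score(self, label: str) -> int:
        return self.counts.get(label, 0)


def build_priors(
    expression: list[ExpressionProfile],
    case: int,
    prior_mode: str = "colchicine",
    m006x_policy: str = "uniform",
    cell_lines: list[str] | None = None,
) -> dict[str, ExpressionProfile]:
    """Assemble the per-cell-line prior profiles for one case.

    ``colchicine`` mode takes each line's colchicine-treated expression
    row, half-splitting II and/or IV onto sub-isotypes as the case's
    scheme requires. ``uniform`` mode assigns 1/M to each isotype. Cell
    lines without measured expression (M006X) fall back to the configured
    policy: a uniform prior or the profile of the sister glioma line
    M010B.
    """
    scheme = CASE_SCHEMES[case]
    measured = {
        p.cell_line: p for p in expression if p.treatment.lower() == "colchicine"
    }
    if cell_lines is None:
        cell_lines = list(measured)
    priors: dict[str, ExpressionProfile] = {}
    for line in cell_lines:
        if prior_mode == "uniform":
            priors[line] = ExpressionProfile(
                line, "colchicine", scheme, np.full(len(scheme), 1.0 / len(scheme))
            )
            continue
        if prior_mode != "colchicine":
            raise ValueError(f"unknown prior mode {prior_mode!r}")
        base = measured.get(line)
        if base is None:
            if m006x_policy == "uniform":
                priors[line] = ExpressionProfile(
                    line, "colchicine", scheme, np.full(len(scheme), 1.0 / len(scheme))
                )
                continue
            if m006x_policy == "mirror_m010b" and "M010B" in measured:
                base = replace(measured["M010B"], cell_line=line)
            else:
                raise ValueError(
                    f"no expression data for {line} and no applicable policy"
                )
        priors[line] = base.split(scheme)
    return priors


def classify_highest(
    solution: MaxEntSolution,
    tie_rel_tol: float = 0.01,
    scheme: IsotypeScheme = COLLAPSED_4,
) -> str:
    """Label the highest-expression isotype of a mean-energy posterior.

    Unsolvable instances map to "0". Otherwise every isotype whose weight
    is within a relative ``tie_rel_tol`` of the maximum belongs to the
    argmax set; a non-singleton set maps to "U".
    """
    if not solution.solvable:
        return LABEL_NO_SOLUTION
    p = solution.posterior
    top = p.max()
    winners = np.flatnonzero(p >= top * (1.0 - tie_rel_tol))
    if winners.size == 1:
        return scheme.labels[int(winners[0])]
    return LABEL_TIE


def _classify_cell(
    solutions: dict[str, MaxEntSolution],
    scheme: IsotypeScheme,
    config: AnalysisConfig,
) -> str:
    label = classify_highest(solutions["mean"], config.tie_rel_tol, scheme)
    if config.tie_mode == "variant_consensus" and label not in (
        LABEL_TIE,
        LABEL_NO_SOLUTION,
    ):
        # demand that the mean+sd / mean-sd energy bands agree on the winner
        for variant in ("mean+sd", "mean-sd"):
            sol = solutions[variant]
            if not sol.solvable:
                continue
            alt = classify_highest(sol, config.tie_rel_tol, scheme)
            if alt not in (label, LABEL_NO_SOLUTION):
                return LABEL_TIE
    return label


def _cell_seed(base: int, i: int, j: int) -> int:
    state = np.random.SeedSequence(entropy=base, spawn_key=(i, j)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def run_grid(
    binding: BindingEnergyTable,
    cytotox: CytotoxicityTable,
    expression: list[ExpressionProfile],
    case: int = 1,
    prior_mode: str = "colchicine",
    config: AnalysisConfig | None = None,
    cell_lines: list[str] | None = None,
) -> list[GridCellResult]:
    """Run the full inference grid for one case and prior mode.

    Derivatives with no logIC50 in any cell line (D14) are dropped
    entirely; per-line missing entries yield NO_DATA cells. Deterministic
    for a fixed config seed.
    """
    config = config or AnalysisConfig()
    scheme = CASE_SCHEMES[case]
    table = collapse_isotypes(binding, scheme, sd_rule=config.sd_rule)
    lines = cell_lines if cell_lines is not None else list(cytotox.cell_lines)
    derivatives = [
        d for d in cytotox.measured_compounds() if d != COLCHICINE_ID and d in table.derivatives
    ]
    priors = build_priors(
        expression, case, prior_mode, config.m006x_policy, cell_lines=lines
    )
    results: list[GridCellResult] = []
    for i, line in enumerate(lines):
        prior = priors[line].floored(config.prior_floor)
        colch_lic50 = cytotox.value(COLCHICINE_ID, line)
        if np.isnan(colch_lic50):
            raise ValueError(f"no colchicine logIC50 for cell line {line}")
        target_c = mean_energy_from_logic50(colch_lic50, config.calibration)
        reference, beta_c = infer_reference_energies(prior, target_c)
        log.info("cell line %s: beta_C = %.6g", line, beta_c)
        for j, deriv in enumerate(derivatives):
            lic50 = cytotox.value(deriv, line)
            if np.isnan(lic50):
                results.append(
                    GridCellResult(line, deriv, case, prior_mode, None, LABEL_NO_DATA)
                )
                continue
            ddg_mean, ddg_sd = table.row(deriv)
            solutions: dict[str, MaxEntSolution] = {}
            for variant in ENERGY_VARIANTS:
                energies = derivative_energies(
                    reference, ddg_mean, ddg_sd, variant, sign=config.ddg_sign
                )
                solutions[variant] = predict_expression(
                    prior,
                    energies,
                    lic50,
                    config.calibration,
                    n_restarts=config.n_restarts,
                    beta_max=config.beta_max,
                    seed=_cell_seed(config.seed, i, j),
                )
            label = _classify_cell(solutions, scheme, config)
            sol = solutions["mean"]
            log.info(
                "%s/%s: label=%s solvable=%s beta=%.6g",
                line,
                deriv,
                label,
                sol.solvable,
                sol.beta,
            )
            results.append(
                GridCellResult(line, deriv, case, prior_mode, solutions, label)
            )
    return results


def frequency_map(
    results: list[GridCellResult], na_as_zero: bool = True
) -> FrequencyMap:
    """Count highest-expression labels over one grid run.

    ``na_as_zero`` folds NO_DATA cells into the "0" score (so every grid
    cell is counted, matching a 19 x 6 = 114 cell total); otherwise they
    are excluded from ``n_cells`` and reported in ``n_no_data``.
    """
    keys = {(r.case, r.prior_mode) for r in results}
    if len(keys) > 1:
        raise ValueError(f"mixed (case, prior_mode) runs in one frequency map: {keys}")
    counts: dict[str, int] = {}
    n_cells = 0
    n_no_data = 0
    for r in results:
        label = r.label
        if label == LABEL_NO_DATA:
            if na_as_zero:
                label = LABEL_NO_SOLUTION
            else:
                n_no_data += 1
                continue
        counts[label] = counts.get(label, 0) + 1
        n_cells += 1
    return FrequencyMap(counts, n_cells, n_no_data)


def potency_order(cytotox: CytotoxicityTable) -> list[str]:
    """Compounds sorted most-potent first by mean logIC50 over measured lines.

    Compounds with no measurement anywhere sort last (flagged by a
    warning in the log); ties break on compound id.
    """
    means = cytotox.logic50.mean(axis=1, skipna=True)
    order = []
    for c in cytotox.compounds:
        m = means[c]
        if np.isnan(m):
            log.warning("compound %s has no logIC50 data; placed last", c)
            order.append((1, float("inf"), c))
        else:
            order.append((0, float(m), c))
    return [c for _, _, c in sorted(order)]
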
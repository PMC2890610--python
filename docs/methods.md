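# Methods

## The inference problem

Microtubule-targeting drugs such as colchicine bind the beta-tubulin
subunit, and the human beta-tubulin isotypes (I, IIa/IIb, III, IVa/IVb)
differ in their binding-site residues and hence in their affinity for any
given compound. Given (i) computed relative binding free energies
ΔΔG_i (kcal/mol) of a panel of colchicine derivatives against each
isotype, (ii) measured cytotoxicity (logIC50, log10 molar) of those
derivatives across cancer cell lines, and (iii) densitometry-derived
isotype expression fractions for colchicine-treated cells, the package
infers the isotype expression distribution of each cell line exposed to
each derivative, and from it which isotype the derivative predominantly
engages.

## Maximum-entropy update

For one cell line and one compound, let μ be a prior distribution over
the M isotypes and ΔG_i the per-isotype binding free energy of the
compound. Cytotoxicity constrains the expression-weighted mean energy

    ⟨ΔG⟩ = Σ_i P_i ΔG_i = a·logIC50 + b,

with (a, b) the linear calibration discussed below. Among all
distributions satisfying this constraint, the one closest to the prior in
relative entropy, S(P‖μ) = −Σ_i P_i ln(P_i/μ_i), is the exponentially
tilted prior

    P_i = μ_i exp(−β ΔG_i) / Z,   Z = Σ_j μ_j exp(−β ΔG_j).

Since d⟨ΔG⟩/dβ = −Var_P(ΔG) ≤ 0, the constraint gap is monotone in β and
the multiplier is unique whenever the target mean lies strictly between
the smallest and largest ΔG_i on the prior's support. Outside that range
no solution exists; such cells are assigned the all-zero expression
vector and the label "0". Cells with no logIC50 measurement are a
distinct NO_DATA outcome (folded into "0" for frequency scoring by
default, so a 19-derivative × 6-line grid always totals 114 cells).

The solver expands a bracket geometrically from the initial guess and
polishes with Brent's method; exponentials are always evaluated after a
max-shift, so no overflow occurs at any representable β·ΔG. Restarts
(100 by default, initial guesses uniform on ±10, seeded) are retained
for procedural fidelity, but because the root is unique they all agree;
the reported β spread over restarts is zero and the mean±SD expression
bands come instead from the three energy variants (ΔΔG mean, mean+SD,
mean−SD).

## Reference energies for colchicine

Per-isotype absolute energies for the reference compound are not
measurable, so they are reconstructed from the colchicine-treated
expression profile P^C itself: writing the Gibbs form with a flat
improper prior (μ_i = 1) and fixing the gauge Z = 1 gives

    ΔG_i^C = −ln(P_i^C)/β^C,   β^C = S(P^C)/⟨ΔG⟩^C,

where S is the Shannon entropy and ⟨ΔG⟩^C the calibrated mean energy of
colchicine in that cell line. Any other gauge differs by an affine shift
absorbed into β; the round-trip (tilting a uniform prior by these
energies reproduces P^C, and a zero relative shift reproduces the prior
at colchicine's own logIC50) is property-tested. Derivative energies are
ΔG_i^C plus the derivative's relative energy ΔΔG_i (direction
config-exposed via `ddg_sign`). Exact zeros in measured profiles (MCF-7
and CEM rows) are floored at `prior_floor` (default 1e-4) and
renormalized before logarithms.

## Isotype schemes and cases

Expression antibodies do not resolve IIa/IIb or IVa/IVb. Case 1 collapses
both pairs (4 states; relative energies averaged within a pair, collapsed
SD = sqrt(sd_a² + sd_b²)/2 treating the two estimates as independent,
with max(sd_a, sd_b) as a config alternative). Case 2 splits only IV,
Case 3 splits both; measured fractions are divided half/half onto
sub-isotypes. M006X has no measured expression; its prior defaults to
uniform (`mirror_m010b` copies the sister glioma line instead).

## Classification and frequency scores

Each grid cell is labelled by the argmax isotype of the mean-energy
posterior. Weights within a relative `tie_rel_tol` (default 1%) of the
maximum count as tied → label "U". A second, config-exposed tie mode
(`variant_consensus`) additionally demands that the mean+SD and mean−SD
energy variants agree on the winner; disagreement → "U". Frequency
scores count labels over the grid; compounds are ordered by potency
using each compound's mean logIC50 over measured cell lines.

## Calibration of the logIC50–energy relation

The linear constants are not derivable from first principles here. The
shipped default is an affinity-scored convention: slope −1.366 kcal/mol
per log10 unit (the magnitude of 2.303·R·T near room temperature) and
intercept 0, under which the uniform-prior D20 prediction ranks isotype
III highest — the sign convention that matches the reference behaviour.

`CALIBRATED_CONFIG` is a second, documented configuration obtained by a
systematic search over slope, intercept, tie tolerance and mode, prior
floor, collapsed-SD rule and ΔΔG sign, scored against the reference
Case 1 frequency scores (I 13, II 7, III 26, IV 5, U 35, "0" 28 over 114
cells) and the A549 III-counts (8 in Case 1, 13 in Case 3). The best
configuration — slope −0.4, intercept −3.5, tie 0.04 with variant
consensus, floor 1e-3, SD rule max, sign −1 — reproduces II, III, IV, U
and the A549 Case 1 count exactly, but yields I = 8, "0" = 33 and an
A549 Case 3 count of 8. No configuration in the searched family
reproduces all counts simultaneously; the residual mismatch is consistent
with the reference analysis's multiplier scatter across restart guesses,
which a solver converging to the unique root cannot (and should not)
emulate. The corresponding acceptance test asserts the full reference
sextet and is expected to fail on exactly those entries; it is kept
failing rather than weakened.

## Dose-response stage

Viability curves are fit with the fixed-Hill logistic
I(x) = I_bot + (I_top − I_bot)/(1 + 10^{h(x − logIC50)}), h = 2.5,
x in log10 molar. Only (I_top, I_bot, logIC50) are regressed
(initialized from the response extremes and the midpoint dose, with a
5-point restart grid on logIC50); after regression I_top and I_bot are
normalized to the fitted I_top. Uncertainties come from a parametric
bootstrap: synthetic data sets are drawn from the best-fit curve plus
Gaussian noise at the fit's root-mean-square residual scale (a
replicate-well-based scale can be passed instead), refit, and summarized
by per-parameter means and standard deviations; replicate parameters are
normalized by the primary fit's I_top so that the I_top spread is
reported rather than identically 1.

## Synthetic data

`make_plate` emulates the study's 8-dose × 8-replicate design with
Gaussian read noise (default sd 0.02 on the normalized viability scale).
`make_scenario` produces maximum-entropy instances with exact known
answers by tilting a flat-simplex prior with a chosen multiplier and
setting the target to the tilted distribution's exact mean; draws whose
tilt collapses the posterior onto a simplex vertex in double precision
are rejected and redrawn, so every emitted instance is strictly
solvable. `make_tables` emits fixture-shaped random tables with value
ranges matching the empirical spread of the real ones (ΔΔG means on
(−30, 40) kcal/mol, logIC50 on (−9, −4.5), ~5% missing entries with the
colchicine row always complete). None of the generators model
densitometry noise, plate-position effects, or correlated energy errors;
passing recovery tests therefore demonstrate correctness of the
inference machinery, not robustness to those real-data artefacts.

## Problem sizes and numerics

The full Case 1 grid (19 derivatives × 6 cell lines × 3 energy variants
× 100 restarts) solves in a few seconds; property gates run 1000 random
instances. Root solving uses xtol 1e-13 and validates the constraint
residual to 1e-8·max(1, |target|); posterior normalization is exact by
construction. Ties in classification break only through the tie
tolerance — there is no index-order dependence. Degenerate inputs
(all-zero expression rows, one-hot priors, constant responses, zero
calibration slope) raise typed errors rather than producing output.
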
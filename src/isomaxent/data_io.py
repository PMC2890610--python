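"""Readers, writers and transforms for the three study tables.

The analysis consumes three small tabular inputs, shipped with the package
as UTF-8 CSV fixtures:

* relative binding free energies (kcal/mol) of 20 colchicine derivatives
  against the six beta-tubulin isotype variants I, IIa, IIb, III, IVa, IVb,
  as "mean ± sd" cells (``table2_binding.csv``);
* logIC50 cytotoxicity values (log10 molar) of colchicine (D00) and its 20
  derivatives across six cancer cell lines, "mean ± se" with ``N/A``
  marking assays without sufficient data (``table4_logic50.csv``);
* densitometry-derived tubulin isotype expression fractions for five cell
  lines under three treatments (``table5_expression.csv``).

Because antibodies cannot always distinguish the IIa/IIb and IVa/IVb
sub-isotypes, the binding table can be collapsed onto coarser isotype
schemes by averaging sub-isotype energies; :func:`collapse_isotypes`
implements that reduction.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsotypeScheme",
    "COLLAPSED_4",
    "SPLIT_IV_5",
    "SPLIT_ALL_6",
    "BindingEnergyTable",
    "CytotoxicityTable",
    "ExpressionProfile",
    "TableParseError",
    "TableValidationError",
    "load_binding_energies",
    "load_cytotoxicity",
    "load_expression",
    "collapse_isotypes",
    "write_binding_energies",
    "write_cytotoxicity",
    "write_expression",
    "fixture_path",
    "load_study_tables",
]


class TableParseError(ValueError):
    """A cell of an input table could not be parsed."""


class TableValidationError(ValueError):
    """A parsed table violates a structural invariant."""


@dataclass(frozen=True)
class IsotypeScheme:
    """An ordered labelling of the beta-tubulin isotypes used as states.

    Three schemes occur in the analysis: the fully split six-isotype
    scheme native to the binding-energy computations, a five-isotype
    scheme where only IVa/IVb remain distinguishable, and the collapsed
    four-isotype scheme matching what the expression antibodies resolve.
    """

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise TableValidationError(f"duplicate isotype labels: {self.labels}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def groups(self) -> dict[str, tuple[str, ...]]:
        """Mapping of each label onto the six-isotype sub-labels it covers."""
        return {lab: _GROUPS.get(lab, (lab,)) for lab in self.labels}


COLLAPSED_4 = IsotypeScheme("collapsed_4", ("I", "II", "III", "IV"))
SPLIT_IV_5 = IsotypeScheme("split_iv_5", ("I", "II", "III", "IVa", "IVb"))
SPLIT_ALL_6 = IsotypeScheme("split_all_6", ("I", "IIa", "IIb", "III", "IVa", "IVb"))

SCHEMES = {s.name: s for s in (COLLAPSED_4, SPLIT_IV_5, SPLIT_ALL_6)}

_GROUPS = {"II": ("IIa", "IIb"), "IV": ("IVa", "IVb")}


def _parse_pm_cell(text: str, *, row: str, col: str) -> tuple[float, float]:
    """Parse a ``"mean ± sd"`` cell, splitting at the first ``±``."""
    if "±" not in text:
        raise TableParseError(f"cell ({row}, {col}) = {text!r}: missing '±'")
    left, _, right = text.partition("±")
    try:
        return float(left.strip()), float(right.strip())
    except ValueError as exc:
        raise TableParseError(f"cell ({row}, {col}) = {text!r}: non-numeric") from exc


def _read_delimited(source: str | Path) -> pd.DataFrame:
    path = Path(source)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


@dataclass
class BindingEnergyTable:
    """Derivative x isotype matrix of relative binding free energies.

    ``mean`` and ``sd`` are DataFrames indexed by derivative id with the
    scheme labels as columns, in kcal/mol. Values are differences relative
    to colchicine for the same isotype (thermodynamic-cycle estimates).
    """

    derivatives: list[str]
    scheme: IsotypeScheme
    mean: pd.DataFrame
    sd: pd.DataFrame

    def __post_init__(self) -> None:
        shape = (len(self.derivatives), len(self.scheme))
        for name, df in (("mean", self.mean), ("sd", self.sd)):
            if df.shape != shape:
                raise TableValidationError(
                    f"{name} has shape {df.shape}, expected {shape}"
                )
        if (self.sd.to_numpy() < 0).any():
            raise TableValidationError("negative sd in binding-energy table")
        if np.isnan(self.mean.to_numpy()).any() or np.isnan(self.sd.to_numpy()).any():
            raise TableValidationError("missing cells in binding-energy table")

    def row(self, derivative: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (mean, sd) vectors for one derivative, scheme-ordered."""
        return (
            self.mean.loc[derivative].to_numpy(dtype=float),
            self.sd.loc[derivative].to_numpy(dtype=float),
        )

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme.name,
            "labels": list(self.scheme.labels),
            "derivatives": self.derivatives,
            "mean": self.mean.to_numpy().tolist(),
            "sd": self.sd.to_numpy().tolist(),
        }


@dataclass
class CytotoxicityTable:
    """Compound x cell-line matrix of logIC50 (log10 molar) with missing cells.

    Missing entries are NaN in both ``logic50`` and ``se``; they are never
    imputed. D00 denotes colchicine itself.
    """

    compounds: list[str]
    cell_lines: list[str]
    logic50: pd.DataFrame
    se: pd.DataFrame

    def __post_init__(self) -> None:
        lic = self.logic50.to_numpy(dtype=float)
        se = self.se.to_numpy(dtype=float)
        if not (np.isnan(lic) == np.isnan(se)).all():
            raise TableValidationError("se present/missing does not match logIC50")
        if (lic[~np.isnan(lic)] >= 0).any():
            warnings.warn(
                "logIC50 values >= 0 found (concentration >= 1 M)", stacklevel=2
            )

    def value(self, compound: str, cell_line: str) -> float:
        """logIC50 for one (compound, cell line); NaN when not measured."""
        return float(self.logic50.loc[compound, cell_line])

    def is_missing(self, compound: str, cell_line: str) -> bool:
        return bool(np.isnan(self.logic50.loc[compound, cell_line]))

    def measured_compounds(self) -> list[str]:
        """Compounds with at least one non-missing logIC50 (drops e.g. D14)."""
        keep = self.logic50.notna().any(axis=1)
        return [c for c in self.compounds if keep[c]]

    def to_json_dict(self) -> dict:
        def cell(v: float) -> float | None:
            return None if np.isnan(v) else float(v)

        return {
            "compounds": self.compounds,
            "cell_lines": self.cell_lines,
            "logic50": [[cell(v) for v in row] for row in self.logic50.to_numpy()],
            "se": [[cell(v) for v in row] for row in self.se.to_numpy()],
        }


@dataclass
class ExpressionProfile:
    """Normalized tubulin isotype expression fractions for one condition.

    ``fractions`` sums to 1 (within 1e-9) over ``scheme.labels``; the raw
    densitometry sum before renormalization is kept in ``raw_sum`` for
    provenance.
    """

    cell_line: str
    treatment: str
    scheme: IsotypeScheme
    fractions: np.ndarray
    raw_sum: float = 1.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.scheme),):
            raise TableValidationError(
                f"{self.cell_line}/{self.treatment}: expected "
                f"{len(self.scheme)} fractions, got {self.fractions.shape}"
            )
        if (self.fractions < 0).any():
            raise TableValidationError(
                f"{self.cell_line}/{self.treatment}: negative fraction"
            )
        total = self.fractions.sum()
        if total <= 0:
            raise TableValidationError(
                f"{self.cell_line}/{self.treatment}: fractions sum to {total}"
            )
        if abs(total - 1.0) > 1e-9:
            raise TableValidationError(
                f"{self.cell_line}/{self.treatment}: fractions sum to {total}, "
                "renormalize before constructing the profile"
            )

    @classmethod
    def from_raw(
        cls,
        cell_line: str,
        treatment: str,
        scheme: IsotypeScheme,
        raw: Sequence[float],
    ) -> "ExpressionProfile":
        """Build a profile from raw fractions, renormalizing to sum 1."""
        raw = np.asarray(raw, dtype=float)
        if (raw < 0).any():
            raise TableValidationError(f"{cell_line}/{treatment}: negative fraction")
        total = raw.sum()
        if total <= 0:
            raise TableValidationError(
                f"{cell_line}/{treatment}: degenerate all-zero expression row"
            )
        return cls(cell_line, treatment, scheme, raw / total, raw_sum=float(total))

    def floored(self, eps: float) -> "ExpressionProfile":
        """Replace zero fractions by ``eps`` and renormalize.

        Exact zeros (as in the MCF-7 and CEM rows) would freeze an isotype
        at zero weight for every downstream exponential tilt and make the
        reference-energy logarithm undefined, so a small floor is applied
        before any maximum-entropy step that takes logs of the prior.
        """
        if eps <= 0:
            raise ValueError("floor must be positive")
        floored = np.maximum(self.fractions, eps)
        return ExpressionProfile(
            self.cell_line,
            self.treatment,
            self.scheme,
            floored / floored.sum(),
            raw_sum=self.raw_sum,
        )

    def split(self, scheme: IsotypeScheme) -> "ExpressionProfile":
        """Map a collapsed profile onto a finer scheme by half/half splitting.

        Expression assays resolve only I, II, III, IV; when sub-isotypes
        IIa/IIb or IVa/IVb are modelled as distinct states, each receives
        half of the measured fraction of its parent isotype.
        """
        if scheme is self.scheme or scheme == self.scheme:
            return self
        if self.scheme != COLLAPSED_4:
            raise TableValidationError("can only split a collapsed 4-isotype profile")
        out = np.empty(len(scheme))
        for j, lab in enumerate(scheme.labels):
            if lab in self.scheme.labels:
                out[j] = self.fractions[self.scheme.index(lab)]
            else:
                parent = lab[:-1]  # IIa -> II, IVb -> IV
                out[j] = self.fractions[self.scheme.index(parent)] / 2.0
        return ExpressionProfile(
            self.cell_line, self.treatment, scheme, out, raw_sum=self.raw_sum
        )

    def to_json_dict(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "treatment": self.treatment,
            "scheme": self.scheme.name,
            "labels": list(self.scheme.labels),
            "fractions": self.fractions.tolist(),
            "raw_sum": self.raw_sum,
        }


def load_binding_energies(source: str | Path) -> BindingEnergyTable:
    """Load the derivative x isotype binding free-energy table.

    The file must carry a header naming the six isotype variants and
    ``mean ± sd`` cells; returns a table in the fully split scheme.
    """
    df = _read_delimited(source)
    key = df.columns[0]
    labels = tuple(c.strip() for c in df.columns[1:])
    if labels != SPLIT_ALL_6.labels:
        raise TableValidationError(
            f"expected isotype columns {SPLIT_ALL_6.labels}, found {labels}"
        )
    derivatives = [str(v).strip() for v in df[key]]
    if len(set(derivatives)) != len(derivatives):
        raise TableValidationError("duplicate derivative id in binding-energy table")
    mean = np.empty((len(derivatives), len(labels)))
    sd = np.empty_like(mean)
    for i, (_, r) in enumerate(df.iterrows()):
        for j, col in enumerate(df.columns[1:]):
            mean[i, j], sd[i, j] = _parse_pm_cell(
                str(r[col]), row=derivatives[i], col=labels[j]
            )
    return BindingEnergyTable(
        derivatives,
        SPLIT_ALL_6,
        pd.DataFrame(mean, index=derivatives, columns=list(labels)),
        pd.DataFrame(sd, index=derivatives, columns=list(labels)),
    )


def load_cytotoxicity(source: str | Path, *, na_marker: str = "N/A") -> CytotoxicityTable:
    """Load the compound x cell-line logIC50 table; ``N/A`` marks missing."""
    df = _read_delimited(source)
    key = df.columns[0]
    cell_lines = [c.strip() for c in df.columns[1:]]
    compounds = [str(v).strip() for v in df[key]]
    if len(set(compounds)) != len(compounds):
        raise TableValidationError("duplicate compound id in cytotoxicity table")
    lic = np.full((len(compounds), len(cell_lines)), np.nan)
    se = np.full_like(lic, np.nan)
    for i, (_, r) in enumerate(df.iterrows()):
        for j, col in enumerate(df.columns[1:]):
            text = str(r[col]).strip()
            if text == na_marker or not text:
                continue
            lic[i, j], se[i, j] = _parse_pm_cell(
                text, row=compounds[i], col=cell_lines[j]
            )
    return CytotoxicityTable(
        compounds,
        cell_lines,
        pd.DataFrame(lic, index=compounds, columns=cell_lines),
        pd.DataFrame(se, index=compounds, columns=cell_lines),
    )


def load_expression(source: str | Path) -> list[ExpressionProfile]:
    """Load expression profiles, one per (cell line, treatment) row.

    Rows are renormalized to sum exactly 1; the raw densitometry sum is
    kept on each profile.
    """
    df = _read_delimited(source)
    cols = [c.strip() for c in df.columns]
    expected = ["cell_line", "treatment", *COLLAPSED_4.labels]
    if cols != expected:
        raise TableValidationError(f"expected columns {expected}, found {cols}")
    profiles = []
    for _, r in df.iterrows():
        try:
            raw = [float(r[c]) for c in df.columns[2:]]
        except ValueError as exc:
            raise TableParseError(
                f"row ({r[df.columns[0]]}, {r[df.columns[1]]}): non-numeric fraction"
            ) from exc
        profiles.append(
            ExpressionProfile.from_raw(
                str(r[df.columns[0]]).strip(),
                str(r[df.columns[1]]).strip(),
                COLLAPSED_4,
                raw,
            )
        )
    return profiles


_COLLAPSE_ALLOWED = {
    SPLIT_ALL_6.name: (COLLAPSED_4, SPLIT_IV_5, SPLIT_ALL_6),
    SPLIT_IV_5.name: (COLLAPSED_4, SPLIT_IV_5),
    COLLAPSED_4.name: (COLLAPSED_4,),
}


def collapse_isotypes(
    table: BindingEnergyTable,
    scheme: IsotypeScheme,
    *,
    sd_rule: str = "quadrature",
) -> BindingEnergyTable:
    """Collapse sub-isotype columns onto a coarser scheme by averaging.

    The collapsed mean for II (resp. IV) is the arithmetic mean of IIa and
    IIb (resp. IVa and IVb). The collapsed sd treats the two sub-isotype
    estimates as independent: ``sqrt(sd_a**2 + sd_b**2) / 2`` (``sd_rule=
    "quadrature"``), with ``"max"`` as a conservative alternative.
    Requesting a scheme finer than the source raises.
    """
    if scheme == table.scheme:
        return table
    if scheme not in _COLLAPSE_ALLOWED[table.scheme.name]:
        raise TableValidationError(
            f"cannot refine {table.scheme.name} into {scheme.name}"
        )
    if sd_rule not in {"quadrature", "max"}:
        raise ValueError(f"unknown sd_rule {sd_rule!r}")
    mean = np.empty((len(table.derivatives), len(scheme)))
    sd = np.empty_like(mean)
    for j, lab in enumerate(scheme.labels):
        subs = [s for s in _GROUPS.get(lab, (lab,)) if s in table.scheme.labels]
        if not subs:  # label present verbatim in the source scheme
            subs = [lab]
        cols_m = table.mean[subs].to_numpy()
        cols_s = table.sd[subs].to_numpy()
        mean[:, j] = cols_m.mean(axis=1)
        if len(subs) == 1:
            sd[:, j] = cols_s[:, 0]
        elif sd_rule == "quadrature":
            sd[:, j] = np.sqrt((cols_s**2).sum(axis=1)) / len(subs)
        else:
            sd[:, j] = cols_s.max(axis=1)
    idx = list(table.derivatives)
    return BindingEnergyTable(
        idx,
        scheme,
        pd.DataFrame(mean, index=idx, columns=list(scheme.labels)),
        pd.DataFrame(sd, index=idx, columns=list(scheme.labels)),
    )


def _fmt(v: float) -> str:
    return repr(float(v))


def write_binding_energies(table: BindingEnergyTable, path: str | Path) -> None:
    """Write a binding table as ``mean ± sd`` CSV (round-trips exactly)."""
    rows = []
    for d in table.derivatives:
        m, s = table.row(d)
        rows.append([d] + [f"{_fmt(mi)} ± {_fmt(si)}" for mi, si in zip(m, s)])
    pd.DataFrame(rows, columns=["derivative", *table.scheme.labels]).to_csv(
        path, index=False
    )


def write_cytotoxicity(table: CytotoxicityTable, path: str | Path) -> None:
    rows = []
    for c in table.compounds:
        row = [c]
        for cl in table.cell_lines:
            v = table.logic50.loc[c, cl]
            s = table.se.loc[c, cl]
            row.append("N/A" if np.isnan(v) else f"{_fmt(v)} ± {_fmt(s)}")
        rows.append(row)
    pd.DataFrame(rows, columns=["compound", *table.cell_lines]).to_csv(
        path, index=False
    )


def write_expression(profiles: Iterable[ExpressionProfile], path: str | Path) -> None:
    """Write profiles back to CSV, de-normalizing to the raw sums."""
    rows = []
    labels = None
    for p in profiles:
        labels = p.scheme.labels
        raw = p.fractions * p.raw_sum
        rows.append([p.cell_line, p.treatment, *[_fmt(v) for v in raw]])
    pd.DataFrame(rows, columns=["cell_line", "treatment", *labels]).to_csv(
        path, index=False
    )


def write_json(obj, path: str | Path) -> None:
    """Serialize any of the table types (or lists of them) to JSON."""

    def default(o):
        if hasattr(o, "to_json_dict"):
            return o.to_json_dict()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def fixture_path(name: str) -> Path:
    """Path of a packaged data fixture, e.g. ``table2_binding.csv``."""
    return Path(resources.files("isomaxent") / "data" / name)


def load_study_tables() -> tuple[
    BindingEnergyTable, CytotoxicityTable, list[ExpressionProfile]
]:
    """Load the three packaged study tables."""
    return (
        load_binding_energies(fixture_path("table2_binding.csv")),
        load_cytotoxicity(fixture_path("table4_logic50.csv")),
        load_expression(fixture_path("table5_expression.csv")),
    )
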
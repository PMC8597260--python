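"""Delimited-text and JSON I/O for methylation classification artifacts.

The on-disk dialects are deliberately plain:

* **Beta matrices** — TSV/CSV with one header row and one ID column, CpGs as
  rows and samples as columns by default (the layout of GEO series-matrix
  tables for 450K arrays); an orientation flag handles the transpose.
* **Sample sheets** — TSV/CSV with a ``sample_id`` column and a ``status``
  column restricted to the three-level smoking vocabulary
  ``current`` / ``former`` / ``never``.
* **Score models** — two-column tables of (CpG ID, weight), with an optional
  intercept row flagged by the reserved ID ``(Intercept)``.
* **Reports** — JSON is canonical (floats at full precision, so read-back is
  bit-exact); a sibling human-readable rendering shows 6 significant digits.

Delimiters are auto-detected from the extension: ``.csv`` means comma,
anything else means tab.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

SMOKING_CLASSES = ("current", "former", "never")
INTERCEPT_ID = "(Intercept)"

#: values outside [0, 1] by no more than this are clamped on read
BETA_TOLERANCE = 1e-9


def _sep_for(path: str | Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """CpG × sample matrix of methylation fractions (beta values).

    ``values`` is indexed by CpG ID with one column per sample ID.  All
    non-missing entries lie in [0, 1]; NaN marks a missing measurement (real
    450K exports contain them), and downstream scoring decides the policy.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("beta matrix is empty")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate CpG ID: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        arr = df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.isinf(arr) | (arr < -BETA_TOLERANCE) | (arr > 1 + BETA_TOLERANCE)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1]: {arr[i, j]!r} at "
                f"CpG {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        # clamp the 1e-9 numerical fringe; normalize axis labels
        np.clip(arr, 0.0, 1.0, out=arr)
        self.values = pd.DataFrame(
            arr,
            index=pd.Index([str(i) for i in df.index]),
            columns=pd.Index([str(c) for c in df.columns]),
        )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)[:5]}")
        return BetaMatrix(self.values.loc[:, list(sample_ids)])


def read_beta_matrix(path: str | Path, orientation: str = "cpg_rows") -> BetaMatrix:
    """Read a delimited beta matrix.

    Parameters
    ----------
    path
        TSV or CSV file with one header row and a leading ID column.
    orientation
        ``"cpg_rows"`` if rows are CpGs (GEO series-matrix layout), or
        ``"sample_rows"`` if rows are samples; the latter is transposed on
        read so the in-memory object is always CpG × sample.
    """
    if orientation not in ("cpg_rows", "sample_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    # locate non-numeric cells before coercion so the error carries coordinates
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at row {row!r}, column {col!r}"
                )
            df[col] = coerced
    if orientation == "sample_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return BetaMatrix(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, orientation: str = "cpg_rows"
) -> None:
    """Write a beta matrix as delimited text (values at 6 significant digits)."""
    if orientation not in ("cpg_rows", "sample_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = beta.values if orientation == "cpg_rows" else beta.values.T
    df.to_csv(path, sep=_sep_for(path), float_format="%.6g", index_label="id")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Per-sample self-reported smoking status plus optional covariates.

    ``table`` is indexed by sample ID and must carry a ``status`` column with
    values from :data:`SMOKING_CLASSES`.  Extra columns (age, sex, study) ride
    along untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "status" not in df.columns:
            raise ValidationError("sample sheet lacks a 'status' column")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        bad = set(df["status"]) - set(SMOKING_CLASSES)
        if bad:
            raise ValidationError(
                f"unknown smoking status values: {sorted(bad)} "
                f"(expected one of {SMOKING_CLASSES})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def status(self) -> pd.Series:
        """Per-sample status, indexed by sample ID."""
        return self.table["status"]

    def binary_labels(self, task: str) -> pd.Series:
        """Map ternary status to a boolean case indicator for one stage.

        ``task="ever_never"`` marks current∪former as cases over all samples;
        ``task="current_former"`` marks current as cases and restricts to
        self-reported ever smokers.
        """
        s = self.table["status"]
        if task == "ever_never":
            return s.isin(["current", "former"])
        if task == "current_former":
            ever = s[s.isin(["current", "former"])]
            return ever == "current"
        raise ValueError(f"unknown task: {task!r}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    try:
        return SampleSheet(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


# ---------------------------------------------------------------------------
# ScoreModel
# ---------------------------------------------------------------------------

@dataclass
class ScoreModel:
    """A weighted-CpG methylation classification score.

    The score of a sample is ``intercept + Σ_j weight_j · beta(cpg_j)``: the
    classical weighted-sum construction used for DNAm smoking scores.  The
    single-CpG AHRR-style model is the degenerate case of one unit-weight
    term.  Weights apply to beta values on the 0–1 scale.
    """

    name: str
    terms: list[tuple[str, float]]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError(f"score model {self.name!r} has no terms")
        seen: set[str] = set()
        for cpg, w in self.terms:
            if cpg in seen:
                raise ValidationError(f"duplicate CpG in model {self.name!r}: {cpg!r}")
            seen.add(cpg)
            if not math.isfinite(w):
                raise ValidationError(f"non-finite weight for {cpg!r} in {self.name!r}")
        if not math.isfinite(self.intercept):
            raise ValidationError(f"non-finite intercept in {self.name!r}")

    @property
    def cpg_ids(self) -> list[str]:
        return [c for c, _ in self.terms]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "terms": [{"cpg_id": c, "weight": w} for c, w in self.terms],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreModel":
        try:
            return cls(
                name=d["name"],
                terms=[(t["cpg_id"], float(t["weight"])) for t in d["terms"]],
                intercept=float(d.get("intercept", 0.0)),
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed score-model record: {exc}") from exc


def read_score_model(path: str | Path, name: str | None = None) -> ScoreModel:
    """Read a two-column (cpg_id, weight) table; ``(Intercept)`` row optional."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cpg_id, weight)")
    cpg_col, w_col = df.columns[:2]
    if df[w_col].isna().any():
        row = df[cpg_col][df[w_col].isna().to_numpy().argmax()]
        raise FormatError(f"{path}: missing weight for {row!r}")
    weights = pd.to_numeric(df[w_col], errors="coerce")
    if weights.isna().any():
        row = df[cpg_col][weights.isna().to_numpy().argmax()]
        raise FormatError(f"{path}: non-numeric weight for {row!r}")
    intercept = 0.0
    terms: list[tuple[str, float]] = []
    for cpg, w in zip(df[cpg_col].astype(str), weights):
        if cpg == INTERCEPT_ID:
            intercept = float(w)
        else:
            terms.append((cpg, float(w)))
    try:
        return ScoreModel(name or Path(path).stem, terms, intercept)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_score_model(model: ScoreModel, path: str | Path) -> None:
    sep = _sep_for(path)
    rows = [{"cpg_id": c, "weight": w} for c, w in model.terms]
    if model.intercept != 0.0:
        rows.append({"cpg_id": INTERCEPT_ID, "weight": model.intercept})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _render_human(obj, indent: int = 0) -> list[str]:
    pad = "  " * indent
    lines: list[str] = []
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            if isinstance(v, (Mapping, list)):
                lines.append(f"{pad}{k}:")
                lines.extend(_render_human(v, indent + 1))
            else:
                lines.append(f"{pad}{k}: {_fmt(v)}")
    elif isinstance(obj, list):
        for v in obj:
            if isinstance(v, (Mapping, list)):
                lines.extend(_render_human(v, indent + 1))
            else:
                lines.append(f"{pad}- {_fmt(v)}")
    else:
        lines.append(f"{pad}{_fmt(obj)}")
    return lines


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_report(report: Mapping, path: str | Path, human: bool = True) -> None:
    """Write an evaluation report as JSON (canonical) plus a .txt rendering.

    The JSON file serializes floats at full precision so a read-back
    reproduces every field bit-exactly; the text rendering rounds to six
    significant digits for the eyeball.
    """
    path = Path(path)
    if hasattr(report, "to_dict"):
        report = report.to_dict()  # type: ignore[union-attr]
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=True)
        fh.write("\n")
    if human:
        txt = path.with_suffix(path.suffix + ".txt")
        with open(txt, "w") as fh:
            fh.write("\n".join(_render_human(report)) + "\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
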
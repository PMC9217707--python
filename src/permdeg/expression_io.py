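"""Readers and writers for expression matrices, design tables, gene lists
and per-gene results tables.

All on-disk formats are plain delimited text (tab by default):

* expression matrix — header ``gene_id<TAB><sample>...``, one numeric row
  per gene (FPKM-like or normalized-intensity values, all ≥ 0);
* design table — ``sample_id<TAB>subject<TAB>condition`` for the paired
  overexpression/knockdown design (condition vocabulary ``OE``,
  ``OE_control``, ``KD``, ``KD_control``) or ``sample_id<TAB>group`` with
  vocabulary ``case``/``control`` for the unpaired design;
* gene list — one symbol per line, optional second column ``up``/``down``;
* results table — the fixed column order written by
  :func:`write_results_table`.

Gene identifiers are canonicalized (upper-cased, whitespace-stripped) on
input; duplicate rows that collapse to the same identifier are averaged,
the usual probe-collapse convention.  Missing values are rejected rather
than imputed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "FormatError",
    "ValidationError",
    "DesignError",
    "VocabularyError",
    "PAIRED_ROLES",
    "UNPAIRED_GROUPS",
    "RESULT_COLUMNS",
    "canonicalize_gene_id",
    "ExpressionMatrix",
    "PairedDesign",
    "UnpairedDesign",
    "GeneList",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_gene_list",
    "write_gene_list",
    "read_results_table",
    "write_results_table",
]

#: Condition vocabulary of the paired perturbation design: overexpression,
#: its vector control, knockdown, and its scrambled-siRNA control.
PAIRED_ROLES = ("OE", "OE_control", "KD", "KD_control")

#: Group vocabulary of the unpaired case/control design.
UNPAIRED_GROUPS = ("case", "control")

#: Fixed column order of a per-gene results table.
RESULT_COLUMNS = ("gene_id", "T", "log2FC", "Pt", "Pf", "is_deg", "direction")


class ParseError(ValueError):
    """A cell could not be parsed as a number, or is missing."""


class FormatError(ValueError):
    """Structural problem with a table (duplicate headers, missing columns)."""


class ValidationError(ValueError):
    """Values violate an invariant (negative, non-finite, empty)."""


class DesignError(ValueError):
    """A design table is incomplete or inconsistent."""


class VocabularyError(DesignError):
    """A condition/group token is outside the accepted vocabulary."""


def canonicalize_gene_id(gene_id: str) -> str:
    """Canonical form of a gene identifier: stripped and upper-cased."""
    return str(gene_id).strip().upper()


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative gene-by-sample expression values.

    Wraps a :class:`pandas.DataFrame` whose index holds canonical gene
    identifiers and whose columns hold sample identifiers.  Construct
    directly from a validated frame, or via :meth:`from_dataframe` which
    canonicalizes identifiers and collapses duplicate gene rows by mean.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("expression matrix must be non-empty")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build a matrix from a raw frame, canonicalizing gene identifiers
        and collapsing duplicate rows by mean."""
        df = df.astype(float).copy()
        df.index = [canonicalize_gene_id(g) for g in df.index]
        if df.index.has_duplicates:
            # groupby(sort=False) keeps first-occurrence order
            df = df.groupby(level=0, sort=False).mean()
        df.index.name = "gene_id"
        return cls(df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same gene/sample labels, new value array."""
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        )

    def columns(self, sample_ids: list[str]) -> np.ndarray:
        """Value block for the given samples (genes × samples), with a
        design-aware error for missing samples."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DesignError(f"samples referenced by design absent from matrix: {missing}")
        return self.data[sample_ids].to_numpy(dtype=float)


@dataclasses.dataclass(frozen=True)
class PairedDesign:
    """Paired overexpression/knockdown design: per subject, one sample for
    each of the four roles OE, OE_control, KD, KD_control."""

    assignments: Mapping[str, Mapping[str, str]]  # subject -> role -> sample_id

    def __post_init__(self) -> None:
        if len(self.assignments) < 2:
            raise DesignError("paired design requires at least 2 subjects")
        seen: set[str] = set()
        for subject, roles in self.assignments.items():
            for role in PAIRED_ROLES:
                if role not in roles:
                    raise DesignError(f"subject {subject!r} is missing role {role!r}")
            extra = set(roles) - set(PAIRED_ROLES)
            if extra:
                raise VocabularyError(
                    f"subject {subject!r} has unknown condition token(s) {sorted(extra)}"
                )
            for role in PAIRED_ROLES:
                sample = roles[role]
                if sample in seen:
                    raise DesignError(f"sample {sample!r} assigned more than once")
                seen.add(sample)

    @property
    def subjects(self) -> list[str]:
        return list(self.assignments)

    @property
    def n_subjects(self) -> int:
        return len(self.assignments)

    def sample_ids(self) -> list[str]:
        return [self.assignments[s][r] for s in self.subjects for r in PAIRED_ROLES]

    def role_samples(self, role: str) -> list[str]:
        """Samples holding `role`, in subject order."""
        if role not in PAIRED_ROLES:
            raise VocabularyError(f"unknown role {role!r}")
        return [self.assignments[s][role] for s in self.subjects]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        matrix.columns(self.sample_ids())


@dataclasses.dataclass(frozen=True)
class UnpairedDesign:
    """Case/control design for a two-group comparison."""

    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise DesignError("each group needs at least 2 samples")
        if set(self.case_samples) & set(self.control_samples):
            raise DesignError("case and control groups overlap")
        if len(set(self.case_samples)) != len(self.case_samples) or len(
            set(self.control_samples)
        ) != len(self.control_samples):
            raise DesignError("duplicate sample in a group")

    def sample_ids(self) -> list[str]:
        return list(self.case_samples) + list(self.control_samples)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        matrix.columns(self.sample_ids())


@dataclasses.dataclass(frozen=True)
class GeneList:
    """Ordered set of canonical gene identifiers with optional up/down tags."""

    genes: tuple[str, ...]
    directions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        canonical = tuple(canonicalize_gene_id(g) for g in self.genes)
        object.__setattr__(self, "genes", canonical)
        if len(set(canonical)) != len(canonical):
            raise ValidationError("duplicate genes in gene list")
        if self.directions is not None:
            dirs = {canonicalize_gene_id(g): d for g, d in self.directions.items()}
            missing = [g for g in canonical if g not in dirs]
            if missing:
                raise ValidationError(f"direction tags missing for {missing[:5]}")
            bad = {d for d in dirs.values() if d not in ("up", "down")}
            if bad:
                raise VocabularyError(f"unknown direction token(s) {sorted(bad)}")
            object.__setattr__(self, "directions", dirs)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a gene-by-sample matrix from delimited text.

    First column: gene identifiers; header row: sample identifiers.
    Raises :class:`FormatError` on duplicate sample headers,
    :class:`ParseError` on a non-numeric or missing cell (naming the cell),
    and :class:`ValidationError` on negative values.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"duplicate sample header(s): {dups}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    for col in df.columns:
        series = df[col]
        if not np.issubdtype(series.dtype, np.number):
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if bad.any():
                gene = series.index[bad][0]
                raise ParseError(
                    f"non-numeric value {series[bad].iloc[0]!r} at gene "
                    f"{gene!r}, sample {col!r}"
                )
            df[col] = coerced
    if df.isna().any().any():
        mask = df.isna().to_numpy()
        g, s = np.argwhere(mask)[0]
        raise ParseError(
            f"missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return ExpressionMatrix.from_dataframe(df)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix as delimited text with 6 significant digits."""
    matrix.data.to_csv(path, sep=delimiter, index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# design tables


def read_design(
    path: str | Path, kind: str, delimiter: str = "\t"
) -> PairedDesign | UnpairedDesign:
    """Read a sample design table.

    ``kind="paired"`` expects columns (sample_id, subject, condition) with
    condition vocabulary OE/OE_control/KD/KD_control.  ``kind="unpaired"``
    expects (sample_id, group) — or (sample_id, subject, condition) with the
    subject column ignored — with vocabulary case/control.  Parsing is
    invariant to row order.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if kind == "paired":
        for col in ("sample_id", "subject", "condition"):
            if col not in df.columns:
                raise FormatError(f"paired design table is missing column {col!r}")
        assignments: dict[str, dict[str, str]] = {}
        for _, row in df.sort_values(["subject", "condition"]).iterrows():
            condition = row["condition"].strip()
            if condition not in PAIRED_ROLES:
                raise VocabularyError(f"unknown condition token {condition!r}")
            roles = assignments.setdefault(row["subject"].strip(), {})
            if condition in roles:
                raise DesignError(
                    f"subject {row['subject']!r} has more than one {condition!r} sample"
                )
            roles[condition] = row["sample_id"].strip()
        return PairedDesign(assignments)
    if kind == "unpaired":
        if "group" in df.columns:
            group_col = "group"
        elif "condition" in df.columns:
            group_col = "condition"
        else:
            raise FormatError("unpaired design table needs a 'group' or 'condition' column")
        if "sample_id" not in df.columns:
            raise FormatError("unpaired design table is missing column 'sample_id'")
        case, control = [], []
        for _, row in df.iterrows():
            token = row[group_col].strip()
            if token == "case":
                case.append(row["sample_id"].strip())
            elif token == "control":
                control.append(row["sample_id"].strip())
            else:
                raise VocabularyError(f"unknown group token {token!r}")
        return UnpairedDesign(tuple(sorted(case)), tuple(sorted(control)))
    raise ValueError(f"kind must be 'paired' or 'unpaired', got {kind!r}")


def write_design(
    design: PairedDesign | UnpairedDesign, path: str | Path, delimiter: str = "\t"
) -> None:
    rows = []
    if isinstance(design, PairedDesign):
        for subject in design.subjects:
            for role in PAIRED_ROLES:
                rows.append((design.assignments[subject][role], subject, role))
        df = pd.DataFrame(rows, columns=["sample_id", "subject", "condition"])
    else:
        for s in design.case_samples:
            rows.append((s, "case"))
        for s in design.control_samples:
            rows.append((s, "control"))
        df = pd.DataFrame(rows, columns=["sample_id", "group"])
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(path: str | Path, delimiter: str = "\t") -> GeneList:
    genes: list[str] = []
    directions: dict[str, str] = {}
    tagged = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split(delimiter)
            genes.append(parts[0])
            if len(parts) > 1 and parts[1]:
                tagged = True
                directions[parts[0]] = parts[1].strip()
    return GeneList(tuple(genes), directions if tagged else None)


def write_gene_list(gene_list: GeneList, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for gene in gene_list.genes:
            if gene_list.directions is not None:
                fh.write(f"{gene}{delimiter}{gene_list.directions[gene]}\n")
            else:
                fh.write(f"{gene}\n")


# ---------------------------------------------------------------------------
# results tables


def write_results_table(stats: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write a per-gene results table with the fixed column order
    (gene_id, T, log2FC, Pt, Pf, is_deg, direction), 6 significant digits."""
    if stats is None or len(stats) == 0:
        raise ValidationError("results table must contain at least one gene")
    missing = [c for c in RESULT_COLUMNS if c not in stats.columns]
    if missing:
        raise FormatError(f"results table is missing column(s) {missing}")
    out = stats.loc[:, list(RESULT_COLUMNS)].copy()
    out["is_deg"] = out["is_deg"].astype(bool)
    out.to_csv(path, sep=delimiter, index=False, float_format="%.6g")


def read_results_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results table is missing column(s) {missing}")
    df["is_deg"] = df["is_deg"].astype(str).str.lower().map({"true": True, "false": False})
    if df["is_deg"].isna().any():
        raise ParseError("unparseable is_deg value in results table")
    df["gene_id"] = [canonicalize_gene_id(g) for g in df["gene_id"]]
    return df
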
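"""Relative quantification of qPCR assays by the 2^-ΔΔCt method.

Each sample contributes a cycle-threshold Ct for the target gene and for a
reference gene (study default 36B4/RPLP0); ΔCt = Ct_target - Ct_reference
removes loading differences, and

    ΔΔCt = mean ΔCt(treated) - mean ΔCt(control),   fold = 2^(-ΔΔCt)

gives the treated/control fold change assuming a doubling per cycle (no
efficiency correction).  Per-treated-sample fold changes against the
control-mean ΔCt are also returned for standard-error reporting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["QpcrError", "QuantificationResult", "read_ct_table", "fold_change_ddct", "fold_change_table"]

CT_COLUMNS = ("sample_id", "group", "gene", "ct")


class QpcrError(ValueError):
    """Malformed Ct table or empty comparison group."""


@dataclasses.dataclass
class QuantificationResult:
    target: str
    reference: str
    treated_group: str
    control_group: str
    ddct: float
    fold_change: float
    per_sample_fold_change: pd.Series  # treated samples vs control-mean ΔCt
    se: float  # standard error of the per-sample fold changes


def read_ct_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a long-format Ct table (sample_id, group, gene, ct)."""
    df = pd.read_csv(path, sep=delimiter)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise QpcrError(f"Ct table is missing column(s) {missing}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if df["ct"].isna().any() or not np.isfinite(df["ct"]).all():
        raise QpcrError("Ct table contains missing or non-finite Ct values")
    return df.loc[:, list(CT_COLUMNS)]


def _delta_ct(ct: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Per-sample ΔCt = Ct_target - Ct_reference with the sample's group.
    Technical replicates (duplicate sample/gene rows) are averaged."""
    sub = ct.loc[ct["gene"].isin([target, reference])]
    pivot = sub.pivot_table(index=["sample_id", "group"], columns="gene", values="ct", aggfunc="mean")
    for gene in (target, reference):
        if gene not in pivot.columns or pivot[gene].isna().any():
            bad = (
                pivot.index.get_level_values("sample_id").tolist()
                if gene not in pivot.columns
                else pivot.index[pivot[gene].isna()].get_level_values("sample_id").tolist()
            )
            raise QpcrError(f"gene {gene!r} not measured for sample(s) {bad[:5]}")
    out = pivot.reset_index()
    out["delta_ct"] = out[target] - out[reference]
    return out[["sample_id", "group", "delta_ct"]]


def fold_change_ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str = "36B4",
    treated_group: str = "treated",
    control_group: str = "control",
) -> QuantificationResult:
    """2^-ΔΔCt fold change of `target` in the treated group vs control."""
    dct = _delta_ct(ct, target, reference)
    treated = dct.loc[dct["group"] == treated_group]
    control = dct.loc[dct["group"] == control_group]
    if treated.empty or control.empty:
        raise QpcrError(
            f"need at least one sample in each of {treated_group!r} and {control_group!r}"
        )
    control_mean = control["delta_ct"].mean()
    ddct = treated["delta_ct"].mean() - control_mean
    per_sample = pd.Series(
        np.exp2(-(treated["delta_ct"].to_numpy() - control_mean)),
        index=treated["sample_id"].to_numpy(),
        name=target,
    )
    se = float(per_sample.std(ddof=1) / np.sqrt(len(per_sample))) if len(per_sample) > 1 else float("nan")
    return QuantificationResult(
        target=target,
        reference=reference,
        treated_group=treated_group,
        control_group=control_group,
        ddct=float(ddct),
        fold_change=float(np.exp2(-ddct)),
        per_sample_fold_change=per_sample,
        se=se,
    )


def fold_change_table(
    ct: pd.DataFrame,
    reference: str = "36B4",
    treated_group: str = "treated",
    control_group: str = "control",
) -> pd.DataFrame:
    """Fold changes for every non-reference gene in a Ct table."""
    targets = sorted(set(ct["gene"]) - {reference})
    if not targets:
        raise QpcrError("no target genes besides the reference")
    rows = []
    for target in targets:
        res = fold_change_ddct(ct, target, reference, treated_group, control_group)
        rows.append((target, res.ddct, res.fold_change, res.se))
    return pd.DataFrame(rows, columns=["gene", "ddct", "fold_change", "se"])
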
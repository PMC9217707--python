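"""Permutation-based differential expression testing.

The paired test targets a crossed perturbation design: for each subject the
regulator is overexpressed (OE) against a vector control and knocked down
(KD) against an siRNA control.  Per subject s and gene g,

    OE_ratio(s,g) = (x_OE + eps) / (x_OE_control + eps)
    KD_ratio(s,g) = (x_KD + eps) / (x_KD_control + eps)

and the per-subject contrast d_s = log2 OE_ratio - log2 KD_ratio feeds a
paired t-statistic T = mean(d) / (sd(d)/sqrt(n)) and a log2 fold change
log2FC = mean(d).  A gene the regulator induces has d > 0 in every subject
(up under OE, down under KD), so the ratio-of-ratios doubles the signal
while the pairing removes subject effects.

Significance comes from empirical nulls: the condition labels are permuted
(by default the four role labels are shuffled independently within each
subject, preserving the pairing structure), T and log2FC are recomputed
for every gene, and the values are pooled across permutations *and* genes
into one null per statistic.  Two-sided empirical p-values carry the
plus-one correction,

    p = (1 + #{ |v| >= |obs| }) / (1 + N).

Genes with Pt <= 0.05 and Pf <= 0.10 (inclusive, defaults) are called
differentially expressed, directed by the sign of log2FC.

The unpaired variant runs an equal-variance two-sample t-test on
log2(x + eps) between case and control groups, with group labels shuffled
across all samples for the null.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import warnings
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .expression_io import (
    DesignError,
    ExpressionMatrix,
    PAIRED_ROLES,
    PairedDesign,
    UnpairedDesign,
)

__all__ = [
    "StatisticUndefinedError",
    "DEGThresholds",
    "RatioTable",
    "NullDistribution",
    "DEGSet",
    "PairedDEGResult",
    "UnpairedDEGResult",
    "compute_ratios",
    "paired_statistics",
    "unpaired_statistics",
    "count_distinct_permutations",
    "build_null",
    "empirical_pvalue",
    "attach_pvalues",
    "annotate_calls",
    "call_degs",
    "per_subject_concordance_report",
    "filter_low_expression",
    "run_paired_deg",
    "run_unpaired_deg",
]

logger = logging.getLogger(__name__)

# contrast coefficients over the role order (OE, OE_control, KD, KD_control):
# d = log2 OE - log2 OE_control - log2 KD + log2 KD_control
_CONTRAST = np.array([1.0, -1.0, -1.0, 1.0])


class StatisticUndefinedError(ValueError):
    """The requested statistic is undefined for this design (too few
    subjects/samples, or an empty null)."""


@dataclasses.dataclass(frozen=True)
class DEGThresholds:
    """Calling thresholds and permutation settings.

    pt_cutoff/pf_cutoff are inclusive upper bounds on the empirical
    p-values; n_permutations is the Monte-Carlo budget B; pseudocount is
    the linear-scale offset eps applied before ratios and logs.
    """

    pt_cutoff: float = 0.05
    pf_cutoff: float = 0.10
    n_permutations: int = 1000
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.pt_cutoff < 1 and 0 < self.pf_cutoff < 1):
            raise ValueError("p-value cutoffs must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclasses.dataclass
class RatioTable:
    """Per-subject OE and KD expression ratios (genes × subjects)."""

    gene_ids: list[str]
    subjects: list[str]
    oe_ratio: np.ndarray
    kd_ratio: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.gene_ids), len(self.subjects))
        if self.oe_ratio.shape != expected or self.kd_ratio.shape != expected:
            raise ValueError("ratio arrays must be genes × subjects")
        for name, arr in (("OE_ratio", self.oe_ratio), ("KD_ratio", self.kd_ratio)):
            if not np.isfinite(arr).all() or (arr <= 0).any():
                raise ValueError(f"{name} values must be finite and positive")

    @property
    def log2_contrast(self) -> np.ndarray:
        """d(s,g) = log2 OE_ratio - log2 KD_ratio, genes × subjects."""
        return np.log2(self.oe_ratio) - np.log2(self.kd_ratio)


@dataclasses.dataclass
class NullDistribution:
    """Pooled empirical null for one statistic.

    `values` holds the finite permuted statistics pooled across all genes
    and permutations; `n_dropped` counts non-finite (degenerate) permuted
    values excluded from the pool.
    """

    kind: Literal["T", "log2FC"]
    values: np.ndarray
    n_permutations: int
    n_genes: int
    seed: int | None = None
    n_dropped: int = 0
    _abs_sorted: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def abs_sorted(self) -> np.ndarray:
        if self._abs_sorted is None:
            self._abs_sorted = np.sort(np.abs(self.values))
        return self._abs_sorted


@dataclasses.dataclass
class DEGSet:
    """Genes called differentially expressed in one comparison."""

    label: str
    genes: pd.DataFrame  # columns: gene_id, direction
    thresholds: DEGThresholds

    @property
    def members(self) -> set[str]:
        return set(self.genes["gene_id"])

    def directions(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["direction"]))

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# observed statistics


def compute_ratios(
    matrix: ExpressionMatrix, design: PairedDesign, pseudocount: float = 1.0
) -> RatioTable:
    """Per-subject OE and KD ratios with pseudocount eps:
    (x_cond + eps) / (x_control + eps)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    oe = matrix.columns(design.role_samples("OE")) + pseudocount
    oe_ctl = matrix.columns(design.role_samples("OE_control")) + pseudocount
    kd = matrix.columns(design.role_samples("KD")) + pseudocount
    kd_ctl = matrix.columns(design.role_samples("KD_control")) + pseudocount
    return RatioTable(
        gene_ids=matrix.gene_ids,
        subjects=design.subjects,
        oe_ratio=oe / oe_ctl,
        kd_ratio=kd / kd_ctl,
    )


def _paired_t(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """T, log2FC and degeneracy flag from a genes × subjects contrast array.

    A gene with zero contrast variance gets T = 0 when the mean is also
    zero (the exact-null case) and T = NaN with degenerate=True otherwise.
    """
    n = d.shape[1]
    log2fc = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (sd / math.sqrt(n))
    zero_sd = sd == 0
    exact_null = zero_sd & (log2fc == 0)
    t[exact_null] = 0.0
    degenerate = zero_sd & ~exact_null
    t[degenerate] = np.nan
    return t, log2fc, degenerate


def paired_statistics(ratios: RatioTable) -> pd.DataFrame:
    """Per-gene paired t-statistic and log2 fold change from the
    OE-vs-KD ratio contrast."""
    if len(ratios.subjects) < 2:
        raise StatisticUndefinedError(
            "paired t-statistic requires at least 2 subjects"
        )
    t, log2fc, degenerate = _paired_t(ratios.log2_contrast)
    return pd.DataFrame(
        {
            "gene_id": ratios.gene_ids,
            "T": t,
            "log2FC": log2fc,
            "degenerate": degenerate,
        }
    )


def _two_sample_t(
    case: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal-variance two-sample t on pre-logged values (genes × samples)."""
    n1, n2 = case.shape[1], control.shape[1]
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    pooled_var = (
        (n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * control.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (np.sqrt(pooled_var) * math.sqrt(1 / n1 + 1 / n2))
    zero_sd = pooled_var == 0
    exact_null = zero_sd & (log2fc == 0)
    t[exact_null] = 0.0
    degenerate = zero_sd & ~exact_null
    t[degenerate] = np.nan
    return t, log2fc, degenerate


def unpaired_statistics(
    matrix: ExpressionMatrix, design: UnpairedDesign, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene equal-variance Student t and log2FC on log2(x + eps)
    between case and control groups."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if len(design.case_samples) < 2 or len(design.control_samples) < 2:
        raise StatisticUndefinedError("each group needs at least 2 samples")
    case = np.log2(matrix.columns(list(design.case_samples)) + pseudocount)
    control = np.log2(matrix.columns(list(design.control_samples)) + pseudocount)
    if not (np.isfinite(case).all() and np.isfinite(control).all()):
        raise ValueError("log2(x + pseudocount) produced non-finite values")
    t, log2fc, degenerate = _two_sample_t(case, control)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "T": t,
            "log2FC": log2fc,
            "degenerate": degenerate,
        }
    )


# ---------------------------------------------------------------------------
# permutation nulls


def count_distinct_permutations(
    design: PairedDesign | UnpairedDesign, scheme: str = "within_subject"
) -> int:
    """Number of distinct label relabelings for a design under a scheme."""
    if isinstance(design, PairedDesign):
        if scheme == "within_subject":
            return math.factorial(4) ** design.n_subjects
        if scheme == "across_samples":
            return math.factorial(4 * design.n_subjects)
        raise ValueError(f"unknown scheme {scheme!r}")
    n1 = len(design.case_samples)
    n = n1 + len(design.control_samples)
    return math.comb(n, n1)


def _iter_paired_assignments_exhaustive(n_subjects: int) -> Iterator[np.ndarray]:
    """Yield every within-subject role assignment: arrays (n_subjects, 4)
    whose row s lists which of subject s's four samples plays each role."""
    perms = [np.array(p) for p in itertools.permutations(range(4))]
    for combo in itertools.product(range(len(perms)), repeat=n_subjects):
        yield np.stack([perms[i] for i in combo])


def build_null(
    matrix: ExpressionMatrix,
    design: PairedDesign | UnpairedDesign,
    n_permutations: int,
    seed: int,
    pseudocount: float = 1.0,
    scheme: str = "within_subject",
    mode: str = "auto",
) -> tuple[NullDistribution, NullDistribution]:
    """Empirical nulls for T and log2FC, pooled across genes and permutations.

    Permutation schemes: for a paired design, ``within_subject`` (default)
    shuffles the four role labels independently within each subject;
    ``across_samples`` reassigns all 4·S samples to the S×4 (subject, role)
    slots.  For an unpaired design the group labels are shuffled across all
    samples.

    Modes: ``auto`` enumerates every distinct relabeling exhaustively when
    their count is <= n_permutations (so the null is exact) and samples
    otherwise; ``exhaustive`` forces enumeration; ``montecarlo`` always
    samples, warning when n_permutations exceeds the distinct count
    (duplicates permitted).  Deterministic given seed; the permutation
    stream is drawn up front so chunked evaluation cannot change it.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if mode not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown mode {mode!r}")
    n_distinct = count_distinct_permutations(design, scheme)
    exhaustive = mode == "exhaustive" or (mode == "auto" and n_distinct <= n_permutations)
    if mode == "montecarlo" and n_permutations > n_distinct:
        warnings.warn(
            f"n_permutations={n_permutations} exceeds the {n_distinct} distinct "
            "relabelings of this design; duplicate permutations permitted",
            stacklevel=2,
        )
    if exhaustive and n_distinct > 200_000:
        raise ValueError(
            f"exhaustive enumeration of {n_distinct} relabelings is not tractable"
        )

    if isinstance(design, PairedDesign):
        t_vals, f_vals, n_dropped, b_used = _paired_null(
            matrix, design, n_permutations, seed, pseudocount, scheme, exhaustive
        )
    else:
        t_vals, f_vals, n_dropped, b_used = _unpaired_null(
            matrix, design, n_permutations, seed, pseudocount, exhaustive
        )
    null_t = NullDistribution(
        "T", t_vals, b_used, matrix.n_genes, seed=seed, n_dropped=n_dropped
    )
    null_f = NullDistribution("log2FC", f_vals, b_used, matrix.n_genes, seed=seed)
    return null_t, null_f


def _paired_null(
    matrix: ExpressionMatrix,
    design: PairedDesign,
    n_permutations: int,
    seed: int,
    pseudocount: float,
    scheme: str,
    exhaustive: bool,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    n_subjects = design.n_subjects
    # L[s]: genes × 4 log2(x + eps) block in role order for subject s
    L = np.stack(
        [
            np.log2(
                matrix.columns(
                    [design.assignments[subj][role] for role in PAIRED_ROLES]
                )
                + pseudocount
            )
            for subj in design.subjects
        ]
    )  # n_subjects × genes × 4

    if scheme == "within_subject":
        if exhaustive:
            assignments = _iter_paired_assignments_exhaustive(n_subjects)
            b_used = count_distinct_permutations(design, scheme)
        else:
            rng = np.random.default_rng(seed)
            base = np.broadcast_to(
                np.arange(4), (n_permutations, n_subjects, 4)
            ).copy()
            all_assignments = rng.permuted(base, axis=2)
            assignments = iter(all_assignments)
            b_used = n_permutations
        t_chunks, f_chunks = [], []
        for assignment in assignments:
            # d_s = contrast over the permuted role columns
            d = np.stack(
                [L[s][:, assignment[s]] @ _CONTRAST for s in range(n_subjects)],
                axis=1,
            )  # genes × subjects
            t, f, _ = _paired_t(d)
            t_chunks.append(t)
            f_chunks.append(f)
    elif scheme == "across_samples":
        if exhaustive:
            raise ValueError(
                "exhaustive enumeration is not supported for the across_samples scheme"
            )
        flat = L.transpose(1, 0, 2).reshape(matrix.n_genes, 4 * n_subjects)
        rng = np.random.default_rng(seed)
        b_used = n_permutations
        t_chunks, f_chunks = [], []
        for _ in range(n_permutations):
            order = rng.permutation(4 * n_subjects)
            slots = flat[:, order].reshape(matrix.n_genes, n_subjects, 4)
            d = slots @ _CONTRAST  # genes × subjects
            t, f, _ = _paired_t(d)
            t_chunks.append(t)
            f_chunks.append(f)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    t_all = np.concatenate(t_chunks)
    f_all = np.concatenate(f_chunks)
    finite = np.isfinite(t_all)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropped %d non-finite permuted T values from the null", n_dropped)
    return t_all[finite], f_all, n_dropped, b_used


def _unpaired_null(
    matrix: ExpressionMatrix,
    design: UnpairedDesign,
    n_permutations: int,
    seed: int,
    pseudocount: float,
    exhaustive: bool,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    samples = design.sample_ids()
    n1 = len(design.case_samples)
    X = np.log2(matrix.columns(samples) + pseudocount)
    n = X.shape[1]

    t_chunks, f_chunks = [], []
    if exhaustive:
        b_used = 0
        for case_idx in itertools.combinations(range(n), n1):
            case_mask = np.zeros(n, dtype=bool)
            case_mask[list(case_idx)] = True
            t, f, _ = _two_sample_t(X[:, case_mask], X[:, ~case_mask])
            t_chunks.append(t)
            f_chunks.append(f)
            b_used += 1
    else:
        rng = np.random.default_rng(seed)
        b_used = n_permutations
        orders = rng.permuted(
            np.broadcast_to(np.arange(n), (n_permutations, n)).copy(), axis=1
        )
        for b in range(n_permutations):
            order = orders[b]
            t, f, _ = _two_sample_t(X[:, order[:n1]], X[:, order[n1:]])
            t_chunks.append(t)
            f_chunks.append(f)

    t_all = np.concatenate(t_chunks)
    f_all = np.concatenate(f_chunks)
    finite = np.isfinite(t_all)
    n_dropped = int((~finite).sum())
    return t_all[finite], f_all, n_dropped, b_used


# ---------------------------------------------------------------------------
# p-values and calling


def empirical_pvalue(
    obs: float | np.ndarray, null: NullDistribution | np.ndarray
) -> float | np.ndarray:
    """Two-sided empirical p with plus-one correction:
    p = (1 + #{ |v| >= |obs| }) / (1 + N).  NaN observations yield NaN."""
    if isinstance(null, NullDistribution):
        abs_sorted = null.abs_sorted
    else:
        null = np.asarray(null, dtype=float)
        abs_sorted = np.sort(np.abs(null))
    n = len(abs_sorted)
    if n == 0:
        raise StatisticUndefinedError("empirical p-value from an empty null")
    obs_arr = np.atleast_1d(np.asarray(obs, dtype=float))
    nan_mask = np.isnan(obs_arr)
    count_ge = n - np.searchsorted(abs_sorted, np.abs(obs_arr), side="left")
    p = (1.0 + count_ge) / (1.0 + n)
    p[nan_mask] = np.nan
    return float(p[0]) if np.isscalar(obs) or np.asarray(obs).ndim == 0 else p


def attach_pvalues(
    stats: pd.DataFrame,
    null_t: NullDistribution,
    null_f: NullDistribution,
) -> pd.DataFrame:
    """Add Pt and Pf columns.  Degenerate genes (T undefined) fall back to
    the log2FC null for Pt, with a warning."""
    out = stats.copy()
    out["Pt"] = empirical_pvalue(out["T"].to_numpy(), null_t)
    out["Pf"] = empirical_pvalue(out["log2FC"].to_numpy(), null_f)
    degenerate = out["degenerate"].to_numpy(dtype=bool)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero contrast variance: "
            "T is undefined; Pt taken from the log2FC null",
            stacklevel=2,
        )
        out.loc[degenerate, "Pt"] = out.loc[degenerate, "Pf"]
    return out


def annotate_calls(
    stats: pd.DataFrame, thresholds: DEGThresholds, kind: str = "paired"
) -> pd.DataFrame:
    """Add is_deg and direction columns (inclusive cutoffs).

    Direction vocabulary: induced/suppressed for the paired regulator
    comparison, up/down for an unpaired comparison; 'none' when log2FC = 0.
    """
    if kind == "paired":
        pos, neg = "induced", "suppressed"
    elif kind == "unpaired":
        pos, neg = "up", "down"
    else:
        raise ValueError(f"kind must be 'paired' or 'unpaired', got {kind!r}")
    out = stats.copy()
    lfc = out["log2FC"].to_numpy()
    out["is_deg"] = (out["Pt"] <= thresholds.pt_cutoff) & (
        out["Pf"] <= thresholds.pf_cutoff
    )
    out["direction"] = np.where(lfc > 0, pos, np.where(lfc < 0, neg, "none"))
    return out


def call_degs(
    stats: pd.DataFrame,
    thresholds: DEGThresholds,
    kind: str = "paired",
    label: str = "comparison",
) -> DEGSet:
    """Genes with Pt <= pt_cutoff and Pf <= pf_cutoff, with directions."""
    annotated = (
        stats
        if {"is_deg", "direction"} <= set(stats.columns)
        else annotate_calls(stats, thresholds, kind)
    )
    members = annotated.loc[annotated["is_deg"], ["gene_id", "direction"]]
    return DEGSet(label=label, genes=members.reset_index(drop=True), thresholds=thresholds)


def per_subject_concordance_report(ratios: RatioTable, degs: DEGSet) -> pd.DataFrame:
    """Per-DEG signs of the per-subject contrast d_s and a concordance flag.

    A gene is concordant when all subjects share the same contrast sign;
    discordant genes are flagged for manual review, never removed.
    """
    d = ratios.log2_contrast
    index = {g: i for i, g in enumerate(ratios.gene_ids)}
    rows = []
    for gene in degs.genes["gene_id"]:
        ds = d[index[gene]]
        signs = ["+" if v > 0 else "-" if v < 0 else "0" for v in ds]
        concordant = bool((ds > 0).all() or (ds < 0).all() or (ds == 0).all())
        rows.append([gene, *signs, concordant])
    columns = ["gene_id"] + [f"sign_{s}" for s in ratios.subjects] + ["concordant"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# pipeline wrappers


def filter_low_expression(
    matrix: ExpressionMatrix, sample_ids: list[str], threshold: float
) -> tuple[ExpressionMatrix, int]:
    """Drop genes whose expression is below `threshold` in every listed
    sample (pseudocount-only artifacts); returns (matrix, n_dropped)."""
    block = matrix.columns(sample_ids)
    keep = (block >= threshold).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d low-expression gene(s) before testing", n_dropped)
        if n_dropped == matrix.n_genes:
            raise ValueError("all genes fall below the low-expression threshold")
        matrix = ExpressionMatrix(matrix.data.loc[keep])
    return matrix, n_dropped


@dataclasses.dataclass
class PairedDEGResult:
    stats: pd.DataFrame
    degs: DEGSet
    ratios: RatioTable
    null_t: NullDistribution
    null_f: NullDistribution
    concordance: pd.DataFrame
    n_low_expression_dropped: int


@dataclasses.dataclass
class UnpairedDEGResult:
    stats: pd.DataFrame
    degs: DEGSet
    null_t: NullDistribution
    null_f: NullDistribution
    n_low_expression_dropped: int


def run_paired_deg(
    matrix: ExpressionMatrix,
    design: PairedDesign,
    thresholds: DEGThresholds = DEGThresholds(),
    seed: int = 0,
    label: str = "paired",
    scheme: str = "within_subject",
    mode: str = "auto",
) -> PairedDEGResult:
    """Full paired test: filter, ratios, statistics, pooled nulls,
    empirical p-values, DEG calls, concordance report."""
    design.validate_against(matrix)
    matrix, n_dropped = filter_low_expression(
        matrix, design.sample_ids(), thresholds.pseudocount
    )
    ratios = compute_ratios(matrix, design, thresholds.pseudocount)
    stats = paired_statistics(ratios)
    null_t, null_f = build_null(
        matrix,
        design,
        thresholds.n_permutations,
        seed,
        thresholds.pseudocount,
        scheme=scheme,
        mode=mode,
    )
    stats = attach_pvalues(stats, null_t, null_f)
    stats = annotate_calls(stats, thresholds, kind="paired")
    degs = call_degs(stats, thresholds, kind="paired", label=label)
    concordance = per_subject_concordance_report(ratios, degs)
    logger.info(
        "%s: %d/%d genes called DEG (%d induced, %d suppressed)",
        label,
        len(degs),
        len(stats),
        int((degs.genes["direction"] == "induced").sum()),
        int((degs.genes["direction"] == "suppressed").sum()),
    )
    return PairedDEGResult(
        stats, degs, ratios, null_t, null_f, concordance, n_dropped
    )


def run_unpaired_deg(
    matrix: ExpressionMatrix,
    design: UnpairedDesign,
    thresholds: DEGThresholds = DEGThresholds(),
    seed: int = 0,
    label: str = "unpaired",
    mode: str = "auto",
) -> UnpairedDEGResult:
    """Full unpaired test: filter, statistics, pooled nulls, p-values, calls."""
    design.validate_against(matrix)
    matrix, n_dropped = filter_low_expression(
        matrix, design.sample_ids(), thresholds.pseudocount
    )
    stats = unpaired_statistics(matrix, design, thresholds.pseudocount)
    null_t, null_f = build_null(
        matrix,
        design,
        thresholds.n_permutations,
        seed,
        thresholds.pseudocount,
        mode=mode,
    )
    stats = attach_pvalues(stats, null_t, null_f)
    stats = annotate_calls(stats, thresholds, kind="unpaired")
    degs = call_degs(stats, thresholds, kind="unpaired", label=label)
    logger.info(
        "%s: %d/%d genes called DEG (%d up, %d down)",
        label,
        len(degs),
        len(stats),
        int((degs.genes["direction"] == "up").sum()),
        int((degs.genes["direction"] == "down").sum()),
    )
    return UnpairedDEGResult(stats, degs, null_t, null_f, n_dropped)
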
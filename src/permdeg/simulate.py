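"""Synthetic-data generator for the full integrative workflow.

Emulates the statistical structure of the study design the pipeline
consumes: one small paired perturbation experiment (by default 3 subjects,
each with overexpression, vector-control, knockdown and siRNA-control
samples) and two unpaired case/control senescence datasets (3 vs 3), with
planted differentially expressed genes of known direction and a known
cross-dataset overlap.

Expression is log-normal: in log2 space each value is

    baseline(g) + subject_effect(s) + condition_effect(g, condition) + N(0, σ)

with the subject effect shared across a subject's four samples (this is
the within-subject correlation the paired contrast removes).  Planted
regulator-induced genes get +effect under OE and -effect under KD relative
to their controls (so the paired contrast sees ≈ 2·effect); suppressed
genes the reverse.  Planted senescence genes shift the case group by
±effect.  Shared "consistent" genes follow the regulator-down consistency
rule (induced → down in senescence, suppressed → up) in every senescence
dataset; shared "inconsistent" genes violate it in exactly one dataset.
Linear-scale matrices are 2^(log2 value), hence strictly positive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    PAIRED_ROLES,
    PairedDesign,
    UnpairedDesign,
    write_design,
    write_expression_matrix,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "WorkedExample",
    "generate_study",
    "make_worked_example",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-shape and effect parameters for :func:`generate_study`.

    Effects and noise are in log2 units; `n_senescence_de` counts the
    senescence-only (non-shared) planted genes per senescence dataset, on
    top of the shared planted genes drawn from the regulator DE blocks.
    """

    n_genes: int = 2000
    n_subjects: int = 3
    n_sen_case: int = 3
    n_sen_control: int = 3
    n_regulator_induced: int = 100
    n_regulator_suppressed: int = 100
    n_senescence_de: int = 300
    n_shared_consistent: int = 5
    n_shared_inconsistent: int = 2
    effect_size: float = 1.0
    sigma: float = 0.25
    subject_sd: float = 0.1
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    senescence_labels: tuple[str, ...] = ("senescence_UV", "senescence_H2O2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.subject_sd < 0 or self.baseline_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.n_subjects < 2:
            raise ValueError("paired design needs at least 2 subjects")
        if min(self.n_sen_case, self.n_sen_control) < 2:
            raise ValueError("senescence groups need at least 2 samples")
        n_shared = self.n_shared_consistent + self.n_shared_inconsistent
        n_regulator = self.n_regulator_induced + self.n_regulator_suppressed
        if n_shared > n_regulator:
            raise ValueError("shared planted genes must fit inside the regulator DE genes")
        needed = n_regulator + len(self.senescence_labels) * self.n_senescence_de
        if needed > self.n_genes:
            raise ValueError(
                f"planted genes ({needed}) exceed n_genes ({self.n_genes})"
            )


@dataclasses.dataclass
class SimulatedStudy:
    """Three generated datasets plus per-gene ground truth."""

    regulator_matrix: ExpressionMatrix
    regulator_design: PairedDesign
    senescence: list[tuple[str, ExpressionMatrix, UnpairedDesign]]
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(self.regulator_matrix, outdir / "regulator_matrix.tsv")
        write_design(self.regulator_design, outdir / "regulator_design.tsv")
        for label, matrix, design in self.senescence:
            write_expression_matrix(matrix, outdir / f"{label}_matrix.tsv")
            write_design(design, outdir / f"{label}_design.tsv")
        self.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _plant_directions(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene ground-truth table of planted effects and directions."""
    g = config.n_genes
    labels = config.senescence_labels
    truth = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:05d}" for i in range(g)],
            "regulator_de": False,
            "regulator_direction": "none",
            "shared": False,
            "shared_consistent": False,
            "shared_inconsistent": False,
        }
    )
    for label in labels:
        truth[f"{label}_de"] = False
        truth[f"{label}_direction"] = "none"

    n_sc, n_si = config.n_shared_consistent, config.n_shared_inconsistent
    idx = 0

    def reg_dir(i: int) -> str:
        return "induced" if i % 2 == 0 else "suppressed"

    # shared genes: regulator DE + DE in every senescence dataset
    for i in range(n_sc + n_si):
        row = idx + i
        direction = reg_dir(i)
        truth.loc[row, ["regulator_de", "regulator_direction", "shared"]] = [
            True,
            direction,
            True,
        ]
        # regulator-down consistency rule: induced -> down in senescence
        expected = "down" if direction == "induced" else "up"
        conflict_with = labels[i % len(labels)] if i >= n_sc else None
        if i >= n_sc:
            truth.loc[row, "shared_inconsistent"] = True
        else:
            truth.loc[row, "shared_consistent"] = True
        for label in labels:
            sen_dir = expected
            if label == conflict_with:
                sen_dir = "up" if expected == "down" else "down"
            truth.loc[row, [f"{label}_de", f"{label}_direction"]] = [True, sen_dir]
    idx += n_sc + n_si

    # remaining regulator-only DE genes, topping up each direction count
    n_shared_induced = sum(1 for i in range(n_sc + n_si) if reg_dir(i) == "induced")
    n_shared_suppressed = (n_sc + n_si) - n_shared_induced
    remaining = [
        ("induced", config.n_regulator_induced - n_shared_induced),
        ("suppressed", config.n_regulator_suppressed - n_shared_suppressed),
    ]
    for direction, count in remaining:
        if count < 0:
            raise ValueError(
                f"n_regulator_{direction} too small for the planted shared genes"
            )
        truth.loc[idx : idx + count - 1, "regulator_de"] = True
        truth.loc[idx : idx + count - 1, "regulator_direction"] = direction
        idx += count

    # senescence-only DE genes, disjoint between datasets and from regulator
    for k, label in enumerate(labels):
        count = config.n_senescence_de
        block = slice(idx, idx + count - 1)
        truth.loc[block, f"{label}_de"] = True
        truth.loc[block, f"{label}_direction"] = [
            "up" if (i + k) % 2 == 0 else "down" for i in range(count)
        ]
        idx += count
    return truth


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the paired regulator study, the senescence datasets and
    their ground truth; fully deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    truth = _plant_directions(config)
    g = config.n_genes
    e = config.effect_size

    reg_sign = truth["regulator_direction"].map(
        {"induced": 1.0, "suppressed": -1.0, "none": 0.0}
    ).to_numpy()

    # paired regulator study -------------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    subjects = [f"S{i + 1}" for i in range(config.n_subjects)]
    subject_effect = rng.normal(0.0, config.subject_sd, size=config.n_subjects)
    role_effect = {
        "OE": e * reg_sign,
        "OE_control": np.zeros(g),
        "KD": -e * reg_sign,
        "KD_control": np.zeros(g),
    }
    columns = {}
    assignments: dict[str, dict[str, str]] = {}
    for s, subj in enumerate(subjects):
        assignments[subj] = {}
        for role in PAIRED_ROLES:
            sample = f"{subj}_{role}"
            assignments[subj][role] = sample
            log2x = (
                baseline
                + subject_effect[s]
                + role_effect[role]
                + rng.normal(0.0, config.sigma, size=g)
            )
            columns[sample] = np.exp2(log2x)
    regulator_matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(truth["gene_id"], name="gene_id"))
    )
    regulator_design = PairedDesign(assignments)

    # senescence datasets ----------------------------------------------------
    senescence = []
    for label in config.senescence_labels:
        sen_baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
        sen_sign = truth[f"{label}_direction"].map(
            {"up": 1.0, "down": -1.0, "none": 0.0}
        ).to_numpy()
        cols = {}
        case, control = [], []
        for i in range(config.n_sen_case):
            sample = f"{label}_case{i + 1}"
            case.append(sample)
            cols[sample] = np.exp2(
                sen_baseline + e * sen_sign + rng.normal(0.0, config.sigma, size=g)
            )
        for i in range(config.n_sen_control):
            sample = f"{label}_control{i + 1}"
            control.append(sample)
            cols[sample] = np.exp2(
                sen_baseline + rng.normal(0.0, config.sigma, size=g)
            )
        matrix = ExpressionMatrix(
            pd.DataFrame(cols, index=pd.Index(truth["gene_id"], name="gene_id"))
        )
        senescence.append((label, matrix, UnpairedDesign(tuple(case), tuple(control))))

    return SimulatedStudy(regulator_matrix, regulator_design, senescence, truth, config)


@dataclasses.dataclass(frozen=True)
class WorkedExample:
    """The five-gene cross-study overlap used as a built-in example.

    Five genes shared by an HDAC4 perturbation DEG set and two senescence
    DEG sets, with their reported directions: DDIT4 and GINS2 (induced by
    the regulator, down in both senescence models) and PGAP6 (suppressed,
    up in both) satisfy the regulator-down consistency rule; MCM7 and OAF
    change inconsistently and are filtered out.
    """

    candidates: tuple[str, ...]
    regulator_directions: dict[str, str]
    senescence_directions: dict[str, dict[str, str]]


def make_worked_example() -> WorkedExample:
    regulator = {
        "DDIT4": "induced",
        "GINS2": "induced",
        "PGAP6": "suppressed",
        "MCM7": "induced",
        "OAF": "suppressed",
    }
    senescence = {
        "senescence_UV": {
            "DDIT4": "down",
            "GINS2": "down",
            "PGAP6": "up",
            "MCM7": "up",
            "OAF": "down",
        },
        "senescence_H2O2": {
            "DDIT4": "down",
            "GINS2": "down",
            "PGAP6": "up",
            "MCM7": "down",
            "OAF": "up",
        },
    }
    return WorkedExample(
        candidates=tuple(sorted(regulator)),
        regulator_directions=regulator,
        senescence_directions=senescence,
    )
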
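import numpy as np
import pandas as pd
import pytest

from permdeg.expression_io import (
    ExpressionMatrix,
    PAIRED_ROLES,
    PairedDesign,
    UnpairedDesign,
)


def make_paired_matrix(n_genes=10, n_subjects=3, seed=0):
    """Random positive matrix plus a matching paired design."""
    rng = np.random.default_rng(seed)
    assignments, columns = {}, {}
    for s in range(n_subjects):
        subject = f"S{s + 1}"
        assignments[subject] = {}
        for role in PAIRED_ROLES:
            sample = f"{subject}_{role}"
            assignments[subject][role] = sample
            columns[sample] = rng.gamma(2.0, 50.0, size=n_genes)
    matrix = ExpressionMatrix(
        pd.DataFrame(
            columns, index=pd.Index([f"G{i + 1:03d}" for i in range(n_genes)], name="gene_id")
        )
    )
    return matrix, PairedDesign(assignments)


def make_unpaired_matrix(n_genes=10, n_case=3, n_control=3, seed=0):
    rng = np.random.default_rng(seed)
    case = tuple(f"case{i + 1}" for i in range(n_case))
    control = tuple(f"ctrl{i + 1}" for i in range(n_control))
    columns = {s: rng.gamma(2.0, 50.0, size=n_genes) for s in case + control}
    matrix = ExpressionMatrix(
        pd.DataFrame(
            columns, index=pd.Index([f"G{i + 1:03d}" for i in range(n_genes)], name="gene_id")
        )
    )
    return matrix, UnpairedDesign(case, control)


@pytest.fixture
def paired_data():
    return make_paired_matrix()


@pytest.fixture
def unpaired_data():
    return make_unpaired_matrix()


@pytest.fixture
def paired_design_table(tmp_path):
    """A complete 3-subject paired design table on disk."""
    rows = ["sample_id\tsubject\tcondition"]
    for s in ("S1", "S2", "S3"):
        for role in PAIRED_ROLES:
            rows.append(f"{s}_{role}\t{s}\t{role}")
    path = tmp_path / "design.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path
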
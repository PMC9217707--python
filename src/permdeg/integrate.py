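"""Multi-comparison DEG intersection and direction-consistency filtering.

Candidate regulator targets are the genes differentially expressed in the
regulator perturbation comparison *and* in every senescence comparison.
The consistency rule then uses the regulator's own behaviour in the
senescence condition to predict each candidate's direction there: if the
regulator is decreased in senescent cells, a gene it induces should fall
and a gene it suppresses should rise.  Candidates violating the prediction
in any senescence dataset are excluded, with a machine-readable reason.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression_io import canonicalize_gene_id
from .degtest import DEGSet

__all__ = [
    "IntegrationError",
    "ComparisonSet",
    "NominationReport",
    "direction_sign",
    "expected_senescence_sign",
    "venn_counts",
    "intersect_all",
    "consistency_filter",
    "nominate_targets",
    "write_nomination_report",
]

_SIGNS = {"up": 1, "induced": 1, "down": -1, "suppressed": -1}


class IntegrationError(ValueError):
    """A candidate lacks a direction entry, or inputs are malformed."""


def direction_sign(direction: str) -> int:
    """+1 for up/induced, -1 for down/suppressed."""
    try:
        return _SIGNS[direction]
    except KeyError:
        raise IntegrationError(f"unknown direction token {direction!r}") from None


def expected_senescence_sign(regulator_sign: int, regulator_change: str) -> int:
    """Predicted senescence-direction sign for a target gene.

    With the regulator decreased in senescence ("down"), induced targets
    (+1) are expected down (-1) and suppressed targets up (+1); with the
    regulator increased the target follows its regulator direction.
    """
    if regulator_change == "down":
        return -regulator_sign
    if regulator_change == "up":
        return regulator_sign
    raise IntegrationError(f"regulator_change must be 'up' or 'down', got {regulator_change!r}")


@dataclasses.dataclass(frozen=True)
class ComparisonSet:
    """A labelled DEG set with a direction for every member gene."""

    label: str
    directions: Mapping[str, str]  # canonical gene -> up/down/induced/suppressed

    def __post_init__(self) -> None:
        canonical = {}
        for gene, direction in self.directions.items():
            direction_sign(direction)  # vocabulary check
            canonical[canonicalize_gene_id(gene)] = direction
        object.__setattr__(self, "directions", canonical)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    @classmethod
    def from_degset(cls, degs: DEGSet) -> "ComparisonSet":
        return cls(degs.label, degs.directions())

    @classmethod
    def from_results_table(cls, label: str, results: pd.DataFrame) -> "ComparisonSet":
        """Build from a degtest results table, keeping only called DEGs."""
        called = results.loc[results["is_deg"]]
        return cls(label, dict(zip(called["gene_id"], called["direction"])))


def venn_counts(sets: Mapping[str, Iterable[str]]) -> dict[frozenset, int]:
    """Cardinality of every exclusive intersection region of 2 or 3 sets.

    Keys are frozensets of labels; a gene counts toward the region of
    exactly the labels whose sets contain it (7 regions for 3 sets, all
    reported, zeros included).
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 3:
        raise IntegrationError("venn_counts requires 2 or 3 sets")
    membership = {label: {canonicalize_gene_id(g) for g in genes} for label, genes in sets.items()}
    regions: dict[frozenset, int] = {}
    # initialize every nonempty label subset
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions[frozenset(combo)] = 0
    for gene in set().union(*membership.values()):
        containing = frozenset(l for l in labels if gene in membership[l])
        regions[containing] += 1
    return regions


def intersect_all(sets: Mapping[str, Iterable[str]]) -> list[str]:
    """Alphabetical list of genes present in every set."""
    iterator = iter(sets.values())
    common = {canonicalize_gene_id(g) for g in next(iterator)}
    for genes in iterator:
        common &= {canonicalize_gene_id(g) for g in genes}
    return sorted(common)


def consistency_filter(
    candidates: Iterable[str],
    regulator_directions: Mapping[str, str],
    senescence_directions: Mapping[str, Mapping[str, str]],
    regulator_change: str = "down",
) -> tuple[list[str], dict[str, str]]:
    """Retain candidates whose direction in EVERY senescence dataset matches
    the rule's prediction.

    Returns (kept, excluded) where `kept` is alphabetical and `excluded`
    maps each rejected gene to semicolon-joined reasons such as
    ``inconsistent:senescence_UV``.  A candidate missing a direction entry
    raises :class:`IntegrationError` naming the gene and comparison.
    """
    reg = {canonicalize_gene_id(g): d for g, d in regulator_directions.items()}
    sen = {
        label: {canonicalize_gene_id(g): d for g, d in dirs.items()}
        for label, dirs in senescence_directions.items()
    }
    if not sen:
        raise IntegrationError("at least one senescence comparison is required")
    kept: list[str] = []
    excluded: dict[str, str] = {}
    for gene in sorted({canonicalize_gene_id(g) for g in candidates}):
        if gene not in reg:
            raise IntegrationError(
                f"candidate {gene!r} has no direction in the regulator comparison"
            )
        expected = expected_senescence_sign(direction_sign(reg[gene]), regulator_change)
        reasons = []
        for label, dirs in sen.items():
            if gene not in dirs:
                raise IntegrationError(
                    f"candidate {gene!r} has no direction in comparison {label!r}"
                )
            if direction_sign(dirs[gene]) != expected:
                reasons.append(f"inconsistent:{label}")
        if reasons:
            excluded[gene] = ";".join(reasons)
        else:
            kept.append(gene)
    return kept, excluded


@dataclasses.dataclass
class NominationReport:
    """Venn counts, the full intersection, the consistent subset, and
    per-gene exclusion reasons for one nomination run."""

    venn: dict[frozenset, int]
    intersection: list[str]
    nominated: list[str]
    exclusions: dict[str, str]
    regulator_change: str

    def as_frame(self) -> pd.DataFrame:
        rows = [(g, "nominated", "") for g in self.nominated]
        rows += [(g, "excluded", reason) for g, reason in sorted(self.exclusions.items())]
        return pd.DataFrame(rows, columns=["gene_id", "status", "reason"])


def nominate_targets(
    regulator_set: ComparisonSet,
    senescence_sets: Sequence[ComparisonSet],
    regulator_change: str = "down",
) -> NominationReport:
    """Full target nomination: intersect the regulator DEG set with every
    senescence DEG set, then apply the direction-consistency rule."""
    if len(senescence_sets) < 1:
        raise IntegrationError("at least one senescence set is required")
    all_sets = {regulator_set.label: regulator_set.genes}
    for s in senescence_sets:
        if s.label in all_sets:
            raise IntegrationError(f"duplicate comparison label {s.label!r}")
        all_sets[s.label] = s.genes
    venn = venn_counts(all_sets) if len(all_sets) <= 3 else {}
    intersection = intersect_all(all_sets)
    nominated, exclusions = consistency_filter(
        intersection,
        regulator_set.directions,
        {s.label: s.directions for s in senescence_sets},
        regulator_change,
    )
    return NominationReport(venn, intersection, nominated, exclusions, regulator_change)


def write_nomination_report(report: NominationReport, path) -> None:
    """Write nominations and exclusions as a TSV."""
    report.as_frame().to_csv(path, sep="\t", index=False)
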
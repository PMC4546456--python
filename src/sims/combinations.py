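"""From score matrices to activation calls, co-activation summaries,
triplet coverage and a coverage-maximizing three-drug menu.

Activation categories follow the published convention: scores 8-10 are
*high* activation, 6-7 *medium*, and anything below 6 is non-activated;
"activated" for all downstream counting means score >= 6.  A candidate
three-drug combination "covers" a patient when all three of its labels are
activated in that patient; the menu selection then maximizes the number of
distinct patients covered by a small set of such triplets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataError
from .registry import DEFAULT_ALIASES, MergedNodeAlias, NodeRegistry

logger = logging.getLogger(__name__)

#: Score thresholds for the activation categories.
HIGH_MIN = 8
ACTIVATED_MIN = 6

CATEGORY_HIGH = "high"
CATEGORY_MEDIUM = "medium"
CATEGORY_NONE = "none"


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (the convention that
    reproduces the published percentages, e.g. 36/121 -> 30%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_of(count: int, total: int) -> int:
    return 0 if total == 0 else round_half_away(100.0 * count / total)


def classify_activation(score: int) -> str:
    """Map an integer score to "high" (8-10), "medium" (6-7) or "none" (<6)."""
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise DataError(f"score must be an integer, got {score!r}")
    if score < 1 or score > 10:
        raise DataError(f"score out of range 1..10: {score}")
    if score >= HIGH_MIN:
        return CATEGORY_HIGH
    if score >= ACTIVATED_MIN:
        return CATEGORY_MEDIUM
    return CATEGORY_NONE


def build_activation_matrix(
    scores: pd.DataFrame,
    aliases: Sequence[MergedNodeAlias] = DEFAULT_ALIASES,
    activated_min: int = ACTIVATED_MIN,
) -> pd.DataFrame:
    """Boolean patient x label matrix from a node x patient score matrix.

    Labels are the node names plus one column per merged alias; an alias
    column is the elementwise OR of its member columns (union semantics).
    """
    values = scores.to_numpy()
    if ((values < 1) | (values > 10)).any():
        raise DataError("scores must be integers in 1..10")
    matrix = (scores.T >= activated_min)
    matrix.index.name = "patient"
    matrix.columns.name = None
    for alias in aliases:
        alias.validate(scores.index)
        matrix[alias.label] = matrix[list(alias.members)].any(axis=1)
    return matrix


@dataclass
class GroupSummary:
    """Activation frequencies within one patient group."""

    group: str
    size: int
    cohort_size: int
    table: pd.DataFrame  # index label, columns count / percent

    @property
    def percent_of_cohort(self) -> int:
        return percent_of(self.size, self.cohort_size)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "size": int(self.size),
            "cohort_size": int(self.cohort_size),
            "percent_of_cohort": self.percent_of_cohort,
            "labels": {
                label: {"count": int(row["count"]), "percent": int(row["percent"])}
                for label, row in self.table.iterrows()
            },
        }


def group_summary(
    matrix: pd.DataFrame,
    group: Union[str, Callable[[pd.DataFrame], pd.Series], pd.Series, None] = None,
    name: Optional[str] = None,
) -> GroupSummary:
    """Per-label activation counts and integer percentages within a group.

    ``group`` selects the member patients: a label (patients with that
    label activated), a boolean Series indexed by patient, a predicate
    called on the matrix, or None for the whole cohort.  Percentages are
    relative to the group size, rounded half away from zero.
    """
    if group is None:
        mask = pd.Series(True, index=matrix.index)
        name = name or "all"
    elif isinstance(group, str):
        if group not in matrix.columns:
            raise DataError(f"unknown group label: {group!r}")
        mask = matrix[group]
        name = name or group
    elif callable(group):
        mask = group(matrix).astype(bool)
        name = name or "predicate"
    else:
        mask = group.reindex(matrix.index, fill_value=False).astype(bool)
        name = name or "predicate"
    members = matrix[mask]
    size = len(members)
    counts = members.sum(axis=0).astype(int)
    table = pd.DataFrame(
        {
            "count": counts,
            "percent": [percent_of(c, size) for c in counts],
        },
        index=matrix.columns,
    )
    return GroupSummary(name, size, len(matrix), table)


@dataclass(frozen=True, order=True)
class TripletCoverage:
    """Patient coverage of one unordered triplet of labels."""

    labels: tuple[str, str, str]
    count: int
    percent: int

    def __post_init__(self) -> None:
        if len(set(self.labels)) != 3:
            raise DataError(f"triplet labels must be 3 distinct: {self.labels}")


def enumerate_triplets(
    matrix: pd.DataFrame,
    must_include: Optional[Iterable[str]] = None,
    excluded_pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> list[TripletCoverage]:
    """All unordered 3-subsets of labels with their patient coverage.

    ``must_include``: labels every triplet must contain (e.g. an
    immunomodulator arm).  ``excluded_pairs``: label pairs that may not
    co-occur in a triplet (mechanistic-independence constraint).  Sorted by
    count descending, ties broken lexicographically; deterministic.
    """
    labels = list(matrix.columns)
    if len(labels) < 3:
        raise DataError("need at least 3 labels to form triplets")
    required = set(must_include or ())
    unknown = required - set(labels)
    if unknown:
        raise DataError(f"must_include label(s) not in matrix: {sorted(unknown)}")
    excluded = {frozenset(p) for p in (excluded_pairs or ())}
    cohort = len(matrix)
    bool_cols = {lab: matrix[lab].to_numpy(dtype=bool) for lab in labels}
    out = []
    for combo in itertools.combinations(sorted(labels), 3):
        if not required.issubset(combo):
            continue
        if any(
            frozenset(pair) in excluded for pair in itertools.combinations(combo, 2)
        ):
            continue
        joint = bool_cols[combo[0]] & bool_cols[combo[1]] & bool_cols[combo[2]]
        count = int(joint.sum())
        out.append(TripletCoverage(combo, count, percent_of(count, cohort)))
    if not out:
        logger.warning("constraints eliminated every triplet")
    out.sort(key=lambda t: (-t.count, t.labels))
    return out


def shared_gene_pairs(
    registry: NodeRegistry,
    aliases: Sequence[MergedNodeAlias] = DEFAULT_ALIASES,
) -> list[tuple[str, str]]:
    """Default mechanistic-independence exclusions: label pairs sharing >= 1
    gene (an alias carries the union of its members' genes)."""
    gene_sets = {node.name: set(node.genes) for node in registry}
    for alias in aliases:
        gene_sets[alias.label] = set().union(
            *(gene_sets[m] for m in alias.members if m in gene_sets)
        )
    pairs = []
    for a, b in itertools.combinations(sorted(gene_sets), 2):
        if gene_sets[a] & gene_sets[b]:
            pairs.append((a, b))
    return pairs


@dataclass
class MenuEntry:
    triplet: TripletCoverage
    new_patients: int
    cumulative_coverage: int


@dataclass
class CombinationMenu:
    """Ordered triplets with cumulative distinct-patient coverage."""

    entries: list[MenuEntry] = field(default_factory=list)
    cohort_size: int = 0

    @property
    def coverage(self) -> int:
        return self.entries[-1].cumulative_coverage if self.entries else 0

    def to_list(self) -> list[dict]:
        return [
            {
                "labels": list(e.triplet.labels),
                "count": e.triplet.count,
                "percent": e.triplet.percent,
                "new_patients": e.new_patients,
                "cumulative_coverage": e.cumulative_coverage,
            }
            for e in self.entries
        ]


def select_menu(
    matrix: pd.DataFrame,
    triplets: Optional[Sequence[TripletCoverage]] = None,
    k: int = 3,
    must_include: Optional[Iterable[str]] = None,
    excluded_pairs: Optional[Iterable[tuple[str, str]]] = None,
    method: str = "auto",
) -> CombinationMenu:
    """Choose ``k`` triplets maximizing distinct-patient coverage.

    ``method="greedy"``: repeatedly take the triplet covering the most
    not-yet-covered patients (ties: higher raw count, then lexicographic);
    the classic (1 - 1/e)-approximation.  ``method="exhaustive"`` searches
    all k-subsets and returns an optimal menu in greedy-style order.
    ``method="auto"`` (default) is exhaustive on small label sets (<= 8
    labels, search space permitting — greedy can be suboptimal even there)
    and greedy otherwise.
    """
    if k < 1:
        raise DataError("menu size k must be >= 1")
    if triplets is None:
        triplets = enumerate_triplets(matrix, must_include, excluded_pairs)
    if len(triplets) < k:
        logger.warning(
            "only %d triplet(s) available; menu shorter than k=%d",
            len(triplets), k,
        )
        k = len(triplets)
    if method == "auto":
        tractable = (
            len(matrix.columns) <= 8
            and math.comb(len(triplets), min(k, len(triplets))) <= 200_000
        )
        method = "exhaustive" if tractable else "greedy"
    patient_sets = {
        t.labels: frozenset(
            matrix.index[matrix[list(t.labels)].all(axis=1)]
        )
        for t in triplets
    }
    if method == "exhaustive":
        best: tuple[int, tuple] = (-1, ())
        for combo in itertools.combinations(triplets, k):
            covered = frozenset().union(*(patient_sets[t.labels] for t in combo))
            if len(covered) > best[0]:
                best = (len(covered), combo)
        chosen = list(best[1])
        # present in greedy-style order for a nondecreasing coverage trace
        menu = CombinationMenu(cohort_size=len(matrix))
        covered: set = set()
        while chosen:
            chosen.sort(
                key=lambda t: (-len(patient_sets[t.labels] - covered), -t.count, t.labels)
            )
            t = chosen.pop(0)
            gain = len(patient_sets[t.labels] - covered)
            covered |= patient_sets[t.labels]
            menu.entries.append(MenuEntry(t, gain, len(covered)))
        return menu
    if method != "greedy":
        raise DataError(f"unknown menu method: {method!r}")
    menu = CombinationMenu(cohort_size=len(matrix))
    covered = set()
    remaining = list(triplets)
    for _ in range(k):
        remaining.sort(
            key=lambda t: (-len(patient_sets[t.labels] - covered), -t.count, t.labels)
        )
        t = remaining.pop(0)
        gain = len(patient_sets[t.labels] - covered)
        covered |= patient_sets[t.labels]
        menu.entries.append(MenuEntry(t, gain, len(covered)))
    return menu


def triplets_to_frame(triplets: Sequence[TripletCoverage]) -> pd.DataFrame:
    """Tabular triplet report (label1..label3, count, percent)."""
    return pd.DataFrame(
        [
            {
                "label1": t.labels[0],
                "label2": t.labels[1],
                "label3": t.labels[2],
                "count": t.count,
                "percent": t.percent,
            }
            for t in triplets
        ],
        columns=["label1", "label2", "label3", "count", "percent"],
    )


def pair_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Explicit pair-coverage counts (patients with both labels activated)."""
    rows = []
    cohort = len(matrix)
    for a, b in itertools.combinations(sorted(matrix.columns), 2):
        count = int((matrix[a] & matrix[b]).sum())
        rows.append(
            {"label1": a, "label2": b, "count": count,
             "percent": percent_of(count, cohort)}
        )
    return pd.DataFrame(rows, columns=["label1", "label2", "count", "percent"])
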
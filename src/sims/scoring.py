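"""Node activation scoring: corrected fold changes, trimmed node means,
decile calibration and the mutation override.

The score of node *k* in one patient is an integer 1-10 built as follows:

1. Every gene *i* gets a corrected fold change
   ``corrected_i = F_i * cnv_i / A_i`` where ``F_i`` is the tumor/normal
   mRNA fold change, ``A_i`` the mean fold change of the (up to five)
   miRNAs predicted to target the gene (translational penalty: an miRNA
   that rises with its target argues against effective over-expression),
   and ``cnv_i`` the copy-number ratio when the gene is amplified, else 1.
2. The node fold change ``E_k`` is the arithmetic mean of the corrected
   fold changes of the member genes passing the trim
   ``max(r, 1/r) >= 1.3`` (the lowest ratio two-dye arrays detect
   reliably); with no passing gene the node is neutral, ``E_k = 1``.
3. ``E_k`` is ranked against a calibrator cohort's ``E_k`` distribution for
   the same node and converted to a decile score
   ``clamp(ceil(10 * F_hat(E_k)), 1, 10)`` with ``F_hat`` the empirical CDF
   (ties counted as <=).
4. A whitelisted activating mutation in any member gene overrides all of
   the above: the node scores 10 and the transcriptomic evidence is unused.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort_io import OmicsInputBundle, PathLike
from .errors import DataError, SimsError
from .registry import (
    InterventionalNode,
    MiRNATargetMap,
    MutationWhitelist,
    NodeRegistry,
)

logger = logging.getLogger(__name__)

#: Lowest fold change considered reliably detected (trim threshold).
DEFAULT_TRIM = 1.3
#: Copy-number ratio at or above which a gene counts as amplified when the
#: CNV table carries no explicit call.
DEFAULT_AMP_THRESHOLD = 1.5
#: Minimum reference cohort size for decile calibration.
MIN_CALIBRATOR_SIZE = 10

CALIBRATOR_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# per-gene corrections

def mean_mirna_fc(mirna_fcs: Sequence[float]) -> float:
    """Mean fold change A_i of the miRNAs targeting one gene.

    Empty list (gene unmapped or miRNA layer absent) -> 1.0, i.e. no
    penalty.  Non-positive values are rejected: fold changes live in ratio
    space.
    """
    values = np.asarray(list(mirna_fcs), dtype=float)
    if values.size == 0:
        return 1.0
    if not np.isfinite(values).all() or (values <= 0).any():
        raise DataError("miRNA fold changes must be finite and > 0")
    return float(values.mean())


@dataclass(frozen=True)
class CorrectedGeneFC:
    """A gene's fold change after miRNA and copy-number corrections."""

    gene: str
    raw_fc: float
    a_i: float = 1.0
    cnv_factor: float = 1.0
    corrected: float = 0.0

    def __post_init__(self) -> None:
        if not (self.corrected > 0 and math.isfinite(self.corrected)):
            raise DataError(
                f"gene {self.gene!r}: corrected fold change "
                f"{self.corrected!r} is not positive and finite"
            )


def corrected_gene_fc(
    raw_fc: float,
    a_i: float = 1.0,
    cnv_ratio: float = 1.0,
    amplified: bool = False,
    gene: str = "",
) -> CorrectedGeneFC:
    """``corrected = raw_fc * (cnv_ratio if amplified else 1) / a_i``."""
    if raw_fc <= 0 or a_i <= 0 or cnv_ratio <= 0:
        raise DataError("fold changes and ratios must be > 0")
    factor = cnv_ratio if amplified else 1.0
    return CorrectedGeneFC(
        gene=gene,
        raw_fc=raw_fc,
        a_i=a_i,
        cnv_factor=factor,
        corrected=raw_fc * factor / a_i,
    )


def call_amplified(cnv: pd.DataFrame, threshold: float = DEFAULT_AMP_THRESHOLD) -> pd.DataFrame:
    """Add an ``amplified`` call (ratio >= threshold) to a CNV table lacking one."""
    out = cnv.copy()
    out["amplified"] = (out["ratio"] >= threshold).astype(int)
    return out


def corrected_fc_matrix(
    bundle: OmicsInputBundle,
    mirna_map: Optional[MiRNATargetMap] = None,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> pd.DataFrame:
    """Gene x patient corrected fold changes for a whole cohort.

    Neutral fallbacks keep every gene defined: unmapped genes (or an absent
    miRNA layer) take ``A_i = 1``; genes without an amplification call take
    copy-number factor 1.
    """
    fc = bundle.gene_fc.astype(float)
    penalty = pd.DataFrame(1.0, index=fc.index, columns=fc.columns)
    if mirna_map is not None and bundle.mirna_fc is not None:
        mirna_fc = bundle.mirna_fc
        available = set(mirna_fc.index)
        n_unmapped = 0
        for gene in fc.index:
            targeting = [m for m in mirna_map.mirnas_for(gene) if m in available]
            if targeting:
                penalty.loc[gene] = mirna_fc.loc[targeting].mean(axis=0)
            else:
                n_unmapped += 1
        if n_unmapped:
            logger.info(
                "%d/%d genes have no measured targeting miRNA; A_i = 1",
                n_unmapped, len(fc.index),
            )
    factor = pd.DataFrame(1.0, index=fc.index, columns=fc.columns)
    if bundle.cnv is not None and len(bundle.cnv):
        cnv = bundle.cnv
        if "amplified" not in cnv.columns:
            cnv = call_amplified(cnv, amp_threshold)
        amped = cnv[cnv["amplified"].astype(bool)]
        for row in amped.itertuples(index=False):
            if row.gene in factor.index and row.patient in factor.columns:
                factor.at[row.gene, row.patient] = float(row.ratio)
    corrected = fc * factor / penalty
    values = corrected.to_numpy()
    if not np.isfinite(values).all() or (values <= 0).any():
        raise DataError("corrected fold changes must be finite and > 0")
    return corrected


# ---------------------------------------------------------------------------
# node fold changes

@dataclass(frozen=True)
class NodeFoldChange:
    """Trimmed-mean fold change E_k of one node in one patient."""

    node: str
    contributing_genes: tuple[str, ...]
    e_k: float
    neutral: bool

    def __post_init__(self) -> None:
        if self.e_k <= 0:
            raise DataError(f"node {self.node!r}: E_k must be > 0")
        if self.neutral != (len(self.contributing_genes) == 0):
            raise DataError("neutral flag inconsistent with contributing genes")


def node_fold_change(
    node: InterventionalNode,
    corrected: Union[Mapping[str, float], pd.Series],
    trim: float = DEFAULT_TRIM,
    strict: bool = False,
) -> NodeFoldChange:
    """E_k for one node: mean corrected FC over genes passing the trim.

    "Absolute fold change" in ratio space means ``max(r, 1/r)``, so both
    2.0-fold up and 2.0-fold down (r = 0.5) pass a 1.3 trim; passers
    contribute their ratio as-is to the mean.  Genes absent from the data
    are skipped; with no passer the node is neutral (E_k = 1).
    ``strict=True`` switches the trim from >= to >.
    """
    passing: list[tuple[str, float]] = []
    for gene in sorted(node.genes):
        value = corrected.get(gene)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        value = float(value)
        if value <= 0:
            raise DataError(f"gene {gene!r}: corrected fold change must be > 0")
        magnitude = max(value, 1.0 / value)
        if (magnitude > trim) if strict else (magnitude >= trim):
            passing.append((gene, value))
    if not passing:
        return NodeFoldChange(node.name, (), 1.0, True)
    genes, values = zip(*passing)
    return NodeFoldChange(node.name, genes, float(np.mean(values)), False)


def node_fold_changes(
    registry: NodeRegistry,
    corrected: pd.DataFrame,
    trim: float = DEFAULT_TRIM,
    strict: bool = False,
) -> dict[str, dict[str, NodeFoldChange]]:
    """node name -> patient -> :class:`NodeFoldChange` for a whole cohort."""
    return {
        node.name: {
            patient: node_fold_change(node, corrected[patient], trim, strict)
            for patient in corrected.columns
        }
        for node in registry
    }


def node_fc_matrix(
    registry: NodeRegistry,
    corrected: pd.DataFrame,
    trim: float = DEFAULT_TRIM,
    strict: bool = False,
) -> pd.DataFrame:
    """Node x patient matrix of E_k values."""
    nfc = node_fold_changes(registry, corrected, trim, strict)
    out = pd.DataFrame.from_dict(
        {node: {p: v.e_k for p, v in per_patient.items()}
         for node, per_patient in nfc.items()},
        orient="index",
    )
    out = out.reindex(index=registry.names, columns=corrected.columns)
    out.index.name = "node"
    return out


# ---------------------------------------------------------------------------
# decile calibration

class Calibrator:
    """Per-node reference E_k distributions and their decile cut points.

    The reference cohort's E_k values define an empirical CDF per node; a
    query E_k maps to ``clamp(ceil(10 * F_hat(e)), 1, 10)``.  A value below
    every reference scores 1; the reference maximum (and anything above)
    scores 10; within a tie block every equal value gets the same score.
    """

    def __init__(self, reference: Mapping[str, Sequence[float]]):
        self._refs: dict[str, np.ndarray] = {}
        for node, values in reference.items():
            arr = np.sort(np.asarray(list(values), dtype=float))
            if arr.size < MIN_CALIBRATOR_SIZE:
                raise DataError(
                    f"calibrator for node {node!r} needs >= "
                    f"{MIN_CALIBRATOR_SIZE} reference values, got {arr.size}"
                )
            if not np.isfinite(arr).all() or (arr <= 0).any():
                raise DataError(f"calibrator for node {node!r}: invalid E_k values")
            self._refs[node] = arr

    @property
    def nodes(self) -> list[str]:
        return list(self._refs)

    def reference(self, node: str) -> np.ndarray:
        if node not in self._refs:
            raise DataError(f"calibrator has no node {node!r}")
        return self._refs[node]

    def cut_points(self, node: str) -> np.ndarray:
        """The nine decile boundaries (empirical quantiles at 0.1 ... 0.9)."""
        return np.quantile(self.reference(node), np.arange(1, 10) / 10)

    def score(self, node: str, e_k: float) -> int:
        refs = self.reference(node)
        rank = int(np.searchsorted(refs, e_k, side="right"))
        return int(min(10, max(1, math.ceil(10 * rank / refs.size))))

    # -- persistence (floats via JSON repr: bit-exact round trip) ----------
    def to_dict(self) -> dict:
        return {
            "format_version": CALIBRATOR_FORMAT_VERSION,
            "nodes": {
                node: {
                    "reference": refs.tolist(),
                    "cut_points": self.cut_points(node).tolist(),
                }
                for node, refs in self._refs.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Calibrator":
        if payload.get("format_version") != CALIBRATOR_FORMAT_VERSION:
            raise DataError("unsupported calibrator format version")
        return cls(
            {node: entry["reference"] for node, entry in payload["nodes"].items()}
        )

    def save(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: PathLike) -> "Calibrator":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Calibrator)
            and self._refs.keys() == other._refs.keys()
            and all(np.array_equal(self._refs[k], other._refs[k]) for k in self._refs)
        )


def build_calibrator(reference: Mapping[str, Sequence[float]]) -> Calibrator:
    """Build a calibrator from per-node lists of reference E_k values."""
    return Calibrator(reference)


def decile_score(e_k: float, node: str, calibrator: Calibrator) -> int:
    """Integer 1-10 decile score of ``e_k`` against the calibrator."""
    return calibrator.score(node, e_k)


# ---------------------------------------------------------------------------
# final node scores

@dataclass(frozen=True)
class NodeScore:
    """Final score of one node in one patient, with its evidence basis."""

    patient: str
    node: str
    score: int
    basis: str  # "mutation" | "expression"
    e_k: float

    def __post_init__(self) -> None:
        if self.score not in range(1, 11):
            raise DataError(f"score must be in 1..10, got {self.score}")
        if self.basis == "mutation" and self.score != 10:
            raise DataError("mutation basis forces score 10")


def _has_whitelisted_event(
    node: InterventionalNode,
    mutations: Union[pd.DataFrame, Iterable[tuple[str, str]]],
    whitelist: MutationWhitelist,
) -> bool:
    if isinstance(mutations, pd.DataFrame):
        events = zip(mutations["gene"], mutations["event_class"])
    else:
        events = mutations
    return any(
        whitelist.matches(gene, cls) and gene.upper() in node.genes
        for gene, cls in events
    )


def score_node(
    patient: str,
    node: InterventionalNode,
    node_fc: NodeFoldChange,
    calibrator: Calibrator,
    mutations: Union[pd.DataFrame, Iterable[tuple[str, str]]] = (),
    whitelist: Optional[MutationWhitelist] = None,
) -> NodeScore:
    """Score one node for one patient.

    A whitelisted activating event in any member gene gives score 10
    (basis "mutation"); the transcriptomic information is then unused.
    Otherwise the decile score of E_k is returned (basis "expression").
    """
    if whitelist is not None and _has_whitelisted_event(node, mutations, whitelist):
        return NodeScore(patient, node.name, 10, "mutation", node_fc.e_k)
    return NodeScore(
        patient, node.name, decile_score(node_fc.e_k, node.name, calibrator),
        "expression", node_fc.e_k,
    )


@dataclass
class ScoringResult:
    """Cohort scoring output: integer score matrix plus provenance."""

    scores: pd.DataFrame  # node x patient, int 1..10
    calibrator: Calibrator
    node_fc: pd.DataFrame  # node x patient E_k values
    basis: pd.DataFrame  # node x patient, "mutation" | "expression"

    def __iter__(self):  # allow ``scores, calibrator = score_cohort(...)``
        return iter((self.scores, self.calibrator))


def score_cohort(
    bundle: OmicsInputBundle,
    registry: NodeRegistry,
    mirna_map: Optional[MiRNATargetMap] = None,
    whitelist: Optional[MutationWhitelist] = None,
    calibrator: Optional[Calibrator] = None,
    trim: float = DEFAULT_TRIM,
    strict_trim: bool = False,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> ScoringResult:
    """Score every node for every patient in a cohort.

    Without an explicit calibrator the cohort is *self-calibrated*: the
    per-node E_k distribution of this very cohort defines the deciles (the
    mode used for the original 121-patient reference cohort).  Self
    calibration needs at least ``MIN_CALIBRATOR_SIZE`` patients.
    """
    bundle = bundle.validate()
    corrected = corrected_fc_matrix(bundle, mirna_map, amp_threshold)
    nfc = node_fold_changes(registry, corrected, trim, strict_trim)
    patients = bundle.patients
    e_k = pd.DataFrame(
        {p: [nfc[name][p].e_k for name in registry.names] for p in patients},
        index=registry.names,
    )
    e_k.index.name = "node"
    if calibrator is None:
        if len(patients) < MIN_CALIBRATOR_SIZE:
            raise SimsError(
                f"self-calibration needs >= {MIN_CALIBRATOR_SIZE} patients "
                f"(got {len(patients)}); supply an external calibrator"
            )
        calibrator = Calibrator(
            {node: e_k.loc[node].tolist() for node in e_k.index}
        )
    mutations_by_patient = {
        patient: group[["gene", "event_class"]]
        for patient, group in bundle.mutations.groupby("patient")
    }
    scores = pd.DataFrame(0, index=e_k.index, columns=patients, dtype=int)
    basis = pd.DataFrame("expression", index=e_k.index, columns=patients)
    empty = pd.DataFrame(columns=["gene", "event_class"])
    for node in registry:
        for patient in patients:
            result = score_node(
                patient, node, nfc[node.name][patient], calibrator,
                mutations_by_patient.get(patient, empty), whitelist,
            )
            scores.at[node.name, patient] = result.score
            basis.at[node.name, patient] = result.basis
    scores.index.name = "node"
    return ScoringResult(scores, calibrator, e_k, basis)
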
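"""Synthetic matched tumor/normal cohorts with planted node activations.

The generator emulates the *structure* the scoring pipeline consumes — one
tumor/normal fold change per gene and per miRNA per patient, gene-level
amplification calls, and a small activating-mutation table — with a known
ground truth of which nodes were planted active in which patient.  Genes of
active nodes draw fold changes from a log-normal effect distribution
(location above the 1.3 trim), all other genes from a log-normal noise
distribution centred on no change.  It makes no attempt to match any real
cohort's correlation structure, histology mix or outcomes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_io import (
    MUTATION_COLUMNS,
    CNV_COLUMNS,
    OmicsInputBundle,
    PathLike,
    compute_fold_changes,
    write_matrix,
)
from .errors import DataError, SimsError
from .registry import (
    MiRNATargetMap,
    MutationWhitelist,
    NodeRegistry,
    default_registry,
    default_whitelist,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the reported cohort structure: about half of the
    cohort activated per node with strong tumor/normal effects (typical
    planted fold change 2.5x against 1.3-trimmed noise), a minority of
    activations carried by mutations rather than expression, and sparse
    miRNA/CNV involvement.
    """

    n_patients: int = 200
    activation_prob: float = 0.5
    effect_mu: float = math.log(2.5)
    effect_sigma: float = 0.25
    noise_sigma: float = 0.2
    mutation_rate: float = 0.2
    mirna_coupling: float = 0.1
    cnv_rate: float = 0.1
    cnv_ratio_low: float = 1.5
    cnv_ratio_high: float = 3.0
    seed: int = 0
    paired_expression: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DataError("n_patients must be >= 1")
        for name in ("activation_prob", "mutation_rate", "mirna_coupling", "cnv_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.effect_mu <= 0:
            raise DataError("effect_mu must be > 0 (log fold-change location)")
        if self.effect_sigma < 0 or self.noise_sigma < 0:
            raise DataError("sigmas must be >= 0")
        if not 1.0 <= self.cnv_ratio_low <= self.cnv_ratio_high:
            raise DataError("need 1 <= cnv_ratio_low <= cnv_ratio_high")


@dataclass
class GroundTruth:
    """Planted activations: patient -> node set, plus planted mutations."""

    active: dict[str, set[str]] = field(default_factory=dict)
    mutations: list[tuple[str, str, str]] = field(default_factory=list)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(p, n) for p, nodes in self.active.items() for n in nodes}

    def to_dict(self) -> dict:
        return {
            "active": {p: sorted(nodes) for p, nodes in self.active.items()},
            "mutations": [list(m) for m in self.mutations],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        return cls(
            active={p: set(v) for p, v in payload["active"].items()},
            mutations=[tuple(m) for m in payload["mutations"]],
        )

    def save(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: PathLike) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def synthetic_mirna_map(registry: NodeRegistry, per_gene: int = 5) -> MiRNATargetMap:
    """A synthetic gene -> miRNA map with ``per_gene`` private miRNAs per
    gene (no download, no licensing; ids are synthetic)."""
    return MiRNATargetMap(
        {
            gene: tuple(f"mir-{gene.lower()}-{j}" for j in range(1, per_gene + 1))
            for gene in sorted(registry.genes)
        }
    )


def generate_cohort(
    config: SimulationConfig,
    registry: Optional[NodeRegistry] = None,
    mirna_map: Optional[MiRNATargetMap] = None,
    whitelist: Optional[MutationWhitelist] = None,
    out_dir: Optional[PathLike] = None,
) -> tuple[OmicsInputBundle, GroundTruth]:
    """Generate a cohort with planted node activations.

    Deterministic given ``config.seed``.  Per patient, each node is planted
    active with probability ``activation_prob``.  An active node containing
    a whitelisted gene is, with probability ``mutation_rate``, represented
    by a mutation instead of expression (its genes then draw noise — the
    override path, not the transcriptomic one, must recover it).  Genes of
    the remaining active nodes draw log-normal effects; with probability
    ``mirna_coupling`` an active gene's targeting miRNAs rise too
    (exercising the penalty), and with probability ``cnv_rate`` an active
    gene is amplified.  With ``out_dir`` set, files are written in the
    formats the I/O layer reads (plus ``truth.json``; in paired mode also
    tumor/normal expression matrices).
    """
    registry = registry or default_registry()
    mirna_map = mirna_map or synthetic_mirna_map(registry)
    whitelist = whitelist or default_whitelist()
    rng = np.random.default_rng(config.seed)

    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    genes = sorted(registry.genes)
    all_mirnas = sorted({m for _, ms in mirna_map.items() for m in ms})
    wl_by_node = {
        node.name: sorted(node.genes & whitelist.genes) for node in registry
    }
    wl_class = {}
    for gene, cls in sorted(whitelist.entries):
        wl_class.setdefault(gene, cls)

    truth = GroundTruth()
    gene_fc = pd.DataFrame(index=genes, columns=patients, dtype=float)
    mirna_fc = pd.DataFrame(index=all_mirnas, columns=patients, dtype=float)
    mutation_rows = []
    cnv_rows = []

    for patient in patients:
        active = {
            node.name
            for node in registry
            if rng.random() < config.activation_prob
        }
        truth.active[patient] = active
        # nodes represented by a mutation rather than expression
        mutated_nodes = set()
        for node in registry:  # fixed draw order
            candidates = wl_by_node[node.name]
            if node.name in active and candidates:
                if rng.random() < config.mutation_rate:
                    gene = candidates[int(rng.integers(len(candidates)))]
                    cls = wl_class[gene]
                    mutation_rows.append(
                        (patient, gene, cls, "synthetic activating event")
                    )
                    truth.mutations.append((patient, gene, node.name))
                    mutated_nodes.add(node.name)
        expression_nodes = active - mutated_nodes
        active_genes = set().union(
            *(registry.node(n).genes for n in expression_nodes)
        ) if expression_nodes else set()

        z = rng.standard_normal(len(genes))
        fc = np.empty(len(genes))
        for i, gene in enumerate(genes):
            if gene in active_genes:
                fc[i] = math.exp(config.effect_mu + config.effect_sigma * z[i])
            else:
                fc[i] = math.exp(config.noise_sigma * z[i])
        gene_fc[patient] = fc

        mirna_fc[patient] = np.exp(
            config.noise_sigma * rng.standard_normal(len(all_mirnas))
        )
        coupling_u = rng.random(len(genes))
        for i, gene in enumerate(genes):
            if gene in active_genes and coupling_u[i] < config.mirna_coupling:
                for mirna in mirna_map.mirnas_for(gene):
                    mirna_fc.at[mirna, patient] = math.exp(
                        config.effect_mu + config.effect_sigma * rng.standard_normal()
                    )

        cnv_u = rng.random(len(genes))
        cnv_r = rng.uniform(config.cnv_ratio_low, config.cnv_ratio_high, len(genes))
        for i, gene in enumerate(genes):
            if gene in active_genes and cnv_u[i] < config.cnv_rate:
                cnv_rows.append((gene, patient, float(cnv_r[i]), 1))

    gene_fc.index.name = "gene"
    mirna_fc.index.name = "mirna"
    bundle = OmicsInputBundle(
        gene_fc=gene_fc,
        mirna_fc=mirna_fc,
        cnv=pd.DataFrame(cnv_rows, columns=CNV_COLUMNS),
        mutations=pd.DataFrame(mutation_rows, columns=MUTATION_COLUMNS),
    ).validate()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        write_matrix(bundle.gene_fc, out / "gene_fc.tsv", fmt)
        write_matrix(bundle.mirna_fc, out / "mirna_fc.tsv", fmt)
        bundle.cnv.to_csv(out / "cnv.tsv", sep="\t", index=False,
                          float_format=fmt, lineterminator="\n")
        bundle.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False,
                                lineterminator="\n")
        truth.save(out / "truth.json")
        if config.paired_expression:
            # raw paired matrices whose ratio reproduces gene_fc exactly
            normal = pd.DataFrame(
                100.0, index=bundle.gene_fc.index, columns=bundle.gene_fc.columns
            )
            tumor = normal * bundle.gene_fc
            assert np.allclose(
                compute_fold_changes(tumor, normal), bundle.gene_fc
            )
            write_matrix(tumor, out / "tumor.tsv", fmt)
            write_matrix(normal, out / "normal.tsv", fmt)
    return bundle, truth


@dataclass
class RecoveryReport:
    """Sensitivity/specificity of planted-activation recovery."""

    sensitivity: float
    specificity: float
    per_node: pd.DataFrame  # index node; columns tp, fn, fp, tn, sens, spec


def evaluate_recovery(
    scores: pd.DataFrame,
    truth: GroundTruth,
    activated_min: int = 6,
) -> RecoveryReport:
    """Compare thresholded scores against the planted ground truth.

    Sensitivity: fraction of planted (patient, node) pairs with score >=
    ``activated_min``; specificity: fraction of non-planted pairs below it.
    """
    patients = [p for p in scores.columns if p in truth.active]
    if not patients:
        raise SimsError("score matrix and ground truth share no patients")
    rows = []
    for node in scores.index:
        tp = fn = fp = tn = 0
        for patient in patients:
            planted = node in truth.active[patient]
            called = scores.at[node, patient] >= activated_min
            if planted and called:
                tp += 1
            elif planted:
                fn += 1
            elif called:
                fp += 1
            else:
                tn += 1
        rows.append(
            {
                "node": node, "tp": tp, "fn": fn, "fp": fp, "tn": tn,
                "sens": tp / (tp + fn) if tp + fn else float("nan"),
                "spec": tn / (tn + fp) if tn + fp else float("nan"),
            }
        )
    per_node = pd.DataFrame(rows).set_index("node")
    tp, fn = per_node["tp"].sum(), per_node["fn"].sum()
    fp, tn = per_node["fp"].sum(), per_node["tn"].sum()
    return RecoveryReport(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        per_node=per_node,
    )
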
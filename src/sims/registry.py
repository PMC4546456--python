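"""Static knowledge base for interventional-node scoring.

An *interventional node* is a drug-actionable group of targets plus the
genes immediately upstream of them (receptors and their ligands, a kinase
and its regulators, ...) that is scored as a single unit.  The bundled
registry transcribes the published 24-node table for NSCLC; every
transcription decision is documented in ``data/provenance.md``.

This module also houses the two auxiliary lookup tables the scoring engine
needs: the gene -> miRNA target map (at most five miRNAs per gene, used for
the translational penalty) and the activating-mutation whitelist (gene,
event-class pairs whose presence forces a node score of 10).
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

from .errors import RegistryError

logger = logging.getLogger(__name__)

Source = Union[str, Path, TextIO]

_GENE_RE = re.compile(r"^[A-Z0-9]+$")

#: Mutation event classes recognised by the whitelist.
POINT_INDEL = "point/indel"
FUSION = "fusion/rearrangement"
EVENT_CLASSES = frozenset({POINT_INDEL, FUSION})

#: Maximum number of miRNAs retained per gene in a target map.
MAX_MIRNAS_PER_GENE = 5


def _open_source(source: Source) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.exists():
        return path.open("r", encoding="utf-8")
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        return io.StringIO(source)
    raise RegistryError(f"no such file: {source}")


@dataclass(frozen=True)
class InterventionalNode:
    """One drug-actionable node: a name, its member genes, drug annotations."""

    name: str
    genes: frozenset[str]
    drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("node name must be non-empty")
        if not self.genes:
            raise RegistryError(f"node {self.name!r} has an empty gene list")
        for g in self.genes:
            if not _GENE_RE.match(g):
                raise RegistryError(
                    f"node {self.name!r}: gene symbol {g!r} is not an "
                    "uppercase alphanumeric token"
                )


class NodeRegistry:
    """An ordered collection of interventional nodes with a gene index."""

    def __init__(self, nodes: Iterable[InterventionalNode]):
        self.nodes: tuple[InterventionalNode, ...] = tuple(nodes)
        names = [n.name for n in self.nodes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate node name(s): {sorted(dupes)}")
        self.gene_index: dict[str, list[str]] = {}
        for node in self.nodes:
            for gene in node.genes:
                self.gene_index.setdefault(gene, []).append(node.name)
        # registry order within each gene's node list
        order = {name: i for i, name in enumerate(names)}
        for gene in self.gene_index:
            self.gene_index[gene].sort(key=order.__getitem__)

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __eq__(self, other) -> bool:
        return isinstance(other, NodeRegistry) and self.nodes == other.nodes

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def genes(self) -> frozenset[str]:
        """Union of all member genes."""
        return frozenset(self.gene_index)

    def node(self, name: str) -> InterventionalNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise RegistryError(f"unknown node: {name!r}")

    def nodes_for_gene(self, gene: str) -> list[str]:
        """Names of every node whose gene set contains ``gene`` (registry
        order); empty list for unknown symbols."""
        return list(self.gene_index.get(gene, []))


def nodes_for_gene(registry: NodeRegistry, gene: str) -> list[str]:
    return registry.nodes_for_gene(gene)


def load_registry(source: Source) -> NodeRegistry:
    """Load a registry from TSV with columns node_name, genes, drugs.

    ``genes`` and ``drugs`` are semicolon-separated; drugs are optional.
    Duplicate gene symbols within one node are de-duplicated; duplicate
    node names, empty gene lists and unparsable rows raise
    :class:`RegistryError`.
    """
    fh = _open_source(source)
    rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if rows and rows[0] and rows[0][0].strip().lower() == "node_name":
        rows = rows[1:]
    if not rows:
        raise RegistryError("registry source contains no node rows")
    nodes = []
    for lineno, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise RegistryError(f"registry row {lineno} is unparsable: {row!r}")
        name = row[0].strip()
        raw_genes = [g.strip().upper() for g in row[1].split(";") if g.strip()]
        genes = frozenset(raw_genes)
        if len(genes) < len(raw_genes):
            logger.info("node %r: duplicate gene symbols de-duplicated", name)
        drugs = ()
        if len(row) > 2 and row[2].strip():
            drugs = tuple(d.strip() for d in row[2].split(";") if d.strip())
        try:
            nodes.append(InterventionalNode(name, genes, drugs))
        except RegistryError as exc:
            raise RegistryError(f"registry row {lineno}: {exc}") from exc
    return NodeRegistry(nodes)


def save_registry(registry: NodeRegistry, path: Union[str, Path]) -> None:
    """Write a registry in the TSV format accepted by :func:`load_registry`."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_name", "genes", "drugs"])
        for node in registry:
            writer.writerow(
                [node.name, ";".join(sorted(node.genes)), ";".join(node.drugs)]
            )


def _data_text(name: str) -> str:
    return resources.files("sims.data").joinpath(name).read_text(encoding="utf-8")


def default_registry() -> NodeRegistry:
    """The bundled 24-node registry (see ``data/provenance.md``)."""
    return load_registry(io.StringIO(_data_text("registry.tsv")))


@dataclass(frozen=True)
class MergedNodeAlias:
    """A reporting label that is the union of two or more nodes.

    The alias counts as activated in a patient iff any member node is
    activated.  Union semantics is the only reading consistent with the
    published group counts (mTOR=30, PI3K=28, merged label=42 in the
    PDL1-activated group: 42 > max and <= sum).
    """

    label: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise RegistryError(f"alias {self.label!r} needs >=2 member nodes")

    def validate(self, labels: Iterable[str]) -> None:
        known = set(labels)
        if self.label in known:
            raise RegistryError(
                f"alias label {self.label!r} collides with an existing node"
            )
        missing = [m for m in self.members if m not in known]
        if missing:
            raise RegistryError(
                f"alias {self.label!r} references unknown node(s): {missing}"
            )


#: Default merged reporting labels.
DEFAULT_ALIASES: tuple[MergedNodeAlias, ...] = (
    MergedNodeAlias("mTOR/PI3K", ("mTOR", "PI3K")),
)


class MiRNATargetMap:
    """gene -> up to five miRNA identifiers predicted to target it."""

    def __init__(self, mapping: Mapping[str, Sequence[str]]):
        self._map: dict[str, tuple[str, ...]] = {}
        for gene, mirnas in mapping.items():
            mirnas = tuple(mirnas)
            if len(mirnas) > MAX_MIRNAS_PER_GENE:
                raise RegistryError(
                    f"gene {gene!r} maps to {len(mirnas)} miRNAs "
                    f"(maximum {MAX_MIRNAS_PER_GENE})"
                )
            if any(not m for m in mirnas):
                raise RegistryError(f"gene {gene!r} has an empty miRNA id")
            self._map[gene.upper()] = mirnas

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._map

    def __eq__(self, other) -> bool:
        return isinstance(other, MiRNATargetMap) and self._map == other._map

    def mirnas_for(self, gene: str) -> tuple[str, ...]:
        """miRNAs targeting ``gene``; empty tuple if unmapped."""
        return self._map.get(gene.upper(), ())

    def items(self):
        return self._map.items()


def load_mirna_map(source: Source) -> MiRNATargetMap:
    """Load a gene -> miRNA map from TSV with columns gene, mirna[, rank].

    Per gene the top five miRNAs by rank (ascending; rank 1 = strongest
    prediction) are kept; without a rank column the first five listed are
    kept and a warning is logged if more were present.
    """
    fh = _open_source(source)
    rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if rows and rows[0][0].strip().lower() == "gene":
        rows = rows[1:]
    per_gene: dict[str, list[tuple[float, int, str]]] = {}
    unranked_overflow = set()
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise RegistryError(f"miRNA map row {i + 1} is unparsable: {row!r}")
        gene = row[0].strip().upper()
        mirna = row[1].strip()
        if not mirna:
            raise RegistryError(f"miRNA map row {i + 1}: empty miRNA id")
        rank = float("inf")
        if len(row) > 2 and row[2].strip():
            rank = float(row[2])
        per_gene.setdefault(gene, []).append((rank, i, mirna))
    mapping = {}
    for gene, entries in per_gene.items():
        entries.sort()  # by rank, then file order
        if len(entries) > MAX_MIRNAS_PER_GENE and all(
            e[0] == float("inf") for e in entries
        ):
            unranked_overflow.add(gene)
        mapping[gene] = [m for _, _, m in entries[:MAX_MIRNAS_PER_GENE]]
    if unranked_overflow:
        logger.warning(
            "miRNA map: %d gene(s) listed >%d unranked miRNAs; keeping the "
            "first %d listed",
            len(unranked_overflow),
            MAX_MIRNAS_PER_GENE,
            MAX_MIRNAS_PER_GENE,
        )
    return MiRNATargetMap(mapping)


class MutationWhitelist:
    """(gene, event class) pairs treated as activating mutations.

    Whitelist membership is the only activating criterion: any listed event
    in a patient forces score 10 for every node containing the gene.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.entries: frozenset[tuple[str, str]] = frozenset(
            (g.upper(), c) for g, c in entries
        )
        for gene, cls in self.entries:
            if cls not in EVENT_CLASSES:
                raise RegistryError(
                    f"whitelist entry {gene!r}: unknown event class {cls!r} "
                    f"(expected one of {sorted(EVENT_CLASSES)})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def matches(self, gene: str, event_class: str) -> bool:
        return (gene.upper(), event_class) in self.entries

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.entries)

    def check_against(self, registry: NodeRegistry) -> list[str]:
        """Return (and log) whitelist genes that resolve to no node."""
        orphans = [g for g in sorted(self.genes) if not registry.nodes_for_gene(g)]
        if orphans:
            logger.warning(
                "whitelist gene(s) not in any registry node: %s", orphans
            )
        return orphans


def load_whitelist(source: Source) -> MutationWhitelist:
    """Load a whitelist from TSV with columns gene, event_class."""
    fh = _open_source(source)
    rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if rows and rows[0][0].strip().lower() == "gene":
        rows = rows[1:]
    entries = []
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise RegistryError(f"whitelist row {i + 1} is unparsable: {row!r}")
        entries.append((row[0].strip(), row[1].strip()))
    return MutationWhitelist(entries)


def default_whitelist() -> MutationWhitelist:
    """EGFR/KRAS/BRAF/PIK3CA/ERBB2 point mutations plus ALK/ROS1/RET fusions.

    TP53 is deliberately absent: not all p53 mutations behave as loss (or
    gain) of function, so it cannot be treated as uniformly activating.
    """
    return load_whitelist(io.StringIO(_data_text("whitelist.tsv")))
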
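"""Reading, validating and writing cohort omics tables.

All expression quantities are *fold changes in ratio space*: tumor/normal
abundance ratios, strictly positive, with down-regulation in (0, 1).  The
ratio convention keeps the miRNA division and copy-number multiplication
used by the scoring engine well defined without sign bookkeeping.

Matrix layout on disk: TSV, first column the gene/miRNA identifier, one
column per patient.  Mutations: MAF-like TSV (patient, gene, event_class,
description) or a VCF whose records carry a gene annotation tag.  CNV: long
TSV (gene, patient, ratio, amplified).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MUTATION_COLUMNS = ["patient", "gene", "event_class", "description"]
CNV_COLUMNS = ["gene", "patient", "ratio", "amplified"]


def compute_fold_changes(
    tumor: pd.DataFrame, normal: pd.DataFrame, epsilon: float = 0.0
) -> pd.DataFrame:
    """Per-gene tumor/normal fold changes from paired expression matrices.

    ``FC = (tumor + epsilon) / (normal + epsilon)``.  Both matrices must
    share identical gene and patient axes; values must be non-negative.
    With ``epsilon = 0`` a zero in ``normal`` is an error rather than a
    silently inflated ratio.
    """
    if epsilon < 0:
        raise DataError("epsilon must be >= 0")
    for axis, ours, theirs in (
        ("gene", tumor.index, normal.index),
        ("patient", tumor.columns, normal.columns),
    ):
        if set(ours) != set(theirs):
            diff = sorted(set(ours).symmetric_difference(theirs))
            raise DataError(
                f"tumor/normal {axis} axes differ; first discrepancy: {diff[0]!r}"
            )
    normal = normal.reindex(index=tumor.index, columns=tumor.columns)
    if (tumor.to_numpy() < 0).any() or (normal.to_numpy() < 0).any():
        raise DataError("expression values must be >= 0")
    denom = normal + epsilon
    if (denom.to_numpy() == 0).any():
        raise DataError(
            "zero normal expression with epsilon=0; set a positive epsilon"
        )
    return (tumor + epsilon) / denom


@dataclass
class OmicsInputBundle:
    """Validated per-patient omics layers sharing one patient axis.

    ``mirna_fc`` and ``cnv`` may be None (missing layers are treated as
    neutral by the scoring engine); ``mutations`` may be empty.
    """

    gene_fc: pd.DataFrame
    mirna_fc: Optional[pd.DataFrame] = None
    cnv: Optional[pd.DataFrame] = None
    mutations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MUTATION_COLUMNS)
    )

    @property
    def patients(self) -> list[str]:
        return list(self.gene_fc.columns)

    def validate(self) -> "OmicsInputBundle":
        _check_fc_matrix(self.gene_fc, "gene_fc")
        if self.mirna_fc is not None:
            _check_fc_matrix(self.mirna_fc, "mirna_fc")
        if self.cnv is not None:
            missing = [c for c in CNV_COLUMNS if c not in self.cnv.columns]
            if missing:
                raise DataError(f"cnv table lacks column(s): {missing}")
            if (self.cnv["ratio"].to_numpy() <= 0).any():
                raise DataError("cnv ratios must be > 0")
        missing = [c for c in MUTATION_COLUMNS[:3] if c not in self.mutations.columns]
        if missing:
            raise DataError(f"mutation table lacks column(s): {missing}")
        return self

    def harmonized(self) -> "OmicsInputBundle":
        """Restrict every layer to the intersection of patient ids.

        Intersection (never union) so no patient is scored with a silently
        absent layer; a warning is logged when layers disagree.
        """
        patients = list(self.gene_fc.columns)
        for name, layer in (("mirna_fc", self.mirna_fc),):
            if layer is not None:
                shared = [p for p in patients if p in set(layer.columns)]
                if len(shared) < len(patients) or len(layer.columns) > len(shared):
                    logger.warning(
                        "patient ids differ between gene_fc and %s; "
                        "keeping the %d shared patients", name, len(shared)
                    )
                patients = shared
        bundle = OmicsInputBundle(
            gene_fc=self.gene_fc[patients],
            mirna_fc=None if self.mirna_fc is None else self.mirna_fc[patients],
            cnv=None
            if self.cnv is None
            else self.cnv[self.cnv["patient"].isin(patients)].reset_index(drop=True),
            mutations=self.mutations[
                self.mutations["patient"].isin(patients)
            ].reset_index(drop=True),
        )
        dropped = set(self.mutations["patient"]) - set(patients)
        if dropped:
            logger.warning(
                "mutation events for %d patient(s) outside the matrix layers "
                "were dropped", len(dropped)
            )
        return bundle


def _check_fc_matrix(df: pd.DataFrame, name: str) -> None:
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"{name}: duplicate row id(s): {dupes[:5]}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError(f"{name}: non-finite fold change")
    if (values <= 0).any():
        raise DataError(f"{name}: fold changes must be > 0 (ratio space)")


def read_matrix(path: PathLike, id_name: str = "gene") -> pd.DataFrame:
    """Read a TSV matrix (first column = identifier, one column per patient)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = id_name
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: PathLike, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format, lineterminator="\n")


def read_mutations(path: PathLike) -> pd.DataFrame:
    """Read a MAF-like mutation TSV (patient, gene, event_class, description)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MUTATION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise DataError(f"mutation table {path}: missing column(s) {missing}")
    if "description" not in df.columns:
        df["description"] = ""
    df["gene"] = df["gene"].str.upper()
    return df[MUTATION_COLUMNS]


def read_mutations_vcf(
    path: PathLike,
    patient: str,
    gene_tag: str = "GENE",
    class_tag: str = "CLASS",
    default_class: str = "point/indel",
) -> pd.DataFrame:
    """Read mutation events for one patient from a VCF.

    Only records carrying the ``gene_tag`` INFO field are used; the event
    class comes from ``class_tag`` when present, else ``default_class``.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    rows = []
    for record in VCF(str(path)):
        gene = record.INFO.get(gene_tag)
        if gene is None:
            continue
        cls = record.INFO.get(class_tag) or default_class
        desc = f"{record.CHROM}:{record.POS}:{record.REF}>{','.join(record.ALT)}"
        rows.append((patient, str(gene).upper(), cls, desc))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_cnv(path: PathLike) -> pd.DataFrame:
    """Read a long CNV table (gene, patient, ratio, amplified)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CNV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cnv table {path}: missing column(s) {missing}")
    df["gene"] = df["gene"].astype(str).str.upper()
    df["patient"] = df["patient"].astype(str)
    df["amplified"] = df["amplified"].astype(int)
    return df[CNV_COLUMNS]


def read_bundle(
    gene_fc: PathLike,
    mirna_fc: Optional[PathLike] = None,
    cnv: Optional[PathLike] = None,
    mutations: Optional[PathLike] = None,
) -> OmicsInputBundle:
    """Read and validate a cohort bundle from files.

    Missing layers are allowed (neutral); patients are harmonized by
    intersection across the supplied matrix layers.
    """
    bundle = OmicsInputBundle(
        gene_fc=read_matrix(gene_fc, "gene"),
        mirna_fc=None if mirna_fc is None else read_matrix(mirna_fc, "mirna"),
        cnv=None if cnv is None else read_cnv(cnv),
        mutations=pd.DataFrame(columns=MUTATION_COLUMNS)
        if mutations is None
        else read_mutations(mutations),
    )
    bundle.gene_fc.index = bundle.gene_fc.index.str.upper()
    return bundle.validate().harmonized()


def write_scores(scores: pd.DataFrame, path: PathLike) -> None:
    """Write a node x patient integer score matrix as TSV."""
    scores.astype(int).to_csv(path, sep="\t", lineterminator="\n")


def read_scores(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(int)
    df.index = df.index.astype(str)
    df.index.name = "node"
    df.columns = df.columns.astype(str)
    return df


def write_activation(matrix: pd.DataFrame, path: PathLike) -> None:
    """Write a patient x label boolean activation matrix as 0/1 TSV."""
    matrix.astype(int).to_csv(path, sep="\t", lineterminator="\n")


def read_activation(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
    df.index = df.index.astype(str)
    df.index.name = "patient"
    df.columns = df.columns.astype(str)
    return df


def write_report(report: dict, path: PathLike) -> None:
    validate_report(report)
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_schema() -> dict:
    return json.loads(
        resources.files("sims.data").joinpath("report.schema.json").read_text()
    )


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def validate_report(report: dict, schema: Optional[dict] = None, _path: str = "$") -> None:
    """Structural validation against the shipped report schema.

    Supports the subset of JSON Schema the shipped schema uses
    (type / required / properties / items).
    """
    schema = report_schema() if schema is None else schema
    expected = schema.get("type")
    if expected and not isinstance(report, _TYPES[expected]):
        raise DataError(f"report{_path}: expected {expected}, got {type(report).__name__}")
    if isinstance(report, bool) and expected in ("integer", "number"):
        raise DataError(f"report{_path}: expected {expected}, got bool")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise DataError(f"report{_path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{_path}.{key}")
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            validate_report(item, schema["items"], f"{_path}[{i}]")
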
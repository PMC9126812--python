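"""Readers and writers for every file format the pipeline touches.

One tabular dialect throughout: tab-separated UTF-8 with '.' decimals.  Gene
sets use standard GMT lines (name, description, then gene ids).  Readers
return the typed containers from :mod:`corticell.containers` and validate
cross-references eagerly so malformed inputs fail with a named cause.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import CohortTable, GeneSetCollection, GenotypeBundle
from .errors import InputError

log = logging.getLogger(__name__)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"malformed TSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# cohort


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort TSV: subject_id, group, age, sex, then region columns."""
    frame = _read_tsv(path, index_col="subject_id")
    try:
        return CohortTable.from_frame(frame)
    except (InputError, ValueError) as exc:
        raise InputError(f"invalid cohort table {path}: {exc}") from exc


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_frame().rename_axis("subject_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a region x gene expression TSV (rows = region labels)."""
    frame = _read_tsv(path, index_col=0)
    frame.index.name = "region"
    if frame.index.has_duplicates:
        raise InputError(f"duplicate region labels in {path}")
    if frame.columns.has_duplicates:
        raise InputError(f"duplicate gene ids in {path}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric expression values in {path}: {exc}") from exc
    if not frame.to_numpy().size or not pd.notna(frame).to_numpy().all():
        raise InputError(f"missing expression values in {path}")
    return frame


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("region").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, fields name, description, genes..."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"input file not found: {path}")
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
            )
        name, desc, *genes = fields
        if name in sets:
            raise InputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = tuple(genes)
        descriptions[name] = desc
    if not sets:
        raise InputError(f"no gene sets found in {path}")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, name), *collection[name]])
        for name in collection.names
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    dosage_path: str | Path,
    annotation_path: str | Path,
    weights_path: str | Path,
    gene_spans_path: str | Path | None = None,
    relatedness_path: str | Path | None = None,
) -> GenotypeBundle:
    """Assemble a :class:`GenotypeBundle` from its TSV components."""
    dosages = _read_tsv(dosage_path, index_col="subject_id")
    try:
        dosages = dosages.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric dosages in {dosage_path}: {exc}") from exc
    annotation = _read_tsv(annotation_path, index_col="snp_id")
    for col in ("chrom", "pos", "gene_id"):
        if col not in annotation.columns:
            raise InputError(f"{annotation_path} missing column {col!r}")
    weights = _read_tsv(weights_path, index_col="snp_id")
    for col in ("effect_allele", "beta"):
        if col not in weights.columns:
            raise InputError(f"{weights_path} missing column {col!r}")
    spans = None
    if gene_spans_path is not None:
        spans = _read_tsv(gene_spans_path, index_col="gene_id")
        for col in ("chrom", "start", "end"):
            if col not in spans.columns:
                raise InputError(f"{gene_spans_path} missing column {col!r}")
    if relatedness_path is not None:
        rel = _read_tsv(relatedness_path, index_col="subject_id")["relatedness"]
        rel = rel.reindex(dosages.index)
        if rel.isna().any():
            raise InputError(f"{relatedness_path} missing subjects present in dosages")
    else:
        rel = pd.Series(0.0, index=dosages.index, name="relatedness")
    try:
        return GenotypeBundle(dosages, annotation, weights, rel, spans)
    except InputError as exc:
        raise InputError(f"inconsistent genotype inputs ({dosage_path}): {exc}") from exc


def write_genotypes(
    bundle: GenotypeBundle,
    dosage_path: str | Path,
    annotation_path: str | Path,
    weights_path: str | Path,
    gene_spans_path: str | Path | None = None,
    relatedness_path: str | Path | None = None,
) -> None:
    bundle.dosages.rename_axis("subject_id").to_csv(dosage_path, sep="\t")
    bundle.annotation.rename_axis("snp_id").to_csv(annotation_path, sep="\t")
    bundle.weights.rename_axis("snp_id").to_csv(weights_path, sep="\t")
    if gene_spans_path is not None and bundle.gene_spans is not None:
        bundle.gene_spans.rename_axis("gene_id").to_csv(gene_spans_path, sep="\t")
    if relatedness_path is not None:
        bundle.relatedness.rename_axis("subject_id").to_frame().to_csv(
            relatedness_path, sep="\t"
        )


# ---------------------------------------------------------------------------
# cross-reference validation


def check_regions(expression: pd.DataFrame, cohort: CohortTable) -> None:
    """Require the expression matrix to cover every cohort region."""
    missing = [r for r in cohort.regions if r not in expression.index]
    if missing:
        raise InputError(
            f"expression matrix missing cohort regions: {missing}"
        )
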
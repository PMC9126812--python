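"""Typed in-memory containers for cohort, gene-set, and genotype data.

Tabular payloads are plain :class:`pandas.DataFrame` objects; the dataclasses
here add identity (which axis is which), cross-reference validation, and
round-trippable (de)serialization hooks used by :mod:`corticell.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

GROUP_HEALTHY = "healthy"
GROUP_PATIENT = "patient"


@dataclass
class CohortTable:
    """Subjects with demographics and regional cortical thickness (mm).

    ``demographics``: index subject_id, columns ``group`` (healthy/patient),
    ``age`` (years), ``sex`` (0 male / 1 female).
    ``cth``: index subject_id, one column per atlas region, values in mm.
    """

    demographics: pd.DataFrame
    cth: pd.DataFrame

    def __post_init__(self) -> None:
        demo, cth = self.demographics, self.cth
        if demo.index.has_duplicates:
            dupes = demo.index[demo.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate subject ids: {dupes[:5]}")
        if not demo.index.equals(cth.index):
            raise InputError("demographics and CTh tables index different subjects")
        missing = {"group", "age", "sex"} - set(demo.columns)
        if missing:
            raise InputError(f"cohort table missing columns: {sorted(missing)}")
        bad_group = set(demo["group"]) - {GROUP_HEALTHY, GROUP_PATIENT}
        if bad_group:
            raise InputError(f"unknown group labels: {sorted(bad_group)}")
        vals = cth.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise InputError("non-finite CTh values in cohort table")
        if (vals <= 0).any():
            raise InputError("non-positive CTh values in cohort table")

    @property
    def subjects(self) -> pd.Index:
        return self.demographics.index

    @property
    def regions(self) -> list[str]:
        return list(self.cth.columns)

    @property
    def n(self) -> int:
        return len(self.demographics)

    def subset(self, group: str) -> "CohortTable":
        """Restrict to one group (``healthy`` or ``patient``)."""
        mask = self.demographics["group"] == group
        return CohortTable(self.demographics.loc[mask].copy(), self.cth.loc[mask].copy())

    def to_frame(self) -> pd.DataFrame:
        """Single flat table (demographics then region columns), for TSV export."""
        return pd.concat([self.demographics, self.cth], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        demo_cols = ["group", "age", "sex"]
        region_cols = [c for c in frame.columns if c not in demo_cols]
        demo = frame[demo_cols].copy()
        demo["age"] = pd.to_numeric(demo["age"], errors="raise")
        demo["sex"] = pd.to_numeric(demo["sex"], errors="raise").astype(int)
        cth = frame[region_cols].astype(float)
        return cls(demo, cth)


@dataclass
class GeneSetCollection:
    """Ordered mapping cell type -> marker gene ids (GMT semantics)."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise InputError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise InputError(f"gene set {name!r} contains duplicate gene ids")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def restrict_to(self, genes) -> tuple["GeneSetCollection", dict[str, int]]:
        """Intersect every set with ``genes``; return (collection, n dropped per set).

        A set whose intersection is empty raises :class:`InputError` naming it.
        """
        available = set(genes)
        kept: dict[str, tuple[str, ...]] = {}
        dropped: dict[str, int] = {}
        for name, members in self.sets.items():
            inter = tuple(g for g in members if g in available)
            if not inter:
                raise InputError(
                    f"gene set {name!r} has no genes in the expression matrix"
                )
            kept[name] = inter
            dropped[name] = len(members) - len(inter)
        return GeneSetCollection(kept, dict(self.descriptions)), dropped


@dataclass
class GenotypeBundle:
    """SNP dosages plus annotation, effect weights, and per-subject covariates.

    ``dosages``: subjects x SNPs, values in [0, 2].
    ``annotation``: index snp_id, columns ``chrom``, ``pos``, ``gene_id``.
    ``weights``: index snp_id, columns ``effect_allele``, ``beta``.
    ``gene_spans`` (optional): index gene_id, columns ``chrom``, ``start``,
    ``end`` -- enables positional genic-boundary SNP selection.
    ``relatedness``: numeric family shared-factor covariate per subject.
    """

    dosages: pd.DataFrame
    annotation: pd.DataFrame
    weights: pd.DataFrame
    relatedness: pd.Series
    gene_spans: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise InputError("non-finite dosage values")
        if vals.min() < 0 or vals.max() > 2:
            raise InputError("dosages outside [0, 2]")
        missing = self.weights.index.difference(self.dosages.columns)
        if len(missing):
            raise InputError(
                f"weighted SNPs absent from dosage matrix: {missing[:5].tolist()}"
            )
        missing_ann = self.dosages.columns.difference(self.annotation.index)
        if len(missing_ann):
            raise InputError(
                f"SNPs missing annotation: {missing_ann[:5].tolist()}"
            )
        if not self.relatedness.index.equals(self.dosages.index):
            raise InputError("relatedness covariate indexes different subjects")

    @property
    def subjects(self) -> pd.Index:
        return self.dosages.index
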
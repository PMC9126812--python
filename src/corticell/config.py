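"""Run configuration: file paths plus the analysis parameters of every stage."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InputError


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Paths point at the five input files (plus optional genotype side tables);
    parameters carry the quantile set, permutation count, FDR level, PCA and
    clustering settings, and the genic boundary for SNP selection.  All
    randomness flows from ``seed``.
    """

    cohort_path: str = "cohort.tsv"
    expression_path: str = "expression.tsv"
    gmt_path: str = "cell_markers.gmt"
    genotype_path: str = "genotypes.tsv"
    annotation_path: str = "snp_annotation.tsv"
    weights_path: str = "weights.tsv"
    gene_spans_path: str | None = "genes.tsv"
    relatedness_path: str | None = "relatedness.tsv"

    quantiles: tuple[float, ...] = (0.05, 0.50, 0.95)
    n_permutations: int = 1000
    fdr_alpha: float = 0.05
    n_pcs: int = 4
    k_max: int = 7
    gap_B: int = 100
    genic_boundary_kb: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        q = tuple(self.quantiles)
        if sorted(q) != list(q) or len(set(q)) != len(q) or not all(0 < t < 1 for t in q):
            raise InputError("quantiles must be strictly increasing within (0, 1)")
        if self.n_permutations < 100:
            raise InputError("n_permutations must be >= 100")
        if not 1 <= self.n_pcs <= 7:
            raise InputError("n_pcs must be between 1 and the number of cell types")
        if not 0 < self.fdr_alpha < 1:
            raise InputError("fdr_alpha must be in (0, 1)")
        self.quantiles = q


def read_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from YAML or JSON; keyword overrides win.

    Relative paths inside the file are resolved against its directory.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"config file not found: {path}")
    text = path.read_text()
    try:
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise InputError(f"malformed config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise InputError(f"config {path} must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise InputError(f"unknown config keys in {path}: {sorted(unknown)}")
    payload.update({k: v for k, v in overrides.items() if v is not None})
    if "quantiles" in payload and payload["quantiles"] is not None:
        payload["quantiles"] = tuple(payload["quantiles"])
    cfg = RunConfig(**payload)
    base = path.parent
    for name in (
        "cohort_path", "expression_path", "gmt_path", "genotype_path",
        "annotation_path", "weights_path", "gene_spans_path", "relatedness_path",
    ):
        value = getattr(cfg, name)
        if value is not None and not Path(value).is_absolute():
            setattr(cfg, name, str(base / value))
    return cfg
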
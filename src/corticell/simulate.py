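"""Synthetic cohorts, expression, and genotypes with planted multi-scale structure.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage is testable without access-restricted imaging
or transcriptomic data:

* healthy cortical thickness (CTh) that is linear in age with an additive sex
  term per region, homoscedastic Gaussian region noise, and a single shared
  subject factor inducing inter-regional correlation;
* quasi-orthogonal cell-type spatial profiles, and a region x gene expression
  matrix in which each marker gene tracks its cell type's profile plus noise;
* patient CTh deviations built as a cell-type-weighted combination of those
  profiles, with subtype structure (which cell types are weighted) and a
  per-subject severity that scales with a cell-set-restricted polygenic
  burden computed from the same synthetic genotypes the validation stage
  scores;
* SNP dosages with per-gene annotation, Gaussian effect weights, and optional
  sib-like family pairs sharing half their dosage values.

Every generated table is a pure function of ``(SimConfig, seed)``.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import CELL_TYPES, DK_LEFT_REGIONS
from .containers import GROUP_HEALTHY, GROUP_PATIENT, CohortTable, GeneSetCollection, GenotypeBundle
from .errors import InputError, NumericalError

log = logging.getLogger(__name__)

_PROFILE_REDRAW_LIMIT = 1000


@dataclass(frozen=True)
class SubtypeSpec:
    """One planted patient subtype.

    ``coupling_weights`` maps cell type -> weight on that cell type's spatial
    profile (negative = thinning where the cell type is highly expressed).
    ``mean_shift`` is a whole-brain deviation offset (z units) scaled by the
    same per-subject severity, so that subtypes differ in mean deviation and
    the polygenic-burden -> severity link is visible in the regional mean.
    """

    label: str
    proportion: float
    coupling_weights: dict[str, float]
    severity_scale: float = 1.0
    mean_shift: float = 0.0


def default_subtypes() -> tuple[SubtypeSpec, ...]:
    """Three-subtype configuration mirroring the planted pattern under study.

    Subtype I: neuronal/endothelial thinning; Subtype II: weak mixed
    neuronal/astrocyte/OPC thinning; Subtype III: astrocyte/OPC thinning.
    Microglia and oligodendrocyte carry zero weight in every subtype (the two
    null cell types).
    """
    return (
        SubtypeSpec(
            "I", 0.25,
            {"excitatory": -1.2, "inhibitory": -1.2, "endothelial": -1.2},
            severity_scale=1.0, mean_shift=-1.0,
        ),
        SubtypeSpec(
            "II", 0.45,
            {"excitatory": -0.6, "inhibitory": -0.6, "astrocyte": -0.6, "OPC": -0.6},
            severity_scale=1.0, mean_shift=-0.85,
        ),
        SubtypeSpec(
            "III", 0.30,
            {"astrocyte": -1.2, "OPC": -1.2},
            severity_scale=1.0, mean_shift=-0.55,
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with defaults defining the study conditions.

    Units: CTh intercepts/offsets/noise in mm, ages in years, expression and
    deviation terms unitless (z-scale), allele frequencies as fractions.
    """

    n_healthy: int = 2000
    n_patient: int = 200
    n_regions: int = 34
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio: float = 0.5
    region_params: pd.DataFrame | None = None  # columns intercept, age_slope, sex_offset, noise_sd
    shared_factor_sd: float = 0.05
    n_genes: int = 1200
    n_celltypes: int = 7
    markers_per_celltype: int = 40
    expression_noise_sd: float = 0.5
    profile_max_corr: float = 0.5
    subtype_config: tuple[SubtypeSpec, ...] = field(default_factory=default_subtypes)
    coupling_jitter_sd: float = 0.2
    deviation_noise_sd: float = 1.0
    n_snps: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    snps_per_gene: int = 3
    effect_sd: float = 0.1
    n_family_pairs: int = 20
    prs_deviation_slope: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise InputError("n_regions must be >= 3")
        props = [s.proportion for s in self.subtype_config]
        if abs(sum(props) - 1.0) > 1e-8:
            raise InputError("subtype proportions must sum to 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InputError("maf_range must lie in (0, 0.5]")
        if self.shared_factor_sd < 0 or self.expression_noise_sd < 0:
            raise InputError("noise SDs must be non-negative")
        if not (0 <= self.sex_ratio <= 1):
            raise InputError("sex_ratio must be a fraction in [0, 1]")
        if self.n_celltypes < 1 or self.n_celltypes > len(CELL_TYPES):
            raise InputError(f"n_celltypes must be in 1..{len(CELL_TYPES)}")

    @property
    def region_names(self) -> list[str]:
        if self.n_regions == len(DK_LEFT_REGIONS):
            return list(DK_LEFT_REGIONS)
        return [f"region{i:02d}" for i in range(self.n_regions)]

    @property
    def celltype_names(self) -> list[str]:
        return list(CELL_TYPES[: self.n_celltypes])

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent random stream derived from the config seed."""
        key = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )

    def resolve_region_params(self) -> pd.DataFrame:
        """Per-region generating parameters; drawn once from the seed when unset.

        Intercepts span the realistic adult cortical range (~2.0-3.4 mm), age
        slopes are mild thinning (-0.008..-0.002 mm/year), sex offsets are
        small, and region noise is 0.12 mm.
        """
        if self.region_params is not None:
            rp = self.region_params
            missing = {"intercept", "age_slope", "sex_offset", "noise_sd"} - set(rp.columns)
            if missing:
                raise InputError(f"region_params missing columns: {sorted(missing)}")
            if (rp["noise_sd"] < 0).any():
                raise InputError("region noise_sd must be non-negative")
            return rp.loc[self.region_names]
        rng = self.rng("region-params")
        n = self.n_regions
        return pd.DataFrame(
            {
                "intercept": rng.uniform(2.0, 3.4, n),
                "age_slope": rng.uniform(-0.008, -0.002, n),
                "sex_offset": rng.uniform(-0.05, 0.05, n),
                "noise_sd": np.full(n, 0.12),
            },
            index=self.region_names,
        )


@dataclass
class TruthRecord:
    """Ground truth planted by the generator, for parameter-recovery oracles."""

    labels: pd.Series  # patient -> subtype label
    coupling_weights: pd.DataFrame  # patients x cell types (severity-scaled)
    severity: pd.Series  # patient -> severity multiplier
    burden: pd.Series  # patient -> standardized cell-set genetic burden
    profiles: pd.DataFrame  # regions x cell types, zero mean / unit SD columns

    def to_json(self, path: Path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "coupling_weights": {
                s: {c: float(v) for c, v in row.items()}
                for s, row in self.coupling_weights.iterrows()
            },
            "severity": {k: float(v) for k, v in self.severity.items()},
            "burden": {k: float(v) for k, v in self.burden.items()},
            "profiles": {
                c: {r: float(v) for r, v in col.items()}
                for c, col in self.profiles.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        labels = pd.Series(payload["labels"]).sort_index()
        weights = pd.DataFrame(payload["coupling_weights"]).T.sort_index()
        return cls(
            labels=labels,
            coupling_weights=weights.loc[labels.index],
            severity=pd.Series(payload["severity"]).loc[labels.index],
            burden=pd.Series(payload["burden"]).loc[labels.index],
            profiles=pd.DataFrame(payload["profiles"]),
        )


# ---------------------------------------------------------------------------
# cell-type spatial profiles and expression


def gen_celltype_profiles(config: SimConfig) -> pd.DataFrame:
    """True cell-type spatial profiles: regions x cell types.

    Columns are drawn as a random orthonormal frame (QR of a Gaussian matrix)
    and then standardized to zero mean and unit sample SD across regions, so
    pairwise correlations are near zero; draws violating the configured
    ``profile_max_corr`` bound are redrawn a bounded number of times.
    """
    if config.n_celltypes > config.n_regions:
        raise InputError("need n_regions >= n_celltypes for quasi-orthogonal profiles")
    rng = config.rng("profiles")
    for _ in range(_PROFILE_REDRAW_LIMIT):
        raw = rng.standard_normal((config.n_regions, config.n_celltypes))
        q, r = np.linalg.qr(raw)
        q = q * np.sign(np.diag(r))  # deterministic orientation
        cols = q - q.mean(axis=0)
        cols = cols / cols.std(axis=0, ddof=1)
        corr = np.corrcoef(cols, rowvar=False)
        if config.n_celltypes == 1:
            off = 0.0
        else:
            off = np.abs(corr - np.eye(config.n_celltypes)).max()
        if off <= config.profile_max_corr:
            return pd.DataFrame(cols, index=config.region_names, columns=config.celltype_names)
    raise NumericalError(
        f"could not draw profiles with pairwise |r| <= {config.profile_max_corr} "
        f"in {_PROFILE_REDRAW_LIMIT} attempts"
    )


def _gene_ids(config: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    """All gene ids plus the marker assignment cell type -> gene ids."""
    n_marker = config.markers_per_celltype * config.n_celltypes
    if n_marker > config.n_genes:
        raise InputError("n_genes too small for the requested marker sets")
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    markers = {
        ct: genes[i * config.markers_per_celltype : (i + 1) * config.markers_per_celltype]
        for i, ct in enumerate(config.celltype_names)
    }
    return genes, markers


def gen_expression(
    config: SimConfig, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Region x gene expression matrix plus disjoint marker gene sets.

    Marker gene g of cell type c has region vector profile_c + N(0, noise);
    background genes are independent standard normals.
    """
    rng = config.rng("expression")
    genes, markers = _gene_ids(config)
    expr = rng.standard_normal((config.n_regions, config.n_genes))
    for ct, ids in markers.items():
        idx = [genes.index(g) for g in ids]
        noise = rng.normal(0.0, config.expression_noise_sd, (config.n_regions, len(ids)))
        expr[:, idx] = profiles[ct].to_numpy()[:, None] + noise
    sets = GeneSetCollection(
        {ct: tuple(ids) for ct, ids in markers.items()},
        {ct: f"synthetic markers for {ct}" for ct in markers},
    )
    return pd.DataFrame(expr, index=config.region_names, columns=genes), sets


# ---------------------------------------------------------------------------
# cohorts


def _draw_demographics(
    config: SimConfig, rng: np.random.Generator, ids: list[str], group: str
) -> pd.DataFrame:
    ages = rng.uniform(*config.age_range, len(ids))
    sexes = (rng.random(len(ids)) < config.sex_ratio).astype(int)
    return pd.DataFrame({"group": group, "age": ages, "sex": sexes}, index=ids)


def _mean_structure(demo: pd.DataFrame, params: pd.DataFrame) -> np.ndarray:
    """Expected CTh per subject x region from the linear age/sex model."""
    return (
        params["intercept"].to_numpy()[None, :]
        + np.outer(demo["age"].to_numpy(), params["age_slope"].to_numpy())
        + np.outer(demo["sex"].to_numpy(), params["sex_offset"].to_numpy())
    )


def gen_healthy_cohort(config: SimConfig) -> CohortTable:
    """Healthy cohort: CTh linear in age/sex plus shared factor and region noise."""
    rng = config.rng("healthy")
    params = config.resolve_region_params()
    ids = [f"hc-{i:04d}" for i in range(config.n_healthy)]
    demo = _draw_demographics(config, rng, ids, GROUP_HEALTHY)
    u = rng.normal(0.0, config.shared_factor_sd, (config.n_healthy, 1))
    eps = rng.standard_normal((config.n_healthy, config.n_regions)) * params[
        "noise_sd"
    ].to_numpy()[None, :]
    cth = _mean_structure(demo, params) + u + eps
    return CohortTable(demo, pd.DataFrame(cth, index=ids, columns=config.region_names))


def patient_ids(config: SimConfig) -> list[str]:
    return [f"scz-{i:04d}" for i in range(config.n_patient)]


def gen_patient_cohort(
    config: SimConfig,
    profiles: pd.DataFrame,
    genotypes: GenotypeBundle | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> tuple[CohortTable, TruthRecord]:
    """Patient cohort with subtype-structured, severity-scaled deviations.

    Deviation field (z units): Delta_ir = severity_i * (sum_c w_ic profile_rc
    + mean_shift_s) + N(0, deviation_noise_sd), where the subject's weights
    w_ic are the subtype's coupling weights plus within-subtype Gaussian
    jitter (SD ``coupling_jitter_sd``) on every cell type that carries
    weight in at least one subtype -- subtypes are graded tendencies rather
    than point masses, so coupling varies continuously across patients while
    unweighted (null) cell types stay exactly uncoupled.  severity_i =
    severity_scale * (1 + prs_deviation_slope * burden_i) truncated at zero,
    with burden_i the standardized cell-set polygenic burden over the
    subtype's weighted cell types, computed from ``genotypes`` exactly as
    the validation stage scores them.  Patient CTh = healthy mean structure
    + shared factor + Delta * region noise SD.
    """
    if config.prs_deviation_slope != 0 and genotypes is None:
        raise InputError(
            "prs_deviation_slope is nonzero but no genotypes were supplied"
        )
    rng = config.rng("patients")
    params = config.resolve_region_params()
    ids = patient_ids(config)
    demo = _draw_demographics(config, rng, ids, GROUP_PATIENT)

    specs = list(config.subtype_config)
    labels = pd.Series(
        rng.choice([s.label for s in specs], size=config.n_patient,
                   p=[s.proportion for s in specs]),
        index=ids, name="subtype",
    )

    burden = pd.Series(0.0, index=ids, name="burden")
    if genotypes is not None and config.prs_deviation_slope != 0:
        if gene_sets is None:
            raise InputError("gene_sets are required to compute cell-set burden")
        from .genetics import cell_prs, snps_for_cell_type

        cell_scores = pd.DataFrame(
            {
                ct: cell_prs(genotypes, snps_for_cell_type(genotypes, gene_sets, ct))
                for ct in config.celltype_names
            }
        ).loc[ids]
        for spec in specs:
            members = labels.index[labels == spec.label]
            if not len(members):
                continue
            sig = [c for c in config.celltype_names if spec.coupling_weights.get(c, 0.0) != 0]
            if not sig:
                continue
            agg = cell_scores[sig].mean(axis=1)
            agg = (agg - agg.mean()) / agg.std(ddof=1)
            burden.loc[members] = agg.loc[members]

    weight_matrix = pd.DataFrame(
        0.0, index=[s.label for s in specs], columns=config.celltype_names
    )
    shift = pd.Series({s.label: s.mean_shift for s in specs})
    scale = pd.Series({s.label: s.severity_scale for s in specs})
    for spec in specs:
        for ct, w in spec.coupling_weights.items():
            if ct not in weight_matrix.columns:
                raise InputError(f"unknown cell type in subtype config: {ct!r}")
            weight_matrix.loc[spec.label, ct] = w

    severity = scale.loc[labels].to_numpy() * (
        1.0 + config.prs_deviation_slope * burden.to_numpy()
    )
    severity = np.clip(severity, 0.0, None)
    w_subject = weight_matrix.loc[labels].to_numpy() * severity[:, None]
    disease_cols = (weight_matrix != 0).any(axis=0).to_numpy()
    if config.coupling_jitter_sd > 0 and disease_cols.any():
        jitter = rng.normal(
            0.0, config.coupling_jitter_sd,
            (config.n_patient, int(disease_cols.sum())),
        )
        w_subject[:, disease_cols] += jitter

    delta = (
        w_subject @ profiles.to_numpy().T
        + (severity * shift.loc[labels].to_numpy())[:, None]
        + rng.normal(0.0, config.deviation_noise_sd, (config.n_patient, config.n_regions))
    )
    u = rng.normal(0.0, config.shared_factor_sd, (config.n_patient, 1))
    cth = _mean_structure(demo, params) + u + delta * params["noise_sd"].to_numpy()[None, :]

    cohort = CohortTable(demo, pd.DataFrame(cth, index=ids, columns=config.region_names))
    truth = TruthRecord(
        labels=labels,
        coupling_weights=pd.DataFrame(
            w_subject, index=ids, columns=config.celltype_names
        ),
        severity=pd.Series(severity, index=ids, name="severity"),
        burden=burden,
        profiles=profiles.copy(),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# genotypes


def gen_genotypes(config: SimConfig, gene_sets: GeneSetCollection) -> GenotypeBundle:
    """SNP dosages, annotation, effect weights, and family structure for patients.

    SNPs are laid out ``snps_per_gene`` per gene, covering every marker gene
    first and then background genes up to ``n_snps``; dosages are
    Binomial(2, maf) draws; effect weights are N(0, effect_sd^2).  Optional
    sib-like family pairs share each dosage value with probability 1/2.
    """
    rng = config.rng("genotypes")
    genes, _ = _gene_ids(config)
    marker_genes = [g for ct in gene_sets.names for g in gene_sets[ct]]
    background = [g for g in genes if g not in set(marker_genes)]
    ordered_genes = marker_genes + background

    n_genes_used = int(np.ceil(config.n_snps / config.snps_per_gene))
    if n_genes_used > len(ordered_genes):
        raise InputError("n_snps requires more genes than are available")
    spans = pd.DataFrame(
        {
            "chrom": [f"chr{(genes.index(g) % 22) + 1}" for g in ordered_genes[:n_genes_used]],
            "start": [100_000 * (genes.index(g) + 1) for g in ordered_genes[:n_genes_used]],
        },
        index=pd.Index(ordered_genes[:n_genes_used], name="gene_id"),
    )
    spans["end"] = spans["start"] + 20_000

    snp_gene = [
        ordered_genes[i // config.snps_per_gene] for i in range(config.n_snps)
    ]
    snp_ids = [f"rs{i:06d}" for i in range(config.n_snps)]
    pos = [
        int(spans.loc[g, "start"] + rng.integers(0, 20_001)) for g in snp_gene
    ]
    annotation = pd.DataFrame(
        {
            "chrom": spans.loc[snp_gene, "chrom"].to_numpy(),
            "pos": pos,
            "gene_id": snp_gene,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )

    ids = patient_ids(config)
    maf = rng.uniform(*config.maf_range, config.n_snps)
    dosages = rng.binomial(2, maf[None, :], (config.n_patient, config.n_snps)).astype(float)

    relatedness = pd.Series(0.0, index=pd.Index(ids), name="relatedness")
    n_pairs = min(config.n_family_pairs, config.n_patient // 2)
    for p in range(n_pairs):
        a, b = 2 * p, 2 * p + 1
        share = rng.random(config.n_snps) < 0.5
        dosages[b, share] = dosages[a, share]
        fam_value = rng.standard_normal()
        relatedness.iloc[a] = fam_value
        relatedness.iloc[b] = fam_value

    weights = pd.DataFrame(
        {
            "effect_allele": rng.choice(list("ACGT"), config.n_snps),
            "beta": rng.normal(0.0, config.effect_sd, config.n_snps),
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeBundle(
        dosages=pd.DataFrame(dosages, index=ids, columns=snp_ids),
        annotation=annotation,
        weights=weights,
        relatedness=relatedness,
        gene_spans=spans,
    )


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class FixtureBundle:
    """All generated study objects, in the order the pipeline consumes them."""

    config: SimConfig
    profiles: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: GeneSetCollection
    genotypes: GenotypeBundle
    healthy: CohortTable
    patients: CohortTable
    truth: TruthRecord

    @property
    def cohort(self) -> CohortTable:
        """Healthy and patient subjects concatenated into one table."""
        return CohortTable(
            pd.concat([self.healthy.demographics, self.patients.demographics]),
            pd.concat([self.healthy.cth, self.patients.cth]),
        )


def gen_fixture_bundle(config: SimConfig) -> FixtureBundle:
    """Run the whole generative chain for one configuration."""
    profiles = gen_celltype_profiles(config)
    expression, gene_sets = gen_expression(config, profiles)
    genotypes = gen_genotypes(config, gene_sets)
    healthy = gen_healthy_cohort(config)
    patients, truth = gen_patient_cohort(config, profiles, genotypes, gene_sets)
    return FixtureBundle(
        config, profiles, expression, gene_sets, genotypes, healthy, patients, truth
    )


def write_fixture_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a bundle and write all input files (TSV/GMT/JSON) to ``outdir``.

    The directory must already exist; the return value maps logical names to
    the written paths.  Files round-trip losslessly through
    :mod:`corticell.io`.
    """
    from . import io as cio

    outdir = Path(outdir)
    if not outdir.is_dir():
        raise InputError(f"output directory does not exist: {outdir}")
    bundle = gen_fixture_bundle(config)
    paths = {
        "cohort": outdir / "cohort.tsv",
        "expression": outdir / "expression.tsv",
        "gene_sets": outdir / "cell_markers.gmt",
        "genotypes": outdir / "genotypes.tsv",
        "annotation": outdir / "snp_annotation.tsv",
        "weights": outdir / "weights.tsv",
        "gene_spans": outdir / "genes.tsv",
        "relatedness": outdir / "relatedness.tsv",
        "truth": outdir / "truth.json",
    }
    cio.write_cohort(bundle.cohort, paths["cohort"])
    cio.write_expression(bundle.expression, paths["expression"])
    cio.write_gmt(bundle.gene_sets, paths["gene_sets"])
    cio.write_genotypes(bundle.genotypes, paths["genotypes"], paths["annotation"],
                        paths["weights"], paths["gene_spans"], paths["relatedness"])
    bundle.truth.to_json(paths["truth"])
    log.info("wrote fixture bundle (%d files) to %s", len(paths), outdir)
    return paths
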
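"""Cell-set-constrained polygenic scores and subtype validation.

A cell-type polygenic score is a weighted allele-dosage sum over SNPs in
(or within a configurable genic boundary of) the cell type's marker genes,
z-standardized across subjects.  Subtype scores average the standardized
cell scores over the cell types in that subtype's coupling signature (the
FDR-significant negative medians).  Validation asks whether, within the
members of each subtype, the matched subtype score covaries with
whole-brain deviation severity (mean delta-z across regions), partialling
out sex, the genome-wide score, and a familial-relatedness covariate, with
BH-FDR across the matched subtype tests.  A full score x subtype
specificity grid is reported unadjusted, and a membership sweep re-runs the
matched correlation at increasing soft-membership thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .containers import GeneSetCollection, GenotypeBundle
from .errors import InputError, NumericalError

log = logging.getLogger(__name__)


def snps_for_cell_type(
    bundle: GenotypeBundle,
    gene_sets: GeneSetCollection,
    cell_type: str,
    boundary_kb: float = 10.0,
) -> list[str]:
    """SNPs in or proximal to the cell type's marker genes.

    When the bundle carries gene spans, a SNP is selected if its position
    lies within the closed interval [gene start - boundary, gene end +
    boundary] of any marker gene on the same chromosome; otherwise selection
    falls back to the annotated gene_id membership.
    """
    if cell_type not in gene_sets.sets:
        raise InputError(f"unknown cell type {cell_type!r}")
    genes = set(gene_sets[cell_type])
    ann = bundle.annotation
    if bundle.gene_spans is not None:
        spans = bundle.gene_spans.loc[bundle.gene_spans.index.isin(genes)]
        pad = boundary_kb * 1000.0
        selected: set[str] = set()
        for _, gene in spans.iterrows():
            hit = ann[
                (ann["chrom"] == gene["chrom"])
                & (ann["pos"] >= gene["start"] - pad)
                & (ann["pos"] <= gene["end"] + pad)
            ]
            selected.update(hit.index)
        snps = [s for s in ann.index if s in selected]
    else:
        snps = ann.index[ann["gene_id"].isin(genes)].tolist()
    if not snps:
        raise InputError(f"no SNPs map to the {cell_type!r} gene set")
    return snps


def cell_prs(bundle: GenotypeBundle, snp_list: list[str]) -> pd.Series:
    """Standardized weighted allele sum over ``snp_list``.

    score_i = sum_snp dosage_{i,snp} * beta_snp, then z-scored across
    subjects (sample SD).  A raw score with zero variance (e.g. all-zero
    weights) raises :class:`NumericalError`.
    """
    if not snp_list:
        raise InputError("empty SNP list for polygenic score")
    missing = [s for s in snp_list if s not in bundle.weights.index]
    if missing:
        raise InputError(f"SNPs without effect weights: {missing[:5]}")
    beta = bundle.weights.loc[snp_list, "beta"].to_numpy()
    raw = bundle.dosages[snp_list].to_numpy() @ beta
    sd = raw.std(ddof=1)
    if not sd > 0:
        raise NumericalError("degenerate score: zero variance across subjects")
    return pd.Series((raw - raw.mean()) / sd, index=bundle.subjects, name="prs")


def genomewide_prs(bundle: GenotypeBundle) -> pd.Series:
    """Standardized score over every weighted SNP (genome-wide liability)."""
    return cell_prs(bundle, bundle.weights.index.tolist()).rename("genomewide_prs")


def subtype_score(cell_scores: pd.DataFrame, signature: list[str]) -> pd.Series:
    """Average the standardized cell scores over a subtype's signature.

    The mean over exactly the signature cell types is re-standardized across
    subjects.  Invariant to the order of the signature.
    """
    if not signature:
        raise InputError("subtype has no signature cell types; score undefined")
    missing = [c for c in signature if c not in cell_scores.columns]
    if missing:
        raise InputError(f"signature cell types without scores: {missing}")
    agg = cell_scores[list(signature)].mean(axis=1)
    sd = agg.std(ddof=1)
    if not sd > 0:
        raise NumericalError("degenerate aggregated score: zero variance")
    return (agg - agg.mean()) / sd


def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates by least squares.

    Both variables are residualized on an intercept plus the covariate
    columns; p is two-sided from a t distribution with n - 2 - q degrees of
    freedom (q covariates).  With no covariates this is the plain Pearson
    correlation.  Collinear covariates trigger a rank warning and a
    pseudo-inverse fit; a variable perfectly explained by the covariates is
    an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise InputError("x and y have different lengths")
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise InputError("covariates do not match the sample size")
    q = c.shape[1]
    if n <= q + 2:
        raise InputError(f"need n > q + 2 observations (n={n}, q={q})")
    design = np.column_stack([np.ones(n), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear covariates; using pseudo-inverse residualization")
    proj = design @ np.linalg.pinv(design)
    rx = x - proj @ x
    ry = y - proj @ y
    sx, sy = np.sqrt((rx**2).sum()), np.sqrt((ry**2).sum())
    tol = 1e-10 * max(1.0, float(np.abs(x).max()), float(np.abs(y).max()))
    if sx <= tol or sy <= tol:
        raise NumericalError("variable perfectly explained by covariates; r undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - q
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class ValidationResult:
    """Matched-subtype partial correlations, specificity grid, and sweep.

    ``primary`` rows per subtype: signature cell types, n, partial_r, p,
    fdr_p.  ``grid`` is every subtype score tested within every subtype's
    members (unadjusted, exploratory).  ``sweep`` is the soft-membership
    threshold sweep for each matched pair.
    """

    primary: pd.DataFrame
    grid: pd.DataFrame
    sweep: pd.DataFrame
    skipped: list


def _covariate_matrix(
    subjects: pd.Index,
    sex: pd.Series,
    genomewide: pd.Series,
    relatedness: pd.Series,
) -> np.ndarray:
    cov = np.column_stack(
        [
            sex.loc[subjects].to_numpy(dtype=float),
            genomewide.loc[subjects].to_numpy(dtype=float),
            relatedness.loc[subjects].to_numpy(dtype=float),
        ]
    )
    # a constant covariate column (e.g. no families) carries no information;
    # drop it rather than triggering rank warnings in every call
    keep = cov.std(axis=0) > 0
    return cov[:, keep]


def validate_subtypes(
    delta_z: pd.DataFrame,
    solution,
    bundle: GenotypeBundle,
    gene_sets: GeneSetCollection,
    profiles,
    sex: pd.Series,
    boundary_kb: float = 10.0,
    fdr_alpha: float = 0.05,
    min_n: int = 10,
    sweep_thresholds: tuple[float, ...] = (0.0, 0.2, 0.3, 0.4, 0.5, 0.6),
) -> ValidationResult:
    """Test subtype-specific polygenic covariance with deviation severity.

    ``solution`` is a :class:`corticell.subtypes.SubtypeSolution` (or any
    object with ``hard_labels`` and ``memberships``); ``profiles`` is the
    matching :class:`corticell.subtypes.SubtypeProfile` providing each
    subtype's signature.
    """
    genotyped = bundle.subjects.intersection(solution.hard_labels.index)
    if not len(genotyped):
        raise InputError("no genotyped subjects intersect the clustered subjects")
    labels = solution.hard_labels.loc[genotyped]
    severity = delta_z.loc[genotyped].mean(axis=1)

    cell_scores = pd.DataFrame(
        {
            ct: cell_prs(bundle, snps_for_cell_type(bundle, gene_sets, ct, boundary_kb))
            for ct in gene_sets.names
        }
    ).loc[genotyped]
    genomewide = genomewide_prs(bundle).loc[genotyped]
    relatedness = bundle.relatedness.loc[genotyped]

    scores: dict = {}
    skipped: list = []
    for subtype in sorted(labels.unique()):
        sig = profiles.signature(subtype, fdr_alpha)
        if not sig:
            warnings.warn(
                f"subtype {subtype!r} has no significant signature; validation skipped"
            )
            skipped.append(subtype)
            continue
        scores[subtype] = (sig, subtype_score(cell_scores, sig))

    primary_rows = []
    grid_rows = []
    sweep_rows = []
    for subtype, (sig, score) in scores.items():
        members = labels.index[labels == subtype]
        if len(members) < min_n:
            warnings.warn(f"subtype {subtype!r} has n={len(members)} < {min_n}; skipped")
            skipped.append(subtype)
            continue
        cov = _covariate_matrix(members, sex, genomewide, relatedness)
        r, p = partial_corr(
            score.loc[members].to_numpy(), severity.loc[members].to_numpy(), cov
        )
        primary_rows.append(
            {
                "subtype": subtype,
                "cell_types": ",".join(sig),
                "n": len(members),
                "partial_r": r,
                "p": p,
            }
        )
        for t in sweep_thresholds:
            member_of = solution.memberships.loc[genotyped, subtype]
            keep = members[member_of.loc[members] >= t]
            if len(keep) < min_n:
                sweep_rows.append(
                    {"subtype": subtype, "threshold": t, "n": len(keep),
                     "partial_r": np.nan}
                )
                continue
            cov_t = _covariate_matrix(keep, sex, genomewide, relatedness)
            r_t, _ = partial_corr(
                score.loc[keep].to_numpy(), severity.loc[keep].to_numpy(), cov_t
            )
            sweep_rows.append(
                {"subtype": subtype, "threshold": t, "n": len(keep), "partial_r": r_t}
            )
        for other in sorted(labels.unique()):
            other_members = labels.index[labels == other]
            if len(other_members) < min_n:
                continue
            cov_o = _covariate_matrix(other_members, sex, genomewide, relatedness)
            r_o, p_o = partial_corr(
                score.loc[other_members].to_numpy(),
                severity.loc[other_members].to_numpy(),
                cov_o,
            )
            grid_rows.append(
                {
                    "score_subtype": subtype,
                    "tested_subtype": other,
                    "n": len(other_members),
                    "partial_r": r_o,
                    "p": p_o,
                }
            )
    primary = pd.DataFrame.from_records(primary_rows)
    if len(primary):
        primary["fdr_p"] = bh_fdr(primary["p"])
    return ValidationResult(
        primary=primary,
        grid=pd.DataFrame.from_records(grid_rows),
        sweep=pd.DataFrame.from_records(sweep_rows),
        skipped=skipped,
    )


def membership_sweep(
    solution,
    score: pd.Series,
    severity: pd.Series,
    covariates: pd.DataFrame | None,
    subtype,
    thresholds: tuple[float, ...],
    min_n: int = 10,
) -> pd.DataFrame:
    """Matched partial correlation at increasing soft-membership cutoffs.

    ``covariates`` must be a subject-indexed DataFrame (or None).  At
    threshold 0 this reproduces the unrestricted members-only estimate;
    rows whose retained n falls below ``min_n`` are reported with NaN r.
    """
    if any(not 0 <= t < 1 for t in thresholds):
        raise InputError("thresholds must lie in [0, 1)")
    if list(thresholds) != sorted(thresholds):
        raise InputError("thresholds must be increasing")
    members = solution.hard_labels.index[solution.hard_labels == subtype]
    rows = []
    for t in thresholds:
        keep = members[solution.memberships.loc[members, subtype] >= t]
        if len(keep) < min_n:
            rows.append({"threshold": t, "n": len(keep), "partial_r": np.nan})
            continue
        cov = covariates.loc[keep].to_numpy() if covariates is not None else None
        r, _ = partial_corr(score.loc[keep].to_numpy(), severity.loc[keep].to_numpy(), cov)
        rows.append({"threshold": t, "n": len(keep), "partial_r": r})
    return pd.DataFrame.from_records(rows)
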
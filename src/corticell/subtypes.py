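"""Cell-based patient subtypes from the coupling matrix.

The subjects x cell-types coupling matrix is reduced to four principal
components, clustered with Ward's linkage, and the number of clusters is
selected with the gap statistic (uniform bounding-box reference, k ranging
1..7, with a one-standard-error dominance rule).  Subjects also receive
continuous ("soft") membership in each subtype via inverse distance to the
cluster centroids in PC space, and each subtype is profiled by the median
coupling per cell type with a Wilcoxon signed-rank test against zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from ._stats import bh_fdr, pearson_with_p
from .errors import InputError

log = logging.getLogger(__name__)


def pca_reduce(coupling: pd.DataFrame, n_pcs: int = 4) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA scores of the coupling matrix plus explained variance.

    Returns (scores: subjects x n_pcs, explained variance ratios, which are
    non-increasing).  Inputs are centered only, not standardized: the columns
    are already on a common correlation scale.
    """
    if n_pcs > coupling.shape[1]:
        raise InputError("n_pcs cannot exceed the number of cell types")
    if coupling.shape[0] < n_pcs:
        raise InputError("fewer subjects than requested principal components")
    if coupling.isna().any().any():
        raise InputError("coupling matrix contains NaN; drop undefined subjects first")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(coupling.to_numpy())
    cols = [f"pc{i + 1}" for i in range(n_pcs)]
    return (
        pd.DataFrame(scores, index=coupling.index, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def ward_cluster(pc_scores: pd.DataFrame, k: int) -> tuple[pd.Series, np.ndarray]:
    """Ward's linkage over PC scores, cut at ``k`` clusters.

    Labels are integers 1..k (relabeled in order of first appearance).
    """
    if not 1 <= k <= len(pc_scores):
        raise InputError(f"k must be in 1..{len(pc_scores)}")
    z = linkage(pc_scores.to_numpy(), method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    order = {old: new for new, old in enumerate(pd.unique(raw), start=1)}
    labels = pd.Series([order[v] for v in raw], index=pc_scores.index, name="subtype")
    return labels, z


def _within_dispersion(points: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    total = 0.0
    for lab in np.unique(labels):
        cluster = points[labels == lab]
        total += ((cluster - cluster.mean(axis=0)) ** 2).sum()
    return total


@dataclass
class GapResult:
    """Gap curve, its standard errors, and the selected cluster count."""

    chosen_k: int
    gap: pd.Series  # index k = 1..k_max
    se: pd.Series
    log_wk: pd.Series


def gap_select(
    pc_scores: pd.DataFrame,
    k_max: int = 7,
    B: int = 100,
    seed: int | None = None,
) -> GapResult:
    """Select the number of Ward clusters with the gap statistic.

    Gap(k) = E*[log W_k] - log W_k, where W_k is the within-cluster
    dispersion of the Ward partition at k and the reference expectation is
    over ``B`` datasets drawn uniformly from the bounding box of the PC
    scores (clustered with the same Ward procedure).  The SE includes the
    sqrt(1 + 1/B) simulation-error factor.  The global maximum of the gap
    curve is accepted outright when it exceeds the runner-up gap by one SE
    of the runner-up; when the curve plateaus instead (several k within one
    SE of the maximum, as happens once every further split of a recovered
    cluster leaves the gap flat), the smallest k on the plateau is chosen.
    With no cluster structure k = 1 itself sits on the plateau and is
    returned.
    """
    if B < 20:
        raise InputError("gap statistic requires B >= 20 reference datasets")
    points = pc_scores.to_numpy()
    ks = list(range(1, k_max + 1))
    rng = np.random.default_rng(seed)

    def ward_wk(data: np.ndarray) -> np.ndarray:
        z = linkage(data, method="ward")
        out = np.empty(len(ks))
        for i, k in enumerate(ks):
            labs = fcluster(z, t=k, criterion="maxclust")
            out[i] = _within_dispersion(data, labs)
        return out

    log_wk = np.log(ward_wk(points))
    lo, hi = points.min(axis=0), points.max(axis=0)
    ref = np.empty((B, len(ks)))
    for b in range(B):
        fake = rng.uniform(lo, hi, size=points.shape)
        ref[b] = np.log(ward_wk(fake))
    gap = ref.mean(axis=0) - log_wk
    se = ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)

    order = np.argsort(gap)[::-1]
    best, runner = order[0], order[1]
    if gap[best] - gap[runner] >= se[runner]:
        chosen = ks[best]
    else:
        on_plateau = np.flatnonzero(gap >= gap[best] - se[best])
        chosen = ks[on_plateau[0]]
    return GapResult(
        chosen_k=chosen,
        gap=pd.Series(gap, index=pd.Index(ks, name="k"), name="gap"),
        se=pd.Series(se, index=pd.Index(ks, name="k"), name="se"),
        log_wk=pd.Series(log_wk, index=pd.Index(ks, name="k"), name="log_wk"),
    )


def soft_membership(pc_scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Continuous 0-1 membership of each subject in each subtype.

    membership_{i,s} = (1/d_{i,s}) / sum_t (1/d_{i,t}) with d the Euclidean
    distance to cluster centroids in PC space; a subject exactly on a
    centroid has membership 1 there.  Rows sum to 1.
    """
    if not labels.index.equals(pc_scores.index):
        raise InputError("labels and PC scores index different subjects")
    uniq = sorted(labels.unique())
    centroids = np.stack(
        [pc_scores.loc[labels == lab].mean(axis=0).to_numpy() for lab in uniq]
    )
    d = np.sqrt(
        ((pc_scores.to_numpy()[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    )
    member = np.zeros_like(d)
    zero = d == 0
    on_centroid = zero.any(axis=1)
    member[on_centroid] = zero[on_centroid].astype(float)
    member[on_centroid] /= member[on_centroid].sum(axis=1, keepdims=True)
    inv = 1.0 / d[~on_centroid]
    member[~on_centroid] = inv / inv.sum(axis=1, keepdims=True)
    return pd.DataFrame(member, index=pc_scores.index, columns=uniq)


@dataclass
class SubtypeSolution:
    """Full clustering result: PC scores, gap curve, labels, memberships."""

    pc_scores: pd.DataFrame
    explained_variance: np.ndarray
    linkage: np.ndarray
    gap: GapResult
    hard_labels: pd.Series
    memberships: pd.DataFrame

    @property
    def chosen_k(self) -> int:
        return self.gap.chosen_k

    def to_frame(self) -> pd.DataFrame:
        """subject_id, hard_label, membership_*, pc_* table for TSV export."""
        out = pd.DataFrame({"hard_label": self.hard_labels})
        for s in self.memberships.columns:
            out[f"membership_{s}"] = self.memberships[s]
        for c in self.pc_scores.columns:
            out[c] = self.pc_scores[c]
        return out


def solve_subtypes(
    coupling: pd.DataFrame,
    n_pcs: int = 4,
    k_max: int = 7,
    gap_B: int = 100,
    seed: int | None = None,
) -> SubtypeSolution:
    """PCA -> gap-selected Ward clustering -> soft memberships, end to end.

    Hard labels are the argmax of the soft memberships: after the Ward cut
    defines the centroids, each subject is assigned to its nearest centroid
    (a single k-means-style reassignment), which keeps hard and soft
    assignments mutually consistent.
    """
    scores, evr = pca_reduce(coupling, n_pcs=n_pcs)
    gap = gap_select(scores, k_max=k_max, B=gap_B, seed=seed)
    ward_labels, z = ward_cluster(scores, gap.chosen_k)
    memberships = soft_membership(scores, ward_labels)
    hard = memberships.idxmax(axis=1).rename("subtype")
    return SubtypeSolution(
        pc_scores=scores,
        explained_variance=evr,
        linkage=z,
        gap=gap,
        hard_labels=hard,
        memberships=memberships,
    )


@dataclass
class SubtypeProfile:
    """Per-subtype coupling signatures and deviation summaries.

    ``stats`` rows are (subtype, cell type) with the median and quartiles of
    coupling r, a Wilcoxon signed-rank p against zero, BH-FDR within subtype
    across cell types, and a flag for significantly negative medians.
    """

    stats: pd.DataFrame
    sizes: pd.Series
    proportions: pd.Series
    mean_regional_deviation: pd.DataFrame  # subtypes x regions
    mean_wholebrain_deviation: pd.Series

    def signature(self, subtype, fdr_alpha: float = 0.05) -> list[str]:
        """Cell types with FDR-significant negative median coupling."""
        sub = self.stats.loc[self.stats["subtype"] == subtype]
        hits = sub[(sub["fdr_p"] < fdr_alpha) & (sub["median_r"] < 0)]
        return hits["cell_type"].tolist()

    def median_matrix(self) -> pd.DataFrame:
        """Subtypes x cell types matrix of median coupling."""
        return self.stats.pivot(index="subtype", columns="cell_type", values="median_r")


def subtype_profiles(
    coupling: pd.DataFrame,
    delta_z: pd.DataFrame,
    labels: pd.Series,
    fdr_alpha: float = 0.05,
) -> SubtypeProfile:
    """Characterize each subtype's coupling signature and deviation severity."""
    if not labels.index.equals(coupling.index):
        raise InputError("labels and coupling matrix index different subjects")
    if not labels.index.equals(delta_z.index):
        raise InputError("labels and deviations index different subjects")
    records = []
    sizes = labels.value_counts().sort_index()
    for subtype in sizes.index:
        members = labels.index[labels == subtype]
        small = len(members) < 5
        if small:
            warnings.warn(
                f"subtype {subtype!r} has only {len(members)} members; tests skipped"
            )
        for ct in coupling.columns:
            vals = coupling.loc[members, ct].dropna().to_numpy()
            if small or np.allclose(vals, 0):
                p = np.nan if small else 1.0
            else:
                p = float(stats.wilcoxon(vals, alternative="two-sided")[1])
            records.append(
                {
                    "subtype": subtype,
                    "cell_type": ct,
                    "median_r": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                    "n": len(vals),
                    "p": p,
                }
            )
    table = pd.DataFrame.from_records(records)
    table["fdr_p"] = np.nan
    for subtype in sizes.index:
        mask = table["subtype"] == subtype
        table.loc[mask, "fdr_p"] = bh_fdr(table.loc[mask, "p"])
    mean_regional = delta_z.groupby(labels).mean()
    mean_wholebrain = delta_z.mean(axis=1).groupby(labels).mean()
    return SubtypeProfile(
        stats=table,
        sizes=sizes,
        proportions=sizes / sizes.sum(),
        mean_regional_deviation=mean_regional,
        mean_wholebrain_deviation=mean_wholebrain,
    )


def profile_conservation(
    medians_a: pd.DataFrame,
    medians_b: pd.DataFrame,
    pairing: dict | None = None,
) -> pd.DataFrame:
    """Correlate per-cell-type median coupling between two cohorts' subtypes.

    ``pairing`` maps subtype labels in A to labels in B (identity default).
    Returns per matched pair the Pearson r and p over the cell-type medians.
    """
    if list(medians_a.columns) != list(medians_b.columns):
        raise InputError("the two profiles cover different cell types")
    pairing = pairing or {s: s for s in medians_a.index}
    rows = {}
    for a_label, b_label in pairing.items():
        r, p = pearson_with_p(
            medians_a.loc[a_label].to_numpy(), medians_b.loc[b_label].to_numpy()
        )
        rows[f"{a_label}~{b_label}"] = {"r": r, "p": p}
    return pd.DataFrame(rows).T
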
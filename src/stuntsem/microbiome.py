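"""Microbiota data reduction: diversity, ordination, clustering, screening.

These are the four constructs the structural models accept as their
"microbiome" node — Shannon alpha diversity, Streptococcaceae relative
abundance, the first principal coordinate of a Euclidean PCoA on relative
abundances, and a two-group Ward clustering — plus the taxon-level Pearson
screen with Benjamini-Hochberg correction and the quartile-contrast utility
used to binarize continuous scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


def _check_no_empty_samples(counts: pd.DataFrame) -> None:
    empty = counts.index[counts.sum(axis=1) <= 0]
    if len(empty):
        raise ValueError(f"all-zero sample(s): {list(empty)}")


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to compositions (each row sums to 1)."""
    _check_no_empty_samples(counts)
    return counts.div(counts.sum(axis=1), axis=0)


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon index (nats) and inverse Simpson index.

    Computed on unaggregated counts without rarefaction: shannon =
    -sum p_i ln p_i over nonzero proportions, inverse Simpson = 1 / sum p_i^2,
    richness = number of nonzero taxa.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    _check_no_empty_samples(counts)
    p = arr / arr.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {
            "richness": (arr > 0).sum(axis=1),
            "shannon": -plogp.sum(axis=1),
            "inverse_simpson": 1.0 / (p**2).sum(axis=1),
        },
        index=counts.index,
    )


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform: log(count + pseudocount) minus the row mean."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def distance_matrix(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Symmetric pairwise distances under 'euclidean' or 'bray_curtis'."""
    if metric == "euclidean":
        d = pdist(table.to_numpy(dtype=float), metric="euclidean")
    elif metric == "bray_curtis":
        d = pdist(table.to_numpy(dtype=float), metric="braycurtis")
    else:
        raise ValueError(f"unknown metric {metric!r}; expected 'euclidean' or 'bray_curtis'")
    return pd.DataFrame(squareform(d), index=table.index, columns=table.index)


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling (PCoA) solution of a distance matrix."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    distance_name: str = ""


def pcoa(distances: pd.DataFrame, distance_name: str = "") -> OrdinationResult:
    """Principal coordinates analysis via classical multidimensional scaling.

    Double-centers -D^2/2, eigendecomposes, and keeps the axes with positive
    eigenvalues. Variance explained is each positive eigenvalue over their
    sum. The sign of each axis is fixed so its largest-magnitude coordinate
    is positive.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(1e-10 * max(evals.max(), 1.0), 0.0)
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(evals)
    for j in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] *= -1
    ve = evals / evals.sum()
    cols = [f"PCo{j + 1}" for j in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=distances.index, columns=cols),
        eigenvalues=evals,
        variance_explained=ve,
        distance_name=distance_name,
    )


def calinski_harabasz(distances: pd.DataFrame | np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index from pairwise Euclidean distances and labels.

    Uses the identity that, for Euclidean distances, the within-cluster sum
    of squares of a cluster equals the sum of its squared pairwise distances
    divided by twice the cluster size; the ratio is
    (B/(k-1)) / (W/(n-k)) with B = T - W.
    """
    D2 = np.asarray(distances, dtype=float) ** 2
    labels = np.asarray(labels)
    n = D2.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k < n clusters")
    total = D2.sum() / (2.0 * n)
    within = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    between = total - within
    return (between / (k - 1)) / (within / (n - k))


@dataclass(frozen=True)
class ClusteringResult:
    """Ward.D2 hierarchical clustering with an automated elbow choice of k."""

    linkage: np.ndarray
    chosen_k: int
    labels: pd.Series
    ch_index: dict[int, float] = field(default_factory=dict)


def ward_cluster(distances: pd.DataFrame, k_range: range = range(2, 11)) -> ClusteringResult:
    """Ward.D2 clustering of a distance matrix with elbow-based selection of k.

    The linkage applies the Lance-Williams recurrence on the squared-distance
    scale with square-root merge heights (the Murtagh-Legendre "Ward2"
    criterion, i.e. hclust's ward.D2). The Calinski-Harabasz index is
    computed for each candidate k and the chosen k maximizes its second
    difference (with CH(1) taken as 0), an automated surrogate for a visual
    elbow; ties go to the smaller k.
    """
    n = distances.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    D = distances.to_numpy(dtype=float)
    if np.allclose(D, 0.0):
        raise ValueError("degenerate input: all pairwise distances are zero")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"k_range {k_range!r} has no feasible k in [2, {n - 1}]")
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method="ward")

    ch: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    eval_ks = sorted(set(ks) | ({max(ks) + 1} if max(ks) + 1 <= n - 1 else set()))
    for k in eval_ks:
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) == k:
            ch[k] = calinski_harabasz(D, lab)
    ext = dict(ch)
    ext[1] = 0.0
    best_k, best_curv = None, -np.inf
    for k in ks:
        if k not in ch or (k - 1) not in ext or (k + 1) not in ext:
            continue
        curv = 2.0 * ext[k] - ext[k - 1] - ext[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    if best_k is None:  # fall back to the highest CH among candidates
        best_k = max((k for k in ks if k in ch), key=lambda k: (ch[k], -k))
    labels = pd.Series(labels_by_k[best_k], index=distances.index, name="cluster")
    return ClusteringResult(
        linkage=Z, chosen_k=best_k, labels=labels, ch_index={k: ch[k] for k in ks if k in ch}
    )


def aggregate_taxa(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, level: str = "family"
) -> pd.DataFrame:
    """Sum counts over taxa sharing the same family or genus."""
    if level not in ("family", "genus"):
        raise ValueError("level must be 'family' or 'genus'")
    return counts.T.groupby(taxonomy[level]).sum().T


def screen_taxa(abundance: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson screen of each (taxon, score) pair with BH correction per score.

    ``abundance`` holds relative abundances aggregated to family or genus
    level; ``scores`` holds one column per neurodevelopmental score. Returns
    a long frame (taxon, score, r, p, q); zero-variance taxa get missing
    r/p/q and are excluded from the BH family size m.
    """
    common = abundance.index.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between abundance and scores")
    ab = abundance.loc[common]
    sc = scores.loc[common]
    rows = []
    for score_name in sc.columns:
        y = sc[score_name].to_numpy(dtype=float)
        rs, ps, taxa = [], [], []
        for taxon in ab.columns:
            x = ab[taxon].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rs.append(np.nan)
                ps.append(np.nan)
            else:
                r, p = stats.pearsonr(x, y)
                rs.append(r)
                ps.append(p)
            taxa.append(taxon)
        ps_arr = np.array(ps)
        qs = np.full_like(ps_arr, np.nan)
        ok = ~np.isnan(ps_arr)
        if ok.any():
            qs[ok] = bh_adjust(ps_arr[ok])
        for taxon, r, p, q in zip(taxa, rs, ps_arr, qs):
            rows.append({"taxon": taxon, "score": score_name, "r": r, "p": p, "q": q})
    return pd.DataFrame(rows)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values for a vector of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("pvalues must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def quartile_contrast(score: pd.Series) -> pd.Series:
    """Binary low/high labels from the first and last quartiles of a score.

    Samples with score <= Q1 are 'low', >= Q3 are 'high'; the middle half is
    dropped. Quartiles use linear-interpolation quantiles.
    """
    if len(score) < 8:
        raise ValueError("need at least 8 samples for a quartile contrast")
    vals = score.to_numpy(dtype=float)
    if np.std(vals) == 0:
        raise ValueError("constant score vector")
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    labels = pd.Series(
        np.where(vals <= q1, "low", np.where(vals >= q3, "high", "")),
        index=score.index,
        name="contrast",
    )
    return labels[labels != ""]


def build_constructs(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, k: int = 2
) -> pd.DataFrame:
    """Per-sample table of the four microbiota constructs.

    Columns: ``shannon`` (alpha diversity, nats), ``streptococcaceae``
    (family-aggregated relative abundance), ``cluster`` (Ward.D2 label cut at
    ``k`` groups on Euclidean distances of relative abundances) and ``pcoa1``
    (first principal coordinate of the same distances).
    """
    fam = aggregate_taxa(counts, taxonomy, "family")
    if "Streptococcaceae" not in fam.columns:
        raise ValueError(
            f"Streptococcaceae absent; available families: {sorted(fam.columns)}"
        )
    rel = relative_abundance(counts)
    fam_rel = aggregate_taxa(rel, taxonomy, "family")
    div = alpha_diversity(counts)
    dist = distance_matrix(rel, "euclidean")
    ord_res = pcoa(dist, "euclidean_relab")
    Z = hierarchy.linkage(squareform(dist.to_numpy(), checks=False), method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.DataFrame(
        {
            "shannon": div["shannon"],
            "streptococcaceae": fam_rel["Streptococcaceae"],
            "cluster": labels,
            "pcoa1": ord_res.coordinates["PCo1"],
        },
        index=counts.index,
    )
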
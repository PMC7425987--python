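"""Probe-count normalization and PCA/clustering of a clock-gene panel.

The expression workflow mirrors a digital probe-count (nCounter-style)
experiment on a clone panel: three-step normalization (positive spike-in
scaling, negative-control background subtraction with a floor of one count,
housekeeping geometric-mean scaling), log2 transform, Bartlett's test of
sphericity as a PCA-adequacy check, correlation-based PCA with cos^2 and
contribution tables, broken-stick retention of components, top-fraction gene
selection by contribution, and hierarchical/k-means clustering of samples
with five optimal-k indexes (silhouette, WSS elbow, gap statistic,
Calinski-Harabasz, BIC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .simulate import CountMatrix


class NormalizationError(ValueError):
    """Control probes unusable for normalization."""


@dataclass
class NormalizedMatrix:
    """Endogenous log2 expression after three-step control normalization."""

    log2: pd.DataFrame  # samples x endogenous genes
    positive_factor: pd.Series
    negative_background: pd.Series
    housekeeping_factor: pd.Series
    dropped_probes: list[str] = field(default_factory=list)
    steps: list[str] = field(default_factory=list)


def nanostring_normalize(
    raw: CountMatrix, drop_probes: list[str] | None = None
) -> NormalizedMatrix:
    """Three-step control-probe normalization, then log2.

    1. Scale each sample by (grand mean of per-sample positive-control means)
       / (that sample's positive-control mean).
    2. Subtract the sample's mean negative-control count (post step 1),
       flooring at 1 count so the log2 transform stays defined.
    3. Scale by (grand geometric mean of per-sample housekeeping geometric
       means) / (the sample's housekeeping geometric mean).

    ``drop_probes`` removes probes that failed upstream QC before any step.
    """
    counts = raw.counts.astype(float)
    dropped = list(drop_probes or [])
    if dropped:
        counts = counts.drop(columns=[p for p in dropped if p in counts.columns])
    classes = raw.probe_class.reindex(counts.columns)

    pos = counts.loc[:, classes == "positive"]
    neg = counts.loc[:, classes == "negative"]
    hk = counts.loc[:, classes == "housekeeping"]
    endo = counts.loc[:, classes == "endogenous"]
    if pos.shape[1] < 2 or neg.shape[1] < 2 or hk.shape[1] < 2:
        raise NormalizationError("need >= 2 probes in every control class")

    # step 1: positive spike-in scaling
    pos_means = pos.mean(axis=1)
    if (pos_means <= 0).any():
        raise NormalizationError("nonpositive positive-control mean")
    pos_factor = pos_means.mean() / pos_means
    scaled = endo.mul(pos_factor, axis=0)
    neg_scaled = neg.mul(pos_factor, axis=0)
    hk_scaled = hk.mul(pos_factor, axis=0)

    # step 2: background subtraction, floored at 1 count
    background = neg_scaled.mean(axis=1)
    cleared = (scaled.sub(background, axis=0)).clip(lower=1.0)
    hk_cleared = (hk_scaled.sub(background, axis=0)).clip(lower=1.0)

    # step 3: housekeeping geometric-mean scaling
    hk_geo = np.exp(np.log(hk_cleared).mean(axis=1))
    if (hk_geo <= 0).any():
        raise NormalizationError("zero housekeeping geometric mean")
    hk_factor = math.exp(float(np.log(hk_geo).mean())) / hk_geo
    final = cleared.mul(hk_factor, axis=0)

    return NormalizedMatrix(
        log2=np.log2(final),
        positive_factor=pos_factor,
        negative_background=background,
        housekeeping_factor=hk_factor,
        dropped_probes=dropped,
        steps=[
            "positive-control arithmetic-mean scaling (grand-mean reference)",
            "negative-control mean subtraction, floor 1 count",
            "housekeeping geometric-mean scaling (grand-geomean reference)",
            "log2 transform",
        ],
    )


@dataclass
class SphericityResult:
    """Bartlett's test of sphericity on the gene correlation matrix."""

    chi2: float
    df: int
    p_value: float
    singular: bool = False

    def summary(self) -> str:
        note = "  (singular correlation matrix)" if self.singular else ""
        return (
            f"Bartlett sphericity: chi2 = {self.chi2:.3f}, df = {self.df}, "
            f"p = {self.p_value:.3g}{note}"
        )


def bartlett_sphericity(log2matrix: pd.DataFrame) -> SphericityResult:
    """chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2.

    A singular correlation matrix yields a flag (chi2 = inf, p = 0) rather
    than an exception; PCA is still permitted.
    """
    x = log2matrix.to_numpy(dtype=float)
    n, p = x.shape
    r = np.corrcoef(x, rowvar=False)
    sign, logdet = np.linalg.slogdet(r)
    df = p * (p - 1) // 2
    if sign <= 0 or not np.isfinite(logdet):
        return SphericityResult(chi2=math.inf, df=df, p_value=0.0, singular=True)
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    from scipy.stats import chi2 as chi2_dist

    return SphericityResult(
        chi2=float(chi2), df=df, p_value=float(chi2_dist.sf(chi2, df))
    )


@dataclass
class PCAResult:
    """Correlation-based PCA with variable cos^2 and contribution tables."""

    eigenvalues: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # genes x PCs (variable-PC correlations)
    cos2: pd.DataFrame  # genes x PCs
    contributions: pd.DataFrame  # genes x PCs, columns sum to 100
    broken_stick: np.ndarray
    n_retained: int
    retention_warning: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.loadings.index)

    def summary(self) -> str:
        lines = [
            "Correlation PCA",
            "-" * 56,
            f"{'PC':>4} {'eigenvalue':>11} {'% var':>8} {'cum %':>8} {'broken stick %':>15}",
        ]
        for k in range(len(self.eigenvalues)):
            lines.append(
                f"{k + 1:>4} {self.eigenvalues[k]:>11.4f} "
                f"{100 * self.proportion[k]:>8.2f} {100 * self.cumulative[k]:>8.2f} "
                f"{100 * self.broken_stick[k]:>15.2f}"
            )
        lines.append(
            f"retained PCs (broken stick): {self.n_retained}"
            + (f"  [{self.retention_warning}]" if self.retention_warning else "")
        )
        return "\n".join(lines)


def broken_stick_proportions(p: int) -> np.ndarray:
    """Expected eigenvalue proportions b_k = (1/p) * sum_{i=k..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def correlation_pca(log2matrix: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the gene-gene correlation matrix.

    Scores are the standardized data projected onto eigenvectors; loadings
    are variable-PC correlations (eigenvector * sqrt(eigenvalue)); cos^2 is
    the squared loading; contributions are 100 * squared eigenvector entries
    (summing to 100 per PC).  Each eigenvector is oriented so its
    largest-magnitude element is positive.
    """
    if log2matrix.isna().any().any():
        raise ValueError("missing values not allowed (no imputation)")
    n, p = log2matrix.shape
    if n < 3 or p < 2:
        raise ValueError("need >= 3 samples and >= 2 genes")
    x = log2matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(log2matrix.columns[sd == 0])
        raise ValueError(f"constant genes cannot enter correlation PCA: {bad}")
    z = (x - x.mean(axis=0)) / sd
    r = np.corrcoef(x, rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|.| element of each eigenvector positive
    for k in range(p):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]

    pcs = [f"PC{k + 1}" for k in range(p)]
    scores = pd.DataFrame(z @ evecs, index=log2matrix.index, columns=pcs)
    loadings = pd.DataFrame(
        evecs * np.sqrt(evals), index=log2matrix.columns, columns=pcs
    )
    cos2 = loadings**2
    contributions = pd.DataFrame(
        100.0 * evecs**2, index=log2matrix.columns, columns=pcs
    )
    proportion = evals / evals.sum()
    bstick = broken_stick_proportions(p)

    run = 0
    for k in range(p):
        if proportion[k] > bstick[k]:
            run += 1
        else:
            break
    warning = ""
    if run == 0:
        run, warning = 1, "PC1 below broken-stick expectation; kept anyway"

    return PCAResult(
        eigenvalues=evals,
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        scores=scores,
        loadings=loadings,
        cos2=cos2,
        contributions=contributions,
        broken_stick=bstick,
        n_retained=run,
        retention_warning=warning,
    )


def broken_stick_retention(result: PCAResult) -> int:
    """Number of leading PCs whose variance share beats the broken stick."""
    return result.n_retained


def select_top_genes(
    result: PCAResult, pc: int, fraction: float = 0.25
) -> list[str]:
    """Top ``ceil(fraction * p)`` genes by contribution to PC ``pc`` (1-based).

    Ties break by cos^2, then gene name.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not 1 <= pc <= len(result.eigenvalues):
        raise ValueError(f"pc must be in [1, {len(result.eigenvalues)}]")
    col = f"PC{pc}"
    p = len(result.genes)
    k = math.ceil(fraction * p)
    ranking = sorted(
        result.genes,
        key=lambda g: (
            -result.contributions.loc[g, col],
            -result.cos2.loc[g, col],
            g,
        ),
    )
    return ranking[:k]


def _standardize_genes(x: pd.DataFrame) -> pd.DataFrame:
    sd = x.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (x - x.mean(axis=0)) / sd


@dataclass
class DendrogramResult:
    """Complete-linkage hierarchical clustering of samples."""

    linkage: np.ndarray
    labels: pd.Series  # sample -> cluster id (1..n_clusters)
    genes: list[str]
    standardized: bool

    def newick(self) -> str:
        """Parenthesized serialization with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.labels.index)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            return (
                f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
                f":{length:.6g}"
            )

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def hierarchical_cluster(
    log2matrix: pd.DataFrame,
    genes: list[str] | None = None,
    n_clusters: int = 3,
    standardize: bool = True,
) -> DendrogramResult:
    """Euclidean-distance, complete-linkage clustering of samples.

    Genes are z-scored by default so abundance differences do not dominate
    the distance; pass ``standardize=False`` to cluster raw log2 values.
    """
    sub = log2matrix if genes is None else log2matrix.loc[:, list(genes)]
    if n_clusters > len(sub):
        raise ValueError("n_clusters exceeds the number of samples")
    x = _standardize_genes(sub) if standardize else sub
    link = hierarchy.linkage(pdist(x.to_numpy(dtype=float)), method="complete")
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return DendrogramResult(
        linkage=link,
        labels=pd.Series(labels, index=sub.index, name="cluster"),
        genes=list(sub.columns),
        standardized=standardize,
    )


@dataclass
class ClusterIndexReport:
    """Five optimal-k indexes over a k range, with per-index optima."""

    k_range: list[int]
    wss: dict[int, float]
    silhouette: dict[int, float]
    gap: dict[int, float]
    gap_se: dict[int, float]
    calinski_harabasz: dict[int, float]
    bic: dict[int, float]
    optimal: dict[str, int]
    consensus_k: int
    rationale: str
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_range,
                "WSS": [self.wss[k] for k in self.k_range],
                "silhouette": [self.silhouette.get(k, math.nan) for k in self.k_range],
                "gap": [self.gap[k] for k in self.k_range],
                "gap_se": [self.gap_se[k] for k in self.k_range],
                "CH": [self.calinski_harabasz.get(k, math.nan) for k in self.k_range],
                "BIC": [self.bic[k] for k in self.k_range],
            }
        )

    def summary(self) -> str:
        lines = ["Optimal-k scan", "-" * 40]
        for name, k in self.optimal.items():
            lines.append(f"{name:>20}: k = {k}")
        lines.append(f"{'consensus':>20}: k = {self.consensus_k} ({self.rationale})")
        return "\n".join(lines)


def _kmeans_wss(x: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, float]:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    return km.labels_, float(km.inertia_)


def optimal_k_scan(
    log2matrix: pd.DataFrame,
    genes: list[str] | None = None,
    k_range: range | list[int] = range(1, 11),
    standardize: bool = True,
    n_reference: int = 50,
    seed: int = 0,
) -> ClusterIndexReport:
    """k-means over ``k_range`` scored by five optimal-k indexes.

    Gap statistic: B = ``n_reference`` uniform draws over the data bounding
    box, optimum by the 1-SE rule (smallest k with gap(k) >= gap(k+1) -
    SE(k+1)).  Elbow: k after which the drop in WSS decreases the most.  BIC:
    spherical Gaussian mixture initialized at the k-means solution (lower is
    better).  Consensus is the modal per-index optimum, ties broken by
    silhouette.
    """
    sub = log2matrix if genes is None else log2matrix.loc[:, list(genes)]
    x = (_standardize_genes(sub) if standardize else sub).to_numpy(dtype=float)
    n = len(x)
    ks = [k for k in k_range if k <= n]
    if not ks:
        raise ValueError("k_range has no feasible k for the sample count")
    rng = np.random.default_rng(seed)

    if np.allclose(x, x[0]):
        flat = {k: 0.0 for k in ks}
        return ClusterIndexReport(
            k_range=ks, wss=flat, silhouette={}, gap=dict(flat), gap_se=dict(flat),
            calinski_harabasz={}, bic=dict(flat),
            optimal={name: 1 for name in ("silhouette", "elbow", "gap", "CH", "BIC")},
            consensus_k=1, rationale="degenerate input: all points identical",
            degenerate=True,
        )

    wss: dict[int, float] = {}
    sil: dict[int, float] = {}
    ch: dict[int, float] = {}
    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        labels, inertia = _kmeans_wss(x, k, seed)
        wss[k] = inertia
        labels_by_k[k] = labels
        if 2 <= k <= n - 1 and len(np.unique(labels)) == k:
            sil[k] = float(silhouette_score(x, labels))
            ch[k] = float(calinski_harabasz_score(x, labels))
        centers = np.vstack([x[labels == c].mean(axis=0) for c in np.unique(labels)])
        gm = GaussianMixture(
            n_components=len(centers), covariance_type="spherical",
            means_init=centers, n_init=1, random_state=seed, max_iter=200,
            reg_covar=1e-6,
        ).fit(x)
        bic[k] = float(gm.bic(x))

    # gap statistic over uniform bounding-box references
    lo, hi = x.min(axis=0), x.max(axis=0)
    log_wss_ref = {k: np.empty(n_reference) for k in ks}
    for b in range(n_reference):
        ref = rng.uniform(lo, hi, size=x.shape)
        for k in ks:
            _, inertia = _kmeans_wss(ref, k, seed)
            log_wss_ref[k][b] = math.log(max(inertia, 1e-300))
    gap: dict[int, float] = {}
    gap_se: dict[int, float] = {}
    for k in ks:
        ref_logs = log_wss_ref[k]
        gap[k] = float(ref_logs.mean() - math.log(max(wss[k], 1e-300)))
        gap_se[k] = float(ref_logs.std(ddof=0) * math.sqrt(1.0 + 1.0 / n_reference))

    optimal: dict[str, int] = {}
    optimal["silhouette"] = max(sil, key=sil.get) if sil else 1
    # elbow: largest drop in the WSS decrease
    if len(ks) >= 3:
        drops = {
            ks[i]: (wss[ks[i - 1]] - wss[ks[i]]) - (wss[ks[i]] - wss[ks[i + 1]])
            for i in range(1, len(ks) - 1)
        }
        optimal["elbow"] = max(drops, key=drops.get)
    else:
        optimal["elbow"] = ks[0]
    k_gap = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - gap_se[ks[i + 1]]:
            k_gap = k
            break
    optimal["gap"] = k_gap
    optimal["CH"] = max(ch, key=ch.get) if ch else 1
    optimal["BIC"] = min(bic, key=bic.get)

    votes = pd.Series(list(optimal.values())).value_counts()
    top = votes.max()
    tied = sorted(votes[votes == top].index)
    if len(tied) == 1:
        consensus = int(tied[0])
        rationale = f"modal vote ({top}/{len(optimal)} indexes)"
    else:
        scored = [(sil.get(k, -math.inf), k) for k in tied]
        consensus = int(max(scored)[1])
        rationale = f"vote tie among {tied}; broken by silhouette"

    return ClusterIndexReport(
        k_range=ks, wss=wss, silhouette=sil, gap=gap, gap_se=gap_se,
        calinski_harabasz=ch, bic=bic, optimal=optimal,
        consensus_k=consensus, rationale=rationale,
    )
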
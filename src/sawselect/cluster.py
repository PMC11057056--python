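"""Clustering of positively selected genes on (omega, percent sites under
selection, delta-GRAVY): feature assembly with a capped-omega winsorizing
policy, PCA for visualization, k-means clustering, and a hypergeometric
term-enrichment test (a deliberate plain-Fisher-style substitute for
graph-aware GO enrichment algorithms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .selection import DEFAULT_OMEGA_CAP, PsgCall

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("omega", "percent_sites", "delta_gravy")


def build_feature_table(
    selection_results: list[PsgCall] | pd.DataFrame,
    delta_gravies: dict[str, float],
    omega_cap: float = DEFAULT_OMEGA_CAP,
) -> pd.DataFrame:
    """Inner-join selection statistics with delta-GRAVY values on gene id.

    Genes missing either feature are dropped with a logged reason; omega
    values at the cap are winsorized to the cap (they would otherwise
    dominate standardization) and flagged in ``omega_capped``.
    """
    if isinstance(selection_results, pd.DataFrame):
        sel = selection_results.copy()
        required = {"gene_id", "omega", "percent_sites"}
        if not required <= set(sel.columns):
            raise ValueError(f"selection table needs columns {sorted(required)}")
        if "omega_capped" not in sel.columns:
            sel["omega_capped"] = False
    else:
        sel = pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in selection_results],
                "omega": [c.omega2 for c in selection_results],
                "percent_sites": [c.percent_sites for c in selection_results],
                "omega_capped": [c.omega_capped for c in selection_results],
            }
        )
    if sel["gene_id"].duplicated().any():
        dupes = sel.loc[sel["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in selection results: {dupes[:5]}")
    missing = sorted(set(sel["gene_id"]) - set(delta_gravies))
    if missing:
        logger.info("dropping %d genes without a delta-GRAVY value: %s ...",
                    len(missing), missing[:5])
    out = sel[sel["gene_id"].isin(delta_gravies)].copy()
    out["delta_gravy"] = out["gene_id"].map(delta_gravies)
    out["omega"] = out["omega"].clip(upper=omega_cap)
    if out.empty:
        logger.warning("feature table is empty: no gene ids shared between inputs")
    return out.reset_index(drop=True)


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray           # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None


def pca(features: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Full-rank PCA of the three-feature table (z-scored by default)."""
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    if not cols:
        cols = list(features.select_dtypes("number").columns)
    X = features[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    scale = None
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"zero-variance column: {cols[zero[0]]!r}")
        scale = sd
        X = (X - X.mean(axis=0)) / sd
    model = PCA(n_components=X.shape[1])
    scores = model.fit_transform(X)
    return PcaResult(
        scores=scores,
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=model.mean_,
        scale=scale,
    )


@dataclass
class KmeansResult:
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float


def kmeans_cluster(
    points: np.ndarray, k: int = 2, n_init: int = 25, seed: int = 0
) -> KmeansResult:
    """k-means (k-means++ seeding, best of ``n_init`` by inertia),
    deterministic given ``seed``."""
    X = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(X)
    return KmeansResult(
        assignments=assignments, centroids=km.cluster_centers_, inertia=float(km.inertia_)
    )


def cluster_features(
    features: pd.DataFrame, k: int = 2, n_init: int = 25, seed: int = 0,
    standardize: bool = True,
) -> tuple[pd.DataFrame, KmeansResult]:
    """Cluster genes in standardized feature space (PCA is for display, not
    for the clustering itself); returns the table with a ``cluster`` column,
    clusters relabelled by decreasing size."""
    cols = list(FEATURE_COLUMNS)
    X = features[cols].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance column: {cols[int(np.flatnonzero(sd==0)[0])]!r}")
        X = (X - X.mean(axis=0)) / sd
    result = kmeans_cluster(X, k=k, n_init=n_init, seed=seed)
    order = np.argsort([-np.sum(result.assignments == c) for c in range(k)], kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    out = features.copy()
    out["cluster"] = [relabel[int(a)] for a in result.assignments]
    result.assignments = out["cluster"].to_numpy()
    result.centroids = result.centroids[order]
    return out, result


def enrich_terms(
    cluster_genes: set[str] | list[str],
    background_genes: set[str] | list[str],
    term_map: dict[str, set[str] | list[str]],
    bh_correct: bool = True,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of annotation terms in a gene
    cluster against a background; terms with zero cluster hits are omitted."""
    cluster = set(cluster_genes)
    background = set(background_genes)
    stray = cluster - background
    if stray:
        raise ValueError(f"cluster genes absent from background: {sorted(stray)[:5]}")
    M, n = len(background), len(cluster)
    rows = []
    for term, members in sorted(term_map.items()):
        members = set(members) & background
        k = len(members & cluster)
        if k == 0:
            continue
        K = len(members)
        p = float(hypergeom.sf(k - 1, M, K, n))
        expected = n * K / M
        rows.append(
            {
                "term": term,
                "cluster_hits": k,
                "term_size": K,
                "expected": expected,
                "enrichment_ratio": k / expected if expected > 0 else np.inf,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows, columns=[
        "term", "cluster_hits", "term_size", "expected", "enrichment_ratio", "p_value"
    ])
    if bh_correct and not df.empty:
        from statsmodels.stats.multitest import multipletests

        df["bh_q"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
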
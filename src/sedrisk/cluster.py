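"""Per-year Ward clustering of sites by metal-concentration profiles.

Sites sampled in a given year are clustered on their (optionally
log10-transformed, per-analyte z-scored) concentration vectors with Ward
linkage on Euclidean distance.  The number of clusters is chosen by mean
silhouette, with the elbow (largest second difference of within-cluster sum
of squares) reported alongside; on disagreement the silhouette wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.metrics import silhouette_score

from . import reference
from .data import SamplePanel


class InsufficientSitesError(ValueError):
    """Fewer than three complete site profiles in the requested year."""


@dataclass
class ClusterResult:
    year: int
    matrix: pd.DataFrame            # standardized sites × analytes
    linkage_matrix: np.ndarray
    leaf_order: list[int]           # site ids in dendrogram order
    labels: pd.Series               # site id -> cluster 1..k
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    wss_by_k: dict[int, float] = field(default_factory=dict)
    elbow_k: int | None = None
    low_confidence: bool = False
    dropped_sites: list[int] = field(default_factory=list)
    dropped_analytes: list[str] = field(default_factory=list)


def prepare_matrix(
    panel: SamplePanel,
    year: int,
    analytes: list[str] | None = None,
    log_transform: bool = True,
    standardize: bool = True,
) -> tuple[pd.DataFrame, list[int], list[str]]:
    """Sites × analytes matrix for one year.

    Concentrations are log10-transformed (they are right-skewed, roughly
    log-normal) and z-scored per analyte.  Sites missing any analyte are
    dropped and listed; zero-variance columns are dropped with a warning.
    Raises :class:`InsufficientSitesError` with < 3 complete rows, mirroring
    years that cannot be clustered for lack of samples.
    """
    analytes = list(analytes or reference.METALS)
    sub = panel.data[(panel.data["year"] == year) & panel.data["analyte"].isin(analytes)]
    wide = sub.pivot_table(index="site_id", columns="analyte", values="value", aggfunc="first")
    wide = wide.reindex(columns=[a for a in analytes if a in wide.columns])
    complete = wide.dropna()
    dropped_sites = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 3:
        raise InsufficientSitesError(
            f"year {year}: only {len(complete)} complete site profiles (need >= 3)"
        )
    mat = np.log10(complete.to_numpy(dtype=float)) if log_transform else complete.to_numpy(dtype=float)
    mat = pd.DataFrame(mat, index=complete.index, columns=complete.columns)
    dropped_cols = [c for c in mat.columns if mat[c].std(ddof=0) == 0]
    if dropped_cols:
        warnings.warn(f"year {year}: dropping zero-variance analytes {dropped_cols}")
        mat = mat.drop(columns=dropped_cols)
    if standardize:
        mat = (mat - mat.mean()) / mat.std(ddof=0)
    return mat, dropped_sites, dropped_cols


def _wss(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def ward_cluster(
    matrix: pd.DataFrame,
    year: int = 0,
    k_range: tuple[int, int] | None = None,
) -> ClusterResult:
    """Agglomerative Ward hierarchy on Euclidean distance with k selection.

    Degenerate input (all rows identical) yields a single flagged cluster.
    """
    if len(matrix) < 3:
        raise InsufficientSitesError(f"need >= 3 rows, got {len(matrix)}")
    x = matrix.to_numpy(dtype=float)
    sites = list(matrix.index)
    if np.ptp(x, axis=0).max() == 0:
        warnings.warn("all site profiles identical; single cluster")
        z = linkage(x, method="ward")
        return ClusterResult(
            year=year, matrix=matrix, linkage_matrix=z,
            leaf_order=[sites[i] for i in leaves_list(z)],
            labels=pd.Series(1, index=matrix.index), k=1, low_confidence=True,
        )
    z = linkage(x, method="ward")
    lo, hi = k_range if k_range else (2, min(8, len(matrix) - 1))
    if lo > hi:
        raise ValueError(f"empty k range [{lo}, {hi}]")
    sil: dict[int, float] = {}
    wss: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(lo, hi + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        wss[k] = _wss(x, labels)
        sil[k] = silhouette_score(x, labels) if len(np.unique(labels)) > 1 else np.nan
    best_k = max(sil, key=lambda k: (sil[k], -k))
    elbow_k = None
    ks = sorted(wss)
    if len(ks) >= 3:
        second_diff = {
            ks[i]: wss[ks[i - 1]] - 2 * wss[ks[i]] + wss[ks[i + 1]] for i in range(1, len(ks) - 1)
        }
        elbow_k = max(second_diff, key=lambda k: (second_diff[k], -k))
        if elbow_k != best_k:
            warnings.warn(
                f"year {year}: silhouette picks k={best_k}, elbow k={elbow_k}; using silhouette"
            )
    return ClusterResult(
        year=year,
        matrix=matrix,
        linkage_matrix=z,
        leaf_order=[sites[i] for i in leaves_list(z)],
        labels=pd.Series(labels_by_k[best_k], index=matrix.index),
        k=best_k,
        silhouette_by_k=sil,
        wss_by_k=wss,
        elbow_k=elbow_k,
        low_confidence=bool(sil[best_k] < 0.3),
    )


def choose_k(result: ClusterResult, k_range: tuple[int, int] | None = None) -> int:
    """k maximising mean silhouette over ``k_range`` (recomputed if the
    range differs from the one used to build the result)."""
    if k_range is None or not result.silhouette_by_k:
        return result.k
    lo, hi = k_range
    candidates = {k: s for k, s in result.silhouette_by_k.items() if lo <= k <= hi}
    if not candidates:
        raise ValueError(f"no silhouette values inside [{lo}, {hi}]")
    return max(candidates, key=lambda k: (candidates[k], -k))


def cluster_year(
    panel: SamplePanel,
    year: int,
    analytes: list[str] | None = None,
    k_range: tuple[int, int] | None = None,
    log_transform: bool = True,
    standardize: bool = True,
) -> ClusterResult:
    mat, dropped_sites, dropped_cols = prepare_matrix(
        panel, year, analytes, log_transform=log_transform, standardize=standardize
    )
    result = ward_cluster(mat, year=year, k_range=k_range)
    result.dropped_sites = dropped_sites
    result.dropped_analytes = dropped_cols
    return result


def heatmap_export(
    result: ClusterResult,
    landuse_categories: dict[int, str] | None = None,
    path: "str | None" = None,
    render_png: "str | None" = None,
) -> pd.DataFrame:
    """Leaf-ordered standardized matrix with cluster and land-use
    annotations, written as CSV when ``path`` is given; optional cosmetic
    PNG rendering."""
    out = result.matrix.loc[result.leaf_order].copy()
    out.insert(0, "cluster", result.labels.loc[result.leaf_order].to_numpy())
    if landuse_categories is not None:
        out.insert(1, "land_use", [landuse_categories.get(s, "") for s in result.leaf_order])
    out.index.name = "site_id"
    if path is not None:
        out.to_csv(path)
    if render_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        numeric = out[result.matrix.columns]
        fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(out))))
        im = ax.imshow(numeric.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(out)), [str(s) for s in out.index])
        ax.set_xticks(range(numeric.shape[1]), numeric.columns, rotation=90)
        fig.colorbar(im, ax=ax, label="z-score of log10 concentration")
        fig.tight_layout()
        fig.savefig(render_png, dpi=120)
        plt.close(fig)
    return out
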
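"""Per-cell feature normalization, graph clustering, phenotype assignment.

The module consumes per-cell feature tables (morphology + marker
intensities, as produced by whole-cell segmentation followed by
scikit-image-style region properties): area, major/minor axis length,
eccentricity, solidity, extent, orientation, PanCK and Vimentin intensity.
Aspect ratio is major/minor.  All features are z-score normalized across
the table, a k-nearest-neighbor graph is built on Euclidean distance in the
z-scored feature space, and communities are found by seeded Louvain
modularity optimization at a low resolution (default 0.1, favoring a small
number of major phenotypes).  Clusters are then named by a rank rule on
their mean z-scores: high PanCK / low Vimentin marks epithelial cells and
cell area splits them into large/small; low PanCK / high Vimentin marks
stromal (large) versus immune (small) cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.sparse import csr_matrix
from sklearn.neighbors import kneighbors_graph

from .io import FormatError, get_logger

log = get_logger(__name__)

FEATURE_COLUMNS = ("area", "major_axis", "minor_axis", "eccentricity",
                   "solidity", "extent", "orientation", "panck", "vimentin")
DERIVED_COLUMNS = FEATURE_COLUMNS + ("aspect_ratio",)

DEFAULT_K_NEIGHBORS = 15
DEFAULT_RESOLUTION = 0.1

PHENOTYPES = ("epithelial-large", "epithelial-small", "stroma", "immune")


def derive_features(table: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Add aspect ratio and z-score columns (``z_<feature>``).

    Rows with a non-positive minor axis (degenerate segmentation) are
    excluded with a log entry.  ``ddof`` selects population (0, default) or
    sample (1) standard deviation for the z-scores; constant columns get
    z = 0.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cell table is missing columns {missing}")
    bad = (table["minor_axis"] <= 0) | (table["major_axis"] < table["minor_axis"])
    if bad.any():
        log.warning("excluding %d cells with degenerate axis lengths",
                    int(bad.sum()))
        table = table.loc[~bad]
    out = table.copy()
    out["aspect_ratio"] = out["major_axis"] / out["minor_axis"]
    for col in DERIVED_COLUMNS:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=ddof)
        out[f"z_{col}"] = 0.0 if sd == 0 else (x - x.mean()) / sd
    return out


def cluster_cells(z_features: np.ndarray | pd.DataFrame,
                  k_neighbors: int = DEFAULT_K_NEIGHBORS,
                  resolution: float = DEFAULT_RESOLUTION,
                  seed: int = 0) -> np.ndarray:
    """Louvain community labels from a symmetrized kNN graph.

    The graph connects each cell to its ``k_neighbors`` Euclidean nearest
    neighbors in z-scored feature space (edges symmetrized by union);
    communities maximize modularity at the given ``resolution``.  Labels are
    deterministic for a fixed seed and relabeled by decreasing cluster size.
    """
    X = np.asarray(z_features, dtype=float)
    if X.ndim != 2:
        raise FormatError("z_features must be 2-D (cells x features)")
    n = X.shape[0]
    if n <= k_neighbors:
        raise FormatError(f"need more than k_neighbors={k_neighbors} cells")
    adj = kneighbors_graph(X, n_neighbors=k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize: union of directed kNN edges
    graph = nx.from_scipy_sparse_array(csr_matrix(adj))
    communities = nx.community.louvain_communities(
        graph, resolution=resolution, seed=seed)
    labels = np.empty(n, dtype=int)
    order = sorted(communities, key=lambda c: (-len(c), min(c)))
    for lab, members in enumerate(order):
        labels[list(members)] = lab
    return labels


@dataclass
class PhenotypeAssignment:
    mapping: dict[int, str]
    ambiguous: dict[int, bool]


def cluster_mean_z(table: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster mean z-scores of PanCK, Vimentin and area."""
    df = table.copy()
    df["_cluster"] = labels
    return df.groupby("_cluster")[["z_panck", "z_vimentin", "z_area"]].mean()


def assign_phenotypes(cluster_means: pd.DataFrame) -> PhenotypeAssignment:
    """Map clusters to the four phenotypes from their mean z-scores.

    "High"/"low" means above/below the across-cluster median of that
    feature; exact median ties are resolved by rank (the upper half of the
    stable ordering counts as high), deciding the marker axis (PanCK)
    first.  PanCK splits epithelial from non-epithelial, Vimentin is the
    confirmatory axis (a cluster whose Vimentin call agrees with its PanCK
    call is flagged ambiguous), and area splits large from small.
    """
    if len(cluster_means) < 1:
        raise FormatError("need at least one cluster")

    def high(series: pd.Series) -> pd.Series:
        n = len(series)
        if n == 1:
            return pd.Series([True], index=series.index)
        order = np.argsort(series.to_numpy(), kind="stable")
        flags = np.zeros(n, dtype=bool)
        flags[order[n - n // 2:]] = True  # upper half (majority low on ties)
        return pd.Series(flags, index=series.index)

    pk_high = high(cluster_means["z_panck"])
    vm_high = high(cluster_means["z_vimentin"])
    area_high = high(cluster_means["z_area"])

    mapping, ambiguous = {}, {}
    for cl in cluster_means.index:
        if pk_high[cl]:
            name = "epithelial-large" if area_high[cl] else "epithelial-small"
            amb = bool(vm_high[cl])  # epithelial should be Vimentin-low
        else:
            name = "stroma" if area_high[cl] else "immune"
            amb = not bool(vm_high[cl])  # non-epithelial should be Vimentin-high
        mapping[int(cl)] = name
        ambiguous[int(cl)] = amb
        if amb:
            log.warning("cluster %s has an ambiguous marker profile "
                        "(PanCK and Vimentin calls agree)", cl)
    return PhenotypeAssignment(mapping=mapping, ambiguous=ambiguous)


def cluster_and_phenotype(table: pd.DataFrame,
                          k_neighbors: int = DEFAULT_K_NEIGHBORS,
                          resolution: float = DEFAULT_RESOLUTION,
                          seed: int = 0, ddof: int = 0) -> pd.DataFrame:
    """Full pipeline: derive features -> cluster -> assign phenotypes.

    Returns the derived table with ``cluster`` and ``phenotype`` columns.
    """
    derived = derive_features(table, ddof=ddof)
    zcols = [f"z_{c}" for c in DERIVED_COLUMNS]
    labels = cluster_cells(derived[zcols].to_numpy(), k_neighbors=k_neighbors,
                           resolution=resolution, seed=seed)
    assignment = assign_phenotypes(cluster_mean_z(derived, labels))
    out = derived.copy()
    out["cluster"] = labels
    out["phenotype"] = [assignment.mapping[int(c)] for c in labels]
    return out
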
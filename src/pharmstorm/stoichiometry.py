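"""Blink-cluster stoichiometry and localization-precision estimation.

A fluorophore blinks; in a sparse-labeling acquisition the localization
points (LPs) of one molecule form a tight spatial cluster.  A
one-fluorophore pharmacoprobe is mostly detected as a single LP, whereas a
secondary antibody carrying an unknown number of fluorophores is usually
detected as an LP cluster with variable membership — the fraction of
single-LP detections therefore separates the two labeling chemistries.
The scatter of a cluster's LPs about its centroid estimates the lateral
localization precision.

Grouping is chained density linkage: two LPs belong to the same molecule
cluster if they are within ``radius`` nm spatially and within
``max_frame_gap`` frames temporally along a chain of such links
(transitive closure).  This is order-independent and matches the
"localization-point cluster" notion; it is only interpretable in the
sparse regime where molecule spacing is much larger than the radius.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import DisjointSet
from scipy.spatial import cKDTree

from .core import LocalizationTable, ValidationError


@dataclass
class ClusteringConfig:
    """Spatial/temporal linkage parameters.

    ``radius`` defaults to ~3x the expected localization precision.
    ``max_frame_gap=None`` disables the temporal constraint (sufficient in
    sparse-labeling experiments, where concurrent neighbors are rare).
    """

    radius: float = 30.0
    max_frame_gap: int | None = None
    min_lps: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("radius must be positive")
        if self.max_frame_gap is not None and self.max_frame_gap < 0:
            raise ValidationError("max_frame_gap must be >= 0")


@dataclass
class MoleculeCluster:
    """One putative molecule: its LPs and per-axis precision estimates.

    Precision fields (sample std about the centroid, n−1 denominator) are
    defined only for clusters with >= 2 LPs; ``precision_lateral`` is the
    arithmetic mean of the x and y precisions.
    """

    lp_indices: np.ndarray
    centroid: tuple[float, float]
    lp_count: int
    precision_x: float | None = None
    precision_y: float | None = None
    precision_lateral: float | None = None


def cluster_blinks(table: LocalizationTable, config: ClusteringConfig | None = None) -> list[MoleculeCluster]:
    """Group LPs into putative molecules by chained density linkage.

    Every LP is assigned to exactly one cluster; clusters are returned in
    order of their first LP's position in the table.
    """
    config = config or ClusteringConfig()
    n = len(table)
    if n == 0:
        return []
    coords = table.coords
    frames = table.data["frame"].to_numpy()
    ds = DisjointSet(range(n))
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(config.radius):
        if config.max_frame_gap is None or abs(int(frames[i]) - int(frames[j])) <= config.max_frame_gap:
            ds.merge(i, j)
    clusters = []
    for subset in ds.subsets():
        idx = np.fromiter(subset, int)
        idx.sort()
        if len(idx) < config.min_lps:
            continue
        pts = coords[idx]
        centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        cluster = MoleculeCluster(idx, centroid, len(idx))
        if len(idx) >= 2:
            cluster.precision_x = float(np.std(pts[:, 0], ddof=1))
            cluster.precision_y = float(np.std(pts[:, 1], ddof=1))
            cluster.precision_lateral = (cluster.precision_x + cluster.precision_y) / 2.0
        clusters.append(cluster)
    clusters.sort(key=lambda c: int(c.lp_indices[0]))
    return clusters


def single_fraction(clusters: list[MoleculeCluster]) -> float:
    """Fraction of molecules detected as a single localization point."""
    if not clusters:
        raise ValidationError("no clusters; single fraction undefined")
    return sum(1 for c in clusters if c.lp_count == 1) / len(clusters)


def localization_precision(
    clusters: list[MoleculeCluster], min_lps: int = 2
) -> tuple[np.ndarray, float]:
    """Per-cluster lateral precision and its median across clusters (nm).

    Only clusters with at least ``min_lps`` (>= 2) LPs contribute; the
    sample standard deviation of a single point is undefined.
    """
    if min_lps < 2:
        raise ValidationError("min_lps must be >= 2 for a precision estimate")
    values = np.array(
        [c.precision_lateral for c in clusters if c.lp_count >= min_lps], float
    )
    if len(values) == 0:
        raise ValidationError(f"no cluster has >= {min_lps} LPs")
    return values, float(np.median(values))


def lp_count_histogram(clusters: list[MoleculeCluster]) -> "np.ndarray":
    """Counts of clusters by LP membership (index k = clusters with k+1 LPs)."""
    if not clusters:
        return np.zeros(0, int)
    counts = np.array([c.lp_count for c in clusters])
    return np.bincount(counts)[1:]
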
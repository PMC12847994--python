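"""Functional clustering of RyR2 subunit locations and cluster statistics.

Calcium-induced calcium release couples receptors whose released Ca2+ can
reach a neighbour before dissipating; diffusion modelling puts that
fire-diffuse-fire distance around 100 nm.  DBSCAN on the 3D subunit positions
with eps = 100 nm and min_pts = 1 therefore groups receptors into functionally
coupled clusters: with min_pts = 1 every subunit belongs to a cluster
(isolated subunits are real singleton clusters) and the partition equals the
connected components of the 100 nm adjacency graph.

Cluster sizes are counted in subunits (SU).  Because only a fraction p_LE of
subunits carries a detected label, sizes are corrected by dividing by p_LE,
and converted to receptor counts by a further division by 4 (the receptor is a
homotetramer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from ._util import round_half_away


@dataclass(frozen=True)
class ClusterParams:
    eps: float = 100.0
    min_pts: int = 1

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


def cluster_subunits(subunits: pd.DataFrame, params: ClusterParams | None = None) -> np.ndarray:
    """DBSCAN labels for each subunit row (3D Euclidean metric).

    With the default min_pts = 1 no point is marked as noise (-1 never
    appears) and the labels are the eps-graph connected components.
    """
    params = params or ClusterParams()
    if len(subunits) == 0:
        return np.zeros(0, dtype=int)
    pts = subunits[["x", "y", "z"]].to_numpy(float)
    return DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(pts)


@dataclass
class ClusterStats:
    """Cluster-size statistics with labeling-efficiency correction.

    All ``mean_*`` fields are per-cluster means; ``frac_*`` fields are
    fractions of subunits (except ``frac_large_clusters``, a fraction of
    clusters).  ``mean_su_corrected = mean_su / p_le`` and
    ``mean_ryr2 = mean_su_corrected / 4``.
    """

    n_clusters: int
    sizes_su: np.ndarray
    mean_su: float
    mean_su_gt1: float
    mean_su_corrected: float
    mean_ryr2: float
    frac_in_large: float
    frac_large_clusters: float
    frac_top3: float
    large_threshold: int
    p_le: float

    def summary(self) -> str:
        return "\n".join(
            [
                "RyR2 cluster statistics",
                f"  clusters                 {self.n_clusters}",
                f"  subunits                 {int(self.sizes_su.sum())}",
                f"  mean SU/cluster          {self.mean_su:.1f}",
                f"  mean SU/cluster (>1 SU)  {self.mean_su_gt1:.1f}",
                f"  corrected (p_LE={self.p_le:.2f})    {self.mean_su_corrected:.1f}",
                f"  mean RyR2/cluster        {self.mean_ryr2:.1f}",
                f"  SU in large clusters     {100 * self.frac_in_large:.1f} %"
                f" (>= {self.large_threshold} SU)",
                f"  large clusters           {100 * self.frac_large_clusters:.1f} %",
                f"  SU in 3 largest          {100 * self.frac_top3:.1f} %",
            ]
        )


def compute_cluster_stats(labels: np.ndarray, p_le: float = 1.0, large_threshold: int = 50) -> ClusterStats:
    """Sizes and derived statistics from DBSCAN labels.

    ``p_le`` divides every cluster size to correct for partial labeling;
    a cluster is "large" if it contains at least ``large_threshold`` SU
    (>= 12.5 receptors at the default 50).
    """
    labels = np.asarray(labels)
    if not 0.0 < p_le <= 1.0:
        raise ValueError(f"p_le must be in (0, 1], got {p_le}")
    if len(labels) == 0:
        raise ValueError("no subunits to summarize")
    _, sizes = np.unique(labels[labels >= 0], return_counts=True)
    noise = int((labels == -1).sum())
    if noise:  # min_pts > 1: noise points count as singleton clusters
        sizes = np.concatenate([sizes, np.ones(noise, int)])
    sizes = np.sort(sizes)[::-1]
    n_su = int(sizes.sum())
    mean_su = float(sizes.mean())
    gt1 = sizes[sizes > 1]
    mean_su_gt1 = float(gt1.mean()) if len(gt1) else float("nan")
    large = sizes >= large_threshold
    return ClusterStats(
        n_clusters=len(sizes),
        sizes_su=sizes,
        mean_su=mean_su,
        mean_su_gt1=mean_su_gt1,
        mean_su_corrected=mean_su / p_le,
        mean_ryr2=mean_su / p_le / 4.0,
        frac_in_large=float(sizes[large].sum() / n_su),
        frac_large_clusters=float(large.mean()),
        frac_top3=float(sizes[:3].sum() / n_su),
        large_threshold=int(large_threshold),
        p_le=float(p_le),
    )


def su_to_ryr2(value: float, p_le: float = 1.0, input_is_ryr2: bool = False) -> float:
    """Convert a subunit count to a receptor count.

    Raw SU input: divide by p_le then by 4 (set p_le = 1 to divide by 4 only).
    ``input_is_ryr2``: the value is already receptors per cluster and only the
    efficiency correction is applied.
    """
    if not 0.0 < p_le <= 1.0:
        raise ValueError(f"p_le must be in (0, 1], got {p_le}")
    if input_is_ryr2:
        return value / p_le
    return value / p_le / 4.0


def report_round(x: float, ndigits: int = 1) -> float:
    """Report-time rounding, half away from zero (4.125 -> 4.1, 8.15 -> 8.2)."""
    return round_half_away(x, ndigits)


def cluster_table(subunits: pd.DataFrame, labels: np.ndarray, p_le: float = 1.0) -> pd.DataFrame:
    """Per-cluster table: id, sizes (raw / corrected / receptors), centroid."""
    labels = np.asarray(labels)
    pts = subunits[["x", "y", "z"]].to_numpy(float)
    rows = []
    next_id = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        members = [idx] if lab >= 0 else [np.array([i]) for i in idx]
        for grp in members:
            c = pts[grp].mean(axis=0)
            size = len(grp)
            rows.append((next_id, size, size / p_le, size / p_le / 4.0, c[0], c[1], c[2]))
            next_id += 1
    return pd.DataFrame(rows, columns=["cluster_id", "size_su", "size_corrected", "size_ryr2", "x", "y", "z"])
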
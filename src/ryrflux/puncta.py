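"""Appearance simulation, 2D rendering, blob finding and nearest-neighbour
analysis of puncta.

This mirrors how localization data are traditionally summarised: render the
points into a 2D super-resolution image (sum of Gaussians on a pixel grid),
detect puncta with a blob finder, and compare the nearest-neighbour (NN)
distance distributions of the detected puncta between imaging conditions with
one-way ANOVA and Tukey's HSD.

``simulate_cluster_appearance`` turns a ground-truth tetramer layout (for
example an EM-traced cluster morphology) into the subunit localizations a
MINFLUX acquisition with partial labeling would record: each tag site is
retained with probability ``p_su`` and perturbed by isotropic Gaussian error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._util import child_rng
from .simulate import ClusterLayout, expand_layout_to_tag_sites


@dataclass(frozen=True)
class EMSimulationConfig:
    """Partial-labeling appearance model: retention probability and 3D error."""

    p_su: float = 0.5
    sigma: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_su <= 1.0:
            raise ValueError(f"p_su must be in [0, 1], got {self.p_su}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def simulate_cluster_appearance(layout: ClusterLayout, cfg: EMSimulationConfig | None = None) -> np.ndarray:
    """Simulated 3D subunit positions (nm) for a layout under partial labeling."""
    cfg = cfg or EMSimulationConfig()
    if len(layout) == 0:
        raise ValueError("layout is empty")
    rng = child_rng(cfg.seed, 3)
    sites = expand_layout_to_tag_sites(layout)[["x", "y", "z"]].to_numpy(float)
    keep = rng.random(len(sites)) < cfg.p_su
    pts = sites[keep]
    if cfg.sigma > 0:
        pts = pts + rng.standard_normal(pts.shape) * cfg.sigma
    return pts


@dataclass
class RenderedImage:
    """2D intensity image with its nm geometry (origin = center of pixel [0,0])."""

    image: np.ndarray
    pixel_size: float
    origin: np.ndarray  # (2,) nm of pixel (row 0, col 0) center; x = cols, y = rows
    gauss_sigma: float

    def pixel_to_nm(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        x = self.origin[0] + np.asarray(cols) * self.pixel_size
        y = self.origin[1] + np.asarray(rows) * self.pixel_size
        return np.column_stack([x, y])


def render_2d(points: np.ndarray, pixel_size: float = 3.0, gauss_sigma: float = 4.0,
              pad: float | None = None) -> RenderedImage:
    """Gaussian rendering of points (x-y projection) on a pixel grid.

    Each point contributes a unit-integral isotropic Gaussian of standard
    deviation ``gauss_sigma`` nm, so the image integral equals the point
    count.  3D input is projected onto x-y.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) == 0:
        raise ValueError("no points to render")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    xy = points[:, :2]
    if pad is None:
        pad = 4.0 * gauss_sigma + 2.0 * pixel_size
    lo = xy.min(axis=0) - pad
    hi = xy.max(axis=0) + pad
    n_cols = int(np.ceil((hi[0] - lo[0]) / pixel_size)) + 1
    n_rows = int(np.ceil((hi[1] - lo[1]) / pixel_size)) + 1
    cols = np.clip(np.round((xy[:, 0] - lo[0]) / pixel_size).astype(int), 0, n_cols - 1)
    rows = np.clip(np.round((xy[:, 1] - lo[1]) / pixel_size).astype(int), 0, n_rows - 1)
    img = np.zeros((n_rows, n_cols))
    np.add.at(img, (rows, cols), 1.0)
    if gauss_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=gauss_sigma / pixel_size, mode="constant", truncate=6.0)
    return RenderedImage(image=img, pixel_size=pixel_size, origin=lo, gauss_sigma=gauss_sigma)


def find_puncta(rendered: RenderedImage, threshold: float = 1.0, blur_size: float = 2.0) -> np.ndarray:
    """Detect puncta in a rendered image; returns (n, 2) centroid coordinates in nm.

    The image is pre-blurred with a Gaussian of ``blur_size`` pixels, then
    thresholded at ``threshold`` times a robust (MAD-based) background scale
    above the background median; connected components above threshold become
    puncta, located at their intensity-weighted centroids.
    """
    img = rendered.image
    if img.size == 0:
        return np.zeros((0, 2))
    blurred = ndimage.gaussian_filter(img, sigma=blur_size, mode="constant") if blur_size > 0 else img
    bg = np.median(blurred)
    scale = 1.4826 * np.median(np.abs(blurred - bg))
    if scale <= 0:
        scale = blurred.std() or 1.0
    mask = blurred > bg + threshold * scale
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros((0, 2))
    coms = ndimage.center_of_mass(blurred, labels, index=np.arange(1, n + 1))
    coms = np.atleast_2d(np.asarray(coms, float))
    return rendered.pixel_to_nm(coms[:, 0], coms[:, 1])


def write_tiff(rendered: RenderedImage, path: str) -> None:
    """Save a rendered image as 32-bit float TIFF with nm pixel size metadata."""
    import tifffile

    res = 1.0 / rendered.pixel_size  # pixels per nm
    tifffile.imwrite(
        path,
        rendered.image.astype(np.float32),
        resolution=(res, res),
        metadata={"unit": "nm", "pixel_size_nm": rendered.pixel_size,
                  "origin_nm": rendered.origin.tolist()},
    )


def nn_distances(points2d: np.ndarray) -> tuple[np.ndarray, float]:
    """Euclidean nearest-neighbour distance of each point (self excluded).

    Returns (distances, median).  Needs at least 2 points.
    """
    points2d = np.atleast_2d(np.asarray(points2d, float))
    if len(points2d) < 2:
        raise ValueError("nearest-neighbour distances need at least 2 points")
    from scipy.spatial import cKDTree

    tree = cKDTree(points2d)
    d, _ = tree.query(points2d, k=2)
    dists = d[:, 1]
    return dists, float(np.median(dists))


def compare_nn_groups(groups: list[np.ndarray], labels: list[str] | None = None) -> dict:
    """One-way ANOVA across >= 2 groups of NN distances plus all-pairs Tukey HSD.

    Returns a dict with ``anova_F``, ``anova_p`` and a ``tukey`` DataFrame with
    columns group1, group2, meandiff, p_adj.
    """
    groups = [np.asarray(g, float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(groups)
    if np.allclose(pooled.var(), 0.0):
        raise ValueError("all values identical; F statistic undefined")
    f_stat, p_val = stats.f_oneway(*groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    group_ids = np.concatenate([np.full(len(g), lab, dtype=object) for g, lab in zip(groups, labels)])
    res = pairwise_tukeyhsd(pooled, group_ids)
    tukey = pd.DataFrame(
        {
            "group1": res.groupsunique[np.array([p[0] for p in _pair_indices(len(labels))])],
            "group2": res.groupsunique[np.array([p[1] for p in _pair_indices(len(labels))])],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
        }
    )
    return {"anova_F": float(f_stat), "anova_p": float(p_val), "tukey": tukey}


def _pair_indices(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def puncta_pipeline(
    points: np.ndarray,
    pixel_size: float = 3.0,
    gauss_sigma: float = 4.0,
    threshold: float = 1.0,
    blur_size: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render -> find puncta -> NN distances; returns (puncta, distances, median)."""
    rendered = render_2d(points, pixel_size=pixel_size, gauss_sigma=gauss_sigma)
    puncta = find_puncta(rendered, threshold=threshold, blur_size=blur_size)
    dists, med = nn_distances(puncta)
    return puncta, dists, med
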
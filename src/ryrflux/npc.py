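"""Labeling-efficiency calibration from 3D nuclear-pore data.

Nup96 occurs in 32 copies per pore: two parallel 8-fold rings, two tag sites
per segment.  Counting how many of the 16 segments carry at least one detected
label and comparing the histogram of these counts with a binomial model gives
the effective labeling efficiency p_LE (the product of chemical labeling and
photo-detection probability per site).

The assay proceeds in stages, each exposed separately:

1. ``detect_npc_candidates`` -- group subunit locations into per-pore point sets;
2. ``NPCTemplateModel`` / ``fit_npc_template`` -- maximum-likelihood fit of a
   rigid double-ring template (center, symmetry axis, in-plane rotation, and
   optionally diameter/spacing) to each point set;
3. ``count_labeled_segments`` -- nearest-anchor segment assignment in the
   fitted frame;
4. ``LabelingEfficiencyModel`` / ``estimate_labeling_efficiency`` -- truncated
   binomial maximum likelihood on the pooled segment-count histogram.

``run_npc_assay`` chains the stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from ._util import axis_from_angles, child_rng


# ---------------------------------------------------------------------------
# template


@dataclass(frozen=True)
class NPCTemplate:
    """Rigid double-ring geometry: segment anchors and per-segment tag sites.

    Segment anchors (one per segment, 16 under the defaults) are used for
    labeled-segment counting; the likelihood of the pose fit uses the
    site-level positions (two tag sites per segment, offset by
    ``site_pair_offset_deg`` along the ring), which is the actual marker
    geometry the data are drawn from.
    """

    ring_diameter: float = 107.0
    ring_spacing: float = 50.0
    n_segments_per_ring: int = 8
    twist_deg: float = 0.0
    sites_per_segment: int = 2
    site_pair_offset_deg: float = 6.0

    def __post_init__(self):
        if self.ring_diameter <= 0 or self.ring_spacing <= 0:
            raise ValueError("ring_diameter and ring_spacing must be positive")
        if self.n_segments_per_ring < 1 or self.sites_per_segment < 1:
            raise ValueError("need at least one segment per ring and one site per segment")

    @property
    def n_segments(self) -> int:
        return 2 * self.n_segments_per_ring

    def _ring_points(self, offsets: np.ndarray, diameter: float | None, spacing: float | None) -> np.ndarray:
        d = self.ring_diameter if diameter is None else float(diameter)
        s = self.ring_spacing if spacing is None else float(spacing)
        r = d / 2.0
        angles = np.arange(self.n_segments_per_ring) * (360.0 / self.n_segments_per_ring)
        out = []
        for z, tw in ((s / 2.0, 0.0), (-s / 2.0, self.twist_deg)):
            for a in angles:
                for off in offsets:
                    ang = np.deg2rad(a + tw + off)
                    out.append([r * np.cos(ang), r * np.sin(ang), z])
        return np.asarray(out)

    def anchors(self, diameter: float | None = None, spacing: float | None = None) -> np.ndarray:
        """Segment anchors (2 * n_segments_per_ring, 3), canonical frame.

        Ring-major order: indices [0, n) are the +z (cytoplasmic) ring, the
        rest the -z (nucleoplasmic) ring.
        """
        return self._ring_points(np.array([0.0]), diameter, spacing)

    def sites(self, diameter: float | None = None, spacing: float | None = None) -> np.ndarray:
        """Tag-site positions (n_segments * sites_per_segment, 3), canonical frame."""
        if self.sites_per_segment == 1:
            offsets = np.array([0.0])
        else:
            offsets = np.linspace(
                -self.site_pair_offset_deg, self.site_pair_offset_deg, self.sites_per_segment
            )
        return self._ring_points(offsets, diameter, spacing)


# ---------------------------------------------------------------------------
# candidate detection


def detect_npc_candidates(
    subunits: pd.DataFrame,
    group_eps: float = 100.0,
    min_points: int = 5,
    max_extent: float = 250.0,
) -> list[np.ndarray]:
    """Group subunit locations into candidate pores.

    DBSCAN (eps = ``group_eps``, min_samples = 1) on the 3D positions; groups
    with fewer than ``min_points`` members or a bounding-box diagonal above
    ``max_extent`` nm are discarded.  Returns index arrays into ``subunits``.
    """
    if group_eps <= 0:
        raise ValueError("group_eps must be positive")
    if len(subunits) == 0:
        return []
    pts = subunits[["x", "y", "z"]].to_numpy(float)
    labels = DBSCAN(eps=group_eps, min_samples=1).fit_predict(pts)
    groups = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_points:
            continue
        extent = np.linalg.norm(pts[idx].max(axis=0) - pts[idx].min(axis=0))
        if extent > max_extent:
            continue
        groups.append(idx)
    return groups


def load_roi_groups(path: str, subunits: pd.DataFrame) -> list[np.ndarray]:
    """Read externally supplied ROIs (JSON list of {id, bbox} or {id, points}).

    A bbox is [[xmin, ymin, zmin], [xmax, ymax, zmax]]; points select the
    nearest subunit each.  Returns index arrays into ``subunits``.
    """
    with open(path) as fh:
        rois = json.load(fh)
    pts = subunits[["x", "y", "z"]].to_numpy(float)
    groups = []
    for roi in rois:
        if "bbox" in roi:
            lo, hi = np.asarray(roi["bbox"][0], float), np.asarray(roi["bbox"][1], float)
            idx = np.flatnonzero(np.all((pts >= lo) & (pts <= hi), axis=1))
        elif "points" in roi:
            targets = np.atleast_2d(np.asarray(roi["points"], float))
            idx = np.unique(cdist(targets, pts).argmin(axis=1))
        else:
            raise ValueError(f"ROI {roi.get('id')} has neither 'bbox' nor 'points'")
        if len(idx):
            groups.append(idx)
    return groups


# ---------------------------------------------------------------------------
# template fitting


@dataclass(frozen=True)
class NPCFitConfig:
    """Likelihood and search settings for the rigid template fit.

    ``sigma`` is the Gaussian scale (nm) around each template tag site; it
    covers the localization error of a subunit position.  ``outlier_weight``
    is the uniform mixture weight absorbing unspecific localizations.
    """

    sigma: float = 3.0
    outlier_weight: float = 0.1
    uniform_halfwidth: float = 150.0  # nm; sets the uniform component density
    free_geometry: bool = False
    n_refine: int = 3       # local refinements of the best coarse starts
    maxfev: int = 400
    coarse_sigma_factor: float = 2.0  # broader Gaussian while ranking starts
    icp_iters: int = 2      # center re-alignment sweeps during coarse ranking

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.outlier_weight < 1.0:
            raise ValueError("outlier_weight must be in [0, 1)")


@dataclass
class NPCFit:
    """Fitted pose (and optionally geometry) of one pore."""

    center: np.ndarray
    axis: np.ndarray
    in_plane_rotation: float
    fitted_diameter: float
    fitted_spacing: float
    loglik: float
    n_points: int
    converged: bool
    template: NPCTemplate
    free_geometry: bool
    segment_labeled: np.ndarray | None = None   # filled by count_labeled_segments
    segment_points: np.ndarray | None = None
    segment_traces: np.ndarray | None = None

    @property
    def n_labeled_segments(self) -> int:
        if self.segment_labeled is None:
            raise ValueError("segments not counted yet; call count_labeled_segments")
        return int(self.segment_labeled.sum())

    def anchors_world(self) -> np.ndarray:
        canonical = self.template.anchors(self.fitted_diameter, self.fitted_spacing)
        r = _pose_from_axis(self.axis, self.in_plane_rotation)
        return canonical @ r.T + self.center

    def summary(self) -> str:
        lines = [
            "NPC template fit",
            f"  points             {self.n_points}",
            f"  center (nm)        ({self.center[0]:.1f}, {self.center[1]:.1f}, {self.center[2]:.1f})",
            f"  axis               ({self.axis[0]:.3f}, {self.axis[1]:.3f}, {self.axis[2]:.3f})",
            f"  tilt (deg)         {np.degrees(np.arccos(np.clip(self.axis[2], -1, 1))):.1f}",
            f"  diameter (nm)      {self.fitted_diameter:.1f}" + ("" if self.free_geometry else " (fixed)"),
            f"  ring spacing (nm)  {self.fitted_spacing:.1f}" + ("" if self.free_geometry else " (fixed)"),
            f"  log-likelihood     {self.loglik:.2f}",
        ]
        if self.segment_labeled is not None:
            lines.append(f"  labeled segments   {self.n_labeled_segments}/{len(self.segment_labeled)}")
        return "\n".join(lines)


def _pose_from_axis(axis: np.ndarray, in_plane_deg: float) -> np.ndarray:
    """Rotation mapping the canonical frame (+z axis) onto ``axis`` with spin."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    tilt = np.degrees(np.arccos(np.clip(axis[2], -1.0, 1.0)))
    azim = np.degrees(np.arctan2(axis[1], axis[0])) if tilt > 1e-9 else 0.0
    from ._util import pose_matrix

    return pose_matrix(azim, tilt, in_plane_deg - (azim if tilt > 1e-9 else 0.0))


def _start_grid() -> list[tuple[float, float, float]]:
    """Deterministic (tilt, azimuth, in-plane) starts for the multi-start search.

    Tilt in 15-degree steps over the half-sphere (axis sign is not
    identifiable), azimuth in 30-degree steps, and 8 in-plane angles covering
    one 45-degree symmetry period.
    """
    starts = []
    for tilt in range(0, 91, 15):
        azims = [0.0] if tilt == 0 else list(np.arange(0.0, 360.0, 30.0))
        for az in azims:
            for psi in np.arange(8) * (45.0 / 8.0):
                starts.append((float(tilt), float(az), float(psi)))
    return starts


_START_ROTATIONS_CACHE: dict = {}


def _start_rotations(template: NPCTemplate) -> tuple[list[tuple[float, float, float]], np.ndarray]:
    """Canonical anchors pre-rotated for every start pose, cached per template."""
    key = (
        template.ring_diameter, template.ring_spacing, template.n_segments_per_ring,
        template.twist_deg, template.sites_per_segment, template.site_pair_offset_deg,
    )
    if key not in _START_ROTATIONS_CACHE:
        starts = _start_grid()
        canonical = template.sites()
        rotated = np.stack(
            [canonical @ _pose_from_axis(axis_from_angles(t, a), psi).T for t, a, psi in starts]
        )
        _START_ROTATIONS_CACHE[key] = (starts, rotated)
    return _START_ROTATIONS_CACHE[key]


class NPCTemplateModel:
    """Maximum-likelihood rigid fit of the double-ring template to one point set.

    Each point is modelled as drawn from an isotropic Gaussian centered at its
    nearest template tag site, mixed with a uniform outlier component.  The
    likelihood is maximised over center (3), axis direction (2) and in-plane
    rotation (1), plus diameter and ring spacing when ``free_geometry``.

    The search is a deterministic multi-start: a coarse grid of axis
    directions x in-plane angles is scored with the center at the centroid,
    and the best starts are refined with a local optimizer.
    """

    def __init__(self, points: np.ndarray, template: NPCTemplate | None = None,
                 config: NPCFitConfig | None = None):
        points = np.atleast_2d(np.asarray(points, float))
        if points.shape[0] < 4:
            raise ValueError(f"pose is unidentifiable below 4 points, got {points.shape[0]}")
        if points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        self.points = points
        self.template = template or NPCTemplate()
        self.config = config or NPCFitConfig()
        self._log_uniform = -3.0 * np.log(2.0 * self.config.uniform_halfwidth)

    # likelihood -----------------------------------------------------------

    def _loglik_points(self, anchors_world: np.ndarray) -> float:
        d2 = cdist(self.points, anchors_world, metric="sqeuclidean").min(axis=1)
        s2 = self.config.sigma**2
        log_gauss = -0.5 * d2 / s2 - 1.5 * np.log(2.0 * np.pi * s2)
        w = self.config.outlier_weight
        if w == 0.0:
            return float(log_gauss.sum())
        return float(np.logaddexp(np.log1p(-w) + log_gauss, np.log(w) + self._log_uniform).sum())

    def _unpack(self, params: np.ndarray):
        center = params[:3]
        axis = axis_from_angles(params[3], params[4])
        psi = params[5]
        if self.config.free_geometry:
            diameter, spacing = abs(params[6]), abs(params[7])
        else:
            diameter, spacing = self.template.ring_diameter, self.template.ring_spacing
        return center, axis, psi, diameter, spacing

    def _negloglik(self, params: np.ndarray) -> float:
        center, axis, psi, diameter, spacing = self._unpack(params)
        sites = self.template.sites(diameter, spacing) @ _pose_from_axis(axis, psi).T + center
        return -self._loglik_points(sites)

    # fitting --------------------------------------------------------------

    def _coarse_rank(self) -> tuple[list, np.ndarray, np.ndarray]:
        """Score every grid start, re-aligning each start's center by a few
        ICP-style sweeps (nearest-site assignment -> inlier mean shift).

        The broadened coarse sigma makes the ranking robust to the offset
        between the point centroid and the true pore center, which grows when
        labeling is sparse.
        """
        starts, rotated = _start_rotations(self.template)
        n_starts, n_sites, _ = rotated.shape
        sigma_c = self.config.sigma * self.config.coarse_sigma_factor
        s2 = sigma_c**2
        w = self.config.outlier_weight
        centroid = self.points.mean(axis=0)
        centers = np.tile(centroid, (n_starts, 1))
        scores = None
        for it in range(self.config.icp_iters + 1):
            flat = (rotated + centers[:, None, :]).reshape(-1, 3)
            d2full = cdist(self.points, flat, metric="sqeuclidean").reshape(
                len(self.points), n_starts, n_sites
            )
            nearest = d2full.argmin(axis=2)
            d2 = np.take_along_axis(d2full, nearest[:, :, None], axis=2)[:, :, 0]
            if it < self.config.icp_iters:
                inlier = d2 < (3.0 * sigma_c) ** 2
                for s_i in range(n_starts):
                    mask = inlier[:, s_i]
                    if mask.sum() >= 4:
                        assigned = rotated[s_i, nearest[mask, s_i]] + centers[s_i]
                        centers[s_i] += (self.points[mask] - assigned).mean(axis=0)
            log_gauss = -0.5 * d2 / s2 - 1.5 * np.log(2.0 * np.pi * s2)
            if w == 0.0:
                scores = log_gauss.sum(axis=0)
            else:
                scores = np.logaddexp(
                    np.log1p(-w) + log_gauss, np.log(w) + self._log_uniform
                ).sum(axis=0)
        return starts, centers, scores

    def fit(self) -> NPCFit:
        sym = 360.0 / self.template.n_segments_per_ring
        starts, centers, scores = self._coarse_rank()
        order = np.argsort(-scores)

        best = None
        step = np.array([3.0, 3.0, 3.0, 8.0, 12.0, 5.0, 4.0, 4.0])
        for rank in order[: max(1, self.config.n_refine)]:
            tilt, azim, psi = starts[int(rank)]
            x0 = [*centers[int(rank)], tilt, azim, psi]
            if self.config.free_geometry:
                x0 += [self.template.ring_diameter, self.template.ring_spacing]
            x0 = np.asarray(x0, float)
            simplex = np.vstack([x0, x0 + np.diag(step[: len(x0)])])
            # two extra free parameters need a larger evaluation budget
            maxfev = self.config.maxfev * (2 if self.config.free_geometry else 1)
            res = optimize.minimize(
                self._negloglik,
                x0,
                method="Nelder-Mead",
                options={
                    "maxfev": maxfev,
                    "xatol": 1e-2,
                    "fatol": 1e-3,
                    "initial_simplex": simplex,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
        res = best
        center, axis, psi, diameter, spacing = self._unpack(res.x)
        if axis[2] < 0:  # sign convention: axis points to non-negative z
            axis = -axis
        return NPCFit(
            center=np.asarray(center, float),
            axis=np.asarray(axis, float),
            in_plane_rotation=float(psi % sym),
            fitted_diameter=float(diameter),
            fitted_spacing=float(spacing),
            loglik=float(-res.fun),
            n_points=len(self.points),
            converged=bool(res.success),
            template=self.template,
            free_geometry=self.config.free_geometry,
        )


def fit_npc_template(points: np.ndarray, template: NPCTemplate | None = None,
                     fit_cfg: NPCFitConfig | None = None) -> NPCFit:
    """Functional wrapper around :class:`NPCTemplateModel`."""
    return NPCTemplateModel(points, template, fit_cfg).fit()


def count_labeled_segments(
    fit: NPCFit, points: np.ndarray, tol: float = 15.0, trace_counts: np.ndarray | None = None
) -> np.ndarray:
    """Assign points to nearest segment anchors; a segment is labeled iff it
    received at least one point within ``tol`` nm.

    Fills ``fit.segment_labeled`` (16 booleans, cytoplasmic ring first),
    ``fit.segment_points`` and, when per-point trace counts are supplied,
    ``fit.segment_traces``.  Returns the boolean flags.
    """
    points = np.atleast_2d(np.asarray(points, float))
    anchors = fit.anchors_world()
    d = cdist(points, anchors)
    nearest = d.argmin(axis=1)
    within = d[np.arange(len(points)), nearest] <= tol
    n_seg = len(anchors)
    labeled = np.zeros(n_seg, bool)
    n_points = np.zeros(n_seg, int)
    n_traces = np.zeros(n_seg, int)
    for i, (seg, ok) in enumerate(zip(nearest, within)):
        if not ok:
            continue
        labeled[seg] = True
        n_points[seg] += 1
        n_traces[seg] += int(trace_counts[i]) if trace_counts is not None else 1
    fit.segment_labeled = labeled
    fit.segment_points = n_points
    fit.segment_traces = n_traces
    return labeled


# ---------------------------------------------------------------------------
# segment-count model


def predicted_segment_distribution(p: float, m: int = 16, s: int = 2, kmin: int = 0) -> np.ndarray:
    """Probability of k labeled segments, k = 0..m, under per-site probability p.

    A segment with s independent sites is labeled with q = 1 - (1-p)^s, so the
    count is Binomial(m, q); with kmin > 0 the law is renormalized to k >= kmin
    (detection truncation).  Entries below kmin are zero; the vector sums to 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0 <= kmin <= m:
        raise ValueError("kmin must be in [0, m]")
    q = 1.0 - (1.0 - p) ** s
    pmf = stats.binom.pmf(np.arange(m + 1), m, q)
    if kmin > 0:
        pmf[:kmin] = 0.0
        tot = pmf.sum()
        if tot <= 0:
            # p == 0 with truncation: no detectable pores; degenerate
            raise ValueError("truncated distribution has no mass (p too small for kmin)")
        pmf = pmf / tot
    return pmf


@dataclass
class LabelingEfficiencyResults:
    """Fitted effective labeling efficiency with uncertainty and diagnostics."""

    p_le: float
    stderr: float
    n_npcs: int
    histogram: np.ndarray
    kmin: int
    m: int
    s: int
    loglik: float
    boundary: bool = False

    def predicted(self) -> np.ndarray:
        return predicted_segment_distribution(self.p_le, self.m, self.s, self.kmin)

    def summary(self) -> str:
        return "\n".join(
            [
                "Effective labeling efficiency (truncated binomial ML)",
                f"  p_LE               {100 * self.p_le:.1f} % +/- {100 * self.stderr:.1f} %",
                f"  pores              {self.n_npcs}",
                f"  segments (m, s)    {self.m} segments, {self.s} sites each",
                f"  truncation kmin    {self.kmin}",
                f"  log-likelihood     {self.loglik:.2f}"
                + ("\n  NOTE: estimate at boundary p = 1" if self.boundary else ""),
            ]
        )

    def plot_cumulative(self, ax=None, ps=(0.3, 0.5, 0.7)):
        """Cumulative observed histogram with predicted curves (display aid)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = np.arange(self.m + 1)
        obs = np.cumsum(self.histogram) / self.histogram.sum()
        ax.step(ks, obs, where="post", color="k", label="observed")
        for p in sorted(set(list(ps) + [round(self.p_le, 3)])):
            pred = np.cumsum(predicted_segment_distribution(p, self.m, self.s, self.kmin))
            style = "--" if abs(p - self.p_le) < 5e-4 else ":"
            ax.plot(ks, pred, style, label=f"p = {p:.3g}")
        ax.set_xlabel("labeled segments k")
        ax.set_ylabel("cumulative fraction")
        ax.legend(fontsize=8)
        return ax


class LabelingEfficiencyModel:
    """Truncated multinomial likelihood for the labeled-segment histogram."""

    def __init__(self, histogram, kmin: int = 1, m: int = 16, s: int = 2):
        histogram = np.asarray(histogram, float).ravel()
        if len(histogram) != m + 1:
            raise ValueError(f"histogram must have {m + 1} bins (k = 0..{m})")
        if histogram.min() < 0:
            raise ValueError("histogram counts must be non-negative")
        if histogram[kmin:].sum() <= 0:
            raise ValueError("no pores at or above kmin; nothing to fit")
        self.histogram = histogram
        self.kmin = int(kmin)
        self.m = int(m)
        self.s = int(s)

    def loglik(self, p: float) -> float:
        pmf = predicted_segment_distribution(p, self.m, self.s, self.kmin)
        ks = slice(self.kmin, None)
        with np.errstate(divide="ignore"):
            lp = np.log(pmf[ks])
        n = self.histogram[ks]
        mask = n > 0
        if np.any(np.isneginf(lp[mask])):
            return -np.inf
        return float((n[mask] * lp[mask]).sum())

    def fit(self) -> LabelingEfficiencyResults:
        n_eff = self.histogram[self.kmin :].sum()
        # boundary: all mass in the top bin
        if self.histogram[self.m] == n_eff:
            return LabelingEfficiencyResults(
                p_le=1.0, stderr=0.0, n_npcs=int(round(self.histogram.sum())),
                histogram=self.histogram, kmin=self.kmin, m=self.m, s=self.s,
                loglik=0.0, boundary=True,
            )
        grid = np.arange(0.001, 1.0, 0.001)
        lls = np.array([self.loglik(p) for p in grid])
        p0 = grid[int(np.argmax(lls))]
        lo, hi = max(1e-6, p0 - 0.002), min(1.0 - 1e-9, p0 + 0.002)
        res = optimize.minimize_scalar(lambda p: -self.loglik(p), bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-9})
        p_hat = float(res.x)
        # curvature of the profile log-likelihood
        h = 1e-4
        if p_hat - h <= 0 or p_hat + h >= 1:
            h = min(p_hat, 1 - p_hat) / 2
        d2 = (self.loglik(p_hat + h) - 2 * self.loglik(p_hat) + self.loglik(p_hat - h)) / h**2
        if d2 < 0:
            stderr = float(1.0 / np.sqrt(-d2))
        else:  # fallback: nonparametric bootstrap over pores
            stderr = self._bootstrap_stderr(p_hat)
        return LabelingEfficiencyResults(
            p_le=p_hat, stderr=stderr, n_npcs=int(round(self.histogram.sum())),
            histogram=self.histogram, kmin=self.kmin, m=self.m, s=self.s,
            loglik=float(-res.fun),
        )

    def _bootstrap_stderr(self, p_hat: float, n_boot: int = 1000, seed: int = 0) -> float:
        rng = child_rng(seed, 99)
        ks = np.repeat(np.arange(self.m + 1), self.histogram.astype(int))
        est = []
        for _ in range(n_boot):
            resample = rng.choice(ks, size=len(ks), replace=True)
            hist = np.bincount(resample, minlength=self.m + 1)
            try:
                est.append(LabelingEfficiencyModel(hist, self.kmin, self.m, self.s).fit().p_le)
            except ValueError:
                continue
        return float(np.std(est)) if est else float("nan")


def estimate_labeling_efficiency(histogram, kmin: int = 1, s: int = 2, m: int = 16) -> LabelingEfficiencyResults:
    """Functional wrapper around :class:`LabelingEfficiencyModel`."""
    return LabelingEfficiencyModel(histogram, kmin=kmin, m=m, s=s).fit()


# ---------------------------------------------------------------------------
# geometry and visit statistics


def estimate_npc_geometry(fits: list[NPCFit], n_boot: int = 1000, seed: int = 0) -> dict:
    """Robust (median) ring spacing and diameter across free-geometry fits,
    with bootstrap standard errors.  Requires >= 2 successful fits."""
    good = [f for f in fits if f.free_geometry and f.converged]
    if not good:
        raise ValueError("no successful free-geometry fits")
    spacing = np.array([f.fitted_spacing for f in good])
    diameter = np.array([f.fitted_diameter for f in good])
    out = {
        "ring_spacing": float(np.median(spacing)),
        "diameter": float(np.median(diameter)),
        "n_npcs": len(good),
    }
    if len(good) < 2:
        out["ring_spacing_se"] = float("nan")
        out["diameter_se"] = float("nan")
        out["single_fit"] = True
        return out
    rng = child_rng(seed, 7)
    meds_s, meds_d = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, len(good), len(good))
        meds_s.append(np.median(spacing[idx]))
        meds_d.append(np.median(diameter[idx]))
    out["ring_spacing_se"] = float(np.std(meds_s))
    out["diameter_se"] = float(np.std(meds_d))
    return out


def site_visit_rate(fits: list[NPCFit], p_le: float | None = None, s: int = 2) -> float:
    """Mean imager visits per tag site, from per-segment trace counts.

    Each labeled segment's trace count is divided by the expected number of
    labeled sites it carries: s when ``p_le`` is omitted (complete labeling),
    otherwise s*p / (1 - (1-p)^s), the mean of a zero-truncated Binomial(s, p).
    """
    counts = []
    for f in fits:
        if f.segment_labeled is None or f.segment_traces is None:
            raise ValueError("segment assignment missing; run count_labeled_segments with trace counts")
        counts.extend(f.segment_traces[f.segment_labeled])
    if not counts:
        raise ValueError("no labeled segments; visit rate undefined")
    denom = float(s)
    if p_le is not None:
        if not 0.0 < p_le <= 1.0:
            raise ValueError("p_le must be in (0, 1]")
        denom = s * p_le / (1.0 - (1.0 - p_le) ** s)
    return float(np.mean(counts) / denom)


# ---------------------------------------------------------------------------
# end-to-end assay


@dataclass
class NPCAssayResult:
    efficiency: LabelingEfficiencyResults
    fits: list = field(default_factory=list)
    geometry: dict | None = None
    visit_rate: float | None = None

    def summary(self) -> str:
        parts = [self.efficiency.summary()]
        if self.geometry is not None:
            parts.append(
                f"  ring spacing (nm)  {self.geometry['ring_spacing']:.1f} +/- {self.geometry['ring_spacing_se']:.1f}"
                f"\n  diameter (nm)      {self.geometry['diameter']:.1f} +/- {self.geometry['diameter_se']:.1f}"
            )
        if self.visit_rate is not None:
            parts.append(f"  visits per site    {self.visit_rate:.2f}")
        return "\n".join(parts)


def run_npc_assay(
    subunits: pd.DataFrame,
    template: NPCTemplate | None = None,
    fit_cfg: NPCFitConfig | None = None,
    group_eps: float = 100.0,
    min_points: int = 5,
    tol: float = 15.0,
    kmin: int = 1,
    estimate_geometry: bool = False,
    groups: list[np.ndarray] | None = None,
) -> NPCAssayResult:
    """Full calibration: detect pores, fit poses, count segments, estimate p_LE."""
    template = template or NPCTemplate()
    fit_cfg = fit_cfg or NPCFitConfig(free_geometry=estimate_geometry)
    if groups is None:
        groups = detect_npc_candidates(subunits, group_eps=group_eps, min_points=min_points)
    pts_all = subunits[["x", "y", "z"]].to_numpy(float)
    traces = subunits["n_traces"].to_numpy(int) if "n_traces" in subunits.columns else None

    fits = []
    m = template.n_segments
    hist = np.zeros(m + 1, float)
    for idx in groups:
        pts = pts_all[idx]
        try:
            fit = NPCTemplateModel(pts, template, fit_cfg).fit()
        except ValueError:
            continue
        tc = traces[idx] if traces is not None else None
        count_labeled_segments(fit, pts, tol=tol, trace_counts=tc)
        hist[fit.n_labeled_segments] += 1
        fits.append(fit)
    if not fits:
        raise ValueError("no pores could be fitted")
    eff = estimate_labeling_efficiency(hist, kmin=kmin, s=2, m=m)
    geometry = estimate_npc_geometry(fits) if estimate_geometry else None
    visit_rate = site_visit_rate(fits, p_le=eff.p_le) if traces is not None else None
    return NPCAssayResult(efficiency=eff, fits=fits, geometry=geometry, visit_rate=visit_rate)
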
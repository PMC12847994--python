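"""Tetramer template fitting and detection-probability algebra.

The four tags of an RyR2 homotetramer sit on the corners of a square: for the
GFP insertion a ~16 nm square rotated 45 degrees to the receptor outline, for
the TagRFP insertion a ~20 nm square aligned with the receptor corners.  When
3 or 4 subunits of one receptor are detected, a least-squares rigid
superposition of the tag square onto the observed points recovers the
receptor's position and 3D orientation; with 3 points the fit also predicts
where the missing fourth corner lies.

Because the corners are unlabeled and coplanar, the orientation is only
identifiable up to the proper symmetry group of the square (order 8: the four
in-plane rotations plus four 180-degree flips); all angular-error metrics here
are symmetry-reduced.

The module also carries the counting algebra that links per-subunit labeling
efficiency p to receptor detection: a receptor is detected iff at least one of
its 4 subunits is labeled, so P(detect) = 1 - (1-p)^4, and the number of
labeled subunits of a detected receptor follows a zero-truncated Binomial(4, p),
which can be inverted to estimate p in situ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._util import kabsch, rotation_angle_deg
from .simulate import TAG_TEMPLATES, tag_corner_offsets


@dataclass(frozen=True)
class TagTemplate:
    """Square of tag sites in the tetramer frame (centroid at origin, z = 0)."""

    tag_kind: str = "GFP16"
    side: float | None = None

    def __post_init__(self):
        if self.tag_kind not in TAG_TEMPLATES:
            raise ValueError(f"unknown tag_kind {self.tag_kind!r}; expected one of {sorted(TAG_TEMPLATES)}")
        if self.side is not None and self.side <= 0:
            raise ValueError("side must be positive")

    @property
    def corners(self) -> np.ndarray:
        return tag_corner_offsets(self.tag_kind, self.side)

    @property
    def offset_angle(self) -> float:
        return TAG_TEMPLATES[self.tag_kind][1]

    def symmetry_rotations(self) -> list[np.ndarray]:
        """Proper rotations mapping the corner set to itself (computed, order 8)."""
        corners = self.corners
        sym = []
        for perm in itertools.permutations(range(4)):
            r, t, rmsd = kabsch(corners[list(perm)], corners)
            if rmsd < 1e-9 and np.linalg.norm(t) < 1e-9 and np.linalg.det(r) > 0:
                if not any(np.allclose(r, s, atol=1e-9) for s in sym):
                    sym.append(r)
        return sym


@dataclass
class TetramerFit:
    """Rigid superposition of the tag square onto 3 or 4 observed points."""

    center: np.ndarray
    rotation: np.ndarray          # proper rotation, template frame -> world
    assignment: tuple[int, ...]   # template corner index for each observed point
    rmsd: float
    n_points: int
    template: TagTemplate
    predicted_fourth: np.ndarray | None = None  # world position of the unseen corner (n = 3)

    @property
    def quaternion(self) -> np.ndarray:
        """Unit quaternion (x, y, z, w) of the fitted rotation."""
        from scipy.spatial.transform import Rotation

        return Rotation.from_matrix(self.rotation).as_quat()

    def summary(self) -> str:
        lines = [
            f"Tetramer fit ({self.template.tag_kind}, {self.n_points} points)",
            f"  center (nm)  ({self.center[0]:.1f}, {self.center[1]:.1f}, {self.center[2]:.1f})",
            f"  rmsd (nm)    {self.rmsd:.2f}",
            f"  assignment   {self.assignment}",
        ]
        if self.predicted_fourth is not None:
            p = self.predicted_fourth
            lines.append(f"  predicted 4th corner (nm)  ({p[0]:.1f}, {p[1]:.1f}, {p[2]:.1f})")
        return "\n".join(lines)


class TetramerModel:
    """Exhaustive-assignment least-squares fit of the tag square to points."""

    def __init__(self, points: np.ndarray, template: TagTemplate | None = None,
                 max_pair_distance: float = 40.0):
        points = np.atleast_2d(np.asarray(points, float))
        if not 3 <= len(points) <= 4:
            raise ValueError(f"need 3 or 4 points, got {len(points)}")
        d = np.linalg.norm(points[:, None] - points[None], axis=-1)
        if d.max() >= max_pair_distance:
            raise ValueError(
                f"points spread over {d.max():.1f} nm, implausible for one tetramer"
            )
        # collinearity gate: largest triangle area over point triples
        area = 0.0
        for i, j, k in itertools.combinations(range(len(points)), 3):
            v1, v2 = points[j] - points[i], points[k] - points[i]
            area = max(area, 0.5 * np.linalg.norm(np.cross(v1, v2)))
        if area < 1.0:
            raise ValueError(f"points are (near-)collinear (max triangle area {area:.2f} nm^2)")
        self.points = points
        self.template = template or TagTemplate()

    def fit(self) -> TetramerFit:
        corners = self.template.corners
        n = len(self.points)
        best = None
        for perm in itertools.permutations(range(4), n):
            r, t, rmsd = kabsch(self.points, corners[list(perm)])
            if best is None or rmsd < best[2]:
                best = (r, t, rmsd, perm)
        r, t, rmsd, perm = best
        center = r @ np.zeros(3) + t  # template centroid is the origin
        predicted = None
        if n == 3:
            missing = (set(range(4)) - set(perm)).pop()
            predicted = r @ corners[missing] + t
        return TetramerFit(
            center=center, rotation=r, assignment=perm, rmsd=rmsd,
            n_points=n, template=self.template, predicted_fourth=predicted,
        )


def fit_tetramer(points: np.ndarray, template: TagTemplate | None = None) -> TetramerFit:
    """Functional wrapper around :class:`TetramerModel`."""
    return TetramerModel(points, template).fit()


def symmetry_reduced_angle(r_est: np.ndarray, r_true: np.ndarray, template: TagTemplate) -> float:
    """Angular error (deg) between rotations, minimized over the square's symmetries."""
    best = 180.0
    for s in template.symmetry_rotations():
        best = min(best, rotation_angle_deg((r_est @ s).T @ r_true))
    return best


# ---------------------------------------------------------------------------
# detection-probability algebra


def detection_probability(p: float, n: int = 4) -> float:
    """Probability that a complex with n independently labeled subunits is seen
    at all: 1 - (1-p)^n."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return 1.0 - (1.0 - p) ** n


def subunit_count_pmf(p: float, n: int = 4) -> np.ndarray:
    """Binomial(n, p) mass function over 0..n labeled subunits."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return stats.binom.pmf(np.arange(n + 1), n, p)


@dataclass
class SubunitCountEstimate:
    p: float
    stderr: float
    n_tetramers: int
    counts: np.ndarray
    boundary: bool = False

    def summary(self) -> str:
        return (
            f"In-situ labeling efficiency from subunit counts\n"
            f"  p            {100 * self.p:.1f} % +/- {100 * self.stderr:.1f} %\n"
            f"  tetramers    {self.n_tetramers}"
            + ("\n  NOTE: estimate at boundary p = 1" if self.boundary else "")
        )


def estimate_ple_from_subunit_counts(counts, n: int = 4) -> SubunitCountEstimate:
    """ML fit of a zero-truncated Binomial(n, p) to observed subunit counts.

    ``counts[k-1]`` is the number of detected tetramers with k labeled
    subunits, k = 1..n (zero-subunit tetramers are invisible).
    """
    counts = np.asarray(counts, float).ravel()
    if len(counts) != n:
        raise ValueError(f"need counts for k = 1..{n}")
    if counts.min() < 0 or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if counts[:-1].sum() == 0:
        return SubunitCountEstimate(p=1.0, stderr=0.0, n_tetramers=int(counts.sum()),
                                    counts=counts, boundary=True)

    ks = np.arange(1, n + 1)

    def loglik(p):
        pmf = stats.binom.pmf(ks, n, p) / (1.0 - (1.0 - p) ** n)
        with np.errstate(divide="ignore"):
            lp = np.log(pmf)
        mask = counts > 0
        if np.any(np.isneginf(lp[mask])):
            return -np.inf
        return float((counts[mask] * lp[mask]).sum())

    res = optimize.minimize_scalar(lambda p: -loglik(p), bounds=(1e-6, 1 - 1e-9),
                                   method="bounded", options={"xatol": 1e-10})
    p_hat = float(res.x)
    h = min(1e-4, p_hat / 2, (1 - p_hat) / 2)
    d2 = (loglik(p_hat + h) - 2 * loglik(p_hat) + loglik(p_hat - h)) / h**2
    stderr = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")
    return SubunitCountEstimate(p=p_hat, stderr=stderr, n_tetramers=int(counts.sum()), counts=counts)


# ---------------------------------------------------------------------------
# experimental candidate proposer


def propose_tetramer_candidates(
    points: np.ndarray, template: TagTemplate | None = None, side_tol: float = 0.3
) -> list[np.ndarray]:
    """Greedy proposer for 4-point tetramer candidates (EXPERIMENTAL).

    Looks for mutual-nearest-neighbour quadruples whose pairwise distances fit
    the template square within ``side_tol`` relative tolerance.  In densely
    stained data candidate assignment is ambiguous; treat the output as
    suggestions to review, not as detections.
    """
    template = template or TagTemplate()
    side = float(np.linalg.norm(template.corners[0] - template.corners[1]))
    diag = side * np.sqrt(2.0)
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 4:
        return []
    d = np.linalg.norm(points[:, None] - points[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    used = np.zeros(len(points), bool)
    out = []
    for i in np.argsort(d.min(axis=1)):
        if used[i]:
            continue
        neigh = np.argsort(d[i])[:3]
        quad = np.array([i, *neigh])
        if used[quad].any():
            continue
        dd = np.sort(d[np.ix_(quad, quad)].ravel())
        dd = dd[np.isfinite(dd)][::2]  # unique pairs (symmetric matrix)
        sides, diags = dd[:4], dd[4:]
        ok_sides = np.all(np.abs(sides - side) <= side_tol * side)
        ok_diags = np.all(np.abs(diags - diag) <= side_tol * diag)
        if ok_sides and ok_diags:
            used[quad] = True
            out.append(quad)
    return out
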
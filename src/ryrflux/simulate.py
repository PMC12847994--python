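"""Seeded generators for synthetic MINFLUX acquisitions of known structures.

Two families of ground truth are produced:

* nuclear pore complex (NPC) fields -- the standard labeling-efficiency
  calibration structure: two parallel 8-fold rings of Nup96 segments, two tag
  sites per segment (32 sites per pore), random 3D pose, Bernoulli labeling at
  ``p_le``, zero-truncated visit counts per detected site, and per-visit
  Gaussian localization error;
* RyR2 tetramer fields -- four tag sites per receptor on the corners of a
  square (16 nm side rotated 45 degrees to the receptor outline for the GFP
  tag, ~20 nm corner-aligned for the TagRFP tag), Bernoulli subunit retention
  at ``p_su``, same visit/noise model.

All coordinates are nm in a right-handed frame with z up.  Every generator is
deterministic given its seed; each localization row carries the trace ID (TID)
of the binding event that produced it, and the ground truth records which tag
site each TID belongs to.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import child_rng, pose_matrix, sample_zt_poisson

LOC_COLUMNS = ["tid", "x", "y", "z"]

TAG_TEMPLATES = {
    # tag kind -> (square side nm, in-plane offset angle vs tetramer outline, deg)
    "GFP16": (16.0, 45.0),
    "RFP20": (20.0, 0.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Per-localization error: isotropic or per-axis Gaussian plus uniform outliers."""

    sigma_xyz: tuple[float, float, float] = (2.0, 2.0, 2.0)
    outlier_fraction: float = 0.0

    def __post_init__(self):
        if len(self.sigma_xyz) != 3 or any(s < 0 for s in self.sigma_xyz):
            raise ValueError(f"sigma_xyz must be three non-negative values, got {self.sigma_xyz}")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError(f"outlier_fraction must be in [0, 1], got {self.outlier_fraction}")


@dataclass(frozen=True)
class VisitModel:
    """Binding-event statistics per detected site.

    ``mean_visits`` is the conditional mean number of imager visits given the
    site was detected at all (so >= 1); the default 1.18 is the regime where a
    site is typically seen once.  ``locs_per_visit`` is the expected number of
    raw localizations recorded per visit (zero-truncated Poisson jitter).
    """

    law: str = "zero-truncated-poisson"
    mean_visits: float = 1.18
    locs_per_visit: float = 1.0

    def __post_init__(self):
        if self.law not in ("zero-truncated-poisson", "fixed"):
            raise ValueError(f"unknown visit law {self.law!r}")
        if self.mean_visits < 1:
            raise ValueError(f"mean_visits must be >= 1, got {self.mean_visits}")
        if self.locs_per_visit < 1:
            raise ValueError(f"locs_per_visit must be >= 1, got {self.locs_per_visit}")

    def sample_visits(self, rng: np.random.Generator, n_sites: int) -> np.ndarray:
        if self.law == "fixed":
            return np.full(n_sites, int(round(self.mean_visits)), dtype=int)
        return sample_zt_poisson(rng, self.mean_visits, n_sites)

    def sample_locs(self, rng: np.random.Generator, n_visits: int) -> np.ndarray:
        return sample_zt_poisson(rng, self.locs_per_visit, n_visits)


@dataclass(frozen=True)
class NPCSimConfig:
    """Field of nuclear pores with random poses on a jittered grid.

    Geometry defaults follow the established Nup96 arrangement: ring diameter
    107 nm, axial ring spacing 50 nm, 8 segments per ring with 2 tag sites per
    segment.  ``site_pair_offset_deg`` sets the angular half-separation of the
    two sites of a segment along the ring (default 6 deg, i.e. ~11 nm apart at
    the default radius).
    """

    n_npcs: int = 150
    ring_diameter: float = 107.0
    ring_spacing: float = 50.0
    n_segments_per_ring: int = 8
    sites_per_segment: int = 2
    twist_deg: float = 0.0
    site_pair_offset_deg: float = 6.0
    p_le: float = 0.6
    max_tilt_deg: float = 30.0
    grid_spacing: float = 400.0
    center_jitter: float = 50.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    visits: VisitModel = field(default_factory=VisitModel)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_le <= 1.0:
            raise ValueError(f"p_le must be in [0, 1], got {self.p_le}")
        if self.ring_diameter <= 0 or self.ring_spacing <= 0:
            raise ValueError("ring_diameter and ring_spacing must be positive")
        if self.n_npcs < 0 or self.n_segments_per_ring < 1 or self.sites_per_segment < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.max_tilt_deg <= 90.0:
            raise ValueError("max_tilt_deg must be in [0, 90]")


@dataclass(frozen=True)
class ClusterLayout:
    """Ground-truth tetramer placement: centers, in-plane angles, plane poses.

    ``plane_poses`` rotate the layout plane (z = 0 template frame) into 3D;
    identity means the layout lies flat.
    """

    centers: np.ndarray          # (N, 3) nm
    angles_deg: np.ndarray       # (N,) in-plane rotation of each tetramer
    tag_kind: str = "RFP20"
    plane_poses: np.ndarray | None = None  # (N, 3, 3) or None = identity

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, float))
        if centers.shape[0] and centers.shape[1] != 3:
            raise ValueError("centers must be (N, 3)")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "angles_deg", np.asarray(self.angles_deg, float).ravel())
        if self.tag_kind not in TAG_TEMPLATES:
            raise ValueError(f"unknown tag_kind {self.tag_kind!r}; expected one of {sorted(TAG_TEMPLATES)}")
        if len(self.angles_deg) != len(self.centers):
            raise ValueError("angles_deg and centers must have the same length")
        if not np.all(np.isfinite(self.centers)) or not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("layout coordinates and angles must be finite")

    def __len__(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
                "angle_deg": self.angles_deg,
                "tag_kind": self.tag_kind,
            }
        )


@dataclass
class GroundTruth:
    """All chemically possible tag sites of a simulated field.

    ``tid_site`` maps each emitted trace ID to the index of the site it came
    from, which lets tests and oracles check conservation exactly.
    """

    sites: np.ndarray            # (M, 3) nm
    labeled: np.ndarray          # (M,) bool
    complex_id: np.ndarray       # (M,) int, owning NPC / tetramer
    poses: np.ndarray            # (K, 3, 3) rotation per complex
    centers: np.ndarray          # (K, 3) complex centers
    visit_counts: np.ndarray     # (M,) int, 0 for unlabeled sites
    tid_site: pd.Series          # index tid -> site index

    @property
    def n_labeled(self) -> int:
        return int(self.labeled.sum())

    def labeled_segment_counts(self, n_segments: int, sites_per_segment: int) -> np.ndarray:
        """Per-complex number of segments with >= 1 labeled site (NPC fields)."""
        counts = []
        per_complex = n_segments * sites_per_segment
        for k in np.unique(self.complex_id):
            lab = self.labeled[self.complex_id == k]
            seg = lab.reshape(n_segments, sites_per_segment).any(axis=1)
            if len(lab) != per_complex:
                raise ValueError("complex does not have the expected site count")
            counts.append(int(seg.sum()))
        return np.asarray(counts, int)


def npc_template_sites(config: NPCSimConfig) -> np.ndarray:
    """Canonical (axis = +z, center at origin) tag-site positions, (S, 3).

    Ordering: ring-major (cytoplasmic ring first), then segment, then the
    sites of the segment -- so sites ``2*j`` and ``2*j + 1`` belong to segment
    ``j`` under the defaults.
    """
    r = config.ring_diameter / 2.0
    seg_angles = np.arange(config.n_segments_per_ring) * (360.0 / config.n_segments_per_ring)
    if config.sites_per_segment == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-config.site_pair_offset_deg, config.site_pair_offset_deg, config.sites_per_segment)
    sites = []
    for ring_sign, ring_twist in ((+1.0, 0.0), (-1.0, config.twist_deg)):
        z = ring_sign * config.ring_spacing / 2.0
        for a in seg_angles:
            for off in offsets:
                ang = np.deg2rad(a + ring_twist + off)
                sites.append([r * np.cos(ang), r * np.sin(ang), z])
    return np.asarray(sites)


def _expand_sites_to_localizations(
    sites: np.ndarray,
    labeled: np.ndarray,
    noise: NoiseModel,
    visits: VisitModel,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Bernoulli-labeled sites -> visit traces -> noisy localizations."""
    labeled_idx = np.flatnonzero(labeled)
    visit_counts = np.zeros(len(sites), dtype=int)
    if len(labeled_idx) == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS}).astype({"tid": int})
        return empty, visit_counts, pd.Series(dtype=int)

    n_visits = visits.sample_visits(rng, len(labeled_idx))
    visit_counts[labeled_idx] = n_visits
    site_of_visit = np.repeat(labeled_idx, n_visits)
    tids = np.arange(len(site_of_visit))
    n_locs = visits.sample_locs(rng, len(tids))

    site_of_loc = np.repeat(site_of_visit, n_locs)
    tid_of_loc = np.repeat(tids, n_locs)
    pos = sites[site_of_loc]
    sigma = np.asarray(noise.sigma_xyz)
    pos = pos + rng.standard_normal(pos.shape) * sigma
    if noise.outlier_fraction > 0:
        is_out = rng.random(len(pos)) < noise.outlier_fraction
        if is_out.any():
            lo = sites.min(axis=0) - 100.0
            hi = sites.max(axis=0) + 100.0
            pos[is_out] = rng.uniform(lo, hi, size=(int(is_out.sum()), 3))

    table = pd.DataFrame({"tid": tid_of_loc, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]})
    tid_site = pd.Series(site_of_visit, index=pd.Index(tids, name="tid"), name="site")
    return table, visit_counts, tid_site


def make_npc_ensemble(config: NPCSimConfig) -> tuple[GroundTruth, pd.DataFrame]:
    """Simulate a field of NPCs and the localization table of its acquisition.

    Pores sit on a jittered square grid (spacing ``grid_spacing``) so that
    neighbouring pores remain separable; each pore's pose has azimuth and spin
    uniform on [0, 360) and tilt uniform on [0, max_tilt_deg].
    """
    rng = child_rng(config.seed, 0)
    n = config.n_npcs
    template = npc_template_sites(config)

    ncols = max(1, int(np.ceil(np.sqrt(n))))
    ij = np.array([(i // ncols, i % ncols) for i in range(n)], dtype=float).reshape(n, 2)
    centers = np.zeros((n, 3))
    if n:
        centers[:, :2] = ij * config.grid_spacing
        centers += rng.uniform(-config.center_jitter, config.center_jitter, size=(n, 3))

    poses = np.empty((n, 3, 3))
    all_sites, complex_id = [], []
    for k in range(n):
        azim = rng.uniform(0.0, 360.0)
        tilt = rng.uniform(0.0, config.max_tilt_deg)
        spin = rng.uniform(0.0, 360.0)
        poses[k] = pose_matrix(azim, tilt, spin)
        world = template @ poses[k].T + centers[k]
        all_sites.append(world)
        complex_id.append(np.full(len(template), k))
    sites = np.concatenate(all_sites) if n else np.zeros((0, 3))
    complex_id = np.concatenate(complex_id) if n else np.zeros(0, int)

    labeled = rng.random(len(sites)) < config.p_le
    table, visit_counts, tid_site = _expand_sites_to_localizations(
        sites, labeled, config.noise, config.visits, rng
    )
    gt = GroundTruth(
        sites=sites,
        labeled=labeled,
        complex_id=complex_id,
        poses=poses,
        centers=centers,
        visit_counts=visit_counts,
        tid_site=tid_site,
    )
    return gt, table


def make_lattice_layout(
    n_rows: int,
    n_cols: int,
    pitch: float = 30.0,
    occupancy: float = 1.0,
    tag_kind: str = "RFP20",
    seed: int = 0,
) -> ClusterLayout:
    """Checkerboard layout of tetramers, each retained with probability ``occupancy``.

    The default 30 nm pitch is a realistic close packing given the ~27 nm
    square footprint of the receptor.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice must have at least one row and one column")
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    if not 0.0 < occupancy <= 1.0:
        raise ValueError(f"occupancy must be in (0, 1], got {occupancy}")
    rng = child_rng(seed, 1)
    ii, jj = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    centers = np.column_stack([jj.ravel() * pitch, ii.ravel() * pitch, np.zeros(n_rows * n_cols)])
    keep = rng.random(len(centers)) < occupancy
    centers = centers[keep]
    return ClusterLayout(centers=centers, angles_deg=np.zeros(len(centers)), tag_kind=tag_kind)


def tag_corner_offsets(tag_kind: str, side: float | None = None) -> np.ndarray:
    """Corner offsets (4, 3) of the tag square in the tetramer frame.

    GFP16: 16 nm side rotated 45 degrees to the tetramer outline; RFP20: 20 nm
    side aligned with the tetramer corners.
    """
    if tag_kind not in TAG_TEMPLATES:
        raise ValueError(f"unknown tag_kind {tag_kind!r}; expected one of {sorted(TAG_TEMPLATES)}")
    default_side, offset = TAG_TEMPLATES[tag_kind]
    s = default_side if side is None else float(side)
    base = np.array([[s / 2, s / 2, 0.0], [-s / 2, s / 2, 0.0], [-s / 2, -s / 2, 0.0], [s / 2, -s / 2, 0.0]])
    from ._util import rot_z

    return base @ rot_z(offset).T


def expand_layout_to_tag_sites(layout: ClusterLayout) -> pd.DataFrame:
    """All chemically possible tag positions of a layout: 4 rows per tetramer."""
    from ._util import rot_z

    corners = tag_corner_offsets(layout.tag_kind)
    rows = []
    for k in range(len(layout)):
        r = rot_z(layout.angles_deg[k])
        if layout.plane_poses is not None:
            r = layout.plane_poses[k] @ r
        world = corners @ r.T + layout.centers[k]
        for c in world:
            rows.append((c[0], c[1], c[2], k))
    df = pd.DataFrame(rows, columns=["x", "y", "z", "complex_id"])
    df["complex_id"] = df["complex_id"].astype(int) if len(df) else pd.Series(dtype=int)
    return df


def make_tetramer_field(
    layout: ClusterLayout,
    p_su: float,
    noise: NoiseModel | None = None,
    visits: VisitModel | None = None,
    seed: int = 0,
) -> tuple[GroundTruth, pd.DataFrame]:
    """Simulate a MINFLUX acquisition of a tetramer layout with partial labeling."""
    if len(layout) == 0:
        raise ValueError("layout is empty")
    if not 0.0 <= p_su <= 1.0:
        raise ValueError(f"p_su must be in [0, 1], got {p_su}")
    noise = noise or NoiseModel(sigma_xyz=(3.0, 3.0, 3.0))
    visits = visits or VisitModel()
    rng = child_rng(seed, 2)

    site_df = expand_layout_to_tag_sites(layout)
    sites = site_df[["x", "y", "z"]].to_numpy()
    complex_id = site_df["complex_id"].to_numpy()
    labeled = rng.random(len(sites)) < p_su
    table, visit_counts, tid_site = _expand_sites_to_localizations(sites, labeled, noise, visits, rng)

    n = len(layout)
    poses = np.repeat(np.eye(3)[None], n, axis=0) if layout.plane_poses is None else layout.plane_poses
    gt = GroundTruth(
        sites=sites,
        labeled=labeled,
        complex_id=complex_id,
        poses=poses,
        centers=layout.centers,
        visit_counts=visit_counts,
        tid_site=tid_site,
    )
    return gt, table


def write_ground_truth(gt: GroundTruth, prefix: str) -> None:
    """Sidecar CSV (sites) + JSON (summary) pair for a generated field."""
    df = pd.DataFrame(
        {
            "x": gt.sites[:, 0],
            "y": gt.sites[:, 1],
            "z": gt.sites[:, 2],
            "labeled": gt.labeled.astype(int),
            "complex_id": gt.complex_id,
            "visits": gt.visit_counts,
        }
    )
    df.to_csv(f"{prefix}_sites.csv", index=False)
    meta = {
        "units": "nm",
        "n_sites": int(len(gt.sites)),
        "n_labeled": gt.n_labeled,
        "n_complexes": int(len(gt.centers)),
    }
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def config_from_json(path: str) -> NPCSimConfig:
    with open(path) as fh:
        raw = json.load(fh)
    noise = NoiseModel(**raw.pop("noise", {}))
    visits = VisitModel(**raw.pop("visits", {}))
    known = {f.name for f in dataclasses.fields(NPCSimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return NPCSimConfig(noise=noise, visits=visits, **raw)
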
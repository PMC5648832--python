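"""Specimen surface reconstruction, scan planning and margin mapping.

The scanner photographs the mounted specimen at many rotation angles,
carves the visual hull of the binary silhouettes on a voxel grid, and
extracts a watertight triangulated surface. Measurement points are then
laid out the way the two-motor kinematics traverse the surface: bands
along the rotation axis at ~one step of geodesic (meridian) spacing,
points around each band at ~one step of arc spacing, rotation-major
order. Per-point margin labels are finally co-registered back onto the
mesh and scored against ground-truth spot positions.

Coordinate conventions: right-handed, millimetres, rotation axis = x,
mounting pole at -x. The camera is orthographic with known scale,
looking along -z; rotating the specimen by theta about +x maps a point
p to Rx(theta) p, and the silhouette records its (x, y) projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

SurfaceMesh = trimesh.Trimesh

LABEL_COLORS = {
    "fatty": (0, 170, 0),
    "clean": (0, 170, 0),
    "fibroadenomatoid": (0, 0, 200),
    "paraffin_positive": (0, 0, 200),
}
POSITIVE_LABELS = ("fibroadenomatoid", "paraffin_positive")


# ---------------------------------------------------------------------------
# Silhouettes and visual hull
# ---------------------------------------------------------------------------

@dataclass
class SilhouetteSet:
    """Binary orthographic silhouettes at known rotation angles.

    ``images`` is (n_views, n_rows, n_cols) boolean; pixel (row, col)
    maps to camera coordinates (y', x) via ``scale`` (mm/pixel) and
    ``origin`` (row, col of the world origin's projection).
    """

    images: np.ndarray
    angles_deg: np.ndarray
    scale: float
    origin: tuple

    def __post_init__(self):
        self.images = np.asarray(self.images, bool)
        self.angles_deg = np.asarray(self.angles_deg, float)
        if self.images.ndim != 3 or self.images.shape[0] != self.angles_deg.size:
            raise ValueError("need one angle per silhouette image")
        if self.images.shape[0] < 2:
            raise ValueError("need >= 2 views")
        if np.any((self.angles_deg < 0) | (self.angles_deg >= 360)):
            raise ValueError("angles must lie in [0, 360)")
        if self.scale <= 0:
            raise ValueError("scale must be > 0 mm/pixel")
        if not self.images.any(axis=(1, 2)).all():
            raise ValueError("every silhouette mask must be non-empty")


def reconstruct_visual_hull(silhouettes: SilhouetteSet,
                            voxel_size: float = 0.25) -> SurfaceMesh:
    """Carve the visual hull and extract a watertight surface mesh.

    A voxel survives iff its center back-projects inside every
    silhouette; the surviving occupancy is meshed by marching cubes. The
    hull over-approximates the true object (it is the maximal shape
    consistent with the silhouettes), so no true surface point is carved
    away beyond discretisation.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    masks = silhouettes.images
    scale = silhouettes.scale
    r0, c0 = silhouettes.origin
    n_rows, n_cols = masks.shape[1:]

    # world-space bounds from the silhouette extents
    cols_any = masks.any(axis=(0, 1))
    rows_any = masks.any(axis=(0, 2))
    cmin, cmax = np.flatnonzero(cols_any)[[0, -1]]
    rmin, rmax = np.flatnonzero(rows_any)[[0, -1]]
    xmin = (cmin - c0 - 1) * scale
    xmax = (cmax - c0 + 1) * scale
    rad = (max(abs(rmin - r0), abs(rmax - r0)) + 1) * scale

    xs = np.arange(xmin, xmax + voxel_size, voxel_size)
    ys = np.arange(-rad, rad + voxel_size, voxel_size)
    zs = ys.copy()
    occ = np.ones((xs.size, ys.size, zs.size), dtype=bool)

    ucol = np.round(xs / scale + c0).astype(np.intp)
    np.clip(ucol, 0, n_cols - 1, out=ucol)
    Y, Z = np.meshgrid(ys, zs, indexing="ij")
    for mask, ang in zip(masks, silhouettes.angles_deg):
        th = np.deg2rad(ang)
        yp = np.cos(th) * Y - np.sin(th) * Z
        vrow = np.round(yp / scale + r0).astype(np.intp)
        inb = (vrow >= 0) & (vrow < n_rows)
        np.clip(vrow, 0, n_rows - 1, out=vrow)
        # (nx, ny, nz) gather: row index per (y, z), column index per x
        occ &= mask[vrow[None, :, :], ucol[:, None, None]]
        occ &= inb[None, :, :]
    if not occ.any():
        raise ValueError("silhouettes are inconsistent: empty visual hull")

    vol = np.pad(occ, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(vol, level=0.5,
                                        spacing=(voxel_size,) * 3)
    verts += np.array([xmin, -rad, -rad]) - voxel_size  # undo padding offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
    if not mesh.is_watertight:
        raise ValueError("marching-cubes surface is not watertight")
    return mesh


# ---------------------------------------------------------------------------
# Scan planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MountingDisc:
    """The pinning disc at the -x pole where the probe cannot reach."""

    center: tuple
    diameter: float = 7.0


@dataclass
class ScanPlan:
    """Ordered measurement points on the mesh (rotation-major traversal)."""

    points: np.ndarray
    normals: np.ndarray
    step: float
    band_index: np.ndarray
    angles: np.ndarray
    excluded_region: MountingDisc | None = None
    manual_point_required: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.points)


def _slice_loop(mesh: SurfaceMesh, x0: float):
    """Ordered closed polyline of the mesh section at plane x = x0.

    Each returned vertex lies exactly on a mesh face. Ordering is by
    azimuth about the rotation axis, valid for sections star-shaped
    about the axis (convex-ish specimens and their visual hulls).
    """
    tri = mesh.triangles  # (n_faces, 3, 3)
    vx = tri[:, :, 0]
    cross = (vx.min(axis=1) <= x0) & (vx.max(axis=1) >= x0)
    cand = tri[cross]
    if cand.size == 0:
        return None
    pts = []
    # intersect each candidate triangle's edges with the plane
    for a, b in ((0, 1), (1, 2), (2, 0)):
        pa, pb = cand[:, a, :], cand[:, b, :]
        da, db = pa[:, 0] - x0, pb[:, 0] - x0
        hit = (da * db) <= 0
        denom = da - db
        ok = hit & (np.abs(denom) > 1e-12)
        t = da[ok] / denom[ok]
        pts.append(pa[ok] + t[:, None] * (pb[ok] - pa[ok]))
    pts = np.vstack(pts)
    if len(pts) < 3:
        return None
    phi = np.arctan2(pts[:, 2], pts[:, 1])
    order = np.argsort(phi)
    loop = pts[order]
    # drop near-duplicate consecutive vertices
    keep = np.ones(len(loop), bool)
    d = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    keep[1:] = d > 1e-9
    loop = loop[keep]
    return loop if len(loop) >= 3 else None


def _radius_profile(mesh: SurfaceMesh, n_bins: int = 200):
    """Mean surface radius about the x axis as a function of x."""
    v = mesh.vertices
    x = v[:, 0]
    r = np.hypot(v[:, 1], v[:, 2])
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=r, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    good = cnts > 0
    rad = np.interp(centers, centers[good], sums[good] / cnts[good])
    return centers, rad


def plan_points(mesh: SurfaceMesh, step: float,
                excluded_region: MountingDisc | None = None,
                x_range: tuple | None = None) -> ScanPlan:
    """Lay out measurement points at ~``step`` spacing over the surface.

    Bands are placed along the rotation axis at equal meridian arc
    spacing; within each band, points are spaced equally along the
    section perimeter. Nearest-neighbour spacing stays within
    [0.5*step, 1.5*step]. Points falling inside the mounting disc are
    removed and flagged (``manual_point_required``). ``x_range``
    restricts planning to an axial interval (band-restricted scans).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    ext = mesh.bounds[1] - mesh.bounds[0]
    # a step up to the full circumference still yields a single band with
    # a handful of points; beyond that nothing is placeable
    if step > 2.0 * np.pi * ext.max():
        raise ValueError("step too large to place any measurement point")
    xc, rad = _radius_profile(mesh)
    drdx = np.gradient(rad, xc)

    lo = mesh.bounds[0][0] if x_range is None else max(x_range[0], mesh.bounds[0][0])
    hi = mesh.bounds[1][0] if x_range is None else min(x_range[1], mesh.bounds[1][0])
    if hi <= lo:
        raise ValueError("empty x_range")
    sel = (xc >= lo) & (xc <= hi)
    xs_f = xc[sel]
    if xs_f.size < 2:
        xs_f = np.linspace(lo, hi, 8)
    rs_f = np.interp(xs_f, xc, rad)
    ds = np.hypot(np.diff(xs_f), np.diff(rs_f))
    s_cum = np.concatenate([[0.0], np.cumsum(ds)])
    total_arc = s_cum[-1]
    n_bands = max(1, int(round(total_arc / step)))
    s_targets = (np.arange(n_bands) + 0.5) * total_arc / n_bands
    band_x = np.interp(s_targets, s_cum, xs_f)

    eps = max(1e-6, 0.02 * step)
    band_x = np.clip(band_x, mesh.bounds[0][0] + eps, mesh.bounds[1][0] - eps)

    all_pts, all_nrm, all_band, all_ang = [], [], [], []
    for bi, x0 in enumerate(band_x):
        loop = _slice_loop(mesh, x0)
        if loop is None:
            continue
        seg = np.diff(np.vstack([loop, loop[:1]]), axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        C = float(seglen.sum())
        m = max(1, int(round(C / step)))
        t_targets = (np.arange(m) + 0.5) * C / m
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        si = np.searchsorted(cum, t_targets, side="right") - 1
        si = np.clip(si, 0, len(seglen) - 1)
        frac = (t_targets - cum[si]) / np.maximum(seglen[si], 1e-12)
        ring = np.vstack([loop, loop[:1]])
        pts = ring[si] + frac[:, None] * seg[si]
        ang = np.arctan2(pts[:, 2], pts[:, 1])
        order = np.argsort(ang)
        pts = pts[order]
        ang = ang[order]
        slope = float(np.interp(x0, xc, drdx))
        nrm = np.column_stack([
            np.full(len(pts), -slope),
            np.cos(ang),
            np.sin(ang),
        ])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        all_pts.append(pts)
        all_nrm.append(nrm)
        all_band.append(np.full(len(pts), bi))
        all_ang.append(ang)
    if not all_pts:
        raise ValueError("no scan points could be placed")
    points = np.vstack(all_pts)
    normals = np.vstack(all_nrm)
    band_index = np.concatenate(all_band)
    angles = np.concatenate(all_ang)

    if excluded_region is None:
        pole = mesh.vertices[np.argmin(mesh.vertices[:, 0])]
        excluded_region = MountingDisc(tuple(pole), 7.0)
    center = np.asarray(excluded_region.center)
    radius = excluded_region.diameter / 2.0
    dist = np.linalg.norm(points - center, axis=1)
    keep = dist > radius
    # the disc hides surface from the scanner whenever it sits on the mesh,
    # whether or not a planned point happened to fall inside it
    vdist = np.linalg.norm(mesh.vertices - center, axis=1)
    manual = bool(np.any(~keep) or (vdist < radius).any())
    return ScanPlan(points[keep], normals[keep], step, band_index[keep],
                    angles[keep], excluded_region, manual,
                    meta={"x_range": x_range, "n_bands": int(n_bands)})


# ---------------------------------------------------------------------------
# Co-registration and localisation scoring
# ---------------------------------------------------------------------------

@dataclass
class MarginMap:
    """Per-point margin labels co-registered onto the surface mesh."""

    mesh: SurfaceMesh
    plan: ScanPlan
    labels: list
    fractions: list              # per-point component-fraction dicts
    face_point_index: np.ndarray  # nearest planned point per mesh face
    vertex_colors: np.ndarray
    orientation: str = "unspecified"


def coregister(plan: ScanPlan, labels, mesh: SurfaceMesh,
               fractions=None, orientation: str = "unspecified") -> MarginMap:
    """Attribute every mesh face (and vertex colour) to its nearest
    planned point's label: green for fatty/clean, blue for
    fibroadenomatoid/paraffin-positive."""
    labels = list(labels)
    if len(labels) != len(plan):
        raise ValueError("one label per planned point required")
    if fractions is None:
        fractions = [{} for _ in labels]
    tree = cKDTree(plan.points)
    _, face_idx = tree.query(mesh.triangles_center)
    _, vert_idx = tree.query(mesh.vertices)
    lab_strings = [l.label if hasattr(l, "label") else str(l) for l in labels]
    colors = np.array([LABEL_COLORS[lab_strings[i]] for i in vert_idx], dtype=np.uint8)
    return MarginMap(mesh, plan, lab_strings, list(fractions), face_idx,
                     colors, orientation)


@dataclass(frozen=True)
class LocalisationResult:
    """Spot-localisation accuracy vs ground truth."""

    n_true: int
    n_detected: int
    predicted_centers: np.ndarray
    matched_true_centers: np.ndarray
    pair_errors: np.ndarray      # per spot pair |predicted - true| distance, mm
    max_abs_error: float
    r_squared: float
    detection_failure: bool


def _project_to_mesh(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Closest surface point for each query, searched over the faces
    adjacent to the nearest vertex (adequate for near-surface queries)."""
    points = np.atleast_2d(points)
    tree = cKDTree(mesh.vertices)
    _, vidx = tree.query(points)
    out = np.empty_like(points)
    for i, (p, vi) in enumerate(zip(points, vidx)):
        faces = mesh.vertex_faces[vi]
        faces = faces[faces >= 0]
        tris = mesh.triangles[faces]
        cand = trimesh.triangles.closest_point(tris, np.tile(p, (len(tris), 1)))
        d = np.linalg.norm(cand - p, axis=1)
        out[i] = cand[np.argmin(d)]
    return out


def _cluster_positive(points: np.ndarray, weights: np.ndarray, cutoff: float):
    """Single-linkage clusters of positive points within ``cutoff``."""
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    data = np.ones(len(pairs))
    adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)
    centers = []
    totals = []
    for c in range(n_comp):
        sel = comp == c
        w = weights[sel]
        centers.append(np.average(points[sel], axis=0, weights=w))
        totals.append(w.sum())
    return np.array(centers), np.array(totals)


def evaluate_localisation(margin_map: MarginMap,
                          true_spot_centers) -> LocalisationResult:
    """Compare predicted spot positions with ground truth.

    Predicted spot centers are the fraction-weighted centroids of the
    single-linkage clusters of positive points, projected back onto the
    mesh surface. Clusters are matched to true centers by minimum-cost
    assignment; the score compares all pairwise 3-D Euclidean inter-spot
    distances (predicted vs true) by per-pair absolute error, the
    maximum error, and the coefficient of determination.
    """
    true_centers = np.atleast_2d(np.asarray(true_spot_centers, float))
    if len(true_centers) < 2:
        raise ValueError("need >= 2 true spots for pairwise distances")
    pos = np.array([l in POSITIVE_LABELS for l in margin_map.labels])
    if not pos.any():
        return LocalisationResult(len(true_centers), 0, np.empty((0, 3)),
                                  true_centers, np.array([]), float("nan"),
                                  float("nan"), True)
    pts = margin_map.plan.points[pos]
    w = np.array([
        max(f.get("paraffin", f.get("fibroadenomatoid", 1.0)), 1e-12)
        for f, p in zip(margin_map.fractions, pos) if p
    ])
    centers, totals = _cluster_positive(pts, w, cutoff=2.5 * margin_map.plan.step)
    n_det = len(centers)
    if n_det < len(true_centers):
        return LocalisationResult(len(true_centers), n_det, centers,
                                  true_centers, np.array([]), float("nan"),
                                  float("nan"), True)
    if n_det > len(true_centers):
        keep = np.argsort(totals)[::-1][: len(true_centers)]
        centers = centers[keep]
    # snap centroids back to the surface
    centers = _project_to_mesh(margin_map.mesh, centers)
    cost = np.linalg.norm(centers[:, None, :] - true_centers[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    pred = centers[ri[np.argsort(ci)]]
    iu = np.triu_indices(len(true_centers), k=1)
    d_pred = np.linalg.norm(pred[iu[0]] - pred[iu[1]], axis=1)
    d_true = np.linalg.norm(true_centers[iu[0]] - true_centers[iu[1]], axis=1)
    errors = np.abs(d_pred - d_true)
    ss_res = float(np.sum((d_pred - d_true) ** 2))
    ss_tot = float(np.sum((d_true - d_true.mean()) ** 2))
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return LocalisationResult(len(true_centers), n_det, pred, true_centers,
                              errors, float(errors.max()), rsq, False)


__all__ = [
    "SilhouetteSet", "SurfaceMesh", "ScanPlan", "MountingDisc", "MarginMap",
    "LocalisationResult", "reconstruct_visual_hull", "plan_points",
    "coregister", "evaluate_localisation", "LABEL_COLORS", "POSITIVE_LABELS",
]
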
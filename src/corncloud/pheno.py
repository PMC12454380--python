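"""Scene alignment, metric scaling, and per-plant trait extraction.

Pipeline: detect the ground (soil) plane by RANSAC, rotate the scene so the
plane normal maps onto +z (Rodrigues rotation), convert scene units to
centimetres with a reference-object scale factor k = L_real / L_virtual
(the 25 cm tray side by default), then measure per plant:

* height         — z_max − z_min of the plant's points, × k
* canopy width   — diagonal √(L² + W²) of the horizontal AABB extents, × k
* volume         — occupied 0.1 cm voxels × voxel volume
* surface area   — ball-pivoting mesh at 0.2 cm radius, triangle areas by
                   Heron's formula
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cloudio import LabeledCloud

log = logging.getLogger(__name__)

__all__ = [
    "PhenotypeRecord", "AlignmentTransform", "PlaneDetectionError",
    "rodrigues_matrix", "detect_ground_plane", "align_to_z", "compute_scale",
    "plant_height", "canopy_width", "voxel_volume", "heron_area",
    "bpa_surface_area", "phenotype_scene",
]


class PlaneDetectionError(RuntimeError):
    """RANSAC failed to find a plane with enough inlier support."""


@dataclass
class PhenotypeRecord:
    """Per-plant traits in cm-based units."""

    plant_id: int
    height_cm: float
    canopy_cm: float
    volume_cm3: float
    area_cm2: float
    point_count: int


@dataclass
class AlignmentTransform:
    """Rotation + scale mapping a reconstructed scene into an upright cm frame."""

    rotation: np.ndarray                    # (3, 3) orthonormal, det +1
    plane_normal_detected: np.ndarray       # unit vector, pre-rotation
    theta: float                            # radians
    scale_k: float = 1.0                    # cm per scene unit
    reference_length_real: float = 25.0     # cm


def rodrigues_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix about the unit ``axis`` by ``theta`` radians.

    R = I cosθ + (1 − cosθ) aaᵀ + sinθ [a]ₓ — the standard Rodrigues form.
    """
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise ValueError("rotation axis must be nonzero")
    a = a / n
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * np.cos(theta) + (1 - np.cos(theta)) * np.outer(a, a) \
        + np.sin(theta) * k


def _fit_plane_lsq(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through points: returns (unit normal, offset d) with n·x = d."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    n = vt[-1]
    return n, float(n @ c)


def detect_ground_plane(
    cloud: LabeledCloud | np.ndarray,
    inlier_threshold: float | None = None,
    n_iterations: int = 1000,
    min_inlier_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """RANSAC ground-plane detection.

    Returns ``(normal, offset, inlier_mask)`` with the plane n·x = d, the
    normal oriented so that the majority of *non-inlier* points (the plants)
    lie on its positive side. ``inlier_threshold`` defaults to 1% of the
    cloud's bounding-box diagonal. Raises :class:`PlaneDetectionError` when no
    plane reaches ``min_inlier_fraction`` support.
    """
    pts = cloud.points if isinstance(cloud, LabeledCloud) else np.asarray(cloud, float)
    n_pts = pts.shape[0]
    if n_pts < 3:
        raise PlaneDetectionError("need at least 3 points")
    if inlier_threshold is None:
        diag = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        inlier_threshold = max(0.01 * diag, 1e-12)
    rng = np.random.default_rng(seed)
    best_mask, best_count = None, -1
    for _ in range(n_iterations):
        idx = rng.choice(n_pts, 3, replace=False)
        p0, p1, p2 = pts[idx]
        nrm = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(nrm)
        if norm < 1e-12:
            continue
        nrm = nrm / norm
        dist = np.abs((pts - p0) @ nrm)
        mask = dist <= inlier_threshold
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
    if best_mask is None or best_count < min_inlier_fraction * n_pts:
        raise PlaneDetectionError(
            f"best plane supports {max(best_count, 0)}/{n_pts} points "
            f"(< {min_inlier_fraction:.0%})"
        )
    # least-squares refit on the consensus set, then one re-selection pass
    normal, d = _fit_plane_lsq(pts[best_mask])
    dist = np.abs(pts @ normal - d)
    mask = dist <= inlier_threshold
    normal, d = _fit_plane_lsq(pts[mask])
    signed = pts[~mask] @ normal - d
    if signed.size and np.median(signed) < 0:
        normal, d = -normal, -d
    return normal, d, mask


def align_to_z(
    cloud: LabeledCloud, plane_normal: np.ndarray,
    reference_length_real: float = 25.0,
) -> tuple[LabeledCloud, AlignmentTransform]:
    """Rotate the scene so the detected ground normal maps onto +z.

    The rotation axis is m × n (m = detected normal, n = ẑ) and the angle
    θ = cos⁻¹(m·n / (|m||n|)); antiparallel normals rotate 180° about x.
    """
    m = np.asarray(plane_normal, dtype=float)
    m = m / np.linalg.norm(m)
    z = np.array([0.0, 0.0, 1.0])
    cosang = float(np.clip(m @ z, -1.0, 1.0))
    theta = float(np.arccos(cosang))
    axis = np.cross(m, z)
    if np.linalg.norm(axis) < 1e-12:
        rot = np.eye(3) if cosang > 0 else rodrigues_matrix([1.0, 0.0, 0.0], np.pi)
    else:
        rot = rodrigues_matrix(axis, theta)
    out = cloud.replace(points=cloud.points @ rot.T, normals=cloud.normals @ rot.T)
    return out, AlignmentTransform(
        rotation=rot, plane_normal_detected=m, theta=theta,
        reference_length_real=reference_length_real,
    )


def compute_scale(cloud_reference_extent: float, reference_length_real: float = 25.0) -> float:
    """Scale factor k = L_real / L_virtual (cm per scene unit)."""
    if cloud_reference_extent <= 0 or reference_length_real <= 0:
        raise ValueError("reference lengths must be positive")
    return reference_length_real / cloud_reference_extent


def plant_height(points: np.ndarray, k: float = 1.0) -> float:
    """H = (z_max − z_min) × k on an aligned plant cloud."""
    points = np.asarray(points, float)
    if points.size == 0:
        raise ValueError("empty plant cloud")
    return float((points[:, 2].max() - points[:, 2].min()) * k)


def canopy_width(points: np.ndarray, k: float = 1.0) -> float:
    """Horizontal AABB diagonal √(L² + W²) × k on an aligned plant cloud."""
    points = np.asarray(points, float)
    if points.size == 0:
        raise ValueError("empty plant cloud")
    ext = points[:, :2].max(axis=0) - points[:, :2].min(axis=0)
    return float(np.hypot(ext[0], ext[1]) * k)


def voxel_volume(points: np.ndarray, k: float = 1.0, voxel_side_cm: float = 0.1) -> float:
    """Occupied-voxel volume: AABB-anchored cubic grid, count × side³.

    Points are scaled to cm by ``k`` first; a voxel is occupied iff it holds
    at least one point.
    """
    points = np.asarray(points, float)
    if points.size == 0:
        warnings.warn("voxel_volume on empty cloud -> 0", stacklevel=2)
        return 0.0
    pts = points * k
    idx = np.floor((pts - pts.min(axis=0)) / voxel_side_cm).astype(np.int64)
    occupied = np.unique(idx, axis=0).shape[0]
    return float(occupied * voxel_side_cm**3)


def heron_area(a: float, b: float, c: float) -> float:
    """Triangle area from side lengths via Heron's formula."""
    s = (a + b + c) / 2.0
    val = s * (s - a) * (s - b) * (s - c)
    return float(np.sqrt(max(val, 0.0)))


def bpa_surface_area(
    points: np.ndarray, k: float = 1.0, ball_radius_cm: float = 0.2,
):
    """Ball-pivoting surface reconstruction and Heron-summed mesh area.

    Returns ``(area_cm2, mesh)`` where mesh is a ``trimesh.Trimesh`` over the
    cm-scaled points. Degenerate inputs (fewer than 3 points, or no
    reconstructable triangle) give area 0 and an empty mesh with a warning.
    """
    import trimesh

    from ._bpa import ball_pivot

    points = np.asarray(points, float)
    pts = points * k
    if pts.shape[0] < 3:
        warnings.warn("bpa_surface_area: fewer than 3 points", stacklevel=2)
        return 0.0, trimesh.Trimesh()
    tris = ball_pivot(pts, ball_radius_cm)
    if len(tris) == 0:
        warnings.warn("bpa_surface_area: no triangles reconstructed", stacklevel=2)
        return 0.0, trimesh.Trimesh()
    v = pts[tris]
    sides = np.stack([
        np.linalg.norm(v[:, 0] - v[:, 1], axis=1),
        np.linalg.norm(v[:, 1] - v[:, 2], axis=1),
        np.linalg.norm(v[:, 2] - v[:, 0], axis=1),
    ], axis=1)
    area = float(sum(heron_area(*s) for s in sides))
    mesh = trimesh.Trimesh(vertices=pts, faces=tris, process=False)
    return area, mesh


@dataclass
class PhenoConfig:
    reference_length_real: float = 25.0     # cm, tray side
    reference_length_virtual: float | None = None  # measured if None
    voxel_side_cm: float = 0.1
    ball_radius_cm: float = 0.2
    compute_area: bool = True
    compute_volume: bool = True
    ransac_iterations: int = 1000
    seed: int = 0


def phenotype_scene(
    cloud: LabeledCloud,
    net_state=None,
    config: PhenoConfig | None = None,
) -> tuple[list[PhenotypeRecord], AlignmentTransform]:
    """Segment (if needed), align, scale, and measure every plant in a scene.

    When the cloud carries labels they are used directly; otherwise
    ``net_state`` (a trained checkpoint) provides semantic labels and
    adaptive-eps clustering separates the instances. Records are ordered by
    plant id.
    """
    from .instseg import corn_dbscan

    config = config or PhenoConfig()
    if cloud.has_labels:
        semantic = cloud.semantic
        instance = cloud.instance
    else:
        if net_state is None:
            raise ValueError("unlabeled cloud requires a trained net_state")
        from .cornnet import predict_cloud
        semantic = predict_cloud(cloud, net_state)
        instance = np.zeros(len(cloud), dtype=np.int64)
        seedling = semantic == 1
        if seedling.sum():
            assign = corn_dbscan(cloud.points[seedling])
            ids = assign.labels.copy()
            ids[ids >= 0] += 1      # clusters -> 1..K
            ids[ids < 0] = 0        # noise joins background
            instance[seedling] = ids

    normal, _d, inlier_mask = detect_ground_plane(
        cloud, n_iterations=config.ransac_iterations, seed=config.seed
    )
    aligned, transform = align_to_z(cloud, normal, config.reference_length_real)

    l_virtual = config.reference_length_virtual
    if l_virtual is None:
        tray = aligned.points[inlier_mask]
        ext = tray[:, :2].max(axis=0) - tray[:, :2].min(axis=0)
        l_virtual = float(ext.max())
    k = compute_scale(l_virtual, config.reference_length_real)
    transform.scale_k = k

    records = []
    for pid in sorted(int(i) for i in np.unique(instance) if i > 0):
        pts = aligned.points[instance == pid]
        vol = voxel_volume(pts, k, config.voxel_side_cm) if config.compute_volume else 0.0
        if config.compute_area:
            area, _mesh = bpa_surface_area(pts, k, config.ball_radius_cm)
        else:
            area = 0.0
        records.append(PhenotypeRecord(
            plant_id=pid,
            height_cm=plant_height(pts, k),
            canopy_cm=canopy_width(pts, k),
            volume_cm3=vol,
            area_cm2=area,
            point_count=int(pts.shape[0]),
        ))
    return records, transform
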
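"""Synthetic multi-plant tray scenes with known ground-truth traits.

A scene is a planar square tray (soil) plus ``n_plants`` seedlings, each a
vertical stem with radial spread and a few parabolic leaf ribbons. Plants are
affinely normalized after sampling so that the untilted z-extent equals the
designed height and the horizontal AABB equals the designed canopy extents
exactly; ground truth is therefore exact by construction, not approximate.
Jitter is injected *before* that normalization and the whole-scene tilt is
applied *after* ground truth is recorded, so alignment and recovery can be
tested against clean references.

Scenes play the role of the labeled tray reconstructions the pipeline was
designed for; they reproduce the thin-structure geometry of seedling clouds
without any biological growth model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cloudio import LabeledCloud, write_labeled_txt
from .pheno import PhenotypeRecord, rodrigues_matrix

__all__ = ["SceneSpec", "SceneRanges", "GenerationError", "generate_scene", "generate_dataset"]

LEAF_THICKNESS = 0.05   # cm; sheet thickness of the generating leaf solid


class GenerationError(RuntimeError):
    """Plant placement failed (tray too crowded for the requested scene)."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic tray scene.

    Lengths are centimetres. ``tray_side`` defaults to the 25 cm cultivation
    tray that serves as the metric reference object downstream.
    """

    n_plants: int = 3
    plant_heights: list[float] | None = None            # cm, per plant
    canopy_extents: list[tuple[float, float]] | None = None  # (L, W) cm, per plant
    leaf_count: list[int] | None = None                 # per plant
    tray_side: float = 25.0
    tilt_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    tilt_deg: float = 0.0
    noise_sd: float = 0.02                              # cm, point jitter
    points_per_plant: int = 600
    points_on_tray: int = 2000
    min_separation: float = 8.0                         # cm between plant centres
    seed: int = 0

    def __post_init__(self):
        if self.plant_heights is None:
            self.plant_heights = [8.0 + 1.5 * i for i in range(self.n_plants)]
        if self.canopy_extents is None:
            self.canopy_extents = [(3.0, 2.5)] * self.n_plants
        if self.leaf_count is None:
            self.leaf_count = [3] * self.n_plants
        for name in ("plant_heights", "canopy_extents", "leaf_count"):
            if len(getattr(self, name)) != self.n_plants:
                raise ValueError(f"{name} must have length n_plants={self.n_plants}")
        if any(h <= 0 for h in self.plant_heights):
            raise ValueError("plant heights must be positive")
        if any(l <= 0 or w <= 0 for l, w in self.canopy_extents):
            raise ValueError("canopy extents must be positive")
        if not (0.0 <= self.tilt_deg <= 45.0):
            raise ValueError("tilt angle must lie in [0, 45] degrees")
        if self.tray_side <= 0:
            raise ValueError("tray side must be positive")
        if self.points_per_plant < 3:
            raise ValueError("points_per_plant must be >= 3 (DBSCAN minpts)")


def _leaf_surface(t, s, reach, attach_z, tip_z, azimuth):
    """Parabolic leaf ribbon P(t, s); returns positions and unit normals."""
    u = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    p = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    rise = tip_z - attach_z
    z = attach_z + rise * (2.0 * t - t * t)
    dz = rise * (2.0 - 2.0 * t)
    pos = u[None, :] * (reach * t)[:, None] + p[None, :] * s[:, None] + np.array([0, 0, 1.0])[None, :] * z[:, None]
    # dP/dt x dP/ds with dP/ds = p
    dt_vec = u[None, :] * reach + np.array([0, 0, 1.0])[None, :] * dz[:, None]
    nrm = np.cross(dt_vec, p[None, :])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return pos, nrm


def _sample_plant(rng: np.random.Generator, n_points: int, n_leaves: int):
    """Raw (unnormalized) plant: stem + leaves; returns points, normals, area weights."""
    n_stem = max(3, int(0.35 * n_points))
    n_leaf = n_points - n_stem
    stem_h = 0.5
    stem_r = 0.03
    # stem: cylinder shell
    z = rng.uniform(0.0, stem_h, n_stem)
    psi = rng.uniform(0, 2 * np.pi, n_stem)
    stem_pts = np.column_stack([stem_r * np.cos(psi), stem_r * np.sin(psi), z])
    stem_nrm = np.column_stack([np.cos(psi), np.sin(psi), np.zeros(n_stem)])

    pts, nrms = [stem_pts], [stem_nrm]
    per_leaf = np.full(n_leaves, n_leaf // n_leaves)
    per_leaf[: n_leaf % n_leaves] += 1
    base_az = rng.uniform(0, 2 * np.pi)
    leaf_params = []
    for j in range(n_leaves):
        az = base_az + 2 * np.pi * j / n_leaves + rng.normal(0, 0.2)
        reach = rng.uniform(0.6, 1.0)
        attach = rng.uniform(0.25, 0.45) * stem_h / 0.5
        tip = rng.uniform(0.8, 1.0)
        width = rng.uniform(0.08, 0.15)
        t = rng.uniform(0, 1, per_leaf[j])
        s = rng.uniform(-width / 2, width / 2, per_leaf[j])
        pos, nrm = _leaf_surface(t, s, reach, attach, tip, az)
        pts.append(pos)
        nrms.append(nrm)
        leaf_params.append((reach, attach, tip, width))
    return np.vstack(pts), np.vstack(nrms), (stem_h, stem_r), leaf_params


def _normalize_plant(points, normals, height, extent_lw):
    """Affine scale so z-extent = height (z min at 0) and horizontal AABB = (L, W)."""
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    scale = np.array([extent_lw[0] / span[0], extent_lw[1] / span[1], height / span[2]])
    pts = (points - lo) * scale
    pts[:, :2] -= (pts[:, :2].max(axis=0) / 2.0)  # centre horizontally
    # normals transform by inverse scale, renormalized
    nrm = normals / scale
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return pts, nrm, scale


def _plant_surface_area(stem_dims, leaf_params, scale):
    """Numeric areas of the scaled generating surfaces: (stem shell, leaf ribbons)."""
    stem_h, stem_r = stem_dims
    a, b = stem_r * scale[0], stem_r * scale[1]
    psi = np.linspace(0, 2 * np.pi, 721)
    circumference = np.trapezoid(np.hypot(a * np.sin(psi), b * np.cos(psi)), psi)
    stem_area = circumference * stem_h * scale[2]
    leaf_area = 0.0
    for reach, attach, tip, width in leaf_params:
        t = np.linspace(0, 1, 501)
        rise = tip - attach
        # anisotropic horizontal scale approximated by its geometric mean for
        # the informational ground truth
        sh = float(np.sqrt(scale[0] * scale[1]))
        arclen = np.trapezoid(np.hypot(reach * sh, rise * (2 - 2 * t) * scale[2]), t)
        leaf_area += arclen * width * sh
    return float(stem_area), float(leaf_area)


def generate_scene(spec: SceneSpec) -> tuple[LabeledCloud, list[PhenotypeRecord]]:
    """Generate one labeled scene and its per-plant ground-truth records.

    Deterministic given ``spec.seed``. Raises :class:`GenerationError` when
    plants cannot be placed at ``min_separation`` within 100 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    half = spec.tray_side / 2.0
    margin = max((max(l, w) for l, w in spec.canopy_extents), default=0.0) / 2.0 + 0.5

    centres: list[np.ndarray] = []
    for _restart in range(100):
        centres = []
        for _ in range(spec.n_plants):
            for _attempt in range(100):
                c = rng.uniform(-half + margin, half - margin, 2)
                if all(np.linalg.norm(c - c0) >= spec.min_separation for c0 in centres):
                    centres.append(c)
                    break
            else:
                break   # dead end; restart the whole placement
        if len(centres) == spec.n_plants:
            break
    else:
        raise GenerationError(
            f"could not place {spec.n_plants} plants at separation "
            f"{spec.min_separation} on a {spec.tray_side} cm tray"
        )

    pts_all, nrm_all, sem_all, inst_all = [], [], [], []
    records = []

    tray = np.column_stack([
        rng.uniform(-half, half, spec.points_on_tray),
        rng.uniform(-half, half, spec.points_on_tray),
        rng.normal(0.0, spec.noise_sd, spec.points_on_tray),
    ])
    pts_all.append(tray)
    nrm_all.append(np.tile([0.0, 0.0, 1.0], (spec.points_on_tray, 1)))
    sem_all.append(np.zeros(spec.points_on_tray, dtype=np.int64))
    inst_all.append(np.zeros(spec.points_on_tray, dtype=np.int64))

    for j in range(spec.n_plants):
        raw_pts, raw_nrm, stem_dims, leaf_params = _sample_plant(
            rng, spec.points_per_plant, spec.leaf_count[j]
        )
        raw_pts = raw_pts + rng.normal(0.0, spec.noise_sd, raw_pts.shape) * 0.02
        pts, nrm, scale = _normalize_plant(
            raw_pts, raw_nrm, spec.plant_heights[j], spec.canopy_extents[j]
        )
        pts[:, :2] += centres[j]
        pts_all.append(pts)
        nrm_all.append(nrm)
        sem_all.append(np.ones(len(pts), dtype=np.int64))
        inst_all.append(np.full(len(pts), j + 1, dtype=np.int64))

        l, w = spec.canopy_extents[j]
        stem_area, leaf_area = _plant_surface_area(stem_dims, leaf_params, scale)
        stem_vol = np.pi * (stem_dims[1] * scale[0]) * (stem_dims[1] * scale[1]) \
            * stem_dims[0] * scale[2]
        records.append(PhenotypeRecord(
            plant_id=j + 1,
            height_cm=float(spec.plant_heights[j]),
            canopy_cm=float(np.hypot(l, w)),
            volume_cm3=float(stem_vol + leaf_area * LEAF_THICKNESS),
            area_cm2=float(stem_area + leaf_area),
            point_count=len(pts),
        ))

    points = np.vstack(pts_all)
    normals = np.vstack(nrm_all)
    if spec.tilt_deg > 0:
        axis = np.asarray(spec.tilt_axis, dtype=float)
        rot = rodrigues_matrix(axis / np.linalg.norm(axis), np.deg2rad(spec.tilt_deg))
        points = points @ rot.T
        normals = normals @ rot.T

    cloud = LabeledCloud(
        points=points, normals=normals,
        semantic=np.concatenate(sem_all), instance=np.concatenate(inst_all),
    )
    return cloud, records


@dataclass
class SceneRanges:
    """Uniform sampling ranges for randomized dataset generation."""

    n_plants: tuple[int, int] = (2, 6)
    height_cm: tuple[float, float] = (5.0, 12.0)
    extent_cm: tuple[float, float] = (2.0, 4.0)
    leaves: tuple[int, int] = (2, 4)
    tilt_deg: tuple[float, float] = (0.0, 15.0)
    noise_sd: float = 0.02
    points_per_plant: int = 600
    points_on_tray: int = 2000


def sample_spec(rng: np.random.Generator, ranges: SceneRanges, seed: int) -> SceneSpec:
    n = int(rng.integers(ranges.n_plants[0], ranges.n_plants[1] + 1))
    axis = rng.normal(size=3)
    axis[2] = 0.0
    if np.linalg.norm(axis) < 1e-9:
        axis = np.array([1.0, 0.0, 0.0])
    axis /= np.linalg.norm(axis)
    return SceneSpec(
        n_plants=n,
        plant_heights=list(rng.uniform(*ranges.height_cm, n)),
        canopy_extents=[tuple(rng.uniform(*ranges.extent_cm, 2)) for _ in range(n)],
        leaf_count=list(rng.integers(ranges.leaves[0], ranges.leaves[1] + 1, n)),
        tilt_axis=tuple(axis),
        tilt_deg=float(rng.uniform(*ranges.tilt_deg)),
        noise_sd=ranges.noise_sd,
        points_per_plant=ranges.points_per_plant,
        points_on_tray=ranges.points_on_tray,
        seed=seed,
    )


def generate_dataset(
    n_scenes: int,
    out_dir: str | Path,
    ranges: SceneRanges | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``n_scenes`` labeled text scenes plus a ground-truth manifest CSV.

    Returns the manifest (columns: scene_id, file, plant_id, height_cm,
    canopy_cm, volume_cm3, area_cm2, tilt_deg).
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    ranges = ranges or SceneRanges()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    for i in range(n_scenes):
        scene_seed = int(master.integers(0, 2**31 - 1))
        spec = sample_spec(master, ranges, scene_seed)
        cloud, records = generate_scene(spec)
        fname = f"scene_{i:04d}.txt"
        write_labeled_txt(cloud, out_dir / fname)
        for rec in records:
            rows.append({
                "scene_id": i, "file": fname, "plant_id": rec.plant_id,
                "height_cm": rec.height_cm, "canopy_cm": rec.canopy_cm,
                "volume_cm3": rec.volume_cm3, "area_cm2": rec.area_cm2,
                "tilt_deg": spec.tilt_deg,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
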
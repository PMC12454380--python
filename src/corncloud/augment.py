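"""The six point-cloud augmentation techniques and the 8:1:1 dataset split.

Each labeled input cloud yields six augmented variants — fake dropout
(10–20% of points removed), Gaussian jitter (sd 0.01, clipped to ±0.05),
per-axis rotation (±10°), global scaling (0.67–1.5 about the centroid),
index shuffling, and per-axis translation (±0.1) — so 106 originals become
742 files including the originals. Files are then assigned to
train/test/validation splits uniformly at random with expected 8:1:1
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cloudio import LabeledCloud, read_labeled_txt, write_labeled_txt

__all__ = [
    "AugmentConfig", "DegenerateInputError",
    "fake_dropout", "jitter", "rotate", "scale", "shuffle", "translate",
    "build_augmented_dataset", "AUGMENTATIONS",
]


class DegenerateInputError(ValueError):
    """Cloud too small for the requested augmentation."""


@dataclass
class AugmentConfig:
    dropout_range: tuple[float, float] = (0.10, 0.20)
    jitter_sd: float = 0.01
    jitter_clip: float = 0.05
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.67, 1.5)
    translation_range: tuple[float, float] = (-0.1, 0.1)
    split_ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.dropout_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("dropout_range must lie inside (0, 1)")
        if self.jitter_clip < self.jitter_sd:
            raise ValueError("jitter_clip must be >= jitter_sd")
        if self.scale_range[0] <= 0:
            raise ValueError("scale factors must be positive")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def fake_dropout(cloud: LabeledCloud, config: AugmentConfig,
                 rng: np.random.Generator) -> LabeledCloud:
    """Drop round(p·N) random points, p ~ U(dropout_range); order preserved."""
    n = len(cloud)
    if n < 10:
        raise DegenerateInputError(
            f"{n} points cannot realize a 10% dropout granularity")
    p = rng.uniform(*config.dropout_range)
    n_drop = int(round(p * n))
    drop = rng.choice(n, n_drop, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)   # sorted -> survivor order kept
    return cloud.take(keep)


def jitter(cloud: LabeledCloud, config: AugmentConfig,
           rng: np.random.Generator) -> LabeledCloud:
    """Add N(0, sd) per-coordinate noise, hard-clipped to ±jitter_clip."""
    d = rng.normal(0.0, config.jitter_sd, cloud.points.shape) if config.jitter_sd > 0 \
        else np.zeros_like(cloud.points)
    d = np.clip(d, -config.jitter_clip, config.jitter_clip)
    return cloud.replace(points=cloud.points + d)


def _axis_rotations(angles_rad: np.ndarray) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rotate(cloud: LabeledCloud, config: AugmentConfig,
           rng: np.random.Generator) -> LabeledCloud:
    """Compose Rz·Ry·Rx with independent per-axis angles in rotation_range_deg."""
    angles = np.deg2rad(rng.uniform(*config.rotation_range_deg, 3))
    r = _axis_rotations(angles)
    return cloud.replace(points=cloud.points @ r.T, normals=cloud.normals @ r.T)


def scale(cloud: LabeledCloud, config: AugmentConfig,
          rng: np.random.Generator) -> LabeledCloud:
    """Scale by one factor s ~ U(scale_range) about the centroid; normals unchanged."""
    s = rng.uniform(*config.scale_range)
    c = cloud.points.mean(axis=0) if len(cloud) else np.zeros(3)
    return cloud.replace(points=c + (cloud.points - c) * s)


def shuffle(cloud: LabeledCloud, rng: np.random.Generator) -> LabeledCloud:
    """Apply one random permutation jointly to points, normals and labels."""
    return cloud.take(rng.permutation(len(cloud)))


def translate(cloud: LabeledCloud, config: AugmentConfig,
              rng: np.random.Generator) -> LabeledCloud:
    """Add a per-axis offset ~ U(translation_range) to all points."""
    offset = rng.uniform(*config.translation_range, 3)
    return cloud.replace(points=cloud.points + offset)


AUGMENTATIONS = {
    "dropout": lambda cl, cfg, rng: fake_dropout(cl, cfg, rng),
    "jitter": lambda cl, cfg, rng: jitter(cl, cfg, rng),
    "rotate": lambda cl, cfg, rng: rotate(cl, cfg, rng),
    "scale": lambda cl, cfg, rng: scale(cl, cfg, rng),
    "shuffle": lambda cl, cfg, rng: shuffle(cl, rng),
    "translate": lambda cl, cfg, rng: translate(cl, cfg, rng),
}


def build_augmented_dataset(
    input_dir: str | Path, output_dir: str | Path,
    config: AugmentConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Augment every labeled .txt cloud in ``input_dir`` and split 8:1:1.

    Each input yields itself plus one variant per technique (7 files total).
    Returns manifests {"train": ..., "test": ..., "val": ...}, also written
    as CSVs next to the output files. Split assignment is per-file uniform
    with the configured ratios, so realized counts fluctuate around 8:1:1.
    """
    config = config or AugmentConfig()
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    files = sorted(p for p in input_dir.glob("*.txt"))
    if not files:
        raise ValueError(f"no .txt clouds found in {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    for f in files:
        cloud = read_labeled_txt(f, has_labels=True)
        variants = {"original": cloud}
        for name, fn in AUGMENTATIONS.items():
            variants[name] = fn(cloud, config, rng)
        for name, var in variants.items():
            out_name = f"{f.stem}__{name}.txt"
            write_labeled_txt(var, output_dir / out_name)
            rows.append({"file": out_name, "source": f.name, "technique": name})
    table = pd.DataFrame(rows)
    ratios = np.asarray(config.split_ratio)
    table["split"] = rng.choice(
        ["train", "test", "val"], size=len(table), p=ratios / ratios.sum())
    manifests = {}
    for split in ("train", "test", "val"):
        m = table[table["split"] == split].drop(columns="split").reset_index(drop=True)
        m.to_csv(output_dir / f"{split}_manifest.csv", index=False)
        manifests[split] = m
    return manifests
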
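"""Labeled point-cloud text I/O.

The exchange format is one point per line::

    x y z Nx Ny Nz [label1 label2]

where ``label1`` is the semantic class (0 = non-seedling, 1 = seedling) and
``label2`` the plant instance (0 = non-seedling, 1..K = individual plants).
Coordinates are unitless scene units; the metric scale factor is applied
downstream, never at I/O time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "LabeledCloud",
    "CloudParseError",
    "CloudValidationError",
    "read_labeled_txt",
    "write_labeled_txt",
    "export_ply",
]


class CloudParseError(ValueError):
    """A line of a cloud text file could not be parsed."""


class CloudValidationError(ValueError):
    """Cloud content violates the labeled-cloud contract."""


@dataclass
class LabeledCloud:
    """Points + unit normals + optional semantic/instance label channels.

    ``semantic`` is per-point in {0, 1}; ``instance`` is 0 on non-seedling
    points and 1..K on seedling points. Both channels are either present
    together (training data) or absent together (inference clouds).
    """

    points: np.ndarray                      # (N, 3) float
    normals: np.ndarray                     # (N, 3) float, unit or all-zero
    semantic: np.ndarray | None = None      # (N,) int in {0, 1}
    instance: np.ndarray | None = None      # (N,) int >= 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        if self.semantic is not None:
            self.semantic = np.asarray(self.semantic, dtype=np.int64).ravel()
        if self.instance is not None:
            self.instance = np.asarray(self.instance, dtype=np.int64).ravel()
        self.validate()

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_labels(self) -> bool:
        return self.semantic is not None

    def validate(self) -> None:
        n = len(self)
        if self.normals.shape[0] != n:
            raise CloudValidationError(
                f"normals length {self.normals.shape[0]} != points length {n}"
            )
        if n:
            norm = np.linalg.norm(self.normals, axis=1)
            bad = ~((np.abs(norm - 1.0) <= 1e-3) | (norm == 0.0))
            if bad.any():
                raise CloudValidationError(
                    f"{int(bad.sum())} normals are neither unit (±1e-3) nor zero"
                )
        for name, ch in (("semantic", self.semantic), ("instance", self.instance)):
            if ch is not None and ch.shape[0] != n:
                raise CloudValidationError(f"{name} length {ch.shape[0]} != {n}")
        if self.semantic is not None:
            if not np.isin(self.semantic, (0, 1)).all():
                raise CloudValidationError("semantic labels outside {0, 1}")
        if self.instance is not None:
            if (self.instance < 0).any():
                raise CloudValidationError("instance labels must be >= 0")
            if self.semantic is not None:
                bad = (self.semantic == 0) & (self.instance > 0)
                if bad.any():
                    raise CloudValidationError(
                        f"{int(bad.sum())} non-seedling points carry an instance id > 0"
                    )

    def take(self, index: np.ndarray) -> "LabeledCloud":
        """Sub-cloud (or reordering) by integer/boolean index, labels included."""
        return LabeledCloud(
            points=self.points[index],
            normals=self.normals[index],
            semantic=None if self.semantic is None else self.semantic[index],
            instance=None if self.instance is None else self.instance[index],
        )

    def replace(self, **kw) -> "LabeledCloud":
        d = dict(points=self.points, normals=self.normals,
                 semantic=self.semantic, instance=self.instance)
        d.update(kw)
        return LabeledCloud(**d)


def _parse_line(fields: list[str], lineno: int) -> np.ndarray:
    try:
        return np.array([float(f) for f in fields], dtype=np.float64)
    except ValueError as e:
        raise CloudParseError(f"line {lineno}: non-numeric field ({e})") from None


def read_labeled_txt(path: str | Path, has_labels: bool = True) -> LabeledCloud:
    """Read a labeled (8-column) or unlabeled (6-column) cloud text file.

    Fields may be separated by runs of whitespace or a single comma. Header
    lines at the top of the file that fail numeric parsing are skipped with a
    log message; a malformed line in the body raises :class:`CloudParseError`
    naming the line number.
    """
    path = Path(path)
    ncol = 8 if has_labels else 6
    raw_lines = path.read_text().splitlines()
    # skip non-numeric header lines at the top of the file
    start = 0
    for lineno, line in enumerate(raw_lines, start=1):
        stripped = line.strip()
        if not stripped:
            start = lineno
            continue
        try:
            _parse_line(stripped.replace(",", " ").split(), lineno)
            break
        except CloudParseError:
            log.info("%s: skipping non-numeric header line %d", path, lineno)
            start = lineno
    body = [l for l in raw_lines[start:] if l.strip()]
    rows: list[np.ndarray] | None = None
    if body:
        from io import StringIO
        try:
            data = np.loadtxt(
                StringIO("\n".join(body).replace(",", " ")), ndmin=2)
            if data.shape[1] != ncol:
                raise CloudParseError(
                    f"line {start + 1}: expected {ncol} fields, got {data.shape[1]}")
            rows = list(data)
        except CloudParseError:
            raise
        except ValueError:
            # fall back to a line-by-line pass to report the offending line
            rows = []
            for lineno, line in enumerate(raw_lines[start:], start=start + 1):
                stripped = line.strip()
                if not stripped:
                    continue
                fields = stripped.replace(",", " ").split()
                if len(fields) != ncol:
                    raise CloudParseError(
                        f"line {lineno}: expected {ncol} fields, got {len(fields)}")
                rows.append(_parse_line(fields, lineno))
    if not rows:
        return LabeledCloud(
            points=np.empty((0, 3)), normals=np.empty((0, 3)),
            semantic=np.empty(0, dtype=np.int64) if has_labels else None,
            instance=np.empty(0, dtype=np.int64) if has_labels else None,
        )
    data = np.vstack(rows)
    if has_labels:
        sem, inst = data[:, 6], data[:, 7]
        if not (np.isclose(sem, np.round(sem)).all() and np.isclose(inst, np.round(inst)).all()):
            raise CloudValidationError("label columns are not integers")
        return LabeledCloud(points=data[:, :3], normals=data[:, 3:6],
                            semantic=np.round(sem).astype(np.int64),
                            instance=np.round(inst).astype(np.int64))
    return LabeledCloud(points=data[:, :3], normals=data[:, 3:6])


def write_labeled_txt(cloud: LabeledCloud, path: str | Path) -> Path:
    """Write a cloud as space-separated text, 6 significant digits, one point per line."""
    import pandas as pd

    cloud.validate()
    path = Path(path)
    cols = {i: cloud.points[:, i] for i in range(3)}
    cols.update({i + 3: cloud.normals[:, i] for i in range(3)})
    if cloud.has_labels:
        cols[6] = cloud.semantic
        cols[7] = cloud.instance
    pd.DataFrame(cols).to_csv(path, sep=" ", float_format="%.6g",
                              header=False, index=False)
    return path


_PALETTE = np.array([
    (228, 26, 28), (55, 126, 184), (77, 175, 74), (152, 78, 163),
    (255, 127, 0), (255, 255, 51), (166, 86, 40), (247, 129, 191),
    (102, 194, 165), (252, 141, 98), (141, 160, 203), (231, 138, 195),
], dtype=np.uint8)
_GRAY = np.array((128, 128, 128), dtype=np.uint8)


def export_ply(cloud: LabeledCloud, color_by: str, path: str | Path) -> Path:
    """Export an ASCII PLY colored by ``semantic`` or ``instance`` for visual QC.

    Background / noise points are gray; each class or instance gets a distinct
    palette color (the palette cycles past 12 instances).
    """
    if color_by not in ("semantic", "instance"):
        raise ValueError(f"color_by must be 'semantic' or 'instance', got {color_by!r}")
    channel = getattr(cloud, color_by)
    if channel is None:
        raise CloudValidationError(f"cloud has no {color_by!r} channel")
    colors = np.tile(_GRAY, (len(cloud), 1))
    fg = channel > 0
    colors[fg] = _PALETTE[(channel[fg] - 1) % len(_PALETTE)]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(cloud)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n"
        )
        for p, c in zip(cloud.points, colors):
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g} {c[0]} {c[1]} {c[2]}\n")
    return path
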
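"""Ball-pivoting surface reconstruction.

A virtual ball of fixed radius r rolls over the point set: wherever it rests
on three points without containing any other point it deposits a triangle.
The front of open (boundary) edges is pivoted until exhausted, then a new
seed triangle is sought among unused points, so disconnected components are
all meshed. Only triangle connectivity is produced — no normals, no hole
filling — which is all the downstream area estimate needs.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ball_pivot"]

_EMPTY_TOL = 1e-7   # relative shrink of the ball for the emptiness test


def _ball_centers(A, B, C, radius):
    """Centers of radius-r balls touching A, B and each row of C.

    Returns (centers_plus, centers_minus, valid_mask); invalid rows are
    collinear triples or triples whose circumradius exceeds r.
    """
    u = B - A
    v = C - A
    w = np.cross(u[None, :], v)
    w2 = np.einsum("ij,ij->i", w, w)
    valid = w2 > 1e-18
    w2s = np.where(valid, w2, 1.0)
    cc = A + (np.cross(w, u[None, :]) * np.einsum("ij,ij->i", v, v)[:, None]
              + np.cross(v, w) * (u @ u)) / (2.0 * w2s[:, None])
    rc2 = np.einsum("ij,ij->i", cc - A[None, :], cc - A[None, :])
    h2 = radius**2 - rc2
    valid &= h2 >= 0.0
    h = np.sqrt(np.where(valid, h2, 0.0))
    n_dir = w / np.sqrt(w2s)[:, None]
    return cc + n_dir * h[:, None], cc - n_dir * h[:, None], valid


class _Pivoter:
    def __init__(self, points: np.ndarray, radius: float):
        self.pts = points
        self.r = radius
        self.tree = cKDTree(points)
        self.tris: list[tuple[int, int, int]] = []
        self.tri_set: set[tuple[int, int, int]] = set()
        self.edge_count: dict[tuple[int, int], int] = {}
        self.front: deque = deque()
        self.used = np.zeros(len(points), dtype=bool)
        self.max_tris = 8 * len(points)

    def _empty(self, center) -> bool:
        # the three support points sit exactly on the ball, so the slightly
        # shrunk query returns them only under pathological noise
        return self.tree.query_ball_point(
            center, self.r * (1.0 - _EMPTY_TOL), return_length=True
        ) == 0

    def _add_triangle(self, a, b, c, center):
        key = tuple(sorted((a, b, c)))
        if key in self.tri_set:
            return False
        for e in ((a, b), (b, c), (c, a)):
            if self.edge_count.get(tuple(sorted(e)), 0) >= 2:
                return False
        self.tri_set.add(key)
        self.tris.append((a, b, c))
        self.used[[a, b, c]] = True
        for e, opp in (((a, b), c), ((b, c), a), ((c, a), b)):
            ek = tuple(sorted(e))
            n = self.edge_count.get(ek, 0) + 1
            self.edge_count[ek] = n
            if n == 1:
                self.front.append((e[0], e[1], opp, center))
        return True

    def _pivot(self, a, b, opp, center):
        A, B = self.pts[a], self.pts[b]
        m = 0.5 * (A + B)
        e = B - A
        elen = np.linalg.norm(e)
        if elen < 1e-12:
            return None
        e_dir = e / elen
        k = min(100, len(self.pts))
        dist, idx = self.tree.query(m, k=k)
        keep = (dist <= 2.0 * self.r) & (idx != a) & (idx != b) & (idx != opp)
        cand = idx[keep]
        if cand.size == 0:
            return None
        cp, cm, valid = _ball_centers(A, B, self.pts[cand], self.r)
        if not valid.any():
            return None
        # rotation angle of each candidate center around the edge, measured
        # from the current ball position; first contact = smallest angle
        ref = center - m
        ref = ref - (ref @ e_dir) * e_dir
        rn = np.linalg.norm(ref)
        if rn < 1e-12:
            return None
        ref /= rn

        def angles(cs):
            d = cs - m
            d = d - np.outer(d @ e_dir, e_dir)
            dn = np.linalg.norm(d, axis=1)
            ok = dn > 1e-12
            dhat = d / np.where(ok, dn, 1.0)[:, None]
            sin = np.cross(np.broadcast_to(ref, dhat.shape), dhat) @ e_dir
            cos = dhat @ ref
            th = np.arctan2(sin, cos)
            th = np.where(th <= 1e-9, th + 2 * np.pi, th)
            return np.where(ok, th, np.inf)

        th_all = np.concatenate([angles(cp), angles(cm)])
        th_all[~np.concatenate([valid, valid])] = np.inf
        centers = np.vstack([cp, cm])
        cand2 = np.concatenate([cand, cand])
        order = np.argsort(th_all)
        for j in order:
            if not np.isfinite(th_all[j]):
                break
            x, c_new = int(cand2[j]), centers[j]
            if self._empty(c_new) and self._add_triangle(a, x, b, c_new):
                return True
        return None

    def _seed(self, anchor: int):
        nbr = sorted(self.tree.query_ball_point(self.pts[anchor], 2.0 * self.r),
                     key=lambda i: np.linalg.norm(self.pts[i] - self.pts[anchor]))
        nbr = [i for i in nbr if i != anchor][:30]
        for qi, q in enumerate(nbr):
            for s in nbr[qi + 1:]:
                cp, cm, valid = _ball_centers(
                    self.pts[anchor], self.pts[q], self.pts[s][None, :], self.r
                )
                if not valid[0]:
                    continue
                for c in (cp[0], cm[0]):
                    if self._empty(c) and self._add_triangle(anchor, q, s, c):
                        return True
        return False

    def run(self) -> np.ndarray:
        order = np.arange(len(self.pts))
        for anchor in order:
            if self.used[anchor]:
                continue
            if not self._seed(int(anchor)):
                continue
            while self.front and len(self.tris) < self.max_tris:
                a, b, opp, center = self.front.popleft()
                if self.edge_count.get(tuple(sorted((a, b))), 0) >= 2:
                    continue  # became interior through glueing
                self._pivot(a, b, opp, center)  # None -> boundary edge
        if not self.tris:
            return np.empty((0, 3), dtype=np.int64)
        return np.asarray(self.tris, dtype=np.int64)


def ball_pivot(points: np.ndarray, radius: float) -> np.ndarray:
    """Reconstruct a triangle mesh; returns an (m, 3) vertex-index array."""
    points = np.ascontiguousarray(points, dtype=np.float64)
    if points.shape[0] < 3:
        return np.empty((0, 3), dtype=np.int64)
    return _Pivoter(points, float(radius)).run()
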
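"""CBAM-augmented hierarchical point network for seedling/background
semantic segmentation.

Encoder: three cascaded set-abstraction (SA) levels, each doing
farthest-point sampling, multi-scale ball grouping, a shared per-point MLP,
a CBAM block (channel then spatial attention) and per-group max pooling.
Decoder: three feature-propagation (FP) levels interpolating coarse features
back to finer resolutions by inverse-distance weighting with skip
connections. A small head MLP emits two per-point class logits.

The loss is the composite printed form L = L_cls + λ·L_reg with L_cls plain
per-point binary cross-entropy (optionally inverse-frequency class-weighted)
and L_reg a sum of absolute differences over externally supplied regression
pairs; λ defaults to 0 because pure semantic segmentation supplies no such
pairs.

Implemented in NumPy over the package's reverse-mode autodiff engine
(:mod:`corncloud._autograd`); training is single-CPU and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._autograd import Adam, Parameter, Tensor, cat, gather_points
from .cloudio import LabeledCloud

__all__ = [
    "SALevel", "NetConfig", "SemanticPrediction", "CornNet",
    "channel_attention", "spatial_attention", "farthest_point_sampling",
    "composite_loss", "class_rebalance_weights",
    "train", "predict_cloud", "resample_indices",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SALevel:
    n_sample: int
    radii: list[float]
    k_neighbors: list[int]
    mlps: list[list[int]]   # one width list per radius


@dataclass
class NetConfig:
    """Architecture + optimization hyperparameters.

    Defaults follow the public multi-scale-grouping segmentation preset
    (sample counts 1024/256/64, paired radii per level) with training set to
    100 epochs, batch 24, Adam at lr 5e-4 and weight decay 1e-4, npoint 4096.
    """

    npoint: int = 4096
    in_channels: int = 6    # xyz + normals
    sa_levels: list[SALevel] = field(default_factory=lambda: [
        SALevel(1024, [0.05, 0.1], [16, 32], [[16, 16, 32], [32, 32, 64]]),
        SALevel(256, [0.1, 0.2], [16, 32], [[64, 64, 128], [64, 96, 128]]),
        SALevel(64, [0.2, 0.4], [16, 32], [[128, 196, 256], [128, 196, 256]]),
    ])
    fp_mlps: list[list[int]] = field(default_factory=lambda: [
        [256, 256], [256, 128], [128, 128, 128]])
    head_mlp: list[int] = field(default_factory=lambda: [128])
    cbam_reduction: int = 8
    loss_lambda: float = 0.0
    class_weighting: bool = True
    epochs: int = 100
    batch_size: int = 24
    lr: float = 5e-4
    weight_decay: float = 1e-4
    seed: int = 0

    @classmethod
    def small(cls, npoint: int = 1024, seed: int = 0) -> "NetConfig":
        """CPU-sized preset used for synthetic-scene experiments."""
        return cls(
            npoint=npoint,
            sa_levels=[
                SALevel(max(npoint // 4, 8), [0.1, 0.2], [16, 16], [[32, 32], [32, 32]]),
                SALevel(max(npoint // 16, 4), [0.2, 0.4], [16, 16], [[64, 64], [64, 64]]),
                SALevel(max(npoint // 64, 2), [0.4, 0.8], [16, 16], [[64, 128], [64, 128]]),
            ],
            fp_mlps=[[128], [64], [64, 32]],
            head_mlp=[32],
            seed=seed,
        )

    def validate(self):
        if len(self.sa_levels) != len(self.fp_mlps):
            raise ValueError("encoder and decoder must have equal level counts")
        for lvl in self.sa_levels:
            if not (len(lvl.radii) == len(lvl.k_neighbors) == len(lvl.mlps)):
                raise ValueError("per-radius lists of an SA level must align")
            if lvl.n_sample < 1 or any(w < 1 for m in lvl.mlps for w in m):
                raise ValueError("sample counts and widths must be positive")
        if self.loss_lambda < 0:
            raise ValueError("loss_lambda must be >= 0")


@dataclass
class SemanticPrediction:
    probs: np.ndarray    # (B, N, 2), rows sum to 1
    labels: np.ndarray   # (B, N) argmax in {0, 1}


# --------------------------------------------------------------------------
# geometry helpers (index computations; no gradients flow through these)
# --------------------------------------------------------------------------

def farthest_point_sampling(coords: np.ndarray, n_sample: int,
                            start: int | None = None) -> np.ndarray:
    """Greedy FPS over one cloud (N, 3); returns indices (n_sample,).

    The default start is the point farthest from the centroid, which makes
    the selected set invariant to input point order (up to exact ties).
    """
    n = coords.shape[0]
    if n_sample > n:
        raise ValueError(f"cannot sample {n_sample} from {n} points")
    if start is None:
        start = int(np.argmax(
            np.einsum("ij,ij->i", coords - coords.mean(0), coords - coords.mean(0))))
    idx = np.empty(n_sample, dtype=np.int64)
    dist = np.full(n, np.inf)
    cur = start
    for i in range(n_sample):
        idx[i] = cur
        d = np.einsum("ij,ij->i", coords - coords[cur], coords - coords[cur])
        np.minimum(dist, d, out=dist)
        cur = int(np.argmax(dist))
    return idx


def _fps_batch(coords: np.ndarray, n_sample: int) -> np.ndarray:
    return np.stack([farthest_point_sampling(c, n_sample) for c in coords])


def _ball_group(coords: np.ndarray, centroids: np.ndarray, radius: float,
                k: int) -> np.ndarray:
    """Indices (B, S, k) of up to k neighbors within radius of each centroid.

    Centroids with fewer than k in-radius neighbors repeat their nearest
    neighbor (standard ball-query fallback).
    """
    d2 = np.sum((centroids[:, :, None, :] - coords[:, None, :, :]) ** 2, axis=-1)
    k_eff = min(k, coords.shape[1])
    part = np.argpartition(d2, k_eff - 1, axis=-1)[..., :k_eff]
    pd2 = np.take_along_axis(d2, part, axis=-1)
    order = np.argsort(pd2, axis=-1)
    idx = np.take_along_axis(part, order, axis=-1)
    pd2 = np.take_along_axis(pd2, order, axis=-1)
    nearest = idx[..., :1]
    idx = np.where(pd2 <= radius**2, idx, nearest)
    if k_eff < k:
        idx = np.concatenate([idx, np.repeat(nearest, k - k_eff, axis=-1)], axis=-1)
    return idx


def _three_nn_interp(fine_xyz: np.ndarray, coarse_xyz: np.ndarray,
                     coarse_feats: Tensor) -> Tensor:
    """Inverse-distance interpolation of coarse features at fine coordinates."""
    d2 = np.sum((fine_xyz[:, :, None, :] - coarse_xyz[:, None, :, :]) ** 2, axis=-1)
    kk = min(3, coarse_xyz.shape[1])
    nn = np.argpartition(d2, kk - 1, axis=-1)[..., :kk]
    nd2 = np.take_along_axis(d2, nn, axis=-1)
    w = 1.0 / (nd2 + 1e-10)
    w = w / w.sum(axis=-1, keepdims=True)          # (B, Nf, kk)
    gathered = gather_points(coarse_feats, nn)      # (B, Nf, kk, C)
    return (gathered * Tensor(w[..., None])).sum(axis=2)


# --------------------------------------------------------------------------
# attention blocks
# --------------------------------------------------------------------------

def channel_attention(features: Tensor, w1, b1, w2, b2) -> tuple[Tensor, Tensor]:
    """Channel attention over a B×N×C feature block.

    Mc = σ(MLP(avgpool_N(F)) + MLP(maxpool_N(F))); returns (Mc, Mc ⊗ F).
    """
    avg = features.mean(axis=1)                    # (B, C)
    mx = features.max(axis=1)                      # (B, C)

    def mlp(x):
        return ((x @ w1 + b1).relu()) @ w2 + b2

    mc = (mlp(avg) + mlp(mx)).sigmoid()            # (B, C)
    applied = features * mc.reshape(mc.shape[0], 1, mc.shape[1])
    return mc, applied


def spatial_attention(features: Tensor, w_conv, b_conv) -> tuple[Tensor, Tensor]:
    """Spatial (per-point) attention over a B×N×C feature block.

    Per-point channel-avg and channel-max are concatenated (B×N×2) and
    convolved by a shared single-point kernel; Ms = σ(conv(...)).
    Returns (Ms, Ms ⊗ F).
    """
    avg = features.mean(axis=2, keepdims=True)     # (B, N, 1)
    mx = features.max(axis=2, keepdims=True)       # (B, N, 1)
    pooled = cat([avg, mx], axis=2)                # (B, N, 2)
    ms = (pooled @ w_conv + b_conv).sigmoid()      # (B, N, 1)
    return ms, features * ms


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

def _he(rng, fan_in, fan_out):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class CornNet:
    """Parameter container + forward pass. Eval-mode forward is deterministic."""

    def __init__(self, config: NetConfig):
        config.validate()
        self.config = config
        self.params: dict[str, Parameter] = {}
        rng = np.random.default_rng(config.seed)
        c_levels = []   # output channels per encoder level
        c_in = config.in_channels
        for li, lvl in enumerate(config.sa_levels):
            c_out_total = 0
            for ri, widths in enumerate(lvl.mlps):
                c = c_in + 3    # relative xyz appended
                for wi, w in enumerate(widths):
                    self._add(rng, f"sa{li}_r{ri}_mlp{wi}", c, w)
                    c = w
                red = max(c // config.cbam_reduction, 1)
                self._add(rng, f"sa{li}_r{ri}_ca1", c, red)
                self._add(rng, f"sa{li}_r{ri}_ca2", red, c)
                self._add(rng, f"sa{li}_r{ri}_sa_conv", 2, 1)
                c_out_total += c
            c_levels.append(c_out_total)
            c_in = c_out_total
        skips = [config.in_channels] + c_levels[:-1]
        c = c_levels[-1]
        for li, widths in enumerate(config.fp_mlps):
            skip_c = skips[len(skips) - 1 - li]
            cin = c + skip_c
            for wi, w in enumerate(widths):
                self._add(rng, f"fp{li}_mlp{wi}", cin, w)
                cin = w
            c = cin
        for wi, w in enumerate(config.head_mlp):
            self._add(rng, f"head{wi}", c, w)
            c = w
        self._add(rng, "logits", c, 2)

    def _add(self, rng, name, cin, cout):
        self.params[f"{name}_W"] = Parameter(_he(rng, cin, cout))
        self.params[f"{name}_b"] = Parameter(np.zeros(cout))

    def _linear(self, name, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}_W"] + self.params[f"{name}_b"]

    # -- forward -----------------------------------------------------------
    def forward(self, coords: np.ndarray, features: np.ndarray) -> tuple[SemanticPrediction, Tensor]:
        """Run the network on a normalized batch.

        ``coords`` is (B, N, 3); ``features`` (B, N, C_in). Returns the
        prediction and the (B, N, 2) probability Tensor (graph-attached for
        training).
        """
        cfg = self.config
        xyz = [coords]
        feats = [Tensor(features)]
        for li, lvl in enumerate(cfg.sa_levels):
            cur_xyz, cur_f = xyz[-1], feats[-1]
            fps_idx = _fps_batch(cur_xyz, lvl.n_sample)
            new_xyz = np.take_along_axis(cur_xyz, fps_idx[..., None], axis=1)
            pooled_all = []
            for ri, radius in enumerate(lvl.radii):
                gidx = _ball_group(cur_xyz, new_xyz, radius, lvl.k_neighbors[ri])
                grouped = gather_points(cur_f, gidx)        # (B, S, K, C)
                b_idx = np.arange(cur_xyz.shape[0])[:, None, None]
                rel = cur_xyz[b_idx, gidx] - new_xyz[:, :, None, :]
                g = cat([grouped, Tensor(rel)], axis=-1)
                for wi in range(len(lvl.mlps[ri])):
                    g = self._linear(f"sa{li}_r{ri}_mlp{wi}", g).relu()
                # CBAM on the group: points axis = K, batch = B*S
                B, S, K, C = g.shape
                gf = g.reshape(B * S, K, C)
                _, gf = channel_attention(
                    gf,
                    self.params[f"sa{li}_r{ri}_ca1_W"], self.params[f"sa{li}_r{ri}_ca1_b"],
                    self.params[f"sa{li}_r{ri}_ca2_W"], self.params[f"sa{li}_r{ri}_ca2_b"],
                )
                _, gf = spatial_attention(
                    gf,
                    self.params[f"sa{li}_r{ri}_sa_conv_W"],
                    self.params[f"sa{li}_r{ri}_sa_conv_b"],
                )
                pooled = gf.max(axis=1).reshape(B, S, C)    # max over group
                pooled_all.append(pooled)
            xyz.append(new_xyz)
            feats.append(cat(pooled_all, axis=-1))

        # decoder
        f = feats[-1]
        for li in range(len(cfg.fp_mlps)):
            fine_level = len(cfg.sa_levels) - 1 - li
            fine_xyz, coarse_xyz = xyz[fine_level], xyz[fine_level + 1]
            interp = _three_nn_interp(fine_xyz, coarse_xyz, f)
            f = cat([interp, feats[fine_level]], axis=-1)
            for wi in range(len(cfg.fp_mlps[li])):
                f = self._linear(f"fp{li}_mlp{wi}", f).relu()

        for wi in range(len(cfg.head_mlp)):
            f = self._linear(f"head{wi}", f).relu()
        logits = self._linear("logits", f)                  # (B, N, 2)
        zmax = logits.max(axis=-1, keepdims=True)
        e = (logits - zmax).exp()
        probs = e / e.sum(axis=-1, keepdims=True)
        pred = SemanticPrediction(
            probs=probs.data.copy(), labels=np.argmax(probs.data, axis=-1)
        )
        return pred, probs

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=np.float64)

    def save(self, path: str | Path):
        import yaml
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        cfg = asdict(self.config)
        np.savez(path, __config__=np.frombuffer(
            yaml.safe_dump(cfg).encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "CornNet":
        import yaml
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        with np.load(path) as z:
            cfg_raw = yaml.safe_load(bytes(z["__config__"]).decode())
            cfg_raw["sa_levels"] = [SALevel(**d) for d in cfg_raw["sa_levels"]]
            net = cls(NetConfig(**cfg_raw))
            net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return net


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

_P_CLAMP = 1e-7


def class_rebalance_weights(targets: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency class weights normalized to mean 1.

    Gives the minority (typically seedling) class proportionally more weight;
    a batch containing only one class falls back to uniform (1, 1).
    """
    t = np.asarray(targets).ravel()
    n1 = int((t == 1).sum())
    n0 = t.size - n1
    if n0 == 0 or n1 == 0:
        return 1.0, 1.0
    w0, w1 = t.size / n0, t.size / n1
    m = (w0 + w1) / 2.0
    return w0 / m, w1 / m


def composite_loss(
    pred, targets: np.ndarray,
    aux_regression: list[tuple[float, float]] | None = None,
    lam: float = 0.0,
    class_weights: tuple[float, float] | None = None,
) -> float:
    """Composite loss L = L_cls + λ·L_reg (scalar, array inputs).

    ``pred`` is the seedling-class probability per point (or a
    :class:`SemanticPrediction`, from which it is taken). L_cls is mean
    binary cross-entropy with probabilities clamped to [1e-7, 1−1e-7];
    L_reg = Σ|t − t̄| over the supplied pairs (empty → 0).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(pred, SemanticPrediction):
        p = pred.probs[..., 1]
    else:
        p = np.asarray(pred, dtype=float)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"pred shape {p.shape} != target shape {y.shape}")
    p = np.clip(p, _P_CLAMP, 1 - _P_CLAMP)
    per_point = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    if class_weights is not None:
        w = np.where(y == 1, class_weights[1], class_weights[0])
        per_point = per_point * w
    l_cls = float(per_point.mean()) if p.size else 0.0
    l_reg = 0.0
    if aux_regression:
        l_reg = float(sum(abs(t - tbar) for t, tbar in aux_regression))
    return l_cls + lam * l_reg


def _loss_graph(probs: Tensor, targets: np.ndarray,
                class_weights: tuple[float, float] | None) -> Tensor:
    """Autograd twin of the classification part of :func:`composite_loss`."""
    y = np.asarray(targets, dtype=np.float64)
    onehot = np.stack([1 - y, y], axis=-1)
    logp = probs.clip(_P_CLAMP, 1 - _P_CLAMP).log()
    per_point = -(Tensor(onehot) * logp).sum(axis=-1)
    if class_weights is not None:
        w = np.where(y == 1, class_weights[1], class_weights[0])
        per_point = per_point * Tensor(w)
    return per_point.mean()


# --------------------------------------------------------------------------
# data plumbing + training
# --------------------------------------------------------------------------

def resample_indices(n: int, npoint: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform subsample without replacement, or repetition-padding when n < npoint."""
    if n >= npoint:
        return rng.choice(n, npoint, replace=False)
    return np.concatenate([np.arange(n), rng.choice(n, npoint - n, replace=True)])


def _normalize_cloud(points: np.ndarray) -> np.ndarray:
    """Center on the centroid and scale into the unit sphere."""
    c = points - points.mean(axis=0)
    scale = np.linalg.norm(c, axis=1).max()
    return c / max(scale, 1e-12)


def _make_batch(clouds: list[LabeledCloud], npoint: int, rng) -> tuple:
    coords, feats, targets = [], [], []
    for cl in clouds:
        idx = resample_indices(len(cl), npoint, rng)
        p = _normalize_cloud(cl.points)[idx]
        coords.append(p)
        feats.append(np.concatenate([p, cl.normals[idx]], axis=1))
        targets.append(cl.semantic[idx] if cl.semantic is not None else None)
    t = None if targets[0] is None else np.stack(targets)
    return np.stack(coords), np.stack(feats), t


def train(
    train_clouds: list[LabeledCloud],
    val_clouds: list[LabeledCloud] | None,
    config: NetConfig,
    log_path: str | Path | None = None,
    progress: bool = False,
) -> tuple[CornNet, pd.DataFrame]:
    """Train on labeled clouds; returns the best-validation network and a log.

    Adam with the configured lr/weight-decay, batches of
    min(batch_size, n_train), inverse-frequency class weights per batch. The
    checkpoint with the lowest validation loss is retained (training loss
    when no validation split is given). Fully deterministic given
    ``config.seed``.
    """
    if not train_clouds:
        raise ValueError("empty training split")
    config.validate()
    net = CornNet(config)
    opt = Adam(net.params.values(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    bs = min(config.batch_size, len(train_clouds))
    rows, best = [], (np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_clouds))
        ep_loss, nb = 0.0, 0
        for start in range(0, len(order), bs):
            batch = [train_clouds[i] for i in order[start:start + bs]]
            coords, feats, targets = _make_batch(batch, config.npoint, rng)
            _, probs = net.forward(coords, feats)
            cw = class_rebalance_weights(targets) if config.class_weighting else None
            loss = _loss_graph(probs, targets, cw)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            nb += 1
        ep_loss /= nb
        row = {"epoch": epoch, "train_loss": ep_loss,
               "val_loss": np.nan, "val_acc": np.nan, "val_miou": np.nan}
        if val_clouds:
            from .metrics import semantic_metrics
            v_loss, accs, mious = [], [], []
            vrng = np.random.default_rng(config.seed + 2)
            for cl in val_clouds:
                coords, feats, targets = _make_batch([cl], config.npoint, vrng)
                pred, probs = net.forward(coords, feats)
                v_loss.append(composite_loss(probs.data[..., 1], targets))
                rep = semantic_metrics(pred.labels.ravel(), targets.ravel())
                accs.append(rep["acc"])
                mious.append(rep["miou"])
            row.update(val_loss=float(np.mean(v_loss)),
                       val_acc=float(np.mean(accs)), val_miou=float(np.mean(mious)))
            crit = row["val_loss"]
        else:
            crit = ep_loss
        if crit < best[0]:
            best = (crit, net.state_dict())
        rows.append(row)
        if progress:
            print(f"epoch {epoch:3d}  train {ep_loss:.4f}  val {row['val_loss']:.4f}"
                  if val_clouds else f"epoch {epoch:3d}  train {ep_loss:.4f}")
    if best[1] is not None:
        net.load_state_dict(best[1])
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return net, log


def predict_cloud(cloud: LabeledCloud, net: CornNet,
                  npoint: int | None = None, seed: int = 0) -> np.ndarray:
    """Semantic labels for every original point of an arbitrary-size cloud.

    The cloud is normalized once, split into random npoint-sized chunks
    covering every point at least once (the last chunk is padded with
    already-covered points), and chunk predictions are combined per point by
    majority vote over hard labels, probability-sum tie-break.
    """
    npoint = npoint or net.config.npoint
    n = len(cloud)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_chunks = int(np.ceil(n / npoint))
    pad = n_chunks * npoint - n
    full = np.concatenate([perm, rng.choice(perm, pad, replace=True)]) if pad else perm
    chunks = full.reshape(n_chunks, npoint)
    norm_pts = _normalize_cloud(cloud.points)
    votes = np.zeros((n, 2), dtype=np.int64)
    psum = np.zeros((n, 2), dtype=np.float64)
    coords = norm_pts[chunks]
    feats = np.concatenate([coords, cloud.normals[chunks]], axis=-1)
    pred, _ = net.forward(coords, feats)
    for ci in range(n_chunks):
        np.add.at(votes, (chunks[ci], pred.labels[ci]), 1)
        np.add.at(psum, chunks[ci], pred.probs[ci])
    labels = np.where(votes[:, 1] > votes[:, 0], 1,
                      np.where(votes[:, 1] < votes[:, 0], 0,
                               (psum[:, 1] >= psum[:, 0]).astype(np.int64)))
    return labels.astype(np.int64)
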
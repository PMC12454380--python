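"""Shared fixtures: synthetic scenes and (expensive) trained networks.

The two training fixtures are session-scoped so the overfit smoke test and
the end-to-end accuracy checks reuse one training run each.
"""

import numpy as np
import pytest

from corncloud.cornnet import NetConfig, predict_cloud, train
from corncloud.metrics import semantic_metrics
from corncloud.synthgen import SceneRanges, SceneSpec, generate_scene, sample_spec


def make_scenes(n, seed, ranges=None):
    master = np.random.default_rng(seed)
    ranges = ranges or SceneRanges()
    out = []
    for _ in range(n):
        spec = sample_spec(master, ranges, int(master.integers(0, 2**31 - 1)))
        out.append(generate_scene(spec))
    return out


@pytest.fixture(scope="session")
def scene3():
    """A deterministic 3-plant scene with its ground-truth records."""
    return generate_scene(SceneSpec(n_plants=3, seed=7))


@pytest.fixture(scope="session")
def overfit_result():
    """Network overfitted on 4 scenes (50 epochs, npoint 512), plus its log."""
    clouds = [c for c, _ in make_scenes(4, seed=11)]
    cfg = NetConfig.small(npoint=512, seed=0)
    cfg.epochs = 50
    net, log = train(clouds, None, cfg)
    return {"net": net, "log": log, "clouds": clouds}


@pytest.fixture(scope="session")
def e2e_result():
    """End-to-end run: 40 scenes, 32/4/4 split, 30 epochs at npoint 1024.

    Returns the trained network, the training log, and held-out semantic
    accuracy / mIoU per test scene.
    """
    scenes = make_scenes(40, seed=42)
    clouds = [c for c, _ in scenes]
    train_c, val_c, test_c = clouds[:32], clouds[32:36], clouds[36:]
    cfg = NetConfig.small(npoint=1024, seed=0)
    cfg.epochs = 30
    net, log = train(train_c, val_c, cfg)
    accs, mious = [], []
    for cl in test_c:
        labels = predict_cloud(cl, net, seed=0)
        rep = semantic_metrics(labels, cl.semantic)
        accs.append(rep["acc"])
        mious.append(rep["miou"])
    return {"net": net, "log": log, "accs": accs, "mious": mious,
            "test_clouds": test_c}
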
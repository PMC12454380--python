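"""The six augmentation techniques and the 8:1:1 split."""

import itertools

import numpy as np
import pytest

from corncloud.augment import (
    AugmentConfig, DegenerateInputError, build_augmented_dataset,
    fake_dropout, jitter, rotate, scale, shuffle, translate,
)
from corncloud.cloudio import LabeledCloud
from corncloud.synthgen import SceneRanges, SceneSpec, generate_dataset, generate_scene


@pytest.fixture
def cloud():
    cl, _ = generate_scene(SceneSpec(n_plants=2, seed=4, points_per_plant=200,
                                     points_on_tray=600))
    return cl


CFG = AugmentConfig()


def rows_of(cl):
    data = np.column_stack([cl.points, cl.normals, cl.semantic, cl.instance])
    return {tuple(r) for r in data}


def test_dropout_retains_80_to_90_percent(cloud):
    rng = np.random.default_rng(0)
    out = fake_dropout(cloud, CFG, rng)
    assert 0.80 * len(cloud) <= len(out) <= 0.90 * len(cloud)
    assert rows_of(out) <= rows_of(cloud)           # survivors are a subset


def test_dropout_exact_count_at_forced_p():
    pts = np.arange(300).reshape(100, 3).astype(float)
    cl = LabeledCloud(points=pts, normals=np.zeros((100, 3)))
    cfg = AugmentConfig(dropout_range=(0.10, 0.10))
    out = fake_dropout(cl, cfg, np.random.default_rng(1))
    assert len(out) == 90
    # survivor order preserved
    assert (np.diff(out.points[:, 0]) > 0).all()


def test_dropout_refuses_tiny_cloud():
    cl = LabeledCloud(points=np.zeros((5, 3)), normals=np.zeros((5, 3)))
    with pytest.raises(DegenerateInputError):
        fake_dropout(cl, CFG, np.random.default_rng(0))


def test_jitter_moments_and_clip():
    n = 100_000
    cl = LabeledCloud(points=np.zeros((n, 3)), normals=np.zeros((n, 3)))
    out = jitter(cl, CFG, np.random.default_rng(2))
    d = out.points
    assert np.abs(d).max() <= 0.05
    assert d.std() == pytest.approx(0.01, rel=0.05)


def test_zero_noise_jitter_is_identity(cloud):
    cfg = AugmentConfig(jitter_sd=0.0, jitter_clip=0.0)
    out = jitter(cloud, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(out.points, cloud.points)


def test_rotation_is_isometry_and_preserves_normals(cloud):
    out = rotate(cloud, CFG, np.random.default_rng(3))
    sub = np.random.default_rng(0).choice(len(cloud), 50, replace=False)
    d0 = np.linalg.norm(cloud.points[sub][:, None] - cloud.points[sub][None], axis=-1)
    d1 = np.linalg.norm(out.points[sub][:, None] - out.points[sub][None], axis=-1)
    np.testing.assert_allclose(d0, d1, atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-9)
    np.testing.assert_array_equal(out.semantic, cloud.semantic)


def test_zero_rotation_is_identity(cloud):
    cfg = AugmentConfig(rotation_range_deg=(0.0, 0.0))
    out = rotate(cloud, cfg, np.random.default_rng(0))
    np.testing.assert_allclose(out.points, cloud.points, atol=1e-12)


def test_scale_bounds_and_distance_scaling(cloud):
    rng = np.random.default_rng(5)
    factors = []
    for _ in range(200):
        out = scale(cloud, CFG, rng)
        ratio = (out.points[1] - out.points[0]) / (cloud.points[1] - cloud.points[0])
        factors.append(ratio[0])
    factors = np.array(factors)
    assert factors.min() >= 0.67 and factors.max() <= 1.5
    cfg1 = AugmentConfig(scale_range=(1.0, 1.0))
    out = scale(cloud, cfg1, rng)
    np.testing.assert_allclose(out.points, cloud.points, atol=1e-12)


def test_shuffle_preserves_row_multiset(cloud):
    out = shuffle(cloud, np.random.default_rng(6))
    assert rows_of(out) == rows_of(cloud)
    one = cloud.take([0])
    np.testing.assert_array_equal(shuffle(one, np.random.default_rng(0)).points,
                                  one.points)


def test_shuffle_hits_every_permutation_of_three_points():
    cl = LabeledCloud(points=np.eye(3), normals=np.zeros((3, 3)))
    rng = np.random.default_rng(7)
    seen = set()
    for _ in range(720):
        out = shuffle(cl, rng)
        seen.add(tuple(np.argmax(out.points, axis=1)))
    assert seen == set(itertools.permutations(range(3)))


def test_translate_offset_bounds_and_identity(cloud):
    rng = np.random.default_rng(8)
    for _ in range(50):
        out = translate(cloud, CFG, rng)
        offset = out.points[0] - cloud.points[0]
        assert (np.abs(offset) <= 0.1).all()
        np.testing.assert_allclose(out.points.mean(0) - cloud.points.mean(0),
                                   offset, atol=1e-9)
    cfg0 = AugmentConfig(translation_range=(0.0, 0.0))
    out = translate(cloud, cfg0, rng)
    np.testing.assert_array_equal(out.points, cloud.points)


def test_build_augmented_dataset_seven_times_rule(tmp_path):
    ranges = SceneRanges(points_per_plant=60, points_on_tray=120)
    generate_dataset(10, tmp_path / "in", ranges=ranges, seed=0)
    manifests = build_augmented_dataset(tmp_path / "in", tmp_path / "out",
                                        AugmentConfig(seed=0))
    total = sum(len(m) for m in manifests.values())
    assert total == 70
    files = {f.name for f in (tmp_path / "out").glob("*.txt")}
    assert len(files) == 70
    listed = [f for m in manifests.values() for f in m["file"]]
    assert len(listed) == len(set(listed))        # disjoint
    assert set(listed) == files                   # exhaustive


def test_augmentation_preserves_label_semantics(cloud):
    rng = np.random.default_rng(9)
    for fn in (lambda c: jitter(c, CFG, rng), lambda c: rotate(c, CFG, rng),
               lambda c: scale(c, CFG, rng), lambda c: translate(c, CFG, rng)):
        out = fn(cloud)
        np.testing.assert_array_equal(out.semantic, cloud.semantic)
        np.testing.assert_array_equal(out.instance, cloud.instance)
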
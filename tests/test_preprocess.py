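"""Bone-extraction pipeline: unit behaviour plus a flood-fill oracle."""

import numpy as np
import pytest

from ribfrac import CTVolume, PreprocessConfig, preprocess_pipeline
from ribfrac.preprocess import (
    apply_bone_mask,
    binarize_hu,
    dilate,
    largest_component,
    remove_small_components,
    window_normalize,
)
from ribfrac.volume import BinaryMask3D


def _vol(arr, spacing=(1, 1, 1)):
    return CTVolume(np.asarray(arr, dtype=np.float32), spacing)


def _mask(arr, spacing=(1, 1, 1)):
    return BinaryMask3D(np.asarray(arr, dtype=np.uint8), spacing)


# -- brute-force flood-fill oracle -----------------------------------------


def _neighbors(connectivity):
    offs = []
    for d in np.ndindex(3, 3, 3):
        d = np.array(d) - 1
        if not d.any():
            continue
        order = int(np.abs(d).sum())
        if (connectivity, order) in {(6, 1)} or (connectivity == 18 and order <= 2) or connectivity == 26:
            offs.append(d)
    return offs


def flood_fill_components(mask, connectivity=26):
    """Oracle: BFS component labeling, components as sorted voxel-index lists."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    offs = _neighbors(connectivity)
    comps = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in offs:
                w = tuple(np.array(v) + d)
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


# -- binarize ---------------------------------------------------------------


@pytest.mark.parametrize("hu,expected", [(181, 1), (100, 0), (180, 1)])
def test_binarize_threshold_inclusive(hu, expected):
    vol = _vol(np.full((2, 2, 2), hu))
    assert binarize_hu(vol, 180).voxels[0, 0, 0] == expected


def test_binarize_monotone_in_threshold(rng):
    vol = _vol(rng.normal(100, 300, (12, 12, 12)))
    low = binarize_hu(vol, 100).voxels
    high = binarize_hu(vol, 300).voxels
    assert (high <= low).all()


# -- size filter ------------------------------------------------------------


def test_size_filter_strictly_less_than_cutoff():
    # at 1 mm^3/voxel: a 3999-voxel component is removed, a 4000-voxel kept
    arr = np.zeros((2, 64, 64), dtype=np.uint8)
    arr[0].flat[:3999] = 1
    assert remove_small_components(_mask(arr), 4000).count() == 0
    arr[0].flat[:4000] = 1
    assert remove_small_components(_mask(arr), 4000).count() == 4000


def test_size_filter_uses_physical_volume():
    m = np.zeros((10, 30, 30), dtype=np.uint8)
    m[0].flat[:500] = 1  # 500 voxels at 8 mm^3/voxel = 4000 mm^3 -> kept
    out = remove_small_components(_mask(m, spacing=(2, 2, 2)), 4000)
    assert out.count() == 500


def test_size_filter_idempotent(rng):
    m = _mask(rng.random((15, 15, 15)) < 0.2)
    once = remove_small_components(m, 10)
    twice = remove_small_components(once, 10)
    np.testing.assert_array_equal(once.voxels, twice.voxels)


def test_size_filter_empty_mask():
    out = remove_small_components(_mask(np.zeros((5, 5, 5))), 4000)
    assert out.count() == 0


# -- dilation ---------------------------------------------------------------


def test_dilate_single_voxel_six_neighborhood():
    m = np.zeros((5, 5, 5), dtype=np.uint8)
    m[2, 2, 2] = 1
    out = dilate(_mask(m), radius_voxels=1, iterations=1)
    assert out.count() == 7
    expected = {(2, 2, 2), (1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)}
    assert set(map(tuple, np.argwhere(out.voxels))) == expected


def test_dilate_monotone_and_identity_cases(rng):
    m = _mask(rng.random((10, 10, 10)) < 0.1)
    grown = dilate(m, 1, 3)
    assert (grown.voxels >= m.voxels).all()
    np.testing.assert_array_equal(dilate(m, 0, 3).voxels, m.voxels)
    np.testing.assert_array_equal(dilate(m, 1, 0).voxels, m.voxels)
    assert dilate(_mask(np.zeros((5, 5, 5))), 1, 2).count() == 0


# -- largest component ------------------------------------------------------


def test_largest_component_picks_max_and_tie_breaks():
    m = np.zeros((10, 10, 10), dtype=np.uint8)
    m[0, 0, :5] = 1  # 5 voxels, first in scan order
    m[5, 5, :5] = 1  # 5 voxels
    m[8, 8, :3] = 1  # 3 voxels
    out = largest_component(_mask(m))
    assert out.count() == 5
    assert out.voxels[0, 0, 0] == 1 and out.voxels[5, 5, 0] == 0


def test_largest_component_empty_warns(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        out = largest_component(_mask(np.zeros((4, 4, 4))))
    assert out.count() == 0
    assert any("empty" in r.message for r in caplog.records)


# -- mask application and windowing ----------------------------------------


def test_apply_bone_mask_select_and_fill(rng):
    vol = _vol(rng.normal(0, 500, (6, 6, 6)))
    ones = _mask(np.ones((6, 6, 6)))
    zeros = _mask(np.zeros((6, 6, 6)))
    np.testing.assert_array_equal(apply_bone_mask(vol, ones).voxels, vol.voxels)
    assert (apply_bone_mask(vol, zeros).voxels == -300).all()
    mixed = _mask(rng.random((6, 6, 6)) < 0.5)
    out = apply_bone_mask(vol, mixed)
    np.testing.assert_array_equal(out.voxels[mixed.voxels == 1], vol.voxels[mixed.voxels == 1])
    assert (out.voxels[mixed.voxels == 0] == -300).all()
    with pytest.raises(ValueError, match="shape"):
        apply_bone_mask(vol, _mask(np.ones((5, 5, 5))))


@pytest.mark.parametrize(
    "hu,expected",
    [(-300.0, 0.0), (900.0, 1.0), (300.0, 0.5), (2000.0, 1.0), (-1000.0, 0.0)],
)
def test_window_normalize_fixed_bounds(hu, expected):
    out = window_normalize(_vol(np.full((2, 2, 2), hu)), level=300, width=1200)
    assert out.voxels[0, 0, 0] == pytest.approx(expected, abs=1e-6)


# -- pipeline + oracle properties -------------------------------------------


def test_pipeline_removes_debris_and_keeps_fractures(preprocessed_phantom, small_phantom):
    ct, gt = small_phantom
    normalized, bone, _ = preprocessed_phantom
    # every ground-truth voxel survives preprocessing
    assert (bone.voxels[gt.voxels > 0] == 1).all()
    # debris (bright, small, detached) contributes nothing to the bone mask:
    # the mask is a single connected component
    comps = flood_fill_components(bone.voxels[::2, ::2, ::2])  # downsample for oracle speed
    assert len(comps) == 1


def test_pipeline_all_air_volume():
    vol = _vol(np.full((48, 48, 48), -1000.0))
    normalized, bone = preprocess_pipeline(vol)
    assert bone.count() == 0
    assert normalized.voxels.max() == 0.0


def test_component_labeling_matches_flood_fill_oracle(rng):
    """scipy-backed labeling/size-filter/largest agree with BFS on random masks."""
    from scipy import ndimage

    from ribfrac.preprocess import connectivity_structure

    for trial in range(30):
        conn = [6, 18, 26][trial % 3]
        shape = tuple(rng.integers(4, 20, size=3))
        m = rng.random(shape) < rng.uniform(0.05, 0.4)
        oracle = flood_fill_components(m, conn)
        labels, n = ndimage.label(m, structure=connectivity_structure(conn))
        assert n == len(oracle)
        got = sorted(
            (sorted(map(tuple, np.argwhere(labels == i)))) for i in range(1, n + 1)
        )
        assert got == sorted(oracle)
        # size filter agreement
        cutoff = int(rng.integers(1, 8))
        kept = remove_small_components(_mask(m), float(cutoff), conn)
        expect = np.zeros(shape, dtype=np.uint8)
        for comp in oracle:
            if len(comp) >= cutoff:
                for v in comp:
                    expect[v] = 1
        np.testing.assert_array_equal(kept.voxels, expect)
        # largest component agreement (size only; ties broken by scan order)
        if oracle:
            biggest = largest_component(_mask(m), conn)
            assert biggest.count() == max(len(c) for c in oracle)
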
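import itertools

import numpy as np
import pytest

from seedhsi.blocks import (
    NONVIABLE,
    VIABLE,
    extract_blocks,
    load_blockset,
    save_blockset,
    seed_level_accuracy,
    systematic_split,
    vote_seed,
)
from seedhsi.core import HyperspectralCube, SeedMask


def brute_force_block_count(labels, seed_id, s):
    """Independent oracle: scan every pixel position on the seed's grid."""
    rows, cols = np.nonzero(labels == seed_id)
    if rows.size == 0:
        return 0
    r0, c0 = rows.min(), cols.min()
    count = 0
    H, W = labels.shape
    for r in range(H - s + 1):
        for c in range(W - s + 1):
            if (r - r0) % s or (c - c0) % s:
                continue
            if r < r0 or c < c0:
                continue
            if np.all(labels[r : r + s, c : c + s] == seed_id):
                count += 1
    return count


def _cube_for(labels, bands=3):
    h, w = labels.shape
    data = np.random.default_rng(0).uniform(0, 1, (h, w, bands))
    return HyperspectralCube(data=data, wavelengths=np.arange(bands) * 10.0 + 500)


class TestExtractBlocks:
    def test_square_seed_10x10_gives_4_blocks(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[3:13, 5:15] = 1
        cube = _cube_for(labels)
        bs = extract_blocks(cube, SeedMask(labels=labels), 5, labels={1: VIABLE})
        assert len(bs) == 4
        assert all(b.class_label == VIABLE for b in bs.blocks)

    def test_scattered_pixels_drop_seed(self):
        rng = np.random.default_rng(4)
        labels = np.zeros((20, 20), dtype=np.int32)
        pts = rng.choice(400, size=12, replace=False)
        labels[np.unravel_index(pts, (20, 20))] = 1
        cube = _cube_for(labels)
        with pytest.warns(UserWarning, match="dropped"):
            bs = extract_blocks(cube, SeedMask(labels=labels), 5)
        assert len(bs) == 0
        assert bs.dropped_seeds == [1]

    def test_circular_seed_matches_brute_force(self):
        yy, xx = np.mgrid[0:30, 0:30]
        labels = (((yy - 15) ** 2 + (xx - 14) ** 2) <= 100).astype(np.int32)
        cube = _cube_for(labels)
        bs = extract_blocks(cube, SeedMask(labels=labels), 5)
        assert len(bs) == brute_force_block_count(labels, 1, 5)

    def test_random_masks_match_brute_force(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            labels = np.zeros((25, 25), dtype=np.int32)
            n_seeds = rng.integers(1, 4)
            for k in range(1, n_seeds + 1):
                r, c = rng.integers(0, 15, 2)
                h, w = rng.integers(3, 11, 2)
                region = labels[r : r + h, c : c + w]
                region[region == 0] = k
            cube = _cube_for(labels)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bs = extract_blocks(cube, SeedMask(labels=labels), 4)
            for k in np.unique(labels[labels > 0]):
                got = sum(1 for b in bs.blocks if b.seed_id == k)
                assert got == brute_force_block_count(labels, k, 4), f"trial {trial}"

    def test_blocks_contain_no_background(self, small_scene):
        from seedhsi.core import calibrate_cube

        cube = calibrate_cube(small_scene.calibration)
        bs = extract_blocks(cube, small_scene.mask, 5, labels=small_scene.classes)
        for b in bs.blocks:
            r, c = b.origin
            assert np.all(small_scene.mask.labels[r : r + 5, c : c + 5] == b.seed_id)

    def test_band_subset_applied(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[0:5, 0:5] = 1
        cube = _cube_for(labels, bands=6)
        bs = extract_blocks(cube, SeedMask(labels=labels), 5,
                            band_indices=np.array([1, 3]))
        assert bs.blocks[0].data.shape == (5, 5, 2)
        assert np.array_equal(bs.blocks[0].data, cube.data[0:5, 0:5, [1, 3]])

    def test_roundtrip_persistence(self, tmp_path):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[1:11, 1:11] = 1
        cube = _cube_for(labels)
        bs = extract_blocks(cube, SeedMask(labels=labels), 5, labels={1: NONVIABLE})
        path = str(tmp_path / "blocks.npz")
        save_blockset(bs, path)
        back = load_blockset(path)
        assert len(back) == len(bs)
        assert np.array_equal(back.data_array(), bs.data_array())
        assert np.array_equal(back.labels(), bs.labels())


class TestSystematicSplit:
    def test_750_stride_10_totals(self):
        train, test = systematic_split(750, 10)
        assert len(test) == 75
        assert len(train) == 675

    def test_partition(self):
        train, test = systematic_split(103, 7)
        assert len(np.intersect1d(train, test)) == 0
        assert np.array_equal(np.sort(np.concatenate([train, test])),
                              np.arange(103))

    def test_first_seed_in_test(self):
        _, test = systematic_split(50, 10)
        assert test[0] == 0

    def test_stride_ge_n_warns_single_pick(self):
        with pytest.warns(UserWarning):
            train, test = systematic_split(10, 10)
        assert list(test) == [0]
        assert len(train) == 9

    def test_exact_10_percent_on_multiples(self):
        for n in (20, 100, 750):
            _, test = systematic_split(n, 10)
            assert len(test) == n // 10

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            systematic_split(100, 1)


class TestVoteSeed:
    def test_unanimous(self):
        p = vote_seed([1, 1, 1, 1])
        assert p.voted_class == 1
        assert p.vote_fraction == 1.0

    def test_majority(self):
        p = vote_seed([1, 1, 2])
        assert p.voted_class == 1
        assert p.vote_fraction == pytest.approx(2 / 3)

    def test_tie_defaults_to_nonviable(self):
        assert vote_seed([1, 2]).voted_class == NONVIABLE

    def test_tie_rule_override(self):
        assert vote_seed([1, 2], tie_rule=VIABLE).voted_class == VIABLE

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vote_seed([])

    def test_exhaustive_enumeration_up_to_11(self):
        # oracle: explicit count comparison with documented tie rule
        for n in range(1, 12):
            for votes in itertools.product([1, 2], repeat=n):
                n1 = votes.count(1)
                n2 = votes.count(2)
                expected = 1 if n1 > n2 else 2
                p = vote_seed(list(votes))
                assert p.voted_class == expected, votes
                assert p.vote_fraction == pytest.approx(max(n1, n2) / n)

    def test_minority_flip_never_changes_outcome(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            votes = rng.choice([1, 2], size=n)
            base = vote_seed(votes).voted_class
            minority = votes != base
            if minority.sum() == 0 or minority.sum() * 2 >= n:
                continue
            flipped = votes.copy()
            flipped[minority] = base
            assert vote_seed(flipped).voted_class == base


class TestSeedLevelAccuracy:
    def test_perfect(self):
        preds = [vote_seed([1, 1], seed_id=i) for i in range(3)]
        assert seed_level_accuracy(preds, {0: 1, 1: 1, 2: 1}) == 1.0

    def test_three_of_four(self):
        preds = [vote_seed([c], seed_id=i) for i, c in enumerate([1, 1, 2, 2])]
        truth = {0: 1, 1: 1, 2: 2, 3: 1}
        assert seed_level_accuracy(preds, truth) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            seed_level_accuracy([], {})

    def test_missing_truth_rejected(self):
        preds = [vote_seed([1], seed_id=5)]
        with pytest.raises(KeyError):
            seed_level_accuracy(preds, {0: 1})
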
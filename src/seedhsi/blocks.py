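"""Block decomposition of masked seed cubes, systematic splitting, and
majority-vote aggregation of per-block predictions to per-seed decisions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import HyperspectralCube, SeedMask

__all__ = [
    "Block",
    "BlockSet",
    "SeedPrediction",
    "VIABLE",
    "NONVIABLE",
    "extract_blocks",
    "systematic_split",
    "vote_seed",
    "seed_level_accuracy",
    "save_blockset",
    "load_blockset",
]

VIABLE = 1
NONVIABLE = 2


@dataclass
class Block:
    """One s×s×K full-foreground sub-cube of a single seed."""

    data: np.ndarray  # (s, s, K)
    seed_id: int
    class_label: int
    origin: tuple[int, int]  # (row, col) of the top-left corner


@dataclass
class BlockSet:
    blocks: list[Block]
    block_size: int
    band_indices: np.ndarray | None = None
    dropped_seeds: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def data_array(self) -> np.ndarray:
        """Stack all block data into one ``(n, s, s, K)`` array."""
        if not self.blocks:
            s = self.block_size
            return np.empty((0, s, s, 0))
        return np.stack([b.data for b in self.blocks])

    def labels(self) -> np.ndarray:
        return np.array([b.class_label for b in self.blocks], dtype=int)

    def seed_ids(self) -> np.ndarray:
        return np.array([b.seed_id for b in self.blocks], dtype=int)

    def subset(self, keep_seed_ids) -> "BlockSet":
        keep = set(int(i) for i in keep_seed_ids)
        return BlockSet(
            blocks=[b for b in self.blocks if b.seed_id in keep],
            block_size=self.block_size,
            band_indices=self.band_indices,
            dropped_seeds=[i for i in self.dropped_seeds if i in keep],
        )

    def with_data(self, data: np.ndarray) -> "BlockSet":
        """Copy of this set with per-block data replaced (e.g. standardized)."""
        if len(data) != len(self.blocks):
            raise ValueError("replacement array length mismatch")
        new = [
            Block(data=d, seed_id=b.seed_id, class_label=b.class_label, origin=b.origin)
            for d, b in zip(data, self.blocks)
        ]
        return BlockSet(new, self.block_size, self.band_indices, list(self.dropped_seeds))


@dataclass
class SeedPrediction:
    seed_id: int
    block_votes: np.ndarray
    voted_class: int
    vote_fraction: float
    block_scores: np.ndarray | None = None


def extract_blocks(
    cube: HyperspectralCube,
    mask: SeedMask,
    block_size: int,
    labels: dict[int, int] | None = None,
    band_indices: np.ndarray | None = None,
) -> BlockSet:
    """Tile every seed into non-overlapping full-foreground s×s blocks.

    The tiling grid is anchored at each seed's bounding-box top-left corner.
    A block is kept iff all ``s*s`` pixels belong to that seed instance
    (blocks containing any background or foreign pixel are discarded).  Seeds
    admitting no full block are recorded in ``dropped_seeds`` with a warning.
    """
    s = int(block_size)
    if s < 1:
        raise ValueError("block_size must be >= 1")
    if mask.labels.shape != cube.data.shape[:2]:
        raise ValueError("cube and mask are not aligned")
    data = cube.data if band_indices is None else cube.data[:, :, band_indices]
    out: list[Block] = []
    dropped: list[int] = []
    for k in mask.instance_ids():
        k = int(k)
        label = labels.get(k, 0) if labels is not None else 0
        rows, cols = np.nonzero(mask.labels == k)
        r0, c0 = rows.min(), cols.min()
        r1, c1 = rows.max() + 1, cols.max() + 1
        n_before = len(out)
        for r in range(r0, r1 - s + 1, s):
            for c in range(c0, c1 - s + 1, s):
                win = mask.labels[r : r + s, c : c + s]
                if np.all(win == k):
                    out.append(
                        Block(
                            data=data[r : r + s, c : c + s, :].copy(),
                            seed_id=k,
                            class_label=label,
                            origin=(int(r), int(c)),
                        )
                    )
        if len(out) == n_before:
            warnings.warn(f"seed {k} admits no full {s}x{s} block; dropped")
            dropped.append(k)
    return BlockSet(out, s, band_indices=band_indices, dropped_seeds=dropped)


def systematic_split(n_seeds: int, stride: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Seed-level systematic split: every ``stride``-th seed goes to test.

    Test seeds sit at ordinal positions 1, 1+stride, 1+2*stride, ... of the
    acquisition order; train is the complement.  Returns 0-based index arrays
    ``(train_ids, test_ids)``.
    """
    if stride < 2:
        raise ValueError("stride must be >= 2")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if stride >= n_seeds:
        warnings.warn("stride >= n_seeds: test set holds only the first seed")
    test = np.arange(0, n_seeds, stride)
    train = np.setdiff1d(np.arange(n_seeds), test)
    return train, test


def vote_seed(
    block_votes,
    seed_id: int = 0,
    tie_rule: int = NONVIABLE,
    block_scores: np.ndarray | None = None,
) -> SeedPrediction:
    """Majority vote over a seed's block predictions.

    ``voted_class`` is the modal class; an exact tie resolves to ``tie_rule``
    (default nonviable, since a viable call requires strictly more than half).
    ``vote_fraction`` is modal count / total.
    """
    votes = np.asarray(block_votes, dtype=int)
    if votes.size == 0:
        raise ValueError("empty vote vector")
    classes, counts = np.unique(votes, return_counts=True)
    top = counts.max()
    winners = classes[counts == top]
    if len(winners) > 1:
        voted = int(tie_rule) if tie_rule in winners else int(winners.min())
    else:
        voted = int(winners[0])
    return SeedPrediction(
        seed_id=seed_id,
        block_votes=votes,
        voted_class=voted,
        vote_fraction=float(top) / votes.size,
        block_scores=block_scores,
    )


def seed_level_accuracy(
    predictions: list[SeedPrediction], truth: dict[int, int]
) -> float:
    """Fraction of seeds whose voted class equals the ground truth."""
    if not predictions:
        raise ValueError("no predictions")
    correct = 0
    for p in predictions:
        if p.seed_id not in truth:
            raise KeyError(f"no truth entry for seed {p.seed_id}")
        correct += int(p.voted_class == truth[p.seed_id])
    return correct / len(predictions)


def save_blockset(bs: BlockSet, path: str) -> None:
    """Persist a BlockSet as ``.npz`` with a JSON sidecar of per-block metadata."""
    np.savez_compressed(path, data=bs.data_array())
    meta = {
        "block_size": bs.block_size,
        "band_indices": None
        if bs.band_indices is None
        else [int(i) for i in bs.band_indices],
        "dropped_seeds": bs.dropped_seeds,
        "blocks": [
            {"seed_id": b.seed_id, "label": b.class_label, "origin": list(b.origin)}
            for b in bs.blocks
        ],
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)


def load_blockset(path: str) -> BlockSet:
    with np.load(path) as z:
        data = z["data"]
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    blocks = [
        Block(
            data=data[i],
            seed_id=m["seed_id"],
            class_label=m["label"],
            origin=tuple(m["origin"]),
        )
        for i, m in enumerate(meta["blocks"])
    ]
    bi = meta["band_indices"]
    return BlockSet(
        blocks,
        meta["block_size"],
        band_indices=None if bi is None else np.array(bi),
        dropped_seeds=meta["dropped_seeds"],
    )
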
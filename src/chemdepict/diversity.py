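"""Diverse fingerprint picking and dataset planning.

The picker is a greedy farthest-point (MaxMin) selection under Tanimoto
distance on bit vectors.  Pools too large to enumerate are replaced by a
seeded uniform subsample before picking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .param_space import (
    FingerprintScheme,
    StyleProfile,
    count_valid_fingerprints,
    fingerprint_at_index,
    reference_profiles,
)

__all__ = [
    "FingerprintPool",
    "tanimoto_distance",
    "maxmin_pick",
    "pool_from_scheme",
    "largest_remainder_counts",
    "PlanRecord",
    "plan_dataset",
]

#: default cap on pool size before seeded subsampling kicks in
DEFAULT_POOL_CAP = 100_000


@dataclass
class FingerprintPool:
    """Equal-length bit vectors plus the scheme they were drawn from."""

    bits: np.ndarray  # (n, L) array of 0/1, uint8
    scheme_id: str
    #: enumeration indices of the rows in the scheme's full fingerprint set
    indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValueError("pool bits must be a 2-D array")

    def __len__(self) -> int:
        return self.bits.shape[0]


def tanimoto_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """1 - |a AND b| / |a OR b|; 0 when both vectors are all-zero."""
    av = np.asarray(a, dtype=bool)
    bv = np.asarray(b, dtype=bool)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    union = int(np.count_nonzero(av | bv))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(av & bv))
    return 1.0 - inter / union


def _pack_words(bits: np.ndarray) -> np.ndarray:
    """Pack (n, L) 0/1 rows into (n, W) uint64 words for fast popcounts."""
    packed = np.packbits(bits.astype(np.uint8), axis=1)  # (n, ceil(L/8)) uint8
    w = -(-packed.shape[1] // 8) * 8
    if packed.shape[1] < w:
        packed = np.pad(packed, ((0, 0), (0, w - packed.shape[1])))
    return packed.reshape(packed.shape[0], -1, 8).copy().view(np.uint64)[:, :, 0]


def maxmin_pick(pool, k: int, seed: int) -> List[int]:
    """Greedy farthest-point pick of ``k`` row indices from a pool.

    The first index is chosen uniformly from the seeded rng; every later
    pick maximises the minimum Tanimoto distance to the already-picked set,
    with ties broken by the lowest index.  Deterministic given ``seed``.
    """
    bits = pool.bits if isinstance(pool, FingerprintPool) else np.asarray(pool)
    bits = np.asarray(bits, dtype=np.uint8)
    n = bits.shape[0]
    if n == 0:
        raise ValueError("cannot pick from an empty pool")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for pool of {n}")

    words = _pack_words(bits)
    counts = np.bitwise_count(words).sum(axis=1).astype(np.float64)

    rng = np.random.default_rng(seed)
    first = int(rng.integers(0, n))
    picked = [first]
    min_dist = np.full(n, np.inf)

    last = first
    for _ in range(k - 1):
        inter = np.bitwise_count(words & words[last]).sum(axis=1)
        union = counts + counts[last] - inter
        with np.errstate(invalid="ignore"):
            dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        np.minimum(min_dist, dist, out=min_dist)
        min_dist[picked] = -1.0  # never re-pick
        last = int(np.argmax(min_dist))  # argmax returns lowest index on ties
        picked.append(last)
    return picked


def pool_from_scheme(
    scheme: FingerprintScheme,
    cap: int = DEFAULT_POOL_CAP,
    seed: int = 0,
) -> FingerprintPool:
    """Enumerate the scheme's valid fingerprints as a pool.

    When the scheme exceeds ``cap`` fingerprints, a seeded uniform
    subsample of ``cap`` enumeration indices is decoded instead.
    """
    n = count_valid_fingerprints(scheme)
    if n <= cap:
        idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=cap, replace=False))
    rows = [fingerprint_at_index(scheme, int(i)).bits for i in idx]
    return FingerprintPool(np.array(rows, dtype=np.uint8), scheme.scheme_id, idx)


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> List[int]:
    """Integer apportionment of ``n`` by fractions, largest remainder first."""
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError(f"fractions must be in [0, 1]: {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1: {fractions}")
    raw = [n * f for f in fractions]
    counts = [math.floor(r) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class PlanRecord:
    """One planned image: style, style fingerprint, optional augmentation."""

    index: int
    style_id: str
    style_fingerprint: Tuple[int, ...]
    augmentation_fingerprint: Optional[Tuple[int, ...]]


def plan_dataset(
    n: int,
    proportions: Sequence[float],
    augmented_fraction: float,
    profiles: Optional[Dict[str, StyleProfile]] = None,
    seed: int = 0,
    pool_cap: int = DEFAULT_POOL_CAP,
    augmentation_scheme: Optional[FingerprintScheme] = None,
) -> List[PlanRecord]:
    """Plan ``n`` images with exact style counts and diverse fingerprints.

    Style counts follow largest-remainder rounding of ``n * fraction``;
    within each style the fingerprints are a MaxMin pick over that style's
    (possibly subsampled) pool, cycled if more images than pool entries are
    requested.  ``augmented_fraction`` of the records (largest-remainder)
    carry an augmentation fingerprint picked the same way.
    """
    if not 0 <= augmented_fraction <= 1:
        raise ValueError(f"augmented fraction must be in [0, 1]: {augmented_fraction}")
    if profiles is None:
        profiles = reference_profiles()
    if augmentation_scheme is None:
        from .augment import augmentation_scheme as _aug_scheme

        augmentation_scheme = _aug_scheme()
    if n == 0:
        return []

    style_ids = list(profiles)
    if len(style_ids) != len(proportions):
        raise ValueError("one fraction per style profile required")
    counts = largest_remainder_counts(n, list(proportions))
    n_aug = largest_remainder_counts(n, [augmented_fraction, 1 - augmented_fraction])[0]

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31, size=len(style_ids) + 3)

    # per-style MaxMin fingerprint sequences, cycled when count > pool
    style_fps: Dict[str, List[Tuple[int, ...]]] = {}
    for sid, count, s in zip(style_ids, counts, sub_seeds):
        if count == 0:
            style_fps[sid] = []
            continue
        pool = pool_from_scheme(profiles[sid].scheme, cap=pool_cap, seed=int(s))
        picks = maxmin_pick(pool, min(count, len(pool)), int(s))
        rows = [tuple(int(b) for b in pool.bits[p]) for p in picks]
        style_fps[sid] = [rows[i % len(rows)] for i in range(count)]

    aug_fps: List[Tuple[int, ...]] = []
    if n_aug > 0:
        aug_pool = pool_from_scheme(
            augmentation_scheme, cap=pool_cap, seed=int(sub_seeds[-3])
        )
        picks = maxmin_pick(aug_pool, min(n_aug, len(aug_pool)), int(sub_seeds[-3]))
        rows = [tuple(int(b) for b in aug_pool.bits[p]) for p in picks]
        aug_fps = [rows[i % len(rows)] for i in range(n_aug)]

    # interleave styles and augmentation flags deterministically
    style_of = np.repeat(np.arange(len(style_ids)), counts)
    rng_shuffle = np.random.default_rng(int(sub_seeds[-2]))
    rng_shuffle.shuffle(style_of)
    augmented = np.zeros(n, dtype=bool)
    augmented[np.random.default_rng(int(sub_seeds[-1])).permutation(n)[:n_aug]] = True

    records = []
    cursor = {sid: 0 for sid in style_ids}
    aug_cursor = 0
    for i in range(n):
        sid = style_ids[int(style_of[i])]
        fp = style_fps[sid][cursor[sid]]
        cursor[sid] += 1
        afp = None
        if augmented[i]:
            afp = aug_fps[aug_cursor]
            aug_cursor += 1
        records.append(PlanRecord(i, sid, fp, afp))
    return records
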
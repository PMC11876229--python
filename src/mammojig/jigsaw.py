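"""Permutation-set design and gapped 3x3 puzzle sampling.

The jigsaw pretext task scrambles the 9 patches of a 3x3 grid by one of
31 predefined permutations (the identity plus 30 derangements chosen for
maximal mutual Hamming distance) and asks the network to recognise which
permutation was applied. Restricting to derangements puts every
non-identity class at the maximal Hamming distance 9 from the identity;
greedy max-min selection then spreads the 30 classes apart from each
other so that no two classes are near-duplicates.

Patch geometry: a 512x512 crop is tiled into a 3x3 grid of 170x170 cells
(the 2 leftover pixel rows/columns on the right/bottom are discarded);
inside each cell an independent random 150x150 window is taken. The
20-pixel slack realises the random gaps that stop the network from
solving the puzzle by matching texture across patch edges. Each patch is
intensity-standardized on its own, which additionally removes absolute
brightness as a shortcut cue.

Permutation convention, used everywhere in this package: grid slot ``i``
(row-major) receives the patch originally at position ``mapping[i]``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "PermutationSet",
    "hamming_distance",
    "is_derangement",
    "generate_permutation_set",
    "exhaustive_permutation_set",
    "mean_pairwise_hamming",
    "sample_puzzle",
    "invert_permutation",
    "PuzzleSample",
]


def _validate_permutation(p, n: int | None = None) -> np.ndarray:
    arr = np.asarray(p, dtype=int)
    size = len(arr) if n is None else n
    if arr.ndim != 1 or len(arr) != size or sorted(arr.tolist()) != list(range(size)):
        raise ValueError(f"not a permutation of 0..{size - 1}: {p!r}")
    return arr


def hamming_distance(p, q) -> int:
    """Number of grid positions at which two permutations disagree."""
    pa = _validate_permutation(p)
    qa = _validate_permutation(q, n=len(pa))
    return int(np.sum(pa != qa))


def is_derangement(p) -> bool:
    """True when the permutation moves every position (no fixed points)."""
    pa = _validate_permutation(p)
    return bool(np.all(pa != np.arange(len(pa))))


def invert_permutation(p) -> tuple[int, ...]:
    pa = _validate_permutation(p)
    inv = np.empty_like(pa)
    inv[pa] = np.arange(len(pa))
    return tuple(int(x) for x in inv)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the puzzle grid."""

    image_size: int = 512
    grid: int = 3
    cell_size: int = 170
    patch_size: int = 150

    def __post_init__(self) -> None:
        if self.grid * self.cell_size > self.image_size:
            raise ValueError("grid does not fit inside the image")
        if self.patch_size > self.cell_size:
            raise ValueError("patch must fit inside a cell")

    @property
    def n_patches(self) -> int:
        return self.grid * self.grid

    @property
    def jitter(self) -> int:
        """Per-axis slack for the random patch window inside a cell."""
        return self.cell_size - self.patch_size


@dataclass
class PermutationSet:
    """Ordered permutation classes of the pretext task (index = label)."""

    permutations: list[tuple[int, ...]]
    seed: int = 0
    mean_pairwise_hamming: float = field(default=0.0)

    def __post_init__(self) -> None:
        perms = [tuple(_validate_permutation(p).tolist()) for p in self.permutations]
        n = len(perms[0])
        if perms[0] != tuple(range(n)):
            raise ValueError("element 0 must be the identity permutation")
        if len(set(perms)) != len(perms):
            raise ValueError("permutations must be distinct")
        for p in perms[1:]:
            if not is_derangement(p):
                raise ValueError(f"non-identity element is not a derangement: {p}")
        self.permutations = perms
        self.mean_pairwise_hamming = mean_pairwise_hamming(perms)

    def __len__(self) -> int:
        return len(self.permutations)

    def __getitem__(self, label: int) -> tuple[int, ...]:
        return self.permutations[label]

    def to_csv(self, path: str | Path) -> None:
        """One row per permutation (row order = class label) + JSON sidecar."""
        path = Path(path)
        arr = np.asarray(self.permutations, dtype=int)
        np.savetxt(path, arr, fmt="%d", delimiter=",")
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "seed": self.seed,
            "mean_pairwise_hamming": self.mean_pairwise_hamming,
            "n_permutations": len(self.permutations),
        }, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PermutationSet":
        path = Path(path)
        arr = np.loadtxt(path, dtype=int, delimiter=",", ndmin=2)
        seed = 0
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            seed = int(json.loads(sidecar.read_text()).get("seed", 0))
        return cls(permutations=[tuple(row) for row in arr], seed=seed)


def mean_pairwise_hamming(perms) -> float:
    """Arithmetic mean of Hamming distance over all unordered pairs."""
    if isinstance(perms, PermutationSet):
        perms = perms.permutations
    arr = np.asarray(list(perms), dtype=int)
    if len(arr) < 2:
        raise ValueError("need at least two permutations")
    total = 0
    for i, j in itertools.combinations(range(len(arr)), 2):
        total += int(np.sum(arr[i] != arr[j]))
    return total / (len(arr) * (len(arr) - 1) / 2)


def _sample_derangement_pool(rng: np.random.Generator, n: int, pool_size: int,
                             max_tries: int | None = None) -> np.ndarray:
    """Distinct random derangements of ``0..n-1`` by rejection sampling."""
    seen: dict[tuple[int, ...], None] = {}
    idx = np.arange(n)
    tries = 0
    limit = max_tries if max_tries is not None else 1000 * pool_size
    while len(seen) < pool_size:
        tries += 1
        if tries > limit:
            raise RuntimeError("derangement pool exhausted before reaching pool_size")
        p = rng.permutation(n)
        if np.all(p != idx):
            seen.setdefault(tuple(int(x) for x in p), None)
    return np.asarray(list(seen), dtype=int)


def _greedy_select(pool: np.ndarray, identity: np.ndarray, n_extra: int
                   ) -> list[np.ndarray]:
    """Greedy max-min Hamming dispersion, seeded with the identity.

    At each step the candidate maximizing its minimum distance to the
    already-selected set is added; ties are broken by the larger mean
    distance to the selected set, then by sampling order (lowest pool
    index wins).
    """
    selected = [identity]
    # dist[i, k]: Hamming distance of pool[i] to selected[k]
    dist = (pool != identity).sum(axis=1, keepdims=True).astype(float)
    available = np.ones(len(pool), dtype=bool)
    for _ in range(n_extra):
        if not available.any():
            raise RuntimeError("candidate pool exhausted before selection complete")
        min_d = dist.min(axis=1)
        mean_d = dist.mean(axis=1)
        min_d[~available] = -1.0
        best_min = min_d.max()
        tied = (min_d == best_min)
        best_mean = mean_d[tied].max()
        tied &= (mean_d == best_mean)
        choice = int(np.flatnonzero(tied)[0])
        selected.append(pool[choice])
        available[choice] = False
        new_col = (pool != pool[choice]).sum(axis=1, keepdims=True).astype(float)
        dist = np.hstack([dist, new_col])
    return selected


def generate_permutation_set(n_extra: int = 30, pool_size: int = 2000,
                             seed: int = 0, n: int = 9) -> PermutationSet:
    """Identity plus ``n_extra`` maximally dispersed derangements.

    A pool of ``pool_size`` distinct random derangements is drawn with the
    seeded generator, then thinned by greedy max-min Hamming dispersion.
    Every non-identity class is automatically at distance ``n`` from the
    identity (derangements); the greedy step controls the class-to-class
    distances.
    """
    if n_extra < 1:
        raise ValueError("n_extra must be >= 1")
    if pool_size < n_extra:
        raise ValueError("pool_size must be >= n_extra")
    rng = np.random.default_rng(seed)
    pool = _sample_derangement_pool(rng, n, pool_size)
    identity = np.arange(n)
    selected = _greedy_select(pool, identity, n_extra)
    return PermutationSet(
        permutations=[tuple(int(x) for x in p) for p in selected], seed=seed
    )


def exhaustive_permutation_set(n: int, n_extra: int) -> PermutationSet:
    """Oracle variant: greedy selection over the pool of ALL derangements
    of ``0..n-1`` in lexicographic order. Tractable only for tiny ``n``;
    used to cross-check the sampled-pool selector on toy grids."""
    all_der = [p for p in itertools.permutations(range(n)) if all(p[i] != i for i in range(n))]
    pool = np.asarray(all_der, dtype=int)
    selected = _greedy_select(pool, np.arange(n), n_extra)
    return PermutationSet(permutations=[tuple(int(x) for x in p) for p in selected])


# ---------------------------------------------------------------------------
# Puzzle sampling
# ---------------------------------------------------------------------------

@dataclass
class PuzzleSample:
    """One pretext-task example: 9 standardized patches + permutation label."""

    patches: np.ndarray  # (n_patches, patch, patch) float64
    label: int
    source_image_id: str = ""

    def __post_init__(self) -> None:
        if self.patches.ndim != 3:
            raise ValueError("patches must be a (n, h, w) array")


def standardize_patch(patch: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance scaling; a constant patch maps to zeros."""
    patch = np.asarray(patch, dtype=np.float64)
    sd = patch.std()
    if sd == 0:
        return np.zeros_like(patch)
    return (patch - patch.mean()) / sd


def sample_puzzle(image: np.ndarray, perm_label: int, permset: PermutationSet,
                  grid: GridSpec | None = None, seed: int = 0,
                  standardize: bool = True) -> PuzzleSample:
    """Cut a gapped 3x3 puzzle from ``image`` and scramble it.

    The image is tiled into ``grid x grid`` cells; a random
    ``patch_size``-square window is drawn independently inside each cell
    (uniform over the jitter range — these are the random gaps). The
    patches are then reordered so that output slot ``i`` holds the patch
    from grid position ``permset[perm_label][i]``, and each patch is
    standardized independently unless ``standardize=False``.
    """
    grid = grid or GridSpec()
    image = np.asarray(image, dtype=np.float64)
    if image.shape[0] < grid.grid * grid.cell_size or image.shape[1] < grid.grid * grid.cell_size:
        raise ValueError(
            f"image {image.shape} too small for {grid.grid}x{grid.grid} grid "
            f"of {grid.cell_size}px cells"
        )
    if not 0 <= perm_label < len(permset):
        raise ValueError(f"permutation label {perm_label} out of range")
    rng = np.random.default_rng(seed)
    jit = grid.jitter
    in_order = []
    for r in range(grid.grid):
        for c in range(grid.grid):
            dr = int(rng.integers(0, jit + 1)) if jit > 0 else 0
            dc = int(rng.integers(0, jit + 1)) if jit > 0 else 0
            r0 = r * grid.cell_size + dr
            c0 = c * grid.cell_size + dc
            in_order.append(image[r0:r0 + grid.patch_size, c0:c0 + grid.patch_size])
    mapping = permset[perm_label]
    patches = np.stack([in_order[mapping[i]] for i in range(grid.n_patches)])
    if standardize:
        patches = np.stack([standardize_patch(p) for p in patches])
    return PuzzleSample(patches=patches, label=perm_label)
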
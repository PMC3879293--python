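"""Diversity-driven feature-subspace selection.

A repository of feature-index subsets is drawn by *directed random
selection* (a fixed number of indices per channel block, concatenated in
channel order — a plain random subset when the layout is one block), an
MLP classifier is trained per subset, the weakest 70% are pruned, and a
greedy forward search then assembles a committee that minimizes
Kuncheva's non-pairwise inter-rater agreement kappa — lower kappa meaning
more disagreement, i.e. more diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

from .experts import ExpertModel, MLPConfig, train_mlp_expert
from .views import FeatureSpaceView

__all__ = [
    "SubsetRepository",
    "PoolEntry",
    "ClassifierPool",
    "directed_random_subset",
    "build_repository",
    "build_pool",
    "prune_pool",
    "interrater_agreement",
    "forward_search",
    "write_repository",
    "read_repository",
]


@dataclass
class SubsetRepository:
    """Feature-index subsets drawn from a channel-block layout."""

    layout: tuple[tuple[int, int], ...]  # per-channel (start, stop) index ranges
    subsets: list[tuple[int, ...]]
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self):
        hi = max(stop for _, stop in self.layout)
        for s in self.subsets:
            if len(set(s)) != len(s) or min(s) < 0 or max(s) >= hi:
                raise ValueError(f"subset {s} has duplicate or out-of-range indices")


def block_layout(n_channels: int, width: int) -> tuple[tuple[int, int], ...]:
    """Contiguous equal-width channel blocks, e.g. 8 channels x 12 PSD bins."""
    return tuple((c * width, (c + 1) * width) for c in range(n_channels))


def directed_random_subset(layout: Sequence[tuple[int, int]], k_per_channel: int,
                           seed: int) -> tuple[int, ...]:
    """Sample k indices without replacement from each channel block.

    Blocks are concatenated in channel order, so e.g. 6 indices per block
    over 8 blocks of 12 yield a 48-dimensional subset of the 96-dimensional
    space.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out: list[int] = []
    for start, stop in layout:
        width = stop - start
        if not (1 <= k_per_channel <= width):
            raise ValueError(f"k_per_channel={k_per_channel} out of range for a "
                             f"block of width {width}")
        out.extend(sorted(start + rng.choice(width, size=k_per_channel, replace=False)))
    return tuple(out)


def build_repository(layout: Sequence[tuple[int, int]], k_per_channel: int,
                     n_subsets: int, seed: int = 0) -> SubsetRepository:
    seeds = [seed + i for i in range(n_subsets)]
    subsets = [directed_random_subset(layout, k_per_channel, s) for s in seeds]
    return SubsetRepository(tuple(layout), subsets, seeds)


@dataclass
class PoolEntry:
    subset: tuple[int, ...]
    model: ExpertModel | None
    accuracy: float
    correct: np.ndarray  # boolean, per validation sample
    error: str | None = None


@dataclass
class ClassifierPool:
    """Trained classifiers with validation accuracies and correctness vectors."""

    entries: list[PoolEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([e.accuracy for e in self.entries])

    def correctness_matrix(self) -> np.ndarray:
        return np.vstack([e.correct for e in self.entries])


def build_pool(repository: SubsetRepository, train: FeatureSpaceView,
               val: FeatureSpaceView, mlp: MLPConfig | None = None) -> ClassifierPool:
    """Train one classifier per subset; failures are recorded, not fatal."""
    if not repository.subsets:
        raise ValueError("empty subset repository")
    mlp = mlp or MLPConfig()
    entries = []
    crisp_train = [(int(c),) for c in train.labels]
    crisp_val = [(int(c),) for c in val.labels]
    for i, subset in enumerate(repository.subsets):
        cols = list(subset)
        cfg = MLPConfig(**{**mlp.__dict__, "seed": mlp.seed + i})
        try:
            model = train_mlp_expert(train.features[:, cols], crisp_train,
                                     val.features[:, cols], crisp_val, cfg)
            pred = model.predict_labels(val.features[:, cols])
            correct = np.array([p == (int(c),) for p, c in zip(pred, val.labels)])
            entries.append(PoolEntry(subset, model, float(correct.mean()), correct))
        except (FloatingPointError, ValueError) as exc:
            entries.append(PoolEntry(subset, None, 0.0,
                                     np.zeros(len(val), dtype=bool), error=str(exc)))
    return ClassifierPool(entries)


def prune_pool(pool: ClassifierPool, keep_fraction: float = 0.3) -> ClassifierPool:
    """Keep the ceil(keep_fraction * n) most accurate classifiers.

    Ties at the cut are broken toward the lower pool index (stable sort on
    descending accuracy).
    """
    if not pool.entries:
        raise ValueError("empty classifier pool")
    n_keep = ceil(keep_fraction * len(pool))
    order = sorted(range(len(pool)), key=lambda i: (-pool.entries[i].accuracy, i))
    keep = sorted(order[:n_keep])
    return ClassifierPool([pool.entries[i] for i in keep])


def interrater_agreement(correctness: np.ndarray) -> float:
    """Kuncheva's non-pairwise inter-rater agreement kappa.

    ``kappa = 1 - sum_j l_j (L - l_j) / (N L (L-1) pbar (1 - pbar))`` with
    ``l_j`` the number of classifiers correct on sample j and ``pbar`` the
    mean accuracy.  Smaller kappa means better diversity.  When every
    classifier is right (or wrong) everywhere, no disagreement is possible
    and kappa is defined as 1 with a warning.
    """
    M = np.asarray(correctness, dtype=bool)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 1:
        raise ValueError("correctness must be (L >= 2) x (N >= 1)")
    L, N = M.shape
    pbar = M.mean()
    if pbar in (0.0, 1.0):
        warnings.warn("degenerate pool (mean accuracy 0 or 1): kappa defined as 1",
                      stacklevel=2)
        return 1.0
    l = M.sum(axis=0)
    return float(1.0 - (l * (L - l)).sum() / (N * L * (L - 1) * pbar * (1.0 - pbar)))


def forward_search(pool: ClassifierPool, target_size: int) -> list[int]:
    """Greedy diverse-committee selection.

    Starts from the most accurate classifier, then repeatedly adds the
    candidate giving the lowest kappa of the enlarged committee; ties break
    toward higher accuracy, then lower pool index.
    """
    n = len(pool)
    if not (1 <= target_size <= n):
        raise ValueError(f"target_size must be in [1, {n}], got {target_size}")
    accs = pool.accuracies
    selected = [int(np.argmax(accs))]  # argmax ties -> lowest index
    M = pool.correctness_matrix()
    while len(selected) < target_size:
        best = None
        for i in range(n):
            if i in selected:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kappa = interrater_agreement(M[selected + [i]])
            key = (kappa, -accs[i], i)
            if best is None or key < best[0]:
                best = (key, i)
        selected.append(best[1])
    return selected


# ---------------------------------------------------------------------------
# TSV persistence: subset id -> comma-separated indices


def write_repository(repo: SubsetRepository, path) -> None:
    with open(path, "w") as fh:
        fh.write("# layout\t" + ";".join(f"{a}:{b}" for a, b in repo.layout) + "\n")
        fh.write("subset_id\tindices\n")
        for i, s in enumerate(repo.subsets):
            fh.write(f"{i}\t" + ",".join(str(j) for j in s) + "\n")


def read_repository(path) -> SubsetRepository:
    with open(path) as fh:
        head = fh.readline()
        layout = tuple(tuple(int(v) for v in tok.split(":"))
                       for tok in head.split("\t")[1].strip().split(";"))
        fh.readline()
        subsets = []
        for line in fh:
            if not line.strip():
                continue
            _, idx = line.rstrip("\n").split("\t")
            subsets.append(tuple(int(v) for v in idx.split(",")))
    return SubsetRepository(layout, subsets)
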
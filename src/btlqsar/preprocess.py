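"""Descriptor treatment and dataset splitting.

The canonical preprocessing order for a descriptor pool is fixed:

1. drop zero-variance columns,
2. drop one member of every intercorrelated pair (|Pearson r| > 0.9),
3. optionally reduce the pool by descriptor similarity on a Kohonen map,
4. autoscale on the training partition (zero mean, unit population SD).

Re-running the filters on their own output is the identity.  Splitting into
training/validation (75/25) or training/test/validation (60/25/15) subsets
is supported either stratified-random or via a self-organizing map of the
compounds (coverage-preserving: held-out compounds are drawn per occupied
neuron, farthest-from-centroid first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import som
from .data import (
    ACTIVE,
    ACTIVITY_THRESHOLD,
    ActivityTable,
    DescriptorMatrix,
    ScalingParams,
    classify_by_threshold,
)

__all__ = [
    "autoscale",
    "drop_zero_variance",
    "drop_intercorrelated",
    "kohonen_reduce",
    "split_dataset",
    "classify_by_threshold",
    "DatasetSplit",
]

ZERO_VARIANCE_TOL = 1e-12


def autoscale(
    X: DescriptorMatrix, params: ScalingParams | None = None
) -> tuple[DescriptorMatrix, ScalingParams]:
    """Standardize columns to zero mean and unit (population) SD.

    With ``params`` absent the statistics are fitted on ``X`` (a training
    partition); with ``params`` given they are applied as-is, which is how
    test and screening compounds are brought into the training scale.
    """
    if params is None:
        sd = X.values.std(axis=0, ddof=0)
        if np.any(sd <= ZERO_VARIANCE_TOL):
            bad = [X.names[j] for j in np.nonzero(sd <= ZERO_VARIANCE_TOL)[0]]
            raise ValueError(
                f"zero-variance columns {bad}: run drop_zero_variance first"
            )
        params = ScalingParams(list(X.names), X.values.mean(axis=0), sd)
    sub = X.select_descriptors(params.names)
    scaled = (sub.values - params.mean) / params.sd
    return DescriptorMatrix(list(X.ids), list(params.names), scaled), params


def drop_zero_variance(
    X: DescriptorMatrix, tol: float = ZERO_VARIANCE_TOL
) -> DescriptorMatrix:
    """Remove (near-)constant columns; survivor order is preserved."""
    var = X.values.var(axis=0, ddof=0)
    keep = [n for n, v in zip(X.names, var) if v > tol]
    if not keep:
        raise ValueError("all descriptor columns are constant")
    return X.select_descriptors(keep)


def drop_intercorrelated(X: DescriptorMatrix, threshold: float = 0.9) -> DescriptorMatrix:
    """Greedy intercorrelation filter.

    Scanning columns left to right, a column is dropped as soon as its
    absolute Pearson correlation with an already-kept column exceeds the
    threshold — i.e. of any offending pair the *earlier* column survives.
    Survivors are pairwise |r| ≤ threshold.
    """
    if X.n_descriptors < 2:
        return X
    corr = np.corrcoef(X.values, rowvar=False)
    keep: list[int] = []
    for j in range(X.n_descriptors):
        if all(abs(corr[j, k]) <= threshold for k in keep):
            keep.append(j)
    return X.select_descriptors([X.names[j] for j in keep])


def kohonen_reduce(
    X: DescriptorMatrix,
    grid: tuple[int, int] | None = None,
    target_pool: int | None = None,
    seed: int = 0,
    epochs: int = 50,
) -> list[str]:
    """Similarity-based descriptor reduction on a Kohonen map.

    The *transposed* matrix is mapped (descriptors as objects described by
    their values across compounds); similar descriptors share a winning
    neuron, and from each occupied neuron only the descriptor closest to the
    neuron's weight vector is retained.  The retained pool size equals the
    number of occupied neurons (grid area is its upper bound).

    Either an explicit ``grid`` or a ``target_pool`` size may be given; with
    the latter, the smallest near-square grid with at least that many neurons
    is used.
    """
    if grid is None:
        if target_pool is None:
            target_pool = X.n_descriptors
        r = int(np.floor(np.sqrt(target_pool)))
        c = int(np.ceil(target_pool / max(r, 1)))
        grid = (max(r, 1), max(c, 1))
    rows, cols = grid
    if rows * cols > X.n_descriptors:
        import warnings

        warnings.warn(
            "Kohonen-reduction grid has more neurons than descriptors; "
            "the result may equal the input pool",
            stacklevel=2,
        )
    # standardize descriptor profiles so the map distances are comparable
    T = X.values.T
    mu = T.mean(axis=1, keepdims=True)
    sd = T.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    T = (T - mu) / sd

    W, _, _ = som.train_som(T, rows, cols, epochs, 0.5, 0.01, seed)
    winners, dists = som.map_to_winners(W, T)
    retained: list[str] = []
    for neuron in np.unique(winners):
        members = np.nonzero(winners == neuron)[0]
        best = members[np.argmin(dists[members])]
        retained.append(X.names[best])
    # report in the original column order for determinism
    order = {n: j for j, n in enumerate(X.names)}
    return sorted(retained, key=order.__getitem__)


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive partition of a compound set."""

    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str] | None = None
    fractions: tuple[float, ...] = ()
    method: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [self.train_ids, self.validation_ids] + (
            [self.test_ids] if self.test_ids is not None else []
        )
        flat = [i for p in parts for i in p]
        if len(flat) != len(set(flat)):
            raise ValueError("split partitions overlap")

    @property
    def all_ids(self) -> list[str]:
        out = list(self.train_ids)
        if self.test_ids is not None:
            out += list(self.test_ids)
        return out + list(self.validation_ids)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "train_ids": self.train_ids,
                "test_ids": self.test_ids,
                "validation_ids": self.validation_ids,
                "fractions": list(self.fractions),
                "method": self.method,
                "seed": self.seed,
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DatasetSplit":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(
            train_ids=list(d["train_ids"]),
            validation_ids=list(d["validation_ids"]),
            test_ids=None if d.get("test_ids") is None else list(d["test_ids"]),
            fractions=tuple(d.get("fractions", ())),
            method=d.get("method", "random"),
            seed=int(d.get("seed", 0)),
        )


def _part_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    sizes = [int(round(f * n)) for f in fractions[1:]]
    sizes.insert(0, n - sum(sizes))
    if min(sizes) <= 0:
        raise ValueError(f"fractions {fractions} give an empty partition at n={n}")
    return sizes


def split_dataset(
    X: DescriptorMatrix,
    y: ActivityTable,
    fractions: tuple[float, ...] = (0.75, 0.25),
    method: str = "random",
    seed: int = 0,
) -> DatasetSplit:
    """Partition compounds into train/validation or train/test/validation.

    ``fractions`` are (train, validation) or (train, test, validation) and
    must sum to 1.  Method "random" stratifies by class; method "som" maps
    the compounds onto a self-organizing map and draws held-out compounds
    per occupied neuron (largest neurons first, farthest compound from the
    neuron's weight vector), which preserves coverage of the descriptor
    space in the training partition.
    """
    if len(fractions) not in (2, 3):
        raise ValueError("fractions must have two or three entries")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if X.ids != y.ids:
        raise ValueError("descriptor and activity tables list different compounds")
    n = X.n_compounds
    sizes = _part_sizes(n, fractions)  # [train, (test,) validation]
    rng = np.random.default_rng(seed)

    if method == "random":
        parts = _stratified_parts(y, sizes, rng)
    elif method == "som":
        parts = _som_parts(X, sizes, seed)
    else:
        raise ValueError(f"unknown split method {method!r}")

    train_ids = [X.ids[i] for i in sorted(parts[0])]
    if len(sizes) == 3:
        test_ids = [X.ids[i] for i in sorted(parts[1])]
        val_ids = [X.ids[i] for i in sorted(parts[2])]
    else:
        test_ids = None
        val_ids = [X.ids[i] for i in sorted(parts[1])]

    split = DatasetSplit(train_ids, val_ids, test_ids, tuple(fractions), method, seed)
    train_labels = {y.labels[X.ids.index(i)] for i in split.train_ids}
    if y.labels is not None and len(set(y.labels)) > 1 and len(train_labels) < 2:
        raise ValueError("a class is absent from the training partition")
    return split


def _stratified_parts(y: ActivityTable, sizes: list[int], rng) -> list[list[int]]:
    """Class-stratified random partition into len(sizes) groups."""
    n = len(y.ids)
    parts: list[list[int]] = [[] for _ in sizes]
    classes = sorted(set(y.labels))
    # shuffle within class, then deal proportionally
    remaining_by_class = {}
    for c in classes:
        idx = [i for i, lab in enumerate(y.labels) if lab == c]
        rng.shuffle(idx)
        remaining_by_class[c] = idx
    quotas = []
    for gi, size in enumerate(sizes):
        quota = {}
        for c in classes:
            quota[c] = size * len(remaining_by_class[c]) / n
        quotas.append(quota)
    for c in classes:
        idx = remaining_by_class[c]
        # largest-remainder apportionment of this class across groups
        raw = [quotas[g][c] for g in range(len(sizes))]
        base = [int(np.floor(r)) for r in raw]
        short = len(idx) - sum(base)
        order = np.argsort([b - r for b, r in zip(base, raw)])  # biggest remainder first
        for g in order[:short]:
            base[g] += 1
        pos = 0
        for g, b in enumerate(base):
            parts[g].extend(idx[pos : pos + b])
            pos += b
    # fix any rounding drift against the requested sizes
    _rebalance(parts, sizes, rng)
    return parts


def _rebalance(parts: list[list[int]], sizes: list[int], rng) -> None:
    for g in range(len(parts)):
        while len(parts[g]) > sizes[g]:
            donor = parts[g].pop(int(rng.integers(len(parts[g]))))
            target = min(range(len(parts)), key=lambda t: len(parts[t]) - sizes[t])
            parts[target].append(donor)


def _som_parts(X: DescriptorMatrix, sizes: list[int], seed: int) -> list[list[int]]:
    """Coverage-preserving split via a compound-space Kohonen map."""
    n = X.n_compounds
    g = max(2, int(np.ceil(np.sqrt(n / 2))))
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X.values - mu) / sd
    W, _, _ = som.train_som(Xs, g, g, 30, 0.5, 0.01, seed)
    winners, dists = som.map_to_winners(W, Xs)

    # held-out pools (every group after the first) are drawn neuron by
    # neuron, biggest occupancy first, taking the compound farthest from the
    # neuron weight vector; this keeps each neuron represented in training
    neurons = sorted(
        np.unique(winners), key=lambda nn: (-np.sum(winners == nn), nn)
    )
    members = {
        nn: sorted(np.nonzero(winners == nn)[0], key=lambda i: -dists[i])
        for nn in neurons
    }
    n_heldout = n - sizes[0]
    heldout: list[int] = []
    while len(heldout) < n_heldout:
        for nn in neurons:
            if members[nn] and len(heldout) < n_heldout:
                heldout.append(members[nn].pop(0))
    train = [i for i in range(n) if i not in set(heldout)]
    parts = [train]
    pos = 0
    for size in sizes[1:]:
        parts.append(heldout[pos : pos + size])
        pos += size
    return parts
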
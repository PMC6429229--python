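"""Genetic-algorithm descriptor-subset selection with cross-validated fitness.

Chromosomes are binary masks over the descriptor pool.  Fitness of a mask is
the mean held-out score of the chosen model type under k-fold
cross-validation — standard accuracy for classification, R² (squared Pearson
correlation) for regression.  The search uses tournament selection (size 2),
uniform crossover, per-bit mutation, random add/remove repair to the subset
size bounds, and elitism, which makes the best-ever fitness monotone
non-decreasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import cpann as _cpann
from . import mlr as _mlr
from .data import ACTIVE, DescriptorMatrix


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 24
    generations: int = 15
    crossover_rate: float = 0.9
    mutation_rate: float = 0.02
    elitism: int = 2
    subset_min: int = 3
    subset_max: int = 15
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.subset_min < 1 or self.subset_max < self.subset_min:
            raise ValueError("need 1 <= subset_min <= subset_max")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("need 0 <= elitism < population_size")
        if self.generations < 0 or self.population_size < 2:
            raise ValueError("need generations >= 0 and population_size >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class GaResult:
    best_mask: np.ndarray
    best_fitness: float
    fitness_history: list[float]
    evaluated_count: int
    descriptor_names: list[str]
    config: GaConfig

    @property
    def selected_names(self) -> list[str]:
        return [n for n, b in zip(self.descriptor_names, self.best_mask) if b]

    def to_json(self, path: str | Path | None = None) -> str:
        from dataclasses import asdict

        text = json.dumps(
            {
                "best_mask": [int(b) for b in self.best_mask],
                "best_fitness": self.best_fitness,
                "fitness_history": self.fitness_history,
                "evaluated_count": self.evaluated_count,
                "descriptor_names": self.descriptor_names,
                "config": asdict(self.config),
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _fold_indices(y: np.ndarray, folds: int, seed: int, stratify: bool):
    """Seeded k-fold split; for stratified folds, retry with a seed offset if
    any training fold misses a class (error after 5 attempts)."""
    n = len(y)
    for attempt in range(5):
        rs = seed + attempt
        if stratify:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            pairs = list(splitter.split(np.zeros(n), y > 0.5))
            if all(len(np.unique(y[tr] > 0.5)) == 2 for tr, _ in pairs):
                return pairs
        else:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=rs)
            return list(splitter.split(np.zeros(n)))
    raise ValueError("could not build stratified folds containing both classes")


def cv_fitness(
    mask: np.ndarray,
    X: DescriptorMatrix,
    y: np.ndarray,
    model_type: str = "mlr",
    folds: int = 5,
    seed: int = 0,
    task: str = "classification",
    cpann_config: "_cpann.CpannConfig | None" = None,
) -> float:
    """Mean held-out score of the masked descriptor subset.

    Classification scores standard accuracy of 0/1 predictions; regression
    scores the squared Pearson correlation of held-out predictions.  A fold
    whose model cannot be fitted (e.g. rank-deficient MLR design) scores 0.
    Deterministic for a fixed seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != X.n_descriptors:
        raise ValueError("mask length does not match descriptor pool")
    if mask.sum() < 1:
        raise ValueError("mask selects no descriptors")
    if model_type not in {"cpann", "mlr"}:
        raise ValueError(f"unknown model_type {model_type!r}")
    y = np.asarray(y, dtype=float).ravel()
    names = [n for n, b in zip(X.names, mask) if b]
    Xsub = X.select_descriptors(names)

    pairs = _fold_indices(y, folds, seed, stratify=(task == "classification"))
    scores = []
    for k, (tr, te) in enumerate(pairs):
        Xtr = DescriptorMatrix([Xsub.ids[i] for i in tr], names, Xsub.values[tr])
        Xte = DescriptorMatrix([Xsub.ids[i] for i in te], names, Xsub.values[te])
        try:
            if model_type == "mlr":
                model = _mlr.fit_mlr(Xtr, y[tr])
                cut = 0.5 if task == "classification" else None
                pred = _mlr.predict_mlr(model, Xte, classification_cut=cut)["raw"].to_numpy()
            else:
                cfg = cpann_config or _cpann.CpannConfig(
                    grid_rows=7, grid_cols=7, epochs=40, seed=seed
                )
                model = _cpann.train_cpann(Xtr, y[tr], cfg, task=task)
                pred = _cpann.predict_cpann(model, Xte)["raw"].to_numpy()
        except (ValueError, np.linalg.LinAlgError):
            scores.append(0.0)
            continue
        if task == "classification":
            scores.append(float(np.mean((pred >= 0.5) == (y[te] >= 0.5))))
        else:
            if np.std(pred) == 0 or np.std(y[te]) == 0:
                scores.append(0.0)
            else:
                scores.append(float(np.corrcoef(pred, y[te])[0, 1] ** 2))
    return float(np.mean(scores))


def _repair(mask: np.ndarray, lo: int, hi: int, rng) -> np.ndarray:
    """Random add/remove until the popcount lies within [lo, hi]."""
    mask = mask.copy()
    on = np.nonzero(mask)[0]
    off = np.nonzero(~mask)[0]
    if on.size > hi:
        drop = rng.choice(on, size=on.size - hi, replace=False)
        mask[drop] = False
    elif on.size < lo:
        add = rng.choice(off, size=lo - on.size, replace=False)
        mask[add] = True
    return mask


def ga_search(
    X: DescriptorMatrix,
    y: np.ndarray,
    model_type: str = "mlr",
    ga: GaConfig | None = None,
    task: str = "classification",
    cpann_config: "_cpann.CpannConfig | None" = None,
) -> GaResult:
    """Evolve descriptor masks toward maximal cross-validated fitness.

    With ``generations=0`` the result is simply the best of the random
    initial population.  Fitness evaluations are cached by mask, so
    ``evaluated_count`` counts distinct masks scored.
    """
    if ga is None:
        ga = GaConfig()
    m = X.n_descriptors
    if m < ga.subset_min:
        raise ValueError(
            f"descriptor pool ({m}) smaller than subset_min ({ga.subset_min})"
        )
    hi = min(ga.subset_max, m)
    rng = np.random.default_rng(ga.seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = cv_fitness(
                mask, X, y, model_type, ga.cv_folds, ga.seed, task, cpann_config
            )
        return cache[key]

    def random_mask() -> np.ndarray:
        size = int(rng.integers(ga.subset_min, hi + 1))
        mask = np.zeros(m, dtype=bool)
        mask[rng.choice(m, size=size, replace=False)] = True
        return mask

    pop = [random_mask() for _ in range(ga.population_size)]
    fits = [fitness(mk) for mk in pop]
    best_i = int(np.argmax(fits))
    best_mask, best_fit = pop[best_i].copy(), fits[best_i]
    history = [best_fit]

    for _ in range(ga.generations):
        order = np.argsort(fits)[::-1]
        newpop = [pop[i].copy() for i in order[: ga.elitism]]
        while len(newpop) < ga.population_size:
            # tournament selection, size 2
            parents = []
            for _k in range(2):
                a, b = rng.integers(ga.population_size, size=2)
                parents.append(pop[a] if fits[a] >= fits[b] else pop[b])
            if rng.random() < ga.crossover_rate:
                swap = rng.random(m) < 0.5
                child = np.where(swap, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(m) < ga.mutation_rate
            child = child ^ flip
            if not child.any():
                child[rng.integers(m)] = True
            child = _repair(child, ga.subset_min, hi, rng)
            newpop.append(child)
        pop = newpop
        fits = [fitness(mk) for mk in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_mask = pop[gen_best].copy()
        history.append(best_fit)

    return GaResult(
        best_mask=best_mask,
        best_fitness=float(best_fit),
        fitness_history=[float(f) for f in history],
        evaluated_count=len(cache),
        descriptor_names=list(X.names),
        config=ga,
    )
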
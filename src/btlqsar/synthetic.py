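"""Synthetic descriptor/activity data with the statistical shape of the
bilitranslocase (BTL) modelling set.

Real BTL modelling data consist of ~120 aromatic compounds described by a few
dozen autoscaled molecular descriptors from commercial software, with a
continuous inhibition activity pKi (Ki in mmol/L) and a binary class split of
50 active / 70 inactive at pKi > 1.3.  The generator emulates exactly that
statistical structure — not molecules: standard-normal descriptor marginals,
a planted linear plus mildly nonlinear structure–activity signal on a known
descriptor subset, Gaussian activity noise, and blocks of near-duplicate
columns (pairwise |r| > 0.9) so the intercorrelation filter always has work
to do.  The planted truth (informative descriptor names, coefficients,
intercept) is kept on the dataset object so downstream models can be scored
against a known ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import ACTIVITY_THRESHOLD, ActivityTable, DescriptorMatrix

#: Within-block perturbation SD; gives pairwise r ≈ 0.98 > 0.9 between
#: members of a correlation block after re-standardization.
_BLOCK_NOISE_SD = 0.15


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic BTL-like dataset.

    Defaults mirror the modelling-set composition: n=120 compounds with a
    50/120 active fraction at the pKi > 1.3 threshold, and a descriptor pool
    of 78 columns of which 8 carry signal.
    """

    n_compounds: int = 120
    n_descriptors: int = 78
    n_informative: int = 8
    active_fraction: float = 50 / 120
    activity_threshold: float = ACTIVITY_THRESHOLD
    noise_sd: float = 0.3
    nonlinearity_weight: float = 0.3
    correlation_block_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0 or self.n_descriptors <= 0 or self.n_informative <= 0:
            raise ValueError("counts must be positive")
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative cannot exceed n_descriptors")
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.nonlinearity_weight <= 1:
            raise ValueError("nonlinearity_weight must lie in [0, 1]")
        if self.correlation_block_size < 1:
            raise ValueError("correlation_block_size must be >= 1")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    descriptors: DescriptorMatrix
    activities: ActivityTable
    true_support: list[str]
    true_coefficients: np.ndarray
    true_intercept: float
    nonlinearity_weight: float
    correlation_blocks: list[list[str]]
    spec: SyntheticSpec

    def write_truth_json(self, path: str | Path) -> None:
        """Persist the planted truth as a small JSON sidecar (test oracle)."""
        payload = {
            "true_support": self.true_support,
            "true_coefficients": self.true_coefficients.tolist(),
            "true_intercept": self.true_intercept,
            "nonlinearity_weight": self.nonlinearity_weight,
            "correlation_blocks": self.correlation_blocks,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _column_layout(spec: SyntheticSpec) -> tuple[list[list[int]], int]:
    """Partition noise columns into correlation blocks of the requested size.

    Returns (blocks as column-index lists, number of independent base draws
    needed).  Informative columns are always independent; trailing noise
    columns that do not fill a whole block stay independent too.
    """
    n_noise = spec.n_descriptors - spec.n_informative
    bs = spec.correlation_block_size
    n_blocks = n_noise // bs if bs >= 2 else 0
    blocks = []
    col = spec.n_informative
    for _ in range(n_blocks):
        blocks.append(list(range(col, col + bs)))
        col += bs
    return blocks, spec.n_descriptors


def generate_btl_like_dataset(spec: SyntheticSpec | None = None, **kwargs) -> SyntheticDataset:
    """Generate a BTL-like descriptor/activity dataset.

    The continuous activity is a linear combination of the informative
    columns plus a pairwise-product term (weighted by
    ``nonlinearity_weight``) plus Gaussian noise; the intercept is then
    calibrated by a quantile shift so the realized active/inactive split
    matches ``active_fraction`` to within one compound, without touching the
    descriptor distribution.  Deterministic for a fixed seed.
    """
    if spec is None:
        spec = SyntheticSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SyntheticSpec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_compounds, spec.n_descriptors

    blocks, _ = _column_layout(spec)
    in_block = {c for b in blocks for c in b}

    X = np.empty((n, m))
    # independent standard-normal columns
    for j in range(m):
        if j not in in_block:
            X[:, j] = rng.standard_normal(n)
    # correlation blocks: shared base + small perturbation, re-standardized
    # so the marginal stays (approximately) standard normal
    norm = math.sqrt(1.0 + _BLOCK_NOISE_SD**2)
    for block in blocks:
        base = rng.standard_normal(n)
        for j in block:
            X[:, j] = (base + _BLOCK_NOISE_SD * rng.standard_normal(n)) / norm

    names = [f"MD{j + 1:03d}" for j in range(m)]
    ids = [f"C{i + 1:03d}" for i in range(n)]

    # planted signal: coefficients of magnitude in [0.5, 1.5] with random sign
    k = spec.n_informative
    beta = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
    y = X[:, :k] @ beta
    if k >= 2:
        y = y + spec.nonlinearity_weight * X[:, 0] * X[:, 1]
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)

    # quantile-shift the intercept so that exactly round(f*n) compounds
    # (within +-1) exceed the activity threshold
    n_active = int(round(spec.active_fraction * n))
    n_active = min(max(n_active, 1), n - 1)
    order = np.sort(y)[::-1]
    cut = (order[n_active - 1] + order[n_active]) / 2.0
    intercept = spec.activity_threshold - cut
    pki = y + intercept

    descriptors = DescriptorMatrix(ids, names, X)
    activities = ActivityTable(ids, pki, threshold=spec.activity_threshold)
    return SyntheticDataset(
        descriptors=descriptors,
        activities=activities,
        true_support=names[:k],
        true_coefficients=beta,
        true_intercept=intercept,
        nonlinearity_weight=spec.nonlinearity_weight,
        correlation_blocks=[[names[c] for c in b] for b in blocks],
        spec=spec,
    )


def generate_screening_set(n: int, template: SyntheticDataset, seed: int) -> DescriptorMatrix:
    """Draw ``n`` new compounds from the template's descriptor distribution.

    Reproduces the generating moments and correlation-block structure of the
    template dataset (same column names), with no activity column — the role
    of an untested screening library.  Default library size in the study
    design is 300.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    spec = template.spec
    rng = np.random.default_rng(seed)
    m = spec.n_descriptors
    name_to_col = {nm: j for j, nm in enumerate(template.descriptors.names)}
    block_cols = [[name_to_col[nm] for nm in b] for b in template.correlation_blocks]
    in_block = {c for b in block_cols for c in b}

    X = np.empty((n, m))
    for j in range(m):
        if j not in in_block:
            X[:, j] = rng.standard_normal(n)
    norm = math.sqrt(1.0 + _BLOCK_NOISE_SD**2)
    for block in block_cols:
        base = rng.standard_normal(n)
        for j in block:
            X[:, j] = (base + _BLOCK_NOISE_SD * rng.standard_normal(n)) / norm

    ids = [f"S{i + 1:04d}" for i in range(n)]
    return DescriptorMatrix(ids, list(template.descriptors.names), X)


def true_pki(dataset: SyntheticDataset, X: DescriptorMatrix) -> np.ndarray:
    """Noise-free planted activity of arbitrary compounds (oracle helper)."""
    sub = X.select_descriptors(dataset.true_support)
    y = sub.values @ dataset.true_coefficients
    if len(dataset.true_support) >= 2:
        y = y + dataset.nonlinearity_weight * sub.values[:, 0] * sub.values[:, 1]
    return y + dataset.true_intercept
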
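"""Kohonen self-organizing map core.

This is the shared engine behind the counter-propagation network (supervised
output layer), the descriptor-similarity reduction step and the SOM-based
dataset split.  A rectangular ``rows × cols`` grid of neurons is trained by
competitive learning: for each input vector the closest neuron (Euclidean
distance) wins and the weights of the winner and its grid neighbourhood are
pulled toward the input.  The learning rate decays linearly from ``eta_max``
to ``eta_min`` over the epochs, and the triangular neighbourhood shrinks
linearly from the full grid radius to winner-only.
"""

from __future__ import annotations

import numpy as np


def grid_coordinates(rows: int, cols: int) -> np.ndarray:
    """(rows*cols, 2) array of (row, col) positions in row-major order."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def grid_distances(rows: int, cols: int, toroidal: bool = False) -> np.ndarray:
    """Pairwise Chebyshev distances between neuron grid positions."""
    pos = grid_coordinates(rows, cols)
    d = np.abs(pos[:, None, :] - pos[None, :, :])
    if toroidal:
        wrap = np.array([rows, cols])
        d = np.minimum(d, wrap - d)
    return d.max(axis=2)


def find_winner(weights: np.ndarray, x: np.ndarray) -> tuple[int, float]:
    """Index and Euclidean distance of the neuron closest to ``x``.

    Ties are broken toward the lowest row-major index (the first minimum).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (weights.shape[1],):
        raise ValueError(f"query has dimension {x.shape}, map expects {weights.shape[1]}")
    d2 = np.einsum("ij,ij->i", weights - x, weights - x)
    j = int(np.argmin(d2))
    return j, float(np.sqrt(d2[j]))


def map_to_winners(weights: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Winning neuron index and distance for every row of ``X`` at once."""
    X = np.asarray(X, dtype=float)
    # ||x - w||^2 = ||x||^2 - 2 x.w + ||w||^2, computed blockwise
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ weights.T
        + (weights**2).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    winners = np.argmin(d2, axis=1)
    dists = np.sqrt(d2[np.arange(len(X)), winners])
    return winners, dists


def train_som(
    X: np.ndarray,
    rows: int,
    cols: int,
    epochs: int,
    eta_max: float,
    eta_min: float,
    seed: int,
    toroidal: bool = False,
    targets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, list[float]]:
    """Train a Kohonen map, optionally counter-propagating an output layer.

    Parameters
    ----------
    X
        Training vectors, shape (n, m); expected standardized.
    targets
        Optional (n, t) target matrix.  When given, an output layer of the
        same grid is updated toward the targets of each winning neuron's
        neighbourhood (the counter-propagation rule), and the per-epoch
        training RMSE of the output layer is recorded.

    Returns
    -------
    kohonen_weights : (rows*cols, m)
    output_weights : (rows*cols, t) or None
    rmse_history : per-epoch training RMSE (empty when no targets)
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("training descriptors contain non-finite values")
    n, m = X.shape
    if n == 0:
        raise ValueError("empty training set")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if not (0 < eta_min <= eta_max <= 1):
        raise ValueError("need 0 < eta_min <= eta_max <= 1")

    rng = np.random.default_rng(seed)
    g = rows * cols
    W = rng.uniform(-0.1, 0.1, size=(g, m))
    U = None
    if targets is not None:
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        if targets.shape[0] == 1 and n != 1:
            targets = targets.T
        if targets.shape[0] != n:
            raise ValueError("targets not aligned with training vectors")
        U = rng.uniform(-0.1, 0.1, size=(g, targets.shape[1]))

    gdist = grid_distances(rows, cols, toroidal)
    r0 = max(rows, cols) - 1  # full grid radius at epoch 0
    # the neighbourhood collapses to winner-only at this fraction of the run;
    # the remaining epochs fine-tune individual neurons, which spreads the
    # map over far more neurons than a radius that only reaches zero at the
    # very last epoch
    shrink_frac = 2.0 / 3.0
    rmse_history: list[float] = []

    for epoch in range(epochs):
        frac = epoch / (epochs - 1) if epochs > 1 else 0.0
        eta = eta_max - (eta_max - eta_min) * frac
        radius = r0 * max(1.0 - frac / shrink_frac, 0.0)
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            j, _ = find_winner(W, x)
            # triangular neighbourhood: 1 at the winner, linearly down to 0
            # at grid distance radius+1
            a = 1.0 - gdist[j] / (radius + 1.0)
            np.maximum(a, 0.0, out=a)
            active = np.nonzero(a)[0]
            coef = (eta * a[active])[:, None]
            W[active] += coef * (x - W[active])
            if U is not None:
                U[active] += coef * (targets[i] - U[active])
        if U is not None:
            winners, _ = map_to_winners(W, X)
            pred = U[winners]
            rmse_history.append(float(np.sqrt(np.mean((pred - targets) ** 2))))

    return W, U, rmse_history
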
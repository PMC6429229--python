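"""Counter-propagation artificial neural network (CP-ANN) models.

A CP-ANN couples a Kohonen self-organizing map (trained on the descriptor
vectors) with an output layer of the same grid whose weights are pulled
toward the targets of the compounds winning each neuron.  Prediction is a
lookup: a query compound is scaled with the training statistics, its winning
neuron found by Euclidean distance, and the neuron's output weight read off —
a class score (cut at 0.5, boundary assigned active) for classification or a
pKi value for regression.

The applicability domain is gated by ED_crt, the maximal Euclidean distance
of any *training* compound to its winning neuron on the final map: a query
whose winner distance exceeds ED_crt falls outside the model's chemical
space and is flagged out-of-domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ACTIVE, INACTIVE, DescriptorMatrix, ScalingParams
from . import som

FORMAT_TAG = "btlqsar-cpann"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class CpannConfig:
    """CP-ANN hyperparameters.

    A 10×10 grid is the default for training sets of ~90–120 compounds
    (neuron count near compound count); learning rate decays linearly from
    ``eta_max`` to ``eta_min``; the triangular neighbourhood shrinks from the
    full grid radius to winner-only over the epochs.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    epochs: int = 100
    eta_max: float = 0.5
    eta_min: float = 0.01
    neighborhood: str = "triangular"
    toroidal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.eta_min <= self.eta_max <= 1):
            raise ValueError("need 0 < eta_min <= eta_max <= 1")
        if self.neighborhood != "triangular":
            raise ValueError("only the triangular neighbourhood is implemented")


@dataclass
class CpannModel:
    kohonen_weights: np.ndarray  # (grid, m)
    output_weights: np.ndarray  # (grid, 1)
    descriptor_names: list[str]
    scaling: ScalingParams
    ed_crt: float
    task: str  # "classification" | "regression"
    config: CpannConfig
    rmse_history: list[float] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.kohonen_weights.shape[0]

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": FORMAT_TAG,
            "version": FORMAT_VERSION,
            "task": self.task,
            "descriptor_names": self.descriptor_names,
            "config": asdict(self.config),
            "scaling": self.scaling.to_dict(),
            "ed_crt": self.ed_crt,
            "kohonen_weights": self.kohonen_weights.ravel().tolist(),
            "output_weights": self.output_weights.ravel().tolist(),
            "rmse_history": self.rmse_history,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CpannModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        if d.get("format") != FORMAT_TAG:
            raise ValueError(f"not a CP-ANN model file (format={d.get('format')!r})")
        cfg = CpannConfig(**d["config"])
        g = cfg.grid_rows * cfg.grid_cols
        m = len(d["descriptor_names"])
        return cls(
            kohonen_weights=np.asarray(d["kohonen_weights"]).reshape(g, m),
            output_weights=np.asarray(d["output_weights"]).reshape(g, -1),
            descriptor_names=list(d["descriptor_names"]),
            scaling=ScalingParams.from_dict(d["scaling"]),
            ed_crt=float(d["ed_crt"]),
            task=d["task"],
            config=cfg,
            rmse_history=list(d.get("rmse_history", [])),
        )


def _scale(model_scaling: ScalingParams, X: DescriptorMatrix, names: list[str]) -> np.ndarray:
    sub = X.select_descriptors(names)
    return (sub.values - model_scaling.mean) / model_scaling.sd


def train_cpann(
    X: DescriptorMatrix,
    y: np.ndarray,
    config: CpannConfig | None = None,
    task: str = "classification",
) -> CpannModel:
    """Train a counter-propagation network.

    ``y`` is a 0/1 class encoding (1=active) for classification or pKi values
    for regression.  Scaling statistics are fitted on the training matrix and
    stored on the model; prediction inputs are scaled with them, so the model
    is self-contained.
    """
    if config is None:
        config = CpannConfig()
    if task not in {"classification", "regression"}:
        raise ValueError(f"unknown task {task!r}")
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != X.n_compounds:
        raise ValueError("targets not aligned with descriptor rows")
    if X.n_compounds == 0:
        raise ValueError("empty training set")
    if not np.all(np.isfinite(X.values)):
        raise ValueError("descriptor matrix contains non-finite values")

    sd = X.values.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = [X.names[j] for j in np.nonzero(sd <= 0)[0]]
        raise ValueError(f"zero-variance descriptors {bad}; filter before training")
    scaling = ScalingParams(list(X.names), X.values.mean(axis=0), sd)
    Xs = (X.values - scaling.mean) / scaling.sd

    W, U, history = som.train_som(
        Xs,
        config.grid_rows,
        config.grid_cols,
        config.epochs,
        config.eta_max,
        config.eta_min,
        config.seed,
        toroidal=config.toroidal,
        targets=y[:, None],
    )
    _, dists = som.map_to_winners(W, Xs)
    return CpannModel(
        kohonen_weights=W,
        output_weights=U,
        descriptor_names=list(X.names),
        scaling=scaling,
        ed_crt=float(dists.max()),
        task=task,
        config=config,
        rmse_history=history,
    )


def find_winner(model: CpannModel, x: np.ndarray) -> tuple[int, float]:
    """Winning neuron (lowest row-major index on ties) and its distance.

    ``x`` must already be in the model's scaled descriptor space.
    """
    return som.find_winner(model.kohonen_weights, x)


def predict_cpann(model: CpannModel, X: DescriptorMatrix) -> pd.DataFrame:
    """Per-compound raw output, prediction and applicability-domain flag.

    Returns a frame indexed by compound id with columns ``raw`` (winning
    neuron's output weight), ``distance``, ``ad_flag`` (distance ≤ ED_crt)
    and either ``label`` (classification, cut 0.5 with the boundary active)
    or ``pKi`` (regression).
    """
    Xs = _scale(model.scaling, X, model.descriptor_names)
    winners, dists = som.map_to_winners(model.kohonen_weights, Xs)
    raw = model.output_weights[winners, 0]
    out = pd.DataFrame(
        {"raw": raw, "distance": dists, "ad_flag": dists <= model.ed_crt},
        index=pd.Index(X.ids, name="compound_id"),
    )
    if model.task == "classification":
        out["label"] = np.where(raw >= 0.5, ACTIVE, INACTIVE)
    else:
        out["pKi"] = raw
    return out
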
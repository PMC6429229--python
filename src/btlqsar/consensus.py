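"""Consensus of predictions across a battery of QSAR models.

Classification consensus follows the two-/three-model agreement protocol:
type A is complete agreement among the predicting models, type B exactly one
disagreement among three.  The strict 3-model consensus accepts only type-A
compounds, the wider "A+B" consensus also accepts majority (2-of-3) calls,
and the pairwise mode requires both of two models to agree.  A model whose
compound falls outside its applicability domain abstains; a consensus
without its quorum of predictions yields no prediction, which is why
consensus coverage shrinks as strictness grows.

Regression consensus combines in-domain model responses by inverse-leverage
weighting, ȳw = (Σ_k y_k/h_k) / (Σ_k 1/h_k): a response from a model for
which the query has low leverage (central, reliable) weighs more.  Model
diversity is measured by the Hamming distance between descriptor masks —
the number of descriptors not shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ACTIVE, INACTIVE

NO_PREDICTION = "no-prediction"


@dataclass(frozen=True)
class ConsensusVerdict:
    per_model: tuple
    combined_label: str  # active / inactive / no-prediction
    agreement_type: str | None  # "A" | "B" | None

    def __post_init__(self) -> None:
        if self.agreement_type == "A":
            voted = [p for p in self.per_model if p in (ACTIVE, INACTIVE)]
            assert len(set(voted)) <= 1, "type A requires full agreement"


def _clean(labels: Sequence) -> list:
    out = []
    for lab in labels:
        if lab in (ACTIVE, INACTIVE):
            out.append(lab)
        elif lab is None or lab == "abstain":
            out.append(None)
        else:
            raise ValueError(f"unknown label {lab!r}")
    return out


def consensus_classify(per_model_labels: Sequence, mode: str = "strict") -> ConsensusVerdict:
    """Combine per-model labels (or abstentions) for one compound.

    ``mode`` is "strict" or "A+B" for three models, "pairwise" for two.
    All modes require every model to have predicted (an out-of-domain
    abstention voids the consensus); "strict" then demands unanimity
    (type A), "A+B" accepts the majority label with at most one disagreement
    (types A and B), and "pairwise" demands agreement of both models.
    """
    labels = _clean(per_model_labels)
    m_expected = 2 if mode == "pairwise" else 3
    if mode not in {"strict", "A+B", "pairwise"}:
        raise ValueError(f"unknown consensus mode {mode!r}")
    if len(labels) != m_expected:
        raise ValueError(f"mode {mode!r} needs {m_expected} models, got {len(labels)}")

    voted = [lab for lab in labels if lab is not None]
    if len(voted) < m_expected:  # quorum: all models must have predicted
        return ConsensusVerdict(tuple(labels), NO_PREDICTION, None)

    n_active = sum(lab == ACTIVE for lab in voted)
    unanimous = n_active in (0, len(voted))
    if mode == "pairwise":
        if unanimous:
            return ConsensusVerdict(tuple(labels), voted[0], "A")
        return ConsensusVerdict(tuple(labels), NO_PREDICTION, None)

    if unanimous:
        return ConsensusVerdict(tuple(labels), voted[0], "A")
    if mode == "A+B":
        majority = ACTIVE if n_active >= 2 else INACTIVE
        return ConsensusVerdict(tuple(labels), majority, "B")
    return ConsensusVerdict(tuple(labels), NO_PREDICTION, "B")


def weighted_average_response(responses: Sequence[float], leverages: Sequence[float]) -> float:
    """Inverse-leverage weighted mean ȳw = (Σ y_k/h_k) / (Σ 1/h_k).

    A convex combination of the model responses; equal leverages reduce it
    to the arithmetic mean.
    """
    y = np.asarray(responses, dtype=float).ravel()
    h = np.asarray(leverages, dtype=float).ravel()
    if y.shape != h.shape or y.size == 0:
        raise ValueError("responses and leverages must be aligned and non-empty")
    if np.any(h <= 0):
        raise ValueError("leverages must be strictly positive")
    w = 1.0 / h
    return float(np.sum(y * w) / np.sum(w))


def hamming_model_distance(mask_i: Sequence, mask_j: Sequence) -> int:
    """Number of descriptors not shared by two models, d_h = b + c.

    ``b`` counts positions selected by model I only, ``c`` those selected by
    model II only.
    """
    a = np.asarray(mask_i, dtype=bool).ravel()
    b = np.asarray(mask_j, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError("descriptor masks differ in pool length")
    return int(np.sum(a ^ b))


def consensus_regression_battery(
    predictions: pd.DataFrame,
    leverages: pd.DataFrame,
    ad_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Per-compound consensus pKi over the in-domain models of a battery.

    The three frames are compounds × models and must share index/columns.
    Out-of-domain models are excluded from both the weighted and the simple
    average; a compound with no in-domain model gets NaN in both.
    """
    if not (predictions.index.equals(leverages.index) and predictions.index.equals(ad_flags.index)):
        raise ValueError("frames must share the compound index")
    if not (list(predictions.columns) == list(leverages.columns) == list(ad_flags.columns)):
        raise ValueError("frames must share the model columns")
    weighted = np.full(len(predictions), np.nan)
    simple = np.full(len(predictions), np.nan)
    n_in_ad = np.zeros(len(predictions), dtype=int)
    for i, cid in enumerate(predictions.index):
        mask = ad_flags.loc[cid].to_numpy(dtype=bool)
        if not mask.any():
            continue
        y = predictions.loc[cid].to_numpy(dtype=float)[mask]
        h = leverages.loc[cid].to_numpy(dtype=float)[mask]
        weighted[i] = weighted_average_response(y, h)
        simple[i] = float(np.mean(y))
        n_in_ad[i] = int(mask.sum())
    return pd.DataFrame(
        {"pKi_weighted": weighted, "pKi_mean": simple, "n_models_in_ad": n_in_ad},
        index=predictions.index,
    )
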
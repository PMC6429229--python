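"""Multiple linear regression with a leverage-based applicability domain.

Ordinary least squares on the intercept-augmented, autoscaled design matrix.
Used both as a regressor and — thresholded at 0.5 on a 0/1 activity target —
as a classifier.  The applicability domain is gated by the leverage
h = x̃ᵀ(XᵀX)⁻¹x̃ of the query against the warning threshold
h* = 3(p+1)/n (p descriptors, n training compounds); for the 11-descriptor
model trained on 90 compounds this gives the classical h* = 0.4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ACTIVE, INACTIVE, DescriptorMatrix, ScalingParams

FORMAT_TAG = "btlqsar-mlr"
FORMAT_VERSION = 1

#: Multiplier of the mean leverage (p+1)/n in the warning threshold.
LEVERAGE_MULTIPLIER = 3.0


def hat_star(p: int, n_train: int, multiplier: float = LEVERAGE_MULTIPLIER) -> float:
    """Leverage warning threshold h* = 3(p+1)/n."""
    if p < 0 or n_train <= 0:
        raise ValueError("need p >= 0 and n_train > 0")
    return multiplier * (p + 1) / n_train


@dataclass
class MlrModel:
    coefficients: np.ndarray  # per descriptor
    intercept: float
    descriptor_names: list[str]
    scaling: ScalingParams
    xtx_inverse: np.ndarray  # (p+1, p+1) of the augmented training design
    hat_star: float
    n_train: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": FORMAT_TAG,
            "version": FORMAT_VERSION,
            "descriptor_names": self.descriptor_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "scaling": self.scaling.to_dict(),
            "xtx_inverse": self.xtx_inverse.tolist(),
            "hat_star": self.hat_star,
            "n_train": self.n_train,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MlrModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        if d.get("format") != FORMAT_TAG:
            raise ValueError(f"not an MLR model file (format={d.get('format')!r})")
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            descriptor_names=list(d["descriptor_names"]),
            scaling=ScalingParams.from_dict(d["scaling"]),
            xtx_inverse=np.asarray(d["xtx_inverse"], dtype=float),
            hat_star=float(d["hat_star"]),
            n_train=int(d["n_train"]),
        )


def _augment(Xs: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((Xs.shape[0], 1)), Xs])


@dataclass
class LeverageMap:
    """Leverage structure of a training design, independent of any response.

    Lets non-linear models (e.g. a counter-propagation network trained on a
    descriptor subset) report the same h = x̃ᵀ(XᵀX)⁻¹x̃ reliability measure
    that MLR models use, so inverse-leverage consensus weighting is
    well-defined across a mixed battery.
    """

    descriptor_names: list[str]
    scaling: ScalingParams
    xtx_inverse: np.ndarray
    hat_star: float
    n_train: int

    @classmethod
    def from_training(cls, X: DescriptorMatrix) -> "LeverageMap":
        sd = X.values.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            bad = [X.names[j] for j in np.nonzero(sd <= 0)[0]]
            raise ValueError(f"zero-variance descriptors {bad}")
        scaling = ScalingParams(list(X.names), X.values.mean(axis=0), sd)
        A = _augment((X.values - scaling.mean) / scaling.sd)
        return cls(
            descriptor_names=list(X.names),
            scaling=scaling,
            xtx_inverse=np.linalg.inv(A.T @ A),
            hat_star=hat_star(X.n_descriptors, X.n_compounds),
            n_train=X.n_compounds,
        )

    def leverages(self, X: DescriptorMatrix) -> np.ndarray:
        sub = X.select_descriptors(self.descriptor_names)
        A = _augment((sub.values - self.scaling.mean) / self.scaling.sd)
        return np.einsum("ij,jk,ik->i", A, self.xtx_inverse, A)


def fit_mlr(X: DescriptorMatrix, y: np.ndarray) -> MlrModel:
    """Ordinary least squares on the autoscaled, intercept-augmented design.

    Requires n > p+1 and a full-rank design; on rank deficiency the error
    names the offending (collinear) columns so they can be filtered upstream.
    """
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.values.shape
    if len(y) != n:
        raise ValueError("targets not aligned with descriptor rows")
    if n <= p + 1:
        raise ValueError(f"need more compounds ({n}) than parameters ({p + 1})")

    sd = X.values.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = [X.names[j] for j in np.nonzero(sd <= 0)[0]]
        raise ValueError(f"zero-variance descriptors {bad}; filter before fitting")
    scaling = ScalingParams(list(X.names), X.values.mean(axis=0), sd)
    A = _augment((X.values - scaling.mean) / scaling.sd)

    # QR-based rank check; tiny diagonal entries of R point at the columns
    # that are linear combinations of earlier ones
    _, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    deficient = np.nonzero(diag < tol)[0]
    if deficient.size:
        bad = [X.names[j - 1] if j > 0 else "<intercept>" for j in deficient]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return MlrModel(
        coefficients=beta[1:],
        intercept=float(beta[0]),
        descriptor_names=list(X.names),
        scaling=scaling,
        xtx_inverse=np.linalg.inv(A.T @ A),
        hat_star=hat_star(p, n),
        n_train=n,
    )


def leverage(model: MlrModel, x: np.ndarray) -> float:
    """Leverage of a single query vector given in the model's *scaled* space."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(model.descriptor_names):
        raise ValueError(
            f"query has {x.size} values, model expects {len(model.descriptor_names)}"
        )
    xa = np.concatenate([[1.0], x])
    return float(xa @ model.xtx_inverse @ xa)


def predict_mlr(
    model: MlrModel,
    X: DescriptorMatrix,
    classification_cut: float | None = None,
) -> pd.DataFrame:
    """Linear predictions with per-compound leverage and AD flag.

    With ``classification_cut`` set (conventionally 0.5 on a 0/1 target) a
    ``label`` column is added, active iff raw ≥ cut.  ``ad_flag`` is True iff
    leverage ≤ h* (strict exceedance fails the domain).
    """
    sub = X.select_descriptors(model.descriptor_names)
    Xs = (sub.values - model.scaling.mean) / model.scaling.sd
    raw = Xs @ model.coefficients + model.intercept
    A = _augment(Xs)
    lev = np.einsum("ij,jk,ik->i", A, model.xtx_inverse, A)
    out = pd.DataFrame(
        {"raw": raw, "leverage": lev, "ad_flag": lev <= model.hat_star},
        index=pd.Index(X.ids, name="compound_id"),
    )
    if classification_cut is not None:
        out["label"] = np.where(raw >= classification_cut, ACTIVE, INACTIVE)
    else:
        out["pKi"] = raw
    return out
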
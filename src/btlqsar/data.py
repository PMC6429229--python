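"""Core tabular containers for QSAR modelling.

A :class:`DescriptorMatrix` is a compounds-by-descriptors numeric table with
compound identifiers and descriptor names; an :class:`ActivityTable` carries
the measured transport-inhibition activity (pKi, with Ki in mmol/L) and/or a
binary active/inactive label for the same compounds.  Both round-trip through
delimited text (comma or tab separated, header row, first column = compound
identifier), which is the interchange format of the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Default activity threshold: a compound is active iff pKi > 1.3.
ACTIVITY_THRESHOLD = 1.3

ACTIVE = "active"
INACTIVE = "inactive"


def classify_by_threshold(pki: float, threshold: float = ACTIVITY_THRESHOLD) -> str:
    """Binary activity call from a pKi value.

    Active means a strict exceedance of the threshold; a compound sitting
    exactly at the threshold is inactive.
    """
    if pki is None or not np.isfinite(pki):
        raise ValueError(f"pKi must be a finite number, got {pki!r}")
    return ACTIVE if pki > threshold else INACTIVE


def _check_unique(items: Sequence, what: str) -> None:
    seen = pd.Index(items)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class DescriptorMatrix:
    """Compounds × molecular-descriptor value table.

    Parameters
    ----------
    ids
        Compound identifiers, one per row, unique.
    names
        Descriptor names, one per column, unique.
    values
        Float matrix of shape ``(len(ids), len(names))``.
    """

    ids: list[str]
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.names = [str(n) for n in self.names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.ids)} ids × {len(self.names)} names"
            )
        _check_unique(self.ids, "compound ids")
        _check_unique(self.names, "descriptor names")

    # -- basic introspection -------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return len(self.ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.names)

    # -- subsetting ----------------------------------------------------------
    def select_descriptors(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Column subset (and reorder) by descriptor name."""
        idx = {n: j for j, n in enumerate(self.names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"descriptors not present: {missing}")
        cols = [idx[n] for n in names]
        return DescriptorMatrix(list(self.ids), list(names), self.values[:, cols])

    def select_compounds(self, ids: Sequence[str]) -> "DescriptorMatrix":
        """Row subset (and reorder) by compound id."""
        idx = {i: r for r, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"compounds not present: {missing}")
        rows = [idx[i] for i in ids]
        return DescriptorMatrix(list(ids), list(self.names), self.values[rows])

    # -- pandas / text I/O ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="compound_id"),
                            columns=self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = _read_delimited(path)
        return cls.from_frame(df)


@dataclass
class ActivityTable:
    """Per-compound activity: pKi values and/or binary class labels.

    ``pki`` may be absent (screening sets carry no measured activity); where
    both are present the label must be consistent with the threshold rule.
    """

    ids: list[str]
    pki: np.ndarray | None = None
    labels: list[str] | None = None
    threshold: float = ACTIVITY_THRESHOLD

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        _check_unique(self.ids, "compound ids")
        if self.pki is not None:
            self.pki = np.asarray(self.pki, dtype=float)
            if self.pki.shape != (len(self.ids),):
                raise ValueError("pKi length does not match ids")
        if self.labels is None and self.pki is not None:
            self.labels = [classify_by_threshold(v, self.threshold) for v in self.pki]
        if self.labels is not None:
            self.labels = [str(c) for c in self.labels]
            bad = sorted(set(self.labels) - {ACTIVE, INACTIVE})
            if bad:
                raise ValueError(f"unknown class labels: {bad}")
            if len(self.labels) != len(self.ids):
                raise ValueError("label length does not match ids")
            if self.pki is not None:
                for i, (v, c) in enumerate(zip(self.pki, self.labels)):
                    if np.isfinite(v) and classify_by_threshold(v, self.threshold) != c:
                        raise ValueError(
                            f"label of compound {self.ids[i]!r} inconsistent with "
                            f"pKi={v} at threshold {self.threshold}"
                        )
        if self.pki is None and self.labels is None:
            raise ValueError("an ActivityTable needs pKi values or labels")

    @property
    def n_active(self) -> int:
        return sum(c == ACTIVE for c in self.labels)

    @property
    def n_inactive(self) -> int:
        return sum(c == INACTIVE for c in self.labels)

    def binary(self) -> np.ndarray:
        """Labels encoded 1=active, 0=inactive."""
        return np.array([1.0 if c == ACTIVE else 0.0 for c in self.labels])

    def select_compounds(self, ids: Sequence[str]) -> "ActivityTable":
        idx = {i: r for r, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"compounds not present: {missing}")
        rows = [idx[i] for i in ids]
        return ActivityTable(
            list(ids),
            None if self.pki is None else self.pki[rows],
            None if self.labels is None else [self.labels[r] for r in rows],
            self.threshold,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {}
        if self.pki is not None:
            data["pKi"] = self.pki
        if self.labels is not None:
            data["class"] = self.labels
        return pd.DataFrame(data, index=pd.Index(self.ids, name="compound_id"))

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep)

    @classmethod
    def read_csv(cls, path: str | Path, threshold: float = ACTIVITY_THRESHOLD) -> "ActivityTable":
        df = _read_delimited(path)
        cols = {c.lower(): c for c in df.columns}
        pki = df[cols["pki"]].to_numpy(float) if "pki" in cols else None
        labels = list(df[cols["class"]].astype(str)) if "class" in cols else None
        return cls(list(df.index.astype(str)), pki, labels, threshold)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, sniffing comma vs tab; first column is the id."""
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".tab"}:
        sep = "\t"
    elif path.suffix.lower() == ".csv":
        sep = ","
    else:
        head = path.read_text().splitlines()[0] if path.stat().st_size else ""
        sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    return pd.read_csv(path, sep=sep, index_col=0)


@dataclass
class ScalingParams:
    """Column means/SDs fitted on a training partition (population SD, ddof=0).

    The convention (population rather than sample SD) is recorded so that a
    serialized model is fully reproducible from its parameters.
    """

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    ddof: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.names) == self.mean.size == self.sd.size):
            raise ValueError("names/mean/sd length mismatch")
        if np.any(self.sd <= 0):
            bad = [self.names[j] for j in np.nonzero(self.sd <= 0)[0]]
            raise ValueError(
                f"non-positive SD for {bad}; drop zero-variance columns before scaling"
            )

    def to_dict(self) -> dict:
        return {"names": list(self.names), "mean": self.mean.tolist(),
                "sd": self.sd.tolist(), "ddof": self.ddof}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(list(d["names"]), np.asarray(d["mean"]), np.asarray(d["sd"]),
                   int(d.get("ddof", 0)))
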
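"""The optimal descriptor and the univariate linear endpoint model.

The descriptor DCW(T, N) of a quasi-SMILES is the sum of learned correlation
weights of its codes.  ``T`` is the rare-code threshold: a code occurring in
fewer than ``T`` active-training records is "rare", excluded from modelling
by pinning its weight to zero ("blocked").  ``N`` is the number of Monte
Carlo epochs used to obtain the weights.  The endpoint model is strictly
univariate linear:

    endpoint ≈ C0 + C1 · DCW(T, N)

with (C0, C1) fitted by ordinary least squares on the active training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codes import Code, QuasiSmiles
from .datasets import Dataset

__all__ = [
    "CorrelationWeights",
    "ModelParams",
    "Prediction",
    "DegenerateFitError",
    "rare_codes",
    "dcw",
    "fit_linear",
    "predict",
]


class DegenerateFitError(ValueError):
    """Raised when the descriptor carries no variance to regress on."""


def _read_json_source(source: str | Path) -> str:
    """Accept either a path to a JSON file or a literal JSON string."""
    text = str(source)
    if text.lstrip().startswith("{"):
        return text
    return Path(source).read_text()


@dataclass(frozen=True)
class CorrelationWeights:
    """Per-code weights plus the blocked (rare) code set.

    Blocked codes always have weight exactly 0.
    """

    weights: Mapping[Code, float]
    blocked: frozenset[Code] = frozenset()
    T: int = 1

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        bad = [c for c in self.blocked if self.weights.get(c, 0.0) != 0.0]
        if bad:
            raise ValueError(f"blocked codes with nonzero weight: {bad}")
        if not all(np.isfinite(list(self.weights.values()) or [0.0])):
            raise ValueError("non-finite correlation weight")

    def weight(self, code: Code) -> float:
        if code in self.blocked:
            return 0.0
        return self.weights.get(code, 0.0)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"T": self.T, "weights": dict(self.weights), "blocked": sorted(self.blocked)},
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CorrelationWeights":
        obj = json.loads(_read_json_source(source))
        return cls(obj["weights"], frozenset(obj.get("blocked", ())), obj.get("T", 1))


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of the univariate endpoint model plus (T, N)."""

    C0: float
    C1: float
    T: int = 1
    N: int = 1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.C0) and np.isfinite(self.C1)):
            raise ValueError("non-finite model coefficients")
        if self.T < 1 or self.N < 1:
            raise ValueError("T and N must be >= 1")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"C0": self.C0, "C1": self.C1, "T": self.T, "N": self.N}, indent=1
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParams":
        obj = json.loads(_read_json_source(source))
        return cls(obj["C0"], obj["C1"], obj.get("T", 1), obj.get("N", 1))


@dataclass(frozen=True)
class Prediction:
    """A single model evaluation: descriptor value and predicted endpoint.

    ``unseen_codes`` counts codes of the quasi-SMILES that are neither
    weighted nor blocked — extrapolation the applicability domain should see.
    """

    id: int | None
    dcw: float
    value: float
    unseen_codes: int = 0


def rare_codes(
    active: Dataset | Iterable,
    T: int,
    vocabulary: Iterable[Code] | None = None,
) -> set[Code]:
    """Codes whose active-training record count is below the threshold T.

    A record containing a code several times still counts once.  With T=1
    this is exactly the set of codes absent from the active set.  The
    ``vocabulary`` names the code universe considered; by default it is the
    codes of the active set itself (in which case T=1 returns nothing).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    records = active.records if isinstance(active, Dataset) else list(active)
    counts: dict[Code, int] = {}
    for r in records:
        for c in set(r.qs.codes):
            counts[c] = counts.get(c, 0) + 1
    universe = set(vocabulary) if vocabulary is not None else set(counts)
    return {c for c in universe if counts.get(c, 0) < T}


def dcw(qs: QuasiSmiles, w: CorrelationWeights) -> float:
    """Sum of correlation weights over the codes of a quasi-SMILES.

    Blocked and unseen codes contribute zero.
    """
    return sum(w.weight(c) for c in qs.codes)


def unseen_codes(qs: QuasiSmiles, w: CorrelationWeights) -> list[Code]:
    """Codes contributing zero because they are neither weighted nor blocked."""
    return [c for c in qs.codes if c not in w.weights and c not in w.blocked]


def fit_linear(
    active: Sequence[tuple[float, float]] | np.ndarray,
    T: int = 1,
    N: int = 1,
) -> ModelParams:
    """Ordinary least squares fit of endpoint on descriptor.

    ``active`` is a sequence of (dcw, endpoint) pairs from the active
    training set.

    Raises
    ------
    DegenerateFitError
        If fewer than two distinct descriptor values are present.
    """
    arr = np.asarray(active, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateFitError("need at least two (dcw, endpoint) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("all descriptor values identical")
    c1, c0 = np.polyfit(x, y, 1)
    return ModelParams(float(c0), float(c1), T, N)


def predict(m: ModelParams, w: CorrelationWeights, qs: QuasiSmiles, id: int | None = None) -> Prediction:
    """Evaluate the linear model on one quasi-SMILES."""
    d = dcw(qs, w)
    return Prediction(id, d, m.C0 + m.C1 * d, len(unseen_codes(qs, w)))
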
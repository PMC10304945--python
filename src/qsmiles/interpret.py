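"""Mechanistic interpretation of correlation weights.

A single optimized weight says little — the optimization is stochastic.  But
a code whose weight comes out positive in *every* repeated run is a stable
promoter of the endpoint, and one that is always negative a stable reducer.
Codes whose weights alternate in sign across runs carry no interpretation,
and codes rare enough to be blocked in every run were never modeled at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .codes import Code
from .descriptor import CorrelationWeights

__all__ = ["CodeVerdict", "classify_codes"]


@dataclass(frozen=True)
class CodeVerdict:
    code: Code
    verdict: str  # promoter | reducer | undefined | blocked
    weights_seen: tuple[float, ...]

    @property
    def min_w(self) -> float:
        return min(self.weights_seen)

    @property
    def max_w(self) -> float:
        return max(self.weights_seen)


def classify_codes(ensemble: Sequence[CorrelationWeights]) -> list[CodeVerdict]:
    """Classify every code of the ensemble's union vocabulary by the sign
    stability of its weights across runs.

    A weight of exactly zero from a non-blocked code is neither positive
    nor negative, so it breaks both promoter and reducer claims.
    """
    if len(ensemble) < 2:
        raise ValueError("an ensemble of at least 2 runs is required")
    vocab = sorted({c for w in ensemble for c in (*w.weights, *w.blocked)})
    verdicts = []
    for c in vocab:
        seen = tuple(w.weight(c) for w in ensemble)
        if all(c in w.blocked or c not in w.weights for w in ensemble):
            verdict = "blocked"
        elif all(v > 0 for v in seen):
            verdict = "promoter"
        elif all(v < 0 for v in seen):
            verdict = "reducer"
        else:
            verdict = "undefined"
        verdicts.append(CodeVerdict(c, verdict, seen))
    return verdicts
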
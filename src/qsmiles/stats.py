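"""Correlation and validation statistics for observed-vs-predicted series.

Beyond the classical quantities (Pearson r, R², Lin's concordance
correlation coefficient, RMSE, MAE, Fisher F, leave-one-out Q²) this module
implements two criteria specific to correlation-weight models:

* **IIC**, the index of ideality of correlation: Pearson r attenuated by the
  imbalance between the mean absolute errors of negative-residual and
  positive-residual observations.  A correlation whose errors are lopsided
  to one side of the line is "less ideal" than one with balanced errors.

* **CII**, the correlation intensity index: one minus the summed positive
  leave-one-out improvements in R².  An observation whose removal improves
  R² is an "oppositionist" of the correlation, one whose removal degrades it
  a "supporter"; CII close to 1 means no single point props the fit up.

Moment conventions are population (1/n) throughout r and CCC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SetStatistics",
    "CIIResult",
    "UndefinedCorrelationError",
    "pearson_r",
    "r2",
    "ccc",
    "iic",
    "cii",
    "q2_loo",
    "rmse",
    "mae",
    "f_ratio",
    "set_statistics",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for a zero-variance series."""


def _pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(obs, dtype=float)
    y = np.asarray(pred, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-d series with n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series contain non-finite values")
    return x, y


def pearson_r(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x, y = _pair(obs, pred)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance in a series")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def r2(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Determination coefficient r² of the correlation."""
    return pearson_r(obs, pred) ** 2


def ccc(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population moments).

    Penalizes location and scale shifts that leave r untouched.  Two equal
    constant series are perfectly concordant (1.0 by convention).
    """
    x, y = _pair(obs, pred)
    denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        if np.array_equal(x, y):
            return 1.0
        raise UndefinedCorrelationError("zero denominator in CCC")
    return float(2.0 * ((x - x.mean()) * (y - y.mean())).mean() / denom)


def iic(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Index of ideality of correlation.

    With residuals e = obs − pred split into the negative class (e < 0) and
    the non-negative class (e ≥ 0):

        IIC = r · min(MAE⁻, MAE⁺) / max(MAE⁻, MAE⁺)

    If either residual class is empty the index is 0 — an entirely one-sided
    correlation is maximally non-ideal.
    """
    x, y = _pair(obs, pred)
    e = x - y
    neg = np.abs(e[e < 0])
    pos = np.abs(e[e >= 0])
    if neg.size == 0 or pos.size == 0:
        return 0.0
    lo, hi = sorted((neg.mean(), pos.mean()))
    if hi == 0.0:
        return pearson_r(obs, pred)
    return pearson_r(obs, pred) * lo / hi


@dataclass(frozen=True)
class CIIResult:
    """CII value plus the per-sample leave-one-out effects.

    ``effects[k]`` is R²₋ₖ − R²; positive means sample k is an
    "oppositionist" (its removal improves the correlation).
    """

    value: float
    effects: tuple[float, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple("oppositionist" if e > 0 else "supporter" for e in self.effects)


def _loo_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R² of (x, y) with each sample removed in turn, via sum downdates."""
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    rx, ry = sx - x, sy - y
    cov = (sxy - x * y) - rx * ry / m
    vx = (sxx - x * x) - rx * rx / m
    vy = (syy - y * y) - ry * ry / m
    with np.errstate(divide="ignore", invalid="ignore"):
        out = cov * cov / (vx * vy)
    return np.where((vx <= 0) | (vy <= 0), 0.0, out)


def cii(obs: Sequence[float], pred: Sequence[float], detail: bool = False):
    """Correlation intensity index.

    CII = 1 − Σₖ max(0, R²₋ₖ − R²) over leave-one-out determination
    coefficients.  With ``detail=True`` returns a :class:`CIIResult`
    carrying the per-sample effects and supporter/oppositionist labels.
    """
    x, y = _pair(obs, pred)
    if x.size < 3:
        raise ValueError("CII needs n >= 3")
    base = pearson_r(obs, pred) ** 2
    effects = _loo_r2(x, y) - base
    value = float(1.0 - np.clip(effects, 0.0, None).sum())
    if detail:
        return CIIResult(value, tuple(float(e) for e in effects))
    return value


def q2_loo(pairs: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """Leave-one-out cross-validated R² of the univariate regression.

    ``pairs`` are (descriptor, observed) tuples; each point is predicted
    from a regression refitted without it.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("q2_loo needs n >= 3 (descriptor, observed) pairs")
    x, y = arr[:, 0], arr[:, 1]
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    m = n - 1
    rx, ry = sx - x, sy - y
    mx, my = rx / m, ry / m
    vx = (sxx - x * x) - rx * mx
    if np.any(vx <= 0):
        raise ValueError("degenerate leave-one-out refit (constant descriptor)")
    c1 = ((sxy - x * y) - rx * my) / vx
    c0 = my - c1 * mx
    press = ((y - (c0 + c1 * x)) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - press / tss)


def rmse(obs: Sequence[float], pred: Sequence[float], ddof: int = 0) -> float:
    """Root mean squared error; ``ddof=1`` gives the Bessel-corrected form
    used by the reference reporting convention."""
    x, y = _pair(obs, pred)
    return float(np.sqrt(((x - y) ** 2).sum() / (x.size - ddof)))


def mae(obs: Sequence[float], pred: Sequence[float]) -> float:
    x, y = _pair(obs, pred)
    return float(np.abs(x - y).mean())


def f_ratio(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Fisher F-ratio of the correlation: r²(n−2)/(1−r²)."""
    x, _ = _pair(obs, pred)
    if x.size < 3:
        raise ValueError("F-ratio needs n >= 3")
    rsq = r2(obs, pred)
    if 1.0 - rsq < 1e-12:  # collinear to machine precision
        return float("inf")
    return float(rsq * (x.size - 2) / (1.0 - rsq))


@dataclass(frozen=True)
class SetStatistics:
    """The per-set summary block: n, R², CCC, IIC, CII, Q², RMSE, MAE, F."""

    n: int
    r2: float
    ccc: float
    iic: float
    cii: float
    q2: float | None
    rmse: float
    mae: float
    f: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "r2", "ccc", "iic", "cii", "q2", "rmse", "mae", "f")}


def set_statistics(
    obs: Sequence[float],
    pred: Sequence[float],
    dcw: Sequence[float] | None = None,
    rmse_ddof: int = 1,
) -> SetStatistics:
    """Compute the full statistics block for one set.

    Q² is computed from (descriptor, observed) pairs when ``dcw`` is given,
    else from (predicted, observed) — identical for a fitted linear model.
    RMSE defaults to the Bessel-corrected (n−1) reporting convention.
    """
    x = np.asarray(dcw if dcw is not None else pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    return SetStatistics(
        n=y.size,
        r2=r2(obs, pred),
        ccc=ccc(obs, pred),
        iic=iic(obs, pred),
        cii=cii(obs, pred),
        q2=q2_loo(np.column_stack([x, y])) if y.size >= 3 else None,
        rmse=rmse(obs, pred, ddof=rmse_ddof),
        mae=mae(obs, pred),
        f=f_ratio(obs, pred),
    )
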
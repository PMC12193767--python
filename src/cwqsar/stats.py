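"""Predictive-potential statistics for observed-vs-calculated series.

Alongside the classical fit statistics (R², Lin's concordance CCC, LOO Q²,
RMSE, MAE, Fisher F) this module implements three criteria of predictive
potential used to steer stochastic weight optimization:

* **IIC** — index of ideality of correlation: the Pearson correlation scaled
  by the balance of the mean absolute errors of the negative- and
  positive-residual classes, ``r * min(MAE-, MAE+) / max(MAE-, MAE+)``.
* **CII** — correlation intensity index: ``1 - sum_k max(0, R²_{-k} - R²)``,
  where ``R²_{-k}`` is the determination coefficient with point *k* removed.
  Points whose removal raises R² are *opponents* of the correlation and their
  "protests" lower the index.
* **CCCP** — coefficient of conformism of correlation prediction: the
  normalized balance ``(supporters - opponents) / n``, a point being a
  supporter when its removal lowers R² and an opponent when it raises R².

Residuals follow the convention ``residual = observed - calculated``
throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .exceptions import UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass
class StatBlock:
    """Per-subset statistics block (one printed report row)."""

    n: int
    r2: float
    ccc: float
    iic: float
    cii: float
    q2: float
    cccp: float
    rmse: float
    mae: float
    f: float
    n_active_attributes: int = 0

    #: report column order
    COLUMNS = ("n", "R2", "CCC", "IIC", "CII", "Q2", "CCCP", "RMSE", "F", "NA")

    def as_row(self) -> dict:
        return {
            "n": self.n,
            "R2": self.r2,
            "CCC": self.ccc,
            "IIC": self.iic,
            "CII": self.cii,
            "Q2": self.q2,
            "CCCP": self.cccp,
            "RMSE": self.rmse,
            "F": self.f,
            "NA": self.n_active_attributes,
        }


def _as_arrays(observed: Sequence[float], calculated: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.shape != calc.shape or obs.ndim != 1:
        raise ValueError("observed and calculated must be 1-D of equal length")
    if not (np.isfinite(obs).all() and np.isfinite(calc).all()):
        raise ValueError("series must be finite")
    return obs, calc


def pearson_r(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Pearson correlation coefficient; raises when either series is constant."""
    obs, calc = _as_arrays(observed, calculated)
    so = obs.std()
    sc = calc.std()
    if so == 0.0 or sc == 0.0:
        raise UndefinedStatisticError("correlation undefined for constant series")
    return float(((obs - obs.mean()) * (calc - calc.mean())).mean() / (so * sc))


def r_squared(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Determination coefficient: squared Pearson correlation."""
    return pearson_r(observed, calculated) ** 2


def ccc(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments)."""
    obs, calc = _as_arrays(observed, calculated)
    vo, vc = obs.var(), calc.var()
    mo, mc = obs.mean(), calc.mean()
    denom = vo + vc + (mo - mc) ** 2
    if denom == 0.0:
        if np.array_equal(obs, calc):
            return 1.0  # identical constants agree perfectly
        raise UndefinedStatisticError("CCC undefined: zero variance and unequal means")
    cov = ((obs - mo) * (calc - mc)).mean()
    return float(2.0 * cov / denom)


def iic(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Index of ideality of correlation.

    ``r * min(MAE-, MAE+) / max(MAE-, MAE+)`` where MAE- is the mean absolute
    residual over points with ``observed - calculated < 0`` and MAE+ over
    points with residual >= 0.  If either residual class is empty (e.g. a
    uniformly biased or perfect fit) the index is 0 by convention.
    """
    obs, calc = _as_arrays(observed, calculated)
    if obs.size < 3:
        raise ValueError("IIC needs at least 3 points")
    res = obs - calc
    neg = np.abs(res[res < 0])
    pos = np.abs(res[res >= 0])
    if neg.size == 0 or pos.size == 0:
        logger.debug("IIC: one residual class empty -> 0 by convention")
        return 0.0
    mae_neg, mae_pos = neg.mean(), pos.mean()
    hi = max(mae_neg, mae_pos)
    if hi == 0.0:
        return 0.0
    r = pearson_r(obs, calc)
    return float(r * min(mae_neg, mae_pos) / hi)


def _loo_r2_deltas(obs: np.ndarray, calc: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """R² of the full series and R²_{-k} for every k, via downdated sums.

    Returns ``(r2_full, r2_loo, valid)`` where ``valid[k]`` is False when the
    series with point k removed is degenerate (constant); such points carry no
    protest and count as ties.
    """
    n = obs.size
    sx, sy = obs.sum(), calc.sum()
    sxx, syy = (obs * obs).sum(), (calc * calc).sum()
    sxy = (obs * calc).sum()

    def _r2(n_, sx_, sy_, sxx_, syy_, sxy_):
        vx = n_ * sxx_ - sx_ * sx_
        vy = n_ * syy_ - sy_ * sy_
        if vx <= 0.0 or vy <= 0.0:
            return None
        cov = n_ * sxy_ - sx_ * sy_
        return (cov * cov) / (vx * vy)

    r2_full = _r2(n, sx, sy, sxx, syy, sxy)
    if r2_full is None:
        raise UndefinedStatisticError("R^2 undefined for constant series")
    m = n - 1
    vx = m * (sxx - obs * obs) - (sx - obs) ** 2
    vy = m * (syy - calc * calc) - (sy - calc) ** 2
    cov = m * (sxy - obs * calc) - (sx - obs) * (sy - calc)
    valid = (vx > 0.0) & (vy > 0.0)
    r2_loo = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_loo[valid] = (cov[valid] ** 2) / (vx[valid] * vy[valid])
    # clip numerical noise: R^2 of n-1 points is in [0, 1]
    np.clip(r2_loo, 0.0, 1.0, out=r2_loo)
    return float(r2_full), r2_loo, valid


def cii(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Correlation intensity index: 1 minus the summed leave-one-out protests."""
    obs, calc = _as_arrays(observed, calculated)
    if obs.size < 4:
        raise ValueError("CII needs at least 4 points")
    r2_full, r2_loo, valid = _loo_r2_deltas(obs, calc)
    protests = np.maximum(0.0, r2_loo[valid] - r2_full)
    return float(1.0 - protests.sum())


def cccp(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Coefficient of conformism of correlation prediction.

    ``(n_supporters - n_opponents) / n``; point k is a supporter when
    ``R²_{-k} < R²`` and an opponent when ``R²_{-k} > R²``.  Exact ties (and
    degenerate removals) count to neither side.
    """
    obs, calc = _as_arrays(observed, calculated)
    n = obs.size
    if n < 4:
        raise ValueError("CCCP needs at least 4 points")
    r2_full, r2_loo, valid = _loo_r2_deltas(obs, calc)
    supporters = int(np.count_nonzero(valid & (r2_loo < r2_full)))
    opponents = int(np.count_nonzero(valid & (r2_loo > r2_full)))
    return float(supporters - opponents) / n


def q2_loo(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Leave-one-out cross-validated R² of the regression of observed on calculated.

    For each point the one-variable OLS is refitted without it and used to
    predict the held-out observation; ``Q² = 1 - PRESS / SS_tot`` with SS_tot
    about the full-series mean.
    """
    obs, calc = _as_arrays(observed, calculated)
    n = obs.size
    if n < 4:
        raise ValueError("Q2 needs at least 4 points")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedStatisticError("Q^2 undefined for constant observed values")
    press = 0.0
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        x, y = calc[mask], obs[mask]
        vx = x.var()
        if vx == 0.0:
            raise UndefinedStatisticError("Q^2: degenerate leave-one-out refit")
        slope = float(((x - x.mean()) * (y - y.mean())).mean() / vx)
        intercept = float(y.mean() - slope * x.mean())
        press += (obs[k] - (intercept + slope * calc[k])) ** 2
    return float(1.0 - press / ss_tot)


def rmse(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Root mean squared error of observed - calculated."""
    obs, calc = _as_arrays(observed, calculated)
    return float(np.sqrt(((obs - calc) ** 2).mean()))


def mae(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Mean absolute error of observed - calculated."""
    obs, calc = _as_arrays(observed, calculated)
    return float(np.abs(obs - calc).mean())


def f_ratio(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Fisher F-ratio of the one-descriptor regression: r²(n-2)/(1-r²)."""
    obs, calc = _as_arrays(observed, calculated)
    n = obs.size
    if n < 3:
        raise ValueError("F needs at least 3 points")
    r2 = r_squared(obs, calc)
    if r2 >= 1.0:
        return math.inf
    return float(r2 * (n - 2) / (1.0 - r2))


def stat_block(
    observed: Sequence[float],
    calculated: Sequence[float],
    n_active_attributes: int = 0,
) -> StatBlock:
    """Compute the full statistics block for one subset."""
    obs, calc = _as_arrays(observed, calculated)
    return StatBlock(
        n=int(obs.size),
        r2=r_squared(obs, calc),
        ccc=ccc(obs, calc),
        iic=iic(obs, calc),
        cii=cii(obs, calc),
        q2=q2_loo(obs, calc),
        cccp=cccp(obs, calc),
        rmse=rmse(obs, calc),
        mae=mae(obs, calc),
        f=f_ratio(obs, calc),
        n_active_attributes=n_active_attributes,
    )
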
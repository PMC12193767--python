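"""Monte Carlo optimization of correlation weights.

The optimizer is a plain accept-if-not-worse hill climb of a target function
over the correlation-weight vector:

    TF0 = R_AT + R_PT - |R_AT - R_PT| * 0.1
    TF1 = TF0 + IIC  * 0.3
    TF2 = TF0 + CII  * 0.3
    TF3 = TF0 + CCCP * 0.3

``R_AT``/``R_PT`` are Pearson correlations between observed endpoint and raw
descriptor DCW on the active and passive training sets; the passive set acts
as an inspector that penalizes models fitting the active set only.  The
criterion term (IIC / CII / CCCP) is evaluated on the *calibration* set using
calibration predictions from the active-set regression, pulling the search
toward weights that generalize.  The validation set plays no role here and is
deliberately absent from every signature in this module.

One *epoch* visits every non-blocked attribute once in seeded-random order,
perturbing its weight by ``step_size * U(-1, 1)`` and keeping the move iff the
target function does not decrease.  The default step size of 1.0 reflects the
short optimization budget (N = 15 epochs means only 15 proposals per weight):
weights start at 1.0 and must be able to traverse the few units separating
them from useful values within that budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .data import Record
from .exceptions import OptimizationImpossibleError, UndefinedStatisticError
from .stats import cccp, cii, iic, pearson_r
from .tokens import extract_attributes
from .weights import WeightTable, attribute_counts, build_blocklist, dcw

VARIANTS = ("TF0", "TF1", "TF2", "TF3")


@dataclass
class TFConfig:
    """Target-function and optimizer configuration.

    The defaults mirror the study conditions: threshold T = 5 for rare
    attributes, N = 15 optimization epochs, weight 0.1 on the training-set
    disparity term and 0.3 on the predictive-potential criterion.
    """

    variant: str = "TF0"
    tf0_coeff: float = 0.1
    criterion_coeff: float = 0.3
    epochs_N: int = 15
    threshold_T: int = 5
    seed: int = 0
    step_size: float = 1.0
    init: str = "ones"           # "ones" | "uniform"
    count_mode: str = "presence"  # frequency notion for T-blocking
    refresh: str = "proposal"     # criterion recomputation granularity

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.epochs_N < 1:
            raise ValueError("epochs_N must be >= 1")
        if self.threshold_T < 0:
            raise ValueError("threshold_T must be >= 0")
        if self.tf0_coeff < 0 or self.criterion_coeff < 0:
            raise ValueError("coefficients must be >= 0")


@dataclass
class OptimizationTrace:
    """Bookkeeping of one optimization run."""

    accepted_moves: int = 0
    proposed_moves: int = 0
    tf_values_per_epoch: List[float] = field(default_factory=list)
    accepted_tf_values: List[float] = field(default_factory=list)
    final_tf: float = float("nan")


def combine_tf(variant: str, tf0: float, criterion: float, criterion_coeff: float = 0.3) -> float:
    """Assemble a target-function value from its TF0 and criterion parts."""
    if variant == "TF0":
        return tf0
    return tf0 + criterion * criterion_coeff


def tf0_value(r_at: float, r_pt: float, tf0_coeff: float = 0.1) -> float:
    """TF0 = R_AT + R_PT - |R_AT - R_PT| * coeff."""
    return r_at + r_pt - abs(r_at - r_pt) * tf0_coeff


def _regression(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """OLS slope/intercept of y on x; raises on constant x."""
    vx = x.var()
    if vx == 0.0:
        raise UndefinedStatisticError("regression undefined: constant descriptor")
    slope = float(((x - x.mean()) * (y - y.mean())).mean() / vx)
    return float(y.mean() - slope * x.mean()), slope


def _criterion_on_calibration(
    variant: str,
    dcw_a: np.ndarray, y_a: np.ndarray,
    dcw_c: np.ndarray, y_c: np.ndarray,
) -> float:
    """IIC/CII/CCCP on the calibration set, predicted by the active-set fit."""
    c0, c1 = _regression(dcw_a, y_a)
    pred_c = c0 + c1 * dcw_c
    if variant == "TF1":
        return iic(y_c, pred_c)
    if variant == "TF2":
        return cii(y_c, pred_c)
    return cccp(y_c, pred_c)


def _tf_from_vectors(
    cfg: TFConfig,
    dcw_a: np.ndarray, y_a: np.ndarray,
    dcw_p: np.ndarray, y_p: np.ndarray,
    dcw_c: np.ndarray, y_c: np.ndarray,
) -> float:
    r_at = pearson_r(y_a, dcw_a)
    r_pt = pearson_r(y_p, dcw_p)
    tf0 = tf0_value(r_at, r_pt, cfg.tf0_coeff)
    if cfg.variant == "TF0":
        return tf0
    crit = _criterion_on_calibration(cfg.variant, dcw_a, y_a, dcw_c, y_c)
    return combine_tf(cfg.variant, tf0, crit, cfg.criterion_coeff)


def target_function(
    cfg: TFConfig,
    active: Sequence[Record],
    passive: Sequence[Record],
    calibration: Sequence[Record],
    table: WeightTable,
) -> float:
    """Target-function value of a weight table on the three building subsets.

    Raises :class:`UndefinedStatisticError` when the descriptor is constant on
    a subset.
    """
    dcw_a = np.array([dcw(r.smiles, table) for r in active])
    dcw_p = np.array([dcw(r.smiles, table) for r in passive])
    dcw_c = np.array([dcw(r.smiles, table) for r in calibration])
    y_a = np.array([r.endpoint for r in active])
    y_p = np.array([r.endpoint for r in passive])
    y_c = np.array([r.endpoint for r in calibration])
    return _tf_from_vectors(cfg, dcw_a, y_a, dcw_p, y_p, dcw_c, y_c)


def _count_matrix(records: Sequence[Record], keys: Sequence[str]) -> np.ndarray:
    """Dense (n_molecules x n_attributes) occurrence-count matrix."""
    index = {k: j for j, k in enumerate(keys)}
    m = np.zeros((len(records), len(keys)))
    for i, rec in enumerate(records):
        for key, mult in extract_attributes(rec.smiles).items():
            j = index.get(key)
            if j is not None:
                m[i, j] = mult
    return m


def optimize(
    cfg: TFConfig,
    active: Sequence[Record],
    passive: Sequence[Record],
    calibration: Sequence[Record],
) -> Tuple[WeightTable, OptimizationTrace]:
    """Monte Carlo hill climb of the target function over correlation weights.

    The blocklist is built from the active training set with ``cfg.threshold_T``;
    blocked weights stay exactly zero.  Deterministic for a fixed config.
    Only the active, passive and calibration subsets are visible to the
    optimizer — validation data cannot leak in by construction.
    """
    counts_a = attribute_counts(active, mode=cfg.count_mode)
    blocked = build_blocklist(counts_a, cfg.threshold_T)
    keys = sorted(k for k in counts_a if k not in blocked)
    if not keys:
        raise OptimizationImpossibleError(
            f"no non-blocked attributes (T={cfg.threshold_T}, "
            f"{len(counts_a)} attributes in active set)"
        )

    rng = np.random.default_rng(cfg.seed)
    if cfg.init == "uniform":
        w = rng.uniform(-1.0, 1.0, size=len(keys))
    else:
        w = np.ones(len(keys))

    m_a = _count_matrix(active, keys)
    m_p = _count_matrix(passive, keys)
    m_c = _count_matrix(calibration, keys)
    y_a = np.array([r.endpoint for r in active])
    y_p = np.array([r.endpoint for r in passive])
    y_c = np.array([r.endpoint for r in calibration])
    dcw_a, dcw_p, dcw_c = m_a @ w, m_p @ w, m_c @ w

    crit_cache = [0.0]

    def tf_of(da, dp, dc):
        # refresh="epoch" holds the criterion term fixed within an epoch and
        # climbs only the cheap TF0 part; "proposal" recomputes everything
        if cfg.variant != "TF0" and cfg.refresh == "epoch":
            r_at = pearson_r(y_a, da)
            r_pt = pearson_r(y_p, dp)
            tf0 = tf0_value(r_at, r_pt, cfg.tf0_coeff)
            return combine_tf(cfg.variant, tf0, crit_cache[0], cfg.criterion_coeff)
        return _tf_from_vectors(cfg, da, y_a, dp, y_p, dc, y_c)

    trace = OptimizationTrace()
    for _ in range(cfg.epochs_N):
        if cfg.variant != "TF0" and cfg.refresh == "epoch":
            crit_cache[0] = _criterion_on_calibration(
                cfg.variant, dcw_a, y_a, dcw_c, y_c
            )
        tf_cur = tf_of(dcw_a, dcw_p, dcw_c)
        order = rng.permutation(len(keys))
        for j in order:
            delta = cfg.step_size * rng.uniform(-1.0, 1.0)
            da = dcw_a + m_a[:, j] * delta
            dp = dcw_p + m_p[:, j] * delta
            dc = dcw_c + m_c[:, j] * delta
            trace.proposed_moves += 1
            try:
                tf_new = tf_of(da, dp, dc)
            except UndefinedStatisticError:
                continue
            if tf_new >= tf_cur:
                w[j] += delta
                dcw_a, dcw_p, dcw_c = da, dp, dc
                tf_cur = tf_new
                trace.accepted_moves += 1
                trace.accepted_tf_values.append(tf_cur)
        trace.tf_values_per_epoch.append(tf_cur)
    trace.final_tf = tf_cur

    counts_p = attribute_counts(passive, mode=cfg.count_mode)
    counts_c = attribute_counts(calibration, mode=cfg.count_mode)
    all_keys = set(counts_a) | blocked
    counts = {
        k: (counts_a.get(k, 0), counts_p.get(k, 0), counts_c.get(k, 0))
        for k in all_keys
    }
    table = WeightTable(
        weights=dict(zip(keys, (float(x) for x in w))),
        blocked=blocked,
        threshold_T=cfg.threshold_T,
        probe_seed=cfg.seed,
        counts=counts,
    )
    return table, trace


def run_probes(
    cfg: TFConfig,
    active: Sequence[Record],
    passive: Sequence[Record],
    calibration: Sequence[Record],
    n_probes: int,
) -> List[Tuple[WeightTable, OptimizationTrace]]:
    """Independent optimization runs ("probes") with derived seeds.

    Probe *i* uses ``cfg.seed + i``; disagreement of weight signs between
    probes is what separates clear promoters from unclear attributes.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    out = []
    for i in range(n_probes):
        probe_cfg = replace(cfg, seed=cfg.seed + i)
        out.append(optimize(probe_cfg, active, passive, calibration))
    return out
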
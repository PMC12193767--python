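"""Final regression model, applicability domain and mechanistic interpretation.

Two levels of API live here:

* Low-level operations mirroring the modeling protocol: :func:`fit_equation`
  (ordinary least squares of the endpoint on the optimal descriptor over the
  active training set), the statistical-defect applicability domain
  (:func:`defect_dk`, :meth:`FittedEquation.smiles_defect`,
  :meth:`FittedEquation.in_domain`) and :func:`classify_attributes`
  (promoters of endpoint increase/decrease across probes).

* A statsmodels-flavoured pair :class:`MonteCarloQSAR` / :class:`QSARResults`:
  construct the model from data, call ``fit()`` to run the full pipeline
  (blocking, Monte Carlo weight optimization, final regression, domain
  calibration), and read estimates, per-subset statistics and ``summary()``
  off the results object.

The applicability domain rests on per-attribute *statistical defects*

    d_k = |P - P'| / (N + N') + |P - P''| / (N + N'') + |P' - P''| / (N' + N'')

where P, P', P'' are the probabilities (presence frequencies divided by subset
size) of attribute A_k in the active training, passive training and
calibration sets and N, N', N'' the corresponding frequencies.  A molecule's
defect D_j sums d_k over its distinct non-blocked attributes; it is in the
domain iff D_j < 2 * mean(D_j over the active training set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import Record, SplitDataset, make_split
from .exceptions import InvalidInputError, UndefinedStatisticError
from .optimize import OptimizationTrace, TFConfig, run_probes
from .stats import StatBlock, stat_block
from .tokens import extract_attributes
from .weights import (
    WeightTable,
    count_active_attributes,
    dcw,
    read_weight_table,
    write_weight_table,
)

ROLE_INCREASE = "promoter_increase"
ROLE_DECREASE = "promoter_decrease"
ROLE_UNCLEAR = "unclear"


def defect_dk(
    freqs: Tuple[float, float, float], probs: Tuple[float, float, float]
) -> float:
    """Statistical defect of one attribute from its per-subset frequencies
    and probabilities (active, passive, calibration).

    Each of the three pairwise terms is the absolute probability difference
    divided by the frequency sum; a term with zero frequency sum contributes
    zero by convention.  Symmetric under any permutation of the subsets.
    """
    n1, n2, n3 = freqs
    p1, p2, p3 = probs
    total = 0.0
    for (na, pa), (nb, pb) in (((n1, p1), (n2, p2)), ((n1, p1), (n3, p3)), ((n2, p2), (n3, p3))):
        denom = na + nb
        if denom > 0:
            total += abs(pa - pb) / denom
    return total


def defect_table(
    table: WeightTable,
    n_active: int,
    n_passive: int,
    n_calibration: int,
) -> Dict[str, float]:
    """d_k for every attribute with recorded per-subset presence counts."""
    if table.counts is None:
        raise InvalidInputError("weight table carries no per-subset counts")
    out: Dict[str, float] = {}
    for key, (na, np_, nc) in table.counts.items():
        probs = (na / n_active, np_ / n_passive, nc / n_calibration)
        out[key] = defect_dk((na, np_, nc), probs)
    return out


@dataclass
class FittedEquation:
    """The final one-descriptor regression: endpoint = c0 + c1 * DCW(T, N)."""

    c0: float
    c1: float
    table: WeightTable
    mean_defect: float = 0.0
    threshold_T: int = 0
    dk: Dict[str, float] = field(default_factory=dict)

    def descriptor(self, smiles: str) -> float:
        return dcw(smiles, self.table)

    def predict(self, smiles: str) -> float:
        return self.c0 + self.c1 * self.descriptor(smiles)

    def smiles_defect(self, smiles: str) -> float:
        """D_j: sum of d_k over the distinct non-blocked attributes present."""
        total = 0.0
        for key in extract_attributes(smiles):  # distinct keys, not multiplicity
            if not self.table.is_blocked(key):
                total += self.dk.get(key, 0.0)
        return total

    def in_domain(self, smiles: str) -> Tuple[bool, float]:
        """Applicability: D_j strictly below twice the mean training defect."""
        dj = self.smiles_defect(smiles)
        return dj < 2.0 * self.mean_defect, dj

    def save(self, path: str | Path) -> None:
        """Plain-text serialization; reloading reproduces predictions bit-exactly."""
        path = Path(path)
        header = (
            f"c0 {self.c0!r}\n"
            f"c1 {self.c1!r}\n"
            f"threshold_T {self.threshold_T}\n"
            f"mean_defect {self.mean_defect!r}\n"
        )
        weight_path = path.with_suffix(path.suffix + ".weights")
        write_weight_table(self.table, weight_path)
        dk_lines = "".join(f"dk {k} {v!r}\n" for k, v in sorted(self.dk.items()))
        path.write_text(header + dk_lines)

    @classmethod
    def load(cls, path: str | Path) -> "FittedEquation":
        path = Path(path)
        fields: Dict[str, float] = {}
        dk: Dict[str, float] = {}
        for line in path.read_text().splitlines():
            if line.startswith("dk "):
                _, key, val = line.split(None, 2)
                dk[key.ljust(12, ".")] = float(val)
            else:
                name, val = line.split(None, 1)
                fields[name] = float(val)
        table = read_weight_table(
            path.with_suffix(path.suffix + ".weights"),
            threshold_T=int(fields["threshold_T"]),
        )
        return cls(
            c0=fields["c0"],
            c1=fields["c1"],
            table=table,
            mean_defect=fields["mean_defect"],
            threshold_T=int(fields["threshold_T"]),
            dk=dk,
        )


def fit_equation(split: SplitDataset, table: WeightTable) -> FittedEquation:
    """OLS of endpoint on DCW over the active training set, plus domain calibration.

    The mean statistical defect is computed over active-training compounds;
    per-attribute d_k values need the per-subset counts stored on the weight
    table (absent counts disable the domain: every molecule gets D_j = 0).
    """
    active = split.active
    x = np.array([dcw(r.smiles, table) for r in active])
    y = np.array([r.endpoint for r in active])
    if len(active) < 3:
        raise InvalidInputError("need >= 3 active-training records to fit")
    vx = x.var()
    if vx == 0.0:
        raise UndefinedStatisticError("constant descriptor on the active training set")
    c1 = float(((x - x.mean()) * (y - y.mean())).mean() / vx)
    c0 = float(y.mean() - c1 * x.mean())
    eq = FittedEquation(
        c0=c0, c1=c1, table=table, threshold_T=table.threshold_T,
    )
    if table.counts is not None:
        eq.dk = defect_table(
            table, len(split.active), len(split.passive), len(split.calibration)
        )
    defects = [eq.smiles_defect(r.smiles) for r in active]
    eq.mean_defect = float(np.mean(defects)) if defects else 0.0
    return eq


# Backwards-friendly alias matching the protocol vocabulary
fit = fit_equation


@dataclass
class AttributeRole:
    """Mechanistic role of one attribute across optimization probes."""

    attribute: str
    role: str
    cw_per_probe: List[float]


def classify_attributes(probes: Sequence[WeightTable]) -> List[AttributeRole]:
    """Classify attributes as promoters of endpoint increase/decrease.

    An attribute is a promoter of increase iff its correlation weight is
    strictly positive in *every* probe, a promoter of decrease iff strictly
    negative in every probe, and unclear otherwise (mixed signs, or an exact
    zero in any probe).  Output is ordered like a printed interpretation
    table: increase block, then decrease block, then unclear, each sorted by
    active-training frequency (descending) where counts are available.
    """
    if len(probes) < 2:
        raise InvalidInputError("attribute classification needs >= 2 probes")
    keys = sorted(set().union(*(set(p.weights) for p in probes)))
    counts = probes[0].counts or {}
    roles: List[AttributeRole] = []
    for key in keys:
        cws = [p.effective_weight(key) for p in probes]
        if all(c > 0 for c in cws):
            role = ROLE_INCREASE
        elif all(c < 0 for c in cws):
            role = ROLE_DECREASE
        else:
            role = ROLE_UNCLEAR
        roles.append(AttributeRole(attribute=key, role=role, cw_per_probe=cws))
    order = {ROLE_INCREASE: 0, ROLE_DECREASE: 1, ROLE_UNCLEAR: 2}
    roles.sort(key=lambda r: (order[r.role], -counts.get(r.attribute, (0, 0, 0))[0], r.attribute))
    return roles


class MonteCarloQSAR:
    """Correlation-weight QSAR model over a molecule/endpoint table.

    Parameters
    ----------
    records : sequence of Record
        Molecules with identifiers, SMILES and a continuous endpoint.
    split : SplitDataset, optional
        A pre-made four-subset split.  When omitted, ``fit`` draws one from
        its seed.

    Examples
    --------
    >>> model = MonteCarloQSAR.from_dataframe(df)          # doctest: +SKIP
    >>> res = model.fit(variant="TF3", n_probes=3, seed=7)  # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(self, records: Sequence[Record], split: Optional[SplitDataset] = None):
        self.records = list(records)
        self.split = split

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_col: str = "id",
        smiles_col: str = "smiles",
        endpoint_col: str = "endpoint",
        split: Optional[SplitDataset] = None,
    ) -> "MonteCarloQSAR":
        records = [
            Record(str(row[id_col]), str(row[smiles_col]), float(row[endpoint_col]))
            for _, row in df.iterrows()
        ]
        return cls(records, split=split)

    def fit(
        self,
        variant: str = "TF3",
        threshold_T: int = 5,
        epochs_N: int = 15,
        n_probes: int = 1,
        seed: int = 0,
        **cfg_kwargs,
    ) -> "QSARResults":
        """Run the full pipeline and return a results object.

        Splits the data (if no split was supplied), optimizes correlation
        weights by Monte Carlo for each probe, fits the final regression on
        the active training set and calibrates the applicability domain.
        """
        split = self.split or make_split(self.records, seed)
        cfg = TFConfig(
            variant=variant,
            threshold_T=threshold_T,
            epochs_N=epochs_N,
            seed=seed,
            **cfg_kwargs,
        )
        probe_results = run_probes(
            cfg, split.active, split.passive, split.calibration, n_probes
        )
        tables = [t for t, _ in probe_results]
        traces = [tr for _, tr in probe_results]
        equations = [fit_equation(split, t) for t in tables]
        return QSARResults(
            model=self, split=split, config=cfg,
            probes=tables, traces=traces, equations=equations,
        )


@dataclass
class QSARResults:
    """Fit results: per-probe weight tables, regressions and diagnostics.

    The first probe is the primary model; ``summary()`` reports its
    per-subset statistics in the standard column order.
    """

    model: MonteCarloQSAR
    split: SplitDataset
    config: TFConfig
    probes: List[WeightTable]
    traces: List[OptimizationTrace]
    equations: List[FittedEquation]

    @property
    def equation(self) -> FittedEquation:
        return self.equations[0]

    @property
    def params(self) -> Dict[str, float]:
        return {"c0": self.equation.c0, "c1": self.equation.c1}

    def predict(self, smiles) -> float | List[float]:
        if isinstance(smiles, str):
            return self.equation.predict(smiles)
        return [self.equation.predict(s) for s in smiles]

    def subset_stats(self, label: str, probe: int = 0) -> StatBlock:
        """Statistics block of one subset under one probe's model."""
        eq = self.equations[probe]
        recs = self.split.subsets[label]
        obs = [r.endpoint for r in recs]
        calc = [eq.predict(r.smiles) for r in recs]
        na = count_active_attributes(eq.table, recs)
        return stat_block(obs, calc, n_active_attributes=na)

    def stats_frame(self, probe: int = 0) -> pd.DataFrame:
        """One report row per subset (A, P, C, V), standard column order."""
        rows = []
        for label in ("active", "passive", "calibration", "validation"):
            block = self.subset_stats(label, probe=probe)
            rows.append({"set": label, **block.as_row()})
        return pd.DataFrame(rows, columns=["set", *StatBlock.COLUMNS])

    def attribute_roles(self) -> List[AttributeRole]:
        return classify_attributes(self.probes)

    def outliers(self, records: Optional[Sequence[Record]] = None) -> List[Record]:
        """Molecules outside the applicability domain (default: all records)."""
        recs = list(records) if records is not None else self.split.all_records
        return [r for r in recs if not self.equation.in_domain(r.smiles)[0]]

    def predict_frame(self, records: Optional[Sequence[Record]] = None) -> pd.DataFrame:
        """Prediction table: id, smiles, DCW, prediction, D_j, in_domain."""
        recs = list(records) if records is not None else self.split.all_records
        rows = []
        for r in recs:
            ok, dj = self.equation.in_domain(r.smiles)
            rows.append({
                "id": r.id,
                "smiles": r.smiles,
                "DCW": self.equation.descriptor(r.smiles),
                "predicted": self.equation.predict(r.smiles),
                "Dj": dj,
                "in_domain": ok,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary in the style of statistical model reports."""
        eq = self.equation
        lines = [
            "Monte Carlo correlation-weight QSAR results",
            "=" * 78,
            f"target function: {self.config.variant}    "
            f"T = {self.config.threshold_T}    N = {self.config.epochs_N} epochs    "
            f"probes = {len(self.probes)}    seed = {self.config.seed}",
            f"endpoint = {eq.c0:.4f} + {eq.c1:.4f} * DCW(T,N)",
            f"mean statistical defect (active set): {eq.mean_defect:.6f}",
            "-" * 78,
        ]
        df = self.stats_frame()
        with pd.option_context("display.float_format", lambda v: f"{v:8.3f}"):
            lines.append(df.to_string(index=False))
        lines.append("=" * 78)
        return "\n".join(lines)

    def plot_observed_vs_predicted(self, ax=None):
        """Scatter of observed vs predicted endpoint, one marker set per subset."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, marker in zip(
            ("active", "passive", "calibration", "validation"), "osD^"
        ):
            recs = self.split.subsets[label]
            obs = [r.endpoint for r in recs]
            pred = [self.equation.predict(r.smiles) for r in recs]
            ax.scatter(obs, pred, marker=marker, s=18, label=label, alpha=0.7)
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("observed pLC50")
        ax.set_ylabel("predicted pLC50")
        ax.legend()
        return ax
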
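"""Correlation-weight tables, rare-attribute blocking and the optimal descriptor.

The optimal descriptor of a molecule is

    DCW(T, N) = sum_k CW(S_k) + sum_k CW(SS_k)

the sum over all single-atom and neighbor-pair attribute occurrences of their
correlation weights.  An attribute is *rare* — and its weight forced to zero —
if its frequency in the active training set is below the threshold T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .data import Record
from .tokens import extract_attributes, make_pair_key, make_single_key, tokenize


@dataclass
class WeightTable:
    """Correlation weights plus the blocked (rare) attribute set.

    ``weights`` holds only non-blocked attributes seen in the active training
    set; any key outside ``weights`` contributes zero to descriptor sums, so
    attributes absent from the active training set are implicitly blocked.
    ``counts`` optionally carries per-subset presence counts (A, P, C) for
    reporting.
    """

    weights: Dict[str, float]
    blocked: Set[str] = field(default_factory=set)
    threshold_T: int = 0
    probe_seed: int = 0
    counts: Optional[Dict[str, Tuple[int, int, int]]] = None

    def is_blocked(self, key: str) -> bool:
        return key in self.blocked or key not in self.weights

    def effective_weight(self, key: str) -> float:
        if key in self.blocked:
            return 0.0
        return self.weights.get(key, 0.0)


def attribute_counts(records: Iterable[Record], mode: str = "presence") -> Dict[str, int]:
    """Frequency of every attribute over a set of molecules.

    ``mode='presence'`` (default) counts molecules containing the attribute at
    least once — the frequency notion used by the statistical-defect formula.
    ``mode='occurrence'`` counts total occurrences instead.
    """
    if mode not in ("presence", "occurrence"):
        raise ValueError(f"unknown count mode {mode!r}")
    counts: Dict[str, int] = {}
    for rec in records:
        attrs = extract_attributes(rec.smiles)
        for key, mult in attrs.items():
            counts[key] = counts.get(key, 0) + (1 if mode == "presence" else mult)
    return counts


def build_blocklist(counts_active: Mapping[str, int], T: int) -> Set[str]:
    """Attributes whose active-training frequency is strictly below T."""
    if T < 0:
        raise ValueError("threshold T must be >= 0")
    return {key for key, n in counts_active.items() if n < T}


def dcw(smiles: str, table: WeightTable) -> float:
    """Optimal descriptor of a molecule under a weight table.

    Each attribute occurrence contributes its correlation weight (so ``CC``
    counts the carbon atom twice); blocked and unknown attributes contribute
    zero.
    """
    toks = tokenize(smiles)
    singles = sum(table.effective_weight(make_single_key(t)) for t in toks)
    pairs = sum(
        table.effective_weight(make_pair_key(a, b)) for a, b in zip(toks, toks[1:])
    )
    return float(singles + pairs)


def count_active_attributes(table: WeightTable, records: Iterable[Record]) -> int:
    """Number of distinct non-blocked attributes occurring in ``records``."""
    seen: Set[str] = set()
    for rec in records:
        for key in extract_attributes(rec.smiles):
            if not table.is_blocked(key):
                seen.add(key)
    return len(seen)


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    """Serialize a weight table as a plain-text column file.

    Columns: 12-char key, CW, blocked flag, presence counts in the active,
    passive and calibration sets (-1 when counts were not recorded).
    """
    lines = ["# key          cw                     blocked  n_active n_passive n_calibration"]
    keys = sorted(set(table.weights) | table.blocked)
    for key in keys:
        cw = table.weights.get(key, 0.0)
        blocked = 1 if key in table.blocked else 0
        na, np_, nc = (table.counts or {}).get(key, (-1, -1, -1))
        lines.append(f"{key}  {cw!r:>22}  {blocked}  {na} {np_} {nc}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_weight_table(path: str | Path, threshold_T: int = 0, probe_seed: int = 0) -> WeightTable:
    """Read a weight table written by :func:`write_weight_table`."""
    weights: Dict[str, float] = {}
    blocked: Set[str] = set()
    counts: Dict[str, Tuple[int, int, int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key = line[:12]
        rest = line[12:].split()
        cw, is_blocked = float(rest[0]), int(rest[1])
        if is_blocked:
            blocked.add(key)
        else:
            weights[key] = cw
        na, np_, nc = (int(x) for x in rest[2:5])
        if (na, np_, nc) != (-1, -1, -1):
            counts[key] = (na, np_, nc)
    return WeightTable(
        weights=weights, blocked=blocked, threshold_T=threshold_T,
        probe_seed=probe_seed, counts=counts or None,
    )
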
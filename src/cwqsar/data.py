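"""Dataset loading and the four-subset split protocol.

Model building uses four disjoint random subsets of roughly 25% each: an
*active training* set (drives the weight optimization), a *passive training*
set (inspects the model during building), a *calibration* set (steers the
predictive-potential criteria and global parameters) and a *validation* set
(never touched until the model is final).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DuplicateIDError, InvalidInputError, SchemaError
from .tokens import tokenize

logger = logging.getLogger(__name__)

SUBSET_LABELS = ("active", "passive", "calibration", "validation")


class Record(NamedTuple):
    """One molecule: identifier, SMILES, continuous endpoint (pLC50)."""

    id: str
    smiles: str
    endpoint: float


@dataclass
class SplitDataset:
    """Four disjoint subsets forming a partition of the input records."""

    active: List[Record]
    passive: List[Record]
    calibration: List[Record]
    validation: List[Record]
    seed: int = 0

    @property
    def subsets(self) -> Dict[str, List[Record]]:
        return {
            "active": self.active,
            "passive": self.passive,
            "calibration": self.calibration,
            "validation": self.validation,
        }

    @property
    def all_records(self) -> List[Record]:
        return self.active + self.passive + self.calibration + self.validation

    def sizes(self) -> Dict[str, int]:
        return {k: len(v) for k, v in self.subsets.items()}

    def __post_init__(self) -> None:
        ids = [r.id for r in self.all_records]
        if len(set(ids)) != len(ids):
            raise DuplicateIDError("subsets are not disjoint by id")


def _subset_sizes(n: int) -> Dict[str, int]:
    """Subset sizes for *n* records.

    Each subset receives ``n // 4`` records; the ``n mod 4`` extras cycle over
    the active-training and calibration sets (active first), the two subsets
    that drive model building.  For n = 311 this yields A=79, P=77, C=78,
    V=77, the sizes used in the source protocol.
    """
    base, extra = divmod(n, 4)
    sizes = {k: base for k in SUBSET_LABELS}
    cycle = ("active", "calibration")
    for i in range(extra):
        sizes[cycle[i % 2]] += 1
    return sizes


def load_table(path: str | Path, fmt: Optional[str] = None) -> List[Record]:
    """Read a molecule table into records.

    Supported formats: ``csv`` / ``tsv`` with a header line naming columns
    ``id``, ``smiles``, ``endpoint`` (case-insensitive, any order), and
    ``smi`` — headerless whitespace-delimited lines ``SMILES  id  endpoint``.
    Rows with a missing/non-finite endpoint or an untokenizable SMILES are
    dropped with a logged warning count.

    Raises
    ------
    SchemaError       if a required column is missing.
    InvalidInputError if the file has no rows.
    DuplicateIDError  if two surviving rows share an id.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".smi": "smi"}.get(path.suffix.lower(), "csv")
    if fmt == "smi":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["smiles", "id", "endpoint"],
            dtype={"smiles": str, "id": str},
        )
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        missing = {"id", "smiles", "endpoint"} - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) == 0:
        raise InvalidInputError(f"{path}: no data rows")

    records: List[Record] = []
    dropped = 0
    for row in df.itertuples(index=False):
        rid = str(row.id).strip()
        smi = str(row.smiles).strip()
        try:
            endpoint = float(row.endpoint)
        except (TypeError, ValueError):
            endpoint = math.nan
        if not math.isfinite(endpoint):
            dropped += 1
            continue
        try:
            tokenize(smi)
        except Exception:
            dropped += 1
            continue
        records.append(Record(rid, smi, endpoint))
    if dropped:
        logger.warning("%s: dropped %d row(s) with bad endpoint or SMILES", path, dropped)
    if not records:
        raise InvalidInputError(f"{path}: no usable rows")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIDError(f"{path}: duplicate id(s) {dups[:5]}")
    return records


def make_split(records: Sequence[Record], seed: int) -> SplitDataset:
    """Randomly partition records into the four subsets.

    Deterministic for a given seed; subset sizes follow :func:`_subset_sizes`;
    order within each subset is shuffled.
    """
    records = list(records)
    if len(records) < 8:
        raise InvalidInputError(f"need >= 8 records to split, got {len(records)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    shuffled = [records[i] for i in order]
    sizes = _subset_sizes(len(records))
    parts: Dict[str, List[Record]] = {}
    pos = 0
    for label in SUBSET_LABELS:
        parts[label] = shuffled[pos : pos + sizes[label]]
        pos += sizes[label]
    return SplitDataset(
        active=parts["active"],
        passive=parts["passive"],
        calibration=parts["calibration"],
        validation=parts["validation"],
        seed=seed,
    )


def make_splits(
    records: Sequence[Record], n_splits: int, master_seed: int
) -> List[SplitDataset]:
    """Produce ``n_splits`` independent splits with derived seeds.

    Split *i* uses seed ``master_seed + i``.  If two splits would share an
    identical validation set, the later one is re-drawn with a shifted seed.
    """
    if n_splits < 1:
        raise InvalidInputError("n_splits must be >= 1")
    splits: List[SplitDataset] = []
    seen_validation: set = set()
    offset = 0
    for i in range(n_splits):
        while True:
            seed = master_seed + i + offset
            split = make_split(records, seed)
            vkey = frozenset(r.id for r in split.validation)
            if vkey not in seen_validation:
                break
            offset += n_splits  # deterministic re-draw on collision
        seen_validation.add(vkey)
        splits.append(split)
    return splits


def assign_in_order(records: Sequence[Record]) -> SplitDataset:
    """Partition records into consecutive blocks (A, P, C, V) without shuffling.

    Used with synthetic fixtures whose record order deliberately encodes an
    unequal attribute prevalence between subsets.
    """
    records = list(records)
    if len(records) < 8:
        raise InvalidInputError(f"need >= 8 records to split, got {len(records)}")
    sizes = _subset_sizes(len(records))
    parts: Dict[str, List[Record]] = {}
    pos = 0
    for label in SUBSET_LABELS:
        parts[label] = records[pos : pos + sizes[label]]
        pos += sizes[label]
    return SplitDataset(
        active=parts["active"],
        passive=parts["passive"],
        calibration=parts["calibration"],
        validation=parts["validation"],
        seed=-1,
    )


def write_split_assignment(split: SplitDataset, path: str | Path) -> None:
    """Write an ``id,subset`` CSV so a published split can be reused bit-exactly."""
    rows = []
    for label, recs in split.subsets.items():
        for r in recs:
            rows.append({"id": r.id, "subset": label})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_split_assignment(path: str | Path, records: Sequence[Record]) -> SplitDataset:
    """Re-apply a saved ``id,subset`` assignment to records."""
    df = pd.read_csv(path, dtype=str)
    if set(df.columns) != {"id", "subset"}:
        raise SchemaError(f"{path}: expected columns id,subset")
    assignment = dict(zip(df["id"], df["subset"]))
    parts: Dict[str, List[Record]] = {k: [] for k in SUBSET_LABELS}
    for r in records:
        label = assignment.get(r.id)
        if label is None:
            raise InvalidInputError(f"record {r.id!r} absent from split file {path}")
        if label not in parts:
            raise InvalidInputError(f"unknown subset label {label!r} in {path}")
        parts[label].append(r)
    return SplitDataset(
        active=parts["active"],
        passive=parts["passive"],
        calibration=parts["calibration"],
        validation=parts["validation"],
        seed=-1,
    )
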
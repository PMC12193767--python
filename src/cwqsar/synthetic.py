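"""Synthetic token-string fixtures with known ground-truth structure.

The modeling method consumes SMILES as *token strings*, not as molecular
graphs, so a faithful test bed only needs (i) strings that tokenize cleanly
and round-trip, and (ii) endpoints generated as a known linear function of
attribute occurrences plus Gaussian noise:

    endpoint = c0 + c1 * sum_k n_k(molecule) * w_true(k) + eps,  eps ~ N(0, sd)

Parentheses and ring digits are emitted in matched pairs so the strings obey
the tokenizer's structural checks; no chemical validity is attempted or
needed.  With the default ten-token vocabulary, 400 molecules and noise
sd = 0.2 the fixtures mimic the difficulty of a real pLC50 table (endpoint
spread of a few log units, attribute counts comfortably above the rarity
threshold T = 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import Record
from .exceptions import GenerationError, InvalidInputError
from .tokens import attributes_of_tokens, extract_attributes, make_pair_key, make_single_key

DEFAULT_VOCABULARY = ("C", "c", "N", "O", "Cl", "S", "=", "1", "(", ")")

#: tokens that must be emitted in matched pairs
_OPEN_CLOSE = {"(": ")", "1": "1"}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic dataset."""

    n_molecules: int = 400
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY
    length_range: Tuple[int, int] = (8, 20)
    true_weights: Dict[str, float] = field(default_factory=dict)
    true_c0: float = 0.0
    true_c1: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vocabulary:
            raise InvalidInputError("vocabulary must be non-empty")
        if self.length_range[0] < 2:
            raise InvalidInputError("minimum molecule length is 2 tokens")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


def default_true_weights(
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
    seed: int = 0,
    n_pairs: int = 8,
) -> Dict[str, float]:
    """Ground-truth weights: one per single-atom attribute plus a few pairs.

    Weights are drawn uniformly from [-1, 1], the scale that keeps the
    endpoint spread within a realistic pLC50 range for 8-20-token molecules.
    """
    rng = np.random.default_rng(seed)
    weights: Dict[str, float] = {}
    # '(' and ')' are emitted in matched pairs, so their occurrence counts are
    # identical in every molecule: individual weights for them would not be
    # identifiable (only their sum is).  Ground truth therefore lives on the
    # identifiable attributes only.
    identifiable = [t for t in vocabulary if t not in ("(", ")")]
    for tok in identifiable:
        weights[make_single_key(tok)] = float(rng.uniform(-1, 1))
    plain = identifiable
    for _ in range(n_pairs):
        a, b = rng.choice(plain, size=2)
        weights[make_pair_key(str(a), str(b))] = float(rng.uniform(-1, 1))
    return weights


def _random_token_string(rng: np.random.Generator, spec: FixtureSpec) -> List[str]:
    """Seeded token string with matched parentheses and ring digits."""
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    vocab = list(spec.vocabulary)
    paired_opens = [t for t in ("(", "1") if t in vocab]
    plain = [t for t in vocab if t not in ("(", ")", "1")]
    if not plain:
        raise GenerationError("vocabulary needs at least one unpaired token")

    n_pair_budget = length // 4
    pairs: List[str] = []
    for t in paired_opens:
        k = int(rng.integers(0, n_pair_budget + 1))
        pairs.extend([t] * k)
    n_plain = length - 2 * len(pairs)
    while n_plain < max(2, length // 2):  # keep strings mostly plain tokens
        pairs.pop()
        n_plain = length - 2 * len(pairs)

    toks = [str(rng.choice(plain)) for _ in range(n_plain)]
    for t in pairs:
        # insert open before close at random positions
        i = int(rng.integers(0, len(toks) + 1))
        j = int(rng.integers(i, len(toks) + 1))
        toks.insert(i, t)
        toks.insert(j + 1, _OPEN_CLOSE[t])
    return toks


def true_descriptor(smiles: str, true_weights: Dict[str, float]) -> float:
    """Noise-free attribute contribution of a molecule."""
    return sum(
        mult * true_weights.get(key, 0.0)
        for key, mult in extract_attributes(smiles).items()
    )


def generate_dataset(spec: FixtureSpec) -> List[Record]:
    """Generate a deterministic synthetic dataset from a fixture recipe."""
    rng = np.random.default_rng(spec.seed)
    if not spec.true_weights:
        raise InvalidInputError("spec.true_weights must be provided (see default_true_weights)")
    records: List[Record] = []
    for i in range(spec.n_molecules):
        toks = _random_token_string(rng, spec)
        smiles = "".join(toks)
        signal = sum(
            mult * spec.true_weights.get(key, 0.0)
            for key, mult in attributes_of_tokens(toks).items()
        )
        noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
        endpoint = spec.true_c0 + spec.true_c1 * signal + noise
        records.append(Record(f"M{i:04d}", smiles, endpoint))
    return records


def perturb_subset_composition(
    records: Sequence[Record],
    attribute: str,
    enrichment: float,
    rng: Optional[np.random.Generator] = None,
) -> List[Record]:
    """Reorder records so an attribute's prevalence differs between subsets.

    The returned list is meant for :func:`cwqsar.data.assign_in_order`, which
    cuts it into consecutive A/P/C/V blocks.  ``enrichment`` in [0, 1] is the
    fraction of attribute-bearing molecules forced into the active-training
    block: 0 spreads them evenly (d_k ~ 0), 1 concentrates them all in the
    active block (maximal d_k).

    Raises :class:`GenerationError` when the attribute is absent or the
    active block cannot hold the requested number of bearers.
    """
    if not 0.0 <= enrichment <= 1.0:
        raise InvalidInputError("enrichment must be in [0, 1]")
    records = list(records)
    rng = rng or np.random.default_rng(0)
    bearers = [r for r in records if attribute in extract_attributes(r.smiles)]
    others = [r for r in records if attribute not in extract_attributes(r.smiles)]
    if not bearers:
        raise GenerationError(f"attribute {attribute!r} absent from records")
    n = len(records)
    block = n // 4 + (1 if n % 4 else 0)  # active-block capacity

    n_forced = round(enrichment * len(bearers))
    if n_forced > block:
        raise GenerationError(
            f"cannot force {n_forced} bearers into an active block of {block}"
        )
    forced, floating = bearers[:n_forced], bearers[n_forced:]

    # interleave the floating bearers evenly through the remaining records
    rest: List[Optional[Record]] = list(others)
    out_rest: List[Record] = []
    if floating:
        stride = max(1, (len(others) + len(floating)) // len(floating))
        fi = 0
        for i, r in enumerate(rest):
            if fi < len(floating) and i % stride == 0:
                out_rest.append(floating[fi])
                fi += 1
            out_rest.append(r)
        out_rest.extend(floating[fi:])
    else:
        out_rest = list(others)
    return forced + out_rest
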
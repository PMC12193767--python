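"""SMILES tokenization and attribute keys.

A *SMILES atom* is the smallest unit of a SMILES line that cannot be split
without losing meaning: a single character, a two-letter element symbol
(``Cl``, ``Br``, ...), a ``%``-prefixed two-digit ring-closure label, the
``@@`` chirality mark, or an entire bracket atom ``[...]``.

Attributes are either a single SMILES atom or an ordered pair of atoms that
are neighbors in the SMILES line.  Both are serialized as 12-character keys
built from 4-character '.'-padded fields, e.g. ``Cl..........`` for the
chlorine atom and ``c...1.......`` for an aromatic-carbon/ring-digit pair.
Pair keys are canonical: the two fields are ordered by descending byte value,
so the key does not depend on reading direction.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, List

from .exceptions import InvalidInputError, MalformedSMILESError

logger = logging.getLogger(__name__)

#: Two-letter element symbols recognized outside brackets.  The set is
#: deliberately small: only elements that plausibly occur in organic SMILES
#: with a lowercase second letter that is not itself an aromatic atom symbol.
TWO_LETTER_ELEMENTS = ("Cl", "Br", "Si", "Se")

KEY_LENGTH = 12
FIELD_LENGTH = 4
PAD = "."


def tokenize(smiles: str) -> List[str]:
    """Split a SMILES line into SMILES atoms.

    Parameters
    ----------
    smiles : str
        Non-empty, whitespace-stripped SMILES string.

    Returns
    -------
    list of str
        Tokens whose concatenation reproduces the input exactly.

    Raises
    ------
    InvalidInputError
        If the string is empty.
    MalformedSMILESError
        If a bracket atom is unterminated, a stray ``]`` occurs, a ``%``
        ring label lacks its two digits, or the reserved padding character
        ``.`` appears (multi-component SMILES are not supported).
    """
    if not smiles:
        raise InvalidInputError("empty SMILES string")
    tokens: List[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise MalformedSMILESError(f"unterminated bracket atom in {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "]":
            raise MalformedSMILESError(f"unmatched ']' at position {i} in {smiles!r}")
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise MalformedSMILESError(
                    f"'%' ring closure without two digits in {smiles!r}"
                )
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] == "@@":
            tokens.append("@@")
            i += 2
        elif smiles[i : i + 2] in TWO_LETTER_ELEMENTS:
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch == PAD:
            raise MalformedSMILESError(
                f"'.' separator at position {i} in {smiles!r}: "
                "multi-component SMILES are not supported and '.' is reserved "
                "as the attribute-key padding character"
            )
        else:
            tokens.append(ch)
            i += 1
    return tokens


def _field(token: str) -> str:
    """Render a token as a 4-character '.'-padded field.

    Tokens longer than 4 characters (long bracket atoms such as ``[NH3+]``)
    are folded to a stable 4-character code: first three characters + ``#``.
    """
    if len(token) > FIELD_LENGTH:
        code = token[:3] + "#"
        logger.debug("token %r folded to field code %r", token, code)
        return code
    return token.ljust(FIELD_LENGTH, PAD)


def make_single_key(token: str) -> str:
    """12-character attribute key for a single SMILES atom."""
    if not token:
        raise InvalidInputError("empty token")
    return _field(token).ljust(KEY_LENGTH, PAD)


def make_pair_key(a: str, b: str) -> str:
    """12-character attribute key for a pair of neighboring SMILES atoms.

    The key is symmetric: ``make_pair_key(a, b) == make_pair_key(b, a)``.
    Fields are ordered by descending byte value of the padded field, the
    convention used in printed correlation-weight tables (``c...1.......``,
    ``N...(.......``).
    """
    fa, fb = _field(a), _field(b)
    hi, lo = (fa, fb) if fa >= fb else (fb, fa)
    return (hi + lo).ljust(KEY_LENGTH, PAD)


def is_pair_key(key: str) -> bool:
    """True if the 12-character key encodes a neighbor pair."""
    return len(key) == KEY_LENGTH and key[FIELD_LENGTH] != PAD


def extract_attributes(smiles: str) -> Counter:
    """Multiset of attribute keys for a SMILES line.

    A line of *n* tokens yields *n* single-atom keys and *n - 1* neighbor-pair
    keys, counted with multiplicity.
    """
    toks = tokenize(smiles)
    attrs: Counter = Counter()
    for t in toks:
        attrs[make_single_key(t)] += 1
    for a, b in zip(toks, toks[1:]):
        attrs[make_pair_key(a, b)] += 1
    return attrs


def attributes_of_tokens(tokens: Iterable[str]) -> Counter:
    """Like :func:`extract_attributes` but starting from a token list."""
    toks = list(tokens)
    attrs: Counter = Counter()
    for t in toks:
        attrs[make_single_key(t)] += 1
    for a, b in zip(toks, toks[1:]):
        attrs[make_pair_key(a, b)] += 1
    return attrs
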
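"""Token encoding of aligned gRNA–target pairs.

Each of the 23 alignment positions pairs one guide symbol with one target
symbol.  Four bases give 16 ordered base pairs; adding the gap symbol ``-``
(RNA or DNA bulge) extends the vocabulary to the full 5 × 5 = 25 ordered
pairs, each assigned a unique integer token in ``[0, 24]``.  The token
sequence — 23 integers per pair — is what the embedding layer of the network
consumes.

The canonical table lays guide symbols out in row order ``A, T, C, G``
against target symbols in column order ``A, T, C, G, -`` with
``token = 5 * row + column``; the gap (RNA-bulge) row then fills tokens
20–24 in target order ``-, A, T, C, G``.  This yields the anchor
assignments ``AA→0``, ``TA→5``, ``C-→14``, ``GA→15``, ``-A→21``.  The pair
``(-,-)`` receives token 20 for a dense vocabulary even though the pair
invariant makes it unreachable in valid data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_data import PAIR_LENGTH, GuideTargetPair

#: Symbol order defining the canonical token layout (rows = guide symbol,
#: columns = target symbol, token = 5*row + col).
SYMBOL_ORDER = "ATCG-"
VOCABULARY_SIZE = 25


class EncodingError(ValueError):
    """A symbol pair or token falls outside the table's vocabulary."""


@dataclass(frozen=True)
class TokenTable:
    """Bijection between the 25 ordered (guide, target) symbol pairs and tokens 0–24."""

    mapping: dict[tuple[str, str], int]
    inverse: dict[int, tuple[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.mapping) != VOCABULARY_SIZE:
            raise EncodingError(
                f"token table must have {VOCABULARY_SIZE} entries, got {len(self.mapping)}"
            )
        tokens = sorted(self.mapping.values())
        if tokens != list(range(VOCABULARY_SIZE)):
            raise EncodingError("tokens must be a permutation of 0..24")
        object.__setattr__(
            self, "inverse", {v: k for k, v in self.mapping.items()}
        )

    def __getitem__(self, pair: tuple[str, str]) -> int:
        try:
            return self.mapping[pair]
        except KeyError:
            raise EncodingError(f"symbol pair {pair!r} not in vocabulary") from None

    def pair_for(self, token: int) -> tuple[str, str]:
        try:
            return self.inverse[token]
        except KeyError:
            raise EncodingError(f"token {token} outside [0, 24]") from None

    def to_text(self, path: str | Path) -> Path:
        """Export as a two-column text file: ``<guide><target>\t<token>``."""
        path = Path(path)
        lines = [
            f"{g}{t}\t{tok}"
            for (g, t), tok in sorted(self.mapping.items(), key=lambda kv: kv[1])
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @staticmethod
    def from_text(path: str | Path) -> "TokenTable":
        mapping: dict[tuple[str, str], int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            pair, tok = line.split("\t")
            mapping[(pair[0], pair[1])] = int(tok)
        return TokenTable(mapping)


def default_token_table() -> TokenTable:
    """The canonical 25-token table (see module docstring for the layout)."""
    mapping = {
        (g, t): 5 * i + j
        for i, g in enumerate(SYMBOL_ORDER[:4])
        for j, t in enumerate(SYMBOL_ORDER)
    }
    # gap row: (-,-) leads so the bulge tokens (-,A..G) occupy 21-24
    for j, t in enumerate("-ATCG"):
        mapping[("-", t)] = 20 + j
    return TokenTable(mapping)


def encode_pair(
    pair: GuideTargetPair, table: TokenTable | None = None
) -> np.ndarray:
    """Encode one aligned pair into its 23-token integer sequence (5′→3′)."""
    table = table or default_token_table()
    tokens = np.empty(PAIR_LENGTH, dtype=np.int64)
    for i, (g, t) in enumerate(zip(pair.guide, pair.target)):
        try:
            tokens[i] = table[(g, t)]
        except EncodingError as exc:
            raise EncodingError(f"position {i + 1}: {exc}") from None
    return tokens


def encode_dataset(
    pairs: Iterable[GuideTargetPair], table: TokenTable | None = None
) -> np.ndarray:
    """Encode many pairs into an ``(n, 23)`` int64 token matrix."""
    table = table or default_token_table()
    return np.stack([encode_pair(p, table) for p in pairs]) if pairs else np.empty((0, PAIR_LENGTH), dtype=np.int64)


def decode_tokens(
    tokens: Sequence[int] | np.ndarray, table: TokenTable | None = None
) -> tuple[str, str]:
    """Invert :func:`encode_pair`: recover the (guide, target) sequence strings."""
    table = table or default_token_table()
    tokens = np.asarray(tokens)
    if tokens.shape != (PAIR_LENGTH,):
        raise EncodingError(
            f"token sequence must have length {PAIR_LENGTH}, got shape {tokens.shape}"
        )
    guide = []
    target = []
    for tok in tokens.tolist():
        g, t = table.pair_for(int(tok))
        guide.append(g)
        target.append(t)
    return "".join(guide), "".join(target)
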
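"""Shared word tokenizer.

Token identity matters in two places: token-level units for inter-annotator
agreement, and token/parse alignment in the extraction pipeline.  Both use
this tokenizer so unit ids are reproducible.
"""

from __future__ import annotations

import re
from typing import NamedTuple

# word characters (incl. digits), keeping allele stars attached (CYP2D6*4);
# any other non-space character is its own token
_TOKEN_RE = re.compile(r"\w+(?:\*\d+)?|[^\w\s]")


class Token(NamedTuple):
    text: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into word/punctuation tokens with character offsets."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def token_texts(text: str) -> list[str]:
    return [t.text for t in tokenize(text)]
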
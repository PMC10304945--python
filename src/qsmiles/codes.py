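"""Parsing and normalization of quasi-SMILES condition codes.

A quasi-SMILES is a string of bracketed tokens, each encoding one facet of an
experimental situation (e.g. ``[Ag]`` a nanoparticle, ``[nm5]`` a particle
size, ``[24h]`` an exposure time, ``[EC50]`` an endpoint kind, ``[MCF-7]`` a
cell line).  Codes are opaque tokens: no chemistry is parsed.  Because source
tables mix typographic variants (``[24 h]``/``[24h]``, ``[EC50]``/``[ec50]``,
unicode dashes, dot padding), every token is normalized to a canonical form
and code identity is the normalized text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "Code",
    "QuasiSmiles",
    "MalformedCodeError",
    "QuasiSmilesParseError",
    "normalize_code",
    "parse_quasi_smiles",
]

#: A normalized bracketed token, e.g. ``"[ag]"``.  Plain ``str`` — codes are
#: dictionary keys throughout the package.
Code = str


class MalformedCodeError(ValueError):
    """Raised for a token that is not a single bracketed code."""


class QuasiSmilesParseError(ValueError):
    """Raised when a quasi-SMILES string cannot be tokenized.

    ``offset`` is the character position of the offending input.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


# Unicode minus / en dash / em dash all mean "-" in the source tables.
_DASHES = dict.fromkeys(map(ord, "−–—"), "-")
# Trailing "m" (minutes marker) on an all-digit exposure-time token is
# inconsistently printed across sources; the digits alone are canonical.
_MINUTES = re.compile(r"^(\d+)m$")


def normalize_code(raw_token: str) -> Code:
    """Normalize one bracketed token to its canonical form.

    Strips surrounding whitespace and dot padding, removes whitespace inside
    the brackets, unifies unicode dash variants to ASCII ``-``, lower-cases,
    and drops a trailing minutes marker from all-digit time codes.  The
    operation is idempotent.

    Raises
    ------
    MalformedCodeError
        If the token is empty or not of the form ``[...]``.
    """
    tok = raw_token.strip().rstrip(".")
    if not tok:
        raise MalformedCodeError(f"empty code token: {raw_token!r}")
    if not (tok.startswith("[") and tok.endswith("]")) or "[" in tok[1:-1] or "]" in tok[1:-1]:
        raise MalformedCodeError(f"token without matching brackets: {raw_token!r}")
    inner = tok[1:-1].translate(_DASHES)
    inner = re.sub(r"\s+", "", inner).lower()
    inner = _MINUTES.sub(r"\1", inner)
    if not inner:
        raise MalformedCodeError(f"empty code token: {raw_token!r}")
    return f"[{inner}]"


@dataclass(frozen=True)
class QuasiSmiles:
    """An ordered sequence of normalized codes plus the original string.

    Identity is the normalized code sequence; the raw string is kept for
    provenance only.
    """

    codes: tuple[Code, ...]
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("a quasi-SMILES needs at least one code")

    def __iter__(self) -> Iterator[Code]:
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def normalized(self) -> str:
        """Canonical serialization: the concatenated normalized codes."""
        return "".join(self.codes)

    def __add__(self, other: "QuasiSmiles") -> "QuasiSmiles":
        return QuasiSmiles(self.codes + other.codes, self.raw + other.raw)


def parse_quasi_smiles(text: str) -> QuasiSmiles:
    """Tokenize a quasi-SMILES string into its normalized codes.

    Codes are returned left to right.  Any character outside brackets other
    than whitespace, and any unbalanced bracket, is an error reported with
    its offset.
    """
    codes: list[Code] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "]":
            raise QuasiSmilesParseError("unmatched ']'", i)
        if ch != "[":
            raise QuasiSmilesParseError(f"stray character {ch!r} outside brackets", i)
        end = text.find("]", i)
        if end < 0:
            raise QuasiSmilesParseError("unbalanced '[' without closing ']'", i)
        if "[" in text[i + 1 : end]:
            raise QuasiSmilesParseError("nested '[' inside code", i)
        codes.append(normalize_code(text[i : end + 1]))
        i = end + 1
    if not codes:
        raise QuasiSmilesParseError("no bracketed codes found", 0)
    return QuasiSmiles(tuple(codes), text)
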
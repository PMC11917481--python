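"""PROSITE-syntax motif matching and LRR annotation for SLRP proteins.

Canonical Small Leucine-Rich Proteoglycans (SLRPs) are defined by an
LRR C-terminal capping motif with an "ear" extension (LRRCE).  This module
implements the subset of PROSITE pattern syntax needed to screen proteins
for the two LRRCE model motifs — the standard one, and a version relaxed
in the C-terminal region — together with two small annotation heuristics:
N-glycosylation sequon scanning (N-{P}-[ST]) and a leucine-rich-repeat
counter based on the LRR consensus window.

Supported pattern syntax: single residues (``A``), residue classes
(``[LIV]``), exclusions (``{P}``), bounded wildcards (``X``, ``X(2)``,
``X(7,20)``), joined by ``-``.  Anchors (``<``/``>``) are not supported.

Matching semantics: every distinct start position with a match is
reported, and for each start the *shortest* satisfying extent is returned
(lazy wildcard expansion).  Presence/absence is what downstream analyses
use, so the extent convention only needs to be deterministic.

Sequence handling is case-insensitive.  Ambiguity letters (X, B, Z) never
satisfy a fixed residue, class, or exclusion element (wildcards accept
them), and a ``*`` terminates the scannable region of a sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional, Union

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_LETTERS = frozenset("XBZ")


class PrositeParseError(ValueError):
    """Raised when a PROSITE pattern string cannot be parsed."""


@dataclass(frozen=True)
class Fixed:
    """A single required residue."""

    residue: str

    def __str__(self) -> str:
        return self.residue


@dataclass(frozen=True)
class ResidueClass:
    """A bracketed set of alternative residues, e.g. ``[LIV]``."""

    residues: tuple[str, ...]

    def __contains__(self, ch: str) -> bool:
        return ch in self.residues

    def __str__(self) -> str:
        return "[" + "".join(self.residues) + "]"


@dataclass(frozen=True)
class Exclusion:
    """A negated residue set, e.g. ``{P}``: any standard residue not listed."""

    residues: tuple[str, ...]

    def __str__(self) -> str:
        return "{" + "".join(self.residues) + "}"


@dataclass(frozen=True)
class Wildcard:
    """``X(min,max)``: between min and max arbitrary residues."""

    min_repeat: int
    max_repeat: int

    def __str__(self) -> str:
        if self.min_repeat == self.max_repeat:
            if self.min_repeat == 1:
                return "X"
            return f"X({self.min_repeat})"
        return f"X({self.min_repeat},{self.max_repeat})"


Element = Union[Fixed, ResidueClass, Exclusion, Wildcard]

_CLASS_RE = re.compile(r"\[([A-Za-z]+)\]$")
_EXCLUSION_RE = re.compile(r"\{([A-Za-z]+)\}$")
_REPEAT_RE = re.compile(r"[Xx]\((\d+)(?:,(\d+))?\)$")


@dataclass(frozen=True)
class PrositePattern:
    """A parsed PROSITE pattern: an ordered tuple of elements."""

    source: str
    elements: tuple[Element, ...]

    def __str__(self) -> str:
        return "-".join(str(el) for el in self.elements)

    @property
    def min_length(self) -> int:
        return sum(
            el.min_repeat if isinstance(el, Wildcard) else 1 for el in self.elements
        )

    @property
    def max_length(self) -> int:
        return sum(
            el.max_repeat if isinstance(el, Wildcard) else 1 for el in self.elements
        )


def _parse_token(token: str) -> Element:
    m = _CLASS_RE.match(token)
    if m is not None:
        letters = tuple(dict.fromkeys(m.group(1).upper()))
        bad = [ch for ch in letters if ch not in AMINO_ACIDS]
        if bad:
            raise PrositeParseError(
                f"non-amino-acid letter {bad[0]!r} in class token {token!r}"
            )
        return ResidueClass(letters)
    m = _EXCLUSION_RE.match(token)
    if m is not None:
        letters = tuple(dict.fromkeys(m.group(1).upper()))
        bad = [ch for ch in letters if ch not in AMINO_ACIDS]
        if bad:
            raise PrositeParseError(
                f"non-amino-acid letter {bad[0]!r} in exclusion token {token!r}"
            )
        return Exclusion(letters)
    m = _REPEAT_RE.match(token)
    if m is not None:
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if lo < 1 or hi < lo:
            raise PrositeParseError(
                f"malformed repeat count in token {token!r}: need 0 < min <= max"
            )
        return Wildcard(lo, hi)
    if token.upper() == "X":
        return Wildcard(1, 1)
    if len(token) == 1 and token.upper() in AMINO_ACIDS:
        return Fixed(token.upper())
    if "[" in token or "]" in token:
        raise PrositeParseError(f"unclosed or malformed bracket in token {token!r}")
    if "{" in token or "}" in token:
        raise PrositeParseError(f"unclosed or malformed brace in token {token!r}")
    raise PrositeParseError(f"unrecognized pattern token {token!r}")


def parse_prosite(text: str) -> PrositePattern:
    """Parse a PROSITE-syntax pattern string into a :class:`PrositePattern`.

    Raises :class:`PrositeParseError` naming the offending token on
    malformed input.
    """
    if text is None or not text.strip():
        raise PrositeParseError("empty pattern")
    body = text.strip()
    if body.endswith("."):
        body = body[:-1]
    if body.startswith("<") or body.endswith(">"):
        raise PrositeParseError("pattern anchors '<'/'>' are not supported")
    tokens = body.split("-")
    if any(not tok for tok in tokens):
        raise PrositeParseError(f"empty token in pattern {text!r}")
    elements = tuple(_parse_token(tok) for tok in tokens)
    return PrositePattern(source=text, elements=elements)


# The two LRRCE model motifs screened over SLRP proteins, in PROSITE syntax.
STANDARD_LRRCE_SOURCE = (
    "[LIV]-X(2)-[LVIYFMA]-X-[LIFM]-X(2)-[NH]-X-[ILVF]-X(2)-[VIMFLY]-X(4)-"
    "[FIMLV]-C-X(7,20)-[LYIMV]-X(2)-[ILVTMF]-X-[LVMI]-X(2)-N-X-[IVLMAFT]-"
    "X(8,9)-[FYMPVAIS]-X-C"
)
RELAXED_LRRCE_SOURCE = (
    "[LIV]-X(2)-[LVIYFMA]-X-[LIFM]-X(2)-[NH]-X-[ILVF]-X(2)-[VIMFLY]-X(4)-"
    "[FIMLV]-C-X(7,20)-[LYIMV]-X(2)-[ILVTMF]-X-[LVMI]-X(2)-N-X-[IVLMAFT]-"
    "X(8,12)-C"
)

STANDARD_LRRCE = parse_prosite(STANDARD_LRRCE_SOURCE)
RELAXED_LRRCE = parse_prosite(RELAXED_LRRCE_SOURCE)

_LRRCE_PATTERNS = {"standard": STANDARD_LRRCE, "relaxed": RELAXED_LRRCE}


@dataclass(frozen=True)
class MotifHit:
    """A pattern match: 1-based inclusive coordinates plus the matched span."""

    start: int
    end: int
    span: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid hit coordinates {self.start}..{self.end}")


def _prepare_sequence(sequence: str) -> str:
    seq = sequence.upper()
    star = seq.find("*")
    if star >= 0:
        seq = seq[:star]
    return seq


def _element_accepts(el: Element, ch: str) -> bool:
    if ch not in AMINO_ACIDS:  # ambiguity letters never satisfy typed elements
        return False
    if isinstance(el, Fixed):
        return ch == el.residue
    if isinstance(el, ResidueClass):
        return ch in el.residues
    if isinstance(el, Exclusion):
        return ch not in el.residues
    raise TypeError(el)


def _shortest_match_end(
    elements: tuple[Element, ...], seq: str, start: int
) -> Optional[int]:
    """Exclusive end index of the shortest match of ``elements`` at ``start``.

    Memoized backtracking over wildcard extents; returns None if no match.
    """
    n = len(seq)
    memo: dict[tuple[int, int], Optional[int]] = {}

    def f(i: int, pos: int) -> Optional[int]:
        key = (i, pos)
        if key in memo:
            return memo[key]
        if i == len(elements):
            result: Optional[int] = pos
        else:
            el = elements[i]
            result = None
            if isinstance(el, Wildcard):
                for k in range(el.min_repeat, el.max_repeat + 1):
                    if pos + k > n:
                        break
                    end = f(i + 1, pos + k)
                    if end is not None and (result is None or end < result):
                        result = end
            elif pos < n and _element_accepts(el, seq[pos]):
                result = f(i + 1, pos + 1)
        memo[key] = result
        return result

    return f(0, start)


def scan(pattern: PrositePattern, sequence: str) -> list[MotifHit]:
    """Find all matches of ``pattern`` in ``sequence``.

    One hit is reported per matching start position, with the shortest
    satisfying end for that start.  Hits are sorted by start.  An empty
    sequence yields an empty list.
    """
    seq = _prepare_sequence(sequence)
    hits: list[MotifHit] = []
    limit = len(seq) - pattern.min_length
    for start in range(limit + 1):
        end = _shortest_match_end(pattern.elements, seq, start)
        if end is not None:
            hits.append(MotifHit(start=start + 1, end=end, span=seq[start:end]))
    return hits


def has_lrrce(
    sequence: str, mode: str = "standard"
) -> tuple[bool, Optional[MotifHit]]:
    """Screen a protein for the LRRCE motif.

    ``mode`` selects the built-in pattern (``"standard"`` or ``"relaxed"``).
    Returns ``(present, first_hit_or_None)``.  Any sequence carrying a
    standard LRRCE also carries a relaxed one (the relaxed C-terminal
    ``X(8,12)-C`` subsumes ``X(8,9)-[FYMPVAIS]-X-C``).
    """
    try:
        pattern = _LRRCE_PATTERNS[mode]
    except KeyError:
        raise ValueError(
            f"unknown LRRCE mode {mode!r}; expected 'standard' or 'relaxed'"
        ) from None
    hits = scan(pattern, sequence)
    if hits:
        return True, hits[0]
    return False, None


def find_sequons(sequence: str) -> list[int]:
    """1-based positions of N-glycosylation sequons (N-{P}-[ST])."""
    seq = _prepare_sequence(sequence)
    positions = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            positions.append(i + 1)
    return positions


# LRR consensus window: L-x-x-L-x-L-x-x-N-x-L, with the L slots accepting
# any of {L,I,V,M,F} and the N slot any of {N,T,S,C}.  This counter is a
# documented heuristic and is NOT equivalent to structure-aware LRR
# prediction tools; it is meant for coarse comparisons only.
_LRR_WINDOW = 11
_LRR_L = frozenset("LIVMF")
_LRR_N = frozenset("NTSC")
_LRR_SLOTS = {0: _LRR_L, 3: _LRR_L, 5: _LRR_L, 8: _LRR_N, 10: _LRR_L}


def count_lrr(sequence: str) -> int:
    """Count non-overlapping LRR consensus windows, scanning left to right."""
    seq = _prepare_sequence(sequence)
    count = 0
    pos = 0
    while pos + _LRR_WINDOW <= len(seq):
        if all(seq[pos + off] in allowed for off, allowed in _LRR_SLOTS.items()):
            count += 1
            pos += _LRR_WINDOW
        else:
            pos += 1
    return count


def iter_fasta_report(records: Iterator[tuple[str, str]]) -> Iterator[dict]:
    """Per-sequence LRRCE/sequon/LRR annotation rows for a FASTA stream."""
    for seq_id, seq in records:
        std, std_hit = has_lrrce(seq, "standard")
        rel, rel_hit = has_lrrce(seq, "relaxed")
        first = std_hit or rel_hit
        yield {
            "id": seq_id,
            "standard_lrrce": std,
            "relaxed_lrrce": rel,
            "hit_start": first.start if first else "",
            "hit_end": first.end if first else "",
            "sequons": ",".join(map(str, find_sequons(seq))),
            "lrr_count": count_lrr(seq),
        }
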
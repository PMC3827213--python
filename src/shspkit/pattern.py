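"""PROSITE-style pattern parsing and scanning.

The grammar is the minimal subset needed for sHSP signature work:
dash-separated elements that are single residues (``P``), residue classes
(``[YF]``), or fixed-length wildcard runs (``x`` / ``x(9)``).  Ranges
``x(a,b)`` and the PROSITE anchors ``<``/``>`` are deliberately unsupported.

An ``X`` in a *sequence* (ambiguity) matches only wildcard elements, never a
fixed residue or a class — ambiguous evidence is not evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqio import AMINO_ACIDS, SequenceRecord

#: diagnostic signature of cyanophage sHSPs, located in the predicted
#: β2-β3 strands of the α-crystallin domain
CYANOPHAGE_SIGNATURE_TEXT = "P-P-[YF]-N-[ILV]-[IV]-x(9)-[EQ]"


class PatternSyntaxError(ValueError):
    """Raised on malformed pattern text."""


@dataclass(frozen=True)
class PatternElement:
    """One pattern position group.

    ``allowed`` is the residue set for a width-1 element; ``None`` marks a
    wildcard run of ``width`` positions.
    """

    allowed: frozenset[str] | None
    width: int = 1
    #: class letters in source order, for faithful re-rendering
    letters: str = ""

    @property
    def is_wildcard(self) -> bool:
        return self.allowed is None


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple[PatternElement, ...]
    source_text: str

    @property
    def width(self) -> int:
        return sum(e.width for e in self.elements)

    def render(self) -> str:
        """Re-render the pattern; inverse of :func:`parse_pattern`."""
        parts = []
        for e in self.elements:
            if e.is_wildcard:
                parts.append("x" if e.width == 1 else f"x({e.width})")
            elif len(e.allowed) == 1:
                parts.append(next(iter(e.allowed)))
            else:
                parts.append("[" + (e.letters or "".join(sorted(e.allowed))) + "]")
        return "-".join(parts)


@dataclass(frozen=True)
class PatternHit:
    """A match of a pattern in a sequence; 1-based inclusive coordinates."""

    sequence_id: str
    start: int
    end: int
    matched: str


_WILDCARD_RE = re.compile(r"^x(?:\((\d+)\))?$")
_CLASS_RE = re.compile(r"^\[([A-Z]+)\]$")


def parse_pattern(text: str) -> PrositePattern:
    """Parse dash-separated PROSITE-style pattern text."""
    stripped = text.strip().rstrip(".")
    if not stripped:
        raise PatternSyntaxError("empty pattern")
    elements: list[PatternElement] = []
    for token in stripped.split("-"):
        token = token.strip()
        if not token:
            raise PatternSyntaxError(f"empty element in {text!r}")
        m = _WILDCARD_RE.match(token)
        if m:
            n = int(m.group(1)) if m.group(1) else 1
            if n < 1:
                raise PatternSyntaxError(f"wildcard run length must be >= 1 in {text!r}")
            elements.append(PatternElement(None, n))
            continue
        m = _CLASS_RE.match(token)
        if m:
            residues = m.group(1)
            bad = set(residues) - set(AMINO_ACIDS)
            if bad:
                raise PatternSyntaxError(f"illegal residues {sorted(bad)} in class {token!r}")
            elements.append(PatternElement(frozenset(residues), letters=residues))
            continue
        if len(token) == 1 and token in AMINO_ACIDS:
            elements.append(PatternElement(frozenset(token), letters=token))
            continue
        raise PatternSyntaxError(f"cannot parse element {token!r} in {text!r}")
    return PrositePattern(tuple(elements), stripped)


#: compiled cyanophage signature, 8 elements, width 16
CYANOPHAGE_SIGNATURE = parse_pattern(CYANOPHAGE_SIGNATURE_TEXT)


def _positional_sets(pattern: PrositePattern) -> list[frozenset[str] | None]:
    flat: list[frozenset[str] | None] = []
    for e in pattern.elements:
        flat.extend([e.allowed] * e.width)
    return flat

def scan_pattern(pattern: PrositePattern, record: SequenceRecord) -> list[PatternHit]:
    """Report *all* matches of ``pattern`` in ``record``, overlaps included.

    Hits come back in ascending start order; a sequence shorter than the
    pattern yields an empty list.
    """
    w = pattern.width
    seq = record.residues
    flat = _positional_sets(pattern)
    hits: list[PatternHit] = []
    for start in range(len(seq) - w + 1):
        ok = True
        for offset, allowed in enumerate(flat):
            if allowed is not None and seq[start + offset] not in allowed:
                ok = False
                break
        if ok:
            hits.append(
                PatternHit(
                    sequence_id=record.id,
                    start=start + 1,
                    end=start + w,
                    matched=seq[start : start + w],
                )
            )
    return hits
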
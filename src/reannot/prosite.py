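"""PROSITE-syntax protein motif compilation and scanning.

Supported syntax: fixed residues (``E``), alternative sets (``[HQ]``),
excluded sets (``{P}``), the wildcard ``x``, repeat counts ``(n)`` and
``(n,m)`` on any element, and the terminal anchors ``<`` (N-terminus) and
``>`` (C-terminus). Elements are separated by ``-``; a trailing ``.`` is
tolerated. Example: ``[HQ]-E-G-P-N-V-F`` matches HEGPNVF or QEGPNVF.

Scanning reports every matching window, overlapping matches included, as
1-based inclusive (start, end) positions in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["ProsPattern", "PatternElement", "ProsPatternError", "prosite_scan"]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ProsPatternError(ValueError):
    """Raised for malformed PROSITE pattern syntax, naming the bad element."""


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: kind is 'fixed', 'set', 'exclude' or 'any'.

    ``residue_text`` keeps the residues in their written order so that
    compiling then rendering reproduces the original pattern.
    """

    kind: str
    residues: frozenset[str]
    min_rep: int = 1
    max_rep: int = 1
    residue_text: str = ""

    def accepts(self, aa: str) -> bool:
        if self.kind == "any":
            return True
        if self.kind == "exclude":
            return aa not in self.residues
        return aa in self.residues

    def render(self) -> str:
        if self.kind == "any":
            body = "x"
        elif self.kind == "fixed":
            body = self.residue_text
        elif self.kind == "set":
            body = "[" + self.residue_text + "]"
        else:
            body = "{" + self.residue_text + "}"
        if (self.min_rep, self.max_rep) == (1, 1):
            return body
        if self.min_rep == self.max_rep:
            return f"{body}({self.min_rep})"
        return f"{body}({self.min_rep},{self.max_rep})"


def _parse_repeat(token: str, rep: str) -> tuple[int, int]:
    inner = rep[1:-1]
    try:
        if "," in inner:
            lo, hi = inner.split(",", 1)
            lo_i, hi_i = int(lo), int(hi)
        else:
            lo_i = hi_i = int(inner)
    except ValueError:
        raise ProsPatternError(f"bad repeat count in element {token!r}") from None
    if lo_i < 0 or hi_i < lo_i:
        raise ProsPatternError(f"invalid repeat range in element {token!r}")
    return lo_i, hi_i


def _parse_element(token: str) -> PatternElement:
    body, lo, hi = token, 1, 1
    if "(" in token:
        if not token.endswith(")"):
            raise ProsPatternError(f"unbalanced parentheses in element {token!r}")
        body, rep = token.split("(", 1)
        lo, hi = _parse_repeat(token, "(" + rep)
    if body in ("x", "X"):
        return PatternElement("any", frozenset(), lo, hi, "x")
    if body.startswith("[") and body.endswith("]"):
        residues = body[1:-1].upper()
        kind = "set"
    elif body.startswith("{") and body.endswith("}"):
        residues = body[1:-1].upper()
        kind = "exclude"
    elif len(body) == 1:
        residues = body.upper()
        kind = "fixed"
    else:
        raise ProsPatternError(f"unrecognised pattern element {token!r}")
    if not residues:
        raise ProsPatternError(f"empty residue set in element {token!r}")
    bad = set(residues) - AMINO_ACIDS
    if bad:
        raise ProsPatternError(
            f"non-amino-acid residues {sorted(bad)} in element {token!r}"
        )
    return PatternElement(kind, frozenset(residues), lo, hi, residues)


@dataclass(frozen=True)
class ProsPattern:
    """A compiled PROSITE pattern; compiling then rendering round-trips."""

    pattern_text: str
    elements: tuple[PatternElement, ...] = field(default_factory=tuple)
    n_anchor: bool = False
    c_anchor: bool = False

    @classmethod
    def parse(cls, text: str) -> "ProsPattern":
        raw = text.strip().rstrip(".")
        if not raw:
            raise ProsPatternError("empty pattern")
        work = raw
        n_anchor = work.startswith("<")
        if n_anchor:
            work = work[1:]
        c_anchor = work.endswith(">")
        if c_anchor:
            work = work[:-1]
        tokens = [t for t in work.split("-") if t != ""]
        if not tokens:
            raise ProsPatternError(f"no elements in pattern {text!r}")
        elements = tuple(_parse_element(t) for t in tokens)
        return cls(raw, elements, n_anchor, c_anchor)

    def render(self) -> str:
        body = "-".join(e.render() for e in self.elements)
        return ("<" if self.n_anchor else "") + body + (">" if self.c_anchor else "")

    @property
    def min_length(self) -> int:
        return sum(e.min_rep for e in self.elements)

    def match_ends(self, seq: str, start0: int) -> list[int]:
        """All 0-based exclusive end positions of matches starting at start0."""
        ends: list[int] = []

        def walk(idx: int, pos: int) -> None:
            if idx == len(self.elements):
                ends.append(pos)
                return
            el = self.elements[idx]
            # consume the mandatory repeats
            p = pos
            for _ in range(el.min_rep):
                if p >= len(seq) or not el.accepts(seq[p]):
                    return
                p += 1
            walk(idx + 1, p)
            for _ in range(el.max_rep - el.min_rep):
                if p >= len(seq) or not el.accepts(seq[p]):
                    return
                p += 1
                walk(idx + 1, p)

        walk(0, start0)
        return sorted(set(ends))


def prosite_scan(
    seq: str, pattern: ProsPattern | str
) -> list[tuple[int, int]]:
    """All (start, end) 1-based inclusive windows of ``seq`` matching ``pattern``."""
    if isinstance(pattern, str):
        pattern = ProsPattern.parse(pattern)
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    starts: Sequence[int] = (0,) if pattern.n_anchor else range(len(seq))
    matches: list[tuple[int, int]] = []
    for s in starts:
        for e in pattern.match_ends(seq, s):
            if e == s:
                continue
            if pattern.c_anchor and e != len(seq):
                continue
            matches.append((s + 1, e))
    matches.sort()
    return matches
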
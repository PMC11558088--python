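"""Descriptor extraction from DNA strings and the term alphabet.

Four descriptor kinds are produced from a DNA string:

* **stacking** — sliding 4-character windows (step 1) over each
  parenthesis-delimited stack domain, parentheses included; a domain of
  ``L`` paired nucleotides yields ``L - 1`` quartets, generalizing the
  nearest-neighbor dimer.  The full quartet alphabet has 400 members:
  256 middle ``NNNN``, 128 end ``(NNN`` / ``NNN)`` and 16 double-
  parenthesis ``(NN)`` terms.
* **dangling** — one token per unpaired terminal nucleotide: ``*N`` away
  from the helix, ``N(M`` / ``M)N`` for the nucleotide directly adjacent
  to a parenthesis (``M`` is the nucleotide just inside it); 36 tokens in
  total, 32 of which carry a parenthesis.
* **looping** — single-character tokens for nucleotides between two stack
  domains.
* **initiating** — ``(X`` and ``X)`` for the first/last nucleotide of
  each stack domain, plus the strand separator ``.``.

Reverse-complement symmetry identifies quartets read from the opposite
strand (e.g. ``TGCT`` ≡ ``AGCA``), leaving 136 unique middle and 64
unique end stacking classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .notation import DNA_ALPHABET, NotationError, parse_dna_string, revcomp

KINDS = ("stacking", "dangling", "looping", "initiating")
_BASES = "ACGT"

__all__ = [
    "KINDS",
    "Descriptor",
    "TermTable",
    "DescriptorError",
    "UnknownTermError",
    "extract_stacking",
    "extract_dangling",
    "extract_looping",
    "extract_initiating",
    "extract_all",
    "enumerate_terms",
    "canonicalize_stacking",
]


class DescriptorError(ValueError):
    """Raised when a DNA string has no legal descriptor decomposition."""


class UnknownTermError(KeyError):
    """Raised when a token is absent from a :class:`TermTable`."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"unknown term {token!r}")


@dataclass(frozen=True)
class Descriptor:
    """One descriptor token.

    ``positions`` are 0-based nucleotide indices (counting nucleotides
    only, across the whole string) covered by the token.  ``distance`` is
    the distance in nucleotides from an unpaired (dangling/looping)
    nucleotide to its nearest stack domain — 1 for directly adjacent —
    and ``None`` for stacking/initiating tokens or when the segment has
    no stack domain at all.
    """

    token: str
    kind: str
    positions: tuple = ()
    distance: int | None = None


@dataclass(frozen=True)
class _Segment:
    bases: str
    domains: tuple  # (open_nt_idx, length) in segment-local nucleotide coords
    nt_offset: int  # global nucleotide index of the segment's first base
    index: int  # 0 = strand1


def _segments(text: str) -> tuple[list[_Segment], int | None]:
    """Validate via the parser, then re-scan into per-segment structure.

    Returns the segments and the nucleotide count before the dot (or
    ``None`` if the string is single-stranded).
    """
    parse_dna_string(text)  # raises NotationError on malformed input
    segs: list[_Segment] = []
    nt_offset = 0
    dot_before = None
    for idx, seg in enumerate(text.split(".")):
        bases = []
        domains = []
        open_at = None
        for ch in seg:
            if ch == "(":
                open_at = len(bases)
            elif ch == ")":
                domains.append((open_at, len(bases) - open_at))
                open_at = None
            else:
                bases.append(ch)
        segs.append(_Segment("".join(bases), tuple(domains), nt_offset, idx))
        nt_offset += len(bases)
        if idx == 0 and "." in text:
            dot_before = nt_offset
    return segs, dot_before


def extract_stacking(s: str, both_strands: bool = False) -> list[Descriptor]:
    """Sliding 4-character windows over each stack domain, parens included.

    By default only strand1's domains are encoded (a duplex is encoded
    once); ``both_strands=True`` also walks the second strand's domains.
    A stack domain of fewer than 2 paired nucleotides admits no quartet
    and raises :class:`DescriptorError`.
    """
    segs, _ = _segments(s)
    out: list[Descriptor] = []
    for seg in segs:
        if seg.index > 0 and not both_strands:
            continue
        for i0, ln in seg.domains:
            if ln < 2:
                raise DescriptorError(
                    f"stack domain of length {ln} admits no stacking quartet"
                )
            region = "(" + seg.bases[i0 : i0 + ln] + ")"
            for w in range(len(region) - 3):
                window = region[w : w + 4]
                positions = tuple(
                    seg.nt_offset + i0 + (w + t) - 1
                    for t, ch in enumerate(window)
                    if ch in DNA_ALPHABET
                )
                out.append(Descriptor(window, "stacking", positions))
    return out


def extract_dangling(s: str) -> list[Descriptor]:
    """One token per dangle nucleotide, in string order.

    The nucleotide adjacent to a parenthesis absorbs the parenthesis and
    the first nucleotide inside it (``N(M`` on the 5' side, ``M)N`` on
    the 3' side); every other dangle nucleotide becomes ``*N``.  A
    segment without any stack domain is all dangle: each nucleotide
    yields ``*N`` with ``distance=None``.
    """
    segs, _ = _segments(s)
    out: list[Descriptor] = []
    for seg in segs:
        if not seg.domains:
            for q, b in enumerate(seg.bases):
                out.append(Descriptor("*" + b, "dangling", (seg.nt_offset + q,), None))
            continue
        first_open, first_len = seg.domains[0]
        last_open, last_len = seg.domains[-1]
        last_close = last_open + last_len  # index of first base after the run
        for q in range(first_open):  # 5' dangle
            dist = first_open - q
            if dist == 1:
                token = seg.bases[q] + "(" + seg.bases[first_open]
            else:
                token = "*" + seg.bases[q]
            out.append(Descriptor(token, "dangling", (seg.nt_offset + q,), dist))
        for q in range(last_close, len(seg.bases)):  # 3' dangle
            dist = q - last_close + 1
            if dist == 1:
                token = seg.bases[last_close - 1] + ")" + seg.bases[q]
            else:
                token = "*" + seg.bases[q]
            out.append(Descriptor(token, "dangling", (seg.nt_offset + q,), dist))
    return out


def extract_looping(s: str) -> list[Descriptor]:
    """Single-character tokens for nucleotides between two stack domains.

    The distance of a loop nucleotide is measured to the nearer flanking
    domain.
    """
    segs, _ = _segments(s)
    out: list[Descriptor] = []
    for seg in segs:
        for (o1, l1), (o2, _) in zip(seg.domains, seg.domains[1:]):
            close = o1 + l1
            for q in range(close, o2):
                dist = min(q - close + 1, o2 - q)
                out.append(
                    Descriptor(seg.bases[q], "looping", (seg.nt_offset + q,), dist)
                )
    return out


def extract_initiating(s: str, both_strands: bool = False) -> list[Descriptor]:
    """``(X`` / ``X)`` per stack domain plus one ``.`` if present."""
    segs, dot_before = _segments(s)
    out: list[Descriptor] = []
    for seg in segs:
        if seg.index > 0 and not both_strands:
            continue
        for i0, ln in seg.domains:
            first = seg.nt_offset + i0
            last = seg.nt_offset + i0 + ln - 1
            out.append(Descriptor("(" + seg.bases[i0], "initiating", (first,)))
            out.append(Descriptor(seg.bases[i0 + ln - 1] + ")", "initiating", (last,)))
    if dot_before is not None:
        out.append(Descriptor(".", "initiating", ()))
    return out


def extract_all(s: str, both_strands: bool = False) -> list[Descriptor]:
    """All descriptors, ordered stacking → dangling → looping → initiating,
    string order within each kind."""
    return (
        extract_stacking(s, both_strands)
        + extract_dangling(s)
        + extract_looping(s)
        + extract_initiating(s, both_strands)
    )


def enumerate_terms(kind: str) -> list[str]:
    """The exhaustive legal token alphabet of one descriptor kind.

    Counts: stacking 400 (= 256 middle + 128 end + 16 ``(NN)``),
    dangling 36 (= 16 ``N(M`` + 16 ``M)N`` + 4 ``*N``), looping 4,
    initiating 9 (= 8 + ``.``).
    """
    if kind == "stacking":
        middle = ["".join(p) for p in itertools.product(_BASES, repeat=4)]
        left = ["(" + "".join(p) for p in itertools.product(_BASES, repeat=3)]
        right = ["".join(p) + ")" for p in itertools.product(_BASES, repeat=3)]
        double = ["(" + "".join(p) + ")" for p in itertools.product(_BASES, repeat=2)]
        return middle + left + right + double
    if kind == "dangling":
        with_open = [n + "(" + m for n in _BASES for m in _BASES]
        with_close = [m + ")" + n for m in _BASES for n in _BASES]
        starred = ["*" + n for n in _BASES]
        return with_open + with_close + starred
    if kind == "looping":
        return list(_BASES)
    if kind == "initiating":
        return ["(" + n for n in _BASES] + [n + ")" for n in _BASES] + ["."]
    raise ValueError(f"unknown descriptor kind {kind!r}")


def _stacking_image(token: str) -> str:
    """The opposite-strand reading of a stacking term."""
    if token.startswith("(") and token.endswith(")"):
        return "(" + revcomp(token[1:-1]) + ")"
    if token.startswith("("):
        return revcomp(token[1:]) + ")"
    if token.endswith(")"):
        return "(" + revcomp(token[:-1])
    return revcomp(token)


def canonicalize_stacking(token: str) -> str:
    """Canonical representative of a stacking term's reverse-complement class.

    Two quartets read from opposite strands of the same helix are
    physically identical (``TGCT`` ≡ ``AGCA``); the lexicographically
    smaller of the token and its opposite-strand image is the class
    representative.  Idempotent.
    """
    if token not in _STACKING_SET:
        raise DescriptorError(f"illegal stacking term {token!r}")
    return min(token, _stacking_image(token))


_STACKING_SET = frozenset(enumerate_terms("stacking"))


@dataclass(frozen=True)
class TermTable:
    """Token → identifier mapping (the "Number" feature).

    Identifiers are dense positive integers assigned kind-major in
    lexicographic order within each kind: stacking 1–400, dangling
    401–436, looping 437–440, initiating 441–449.
    """

    ids: dict
    kinds: dict

    @classmethod
    def default(cls) -> "TermTable":
        ids: dict[str, int] = {}
        kinds: dict[str, str] = {}
        next_id = 1
        for kind in KINDS:
            for token in sorted(enumerate_terms(kind)):
                ids[token] = next_id
                kinds[token] = kind
                next_id += 1
        return cls(ids=ids, kinds=kinds)

    def identifier(self, token: str) -> int:
        try:
            return self.ids[token]
        except KeyError:
            raise UnknownTermError(token) from None

    @property
    def max_identifier(self) -> int:
        return max(self.ids.values())

    def __len__(self) -> int:
        return len(self.ids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("token\tkind\tidentifier\n")
            for token, ident in sorted(self.ids.items(), key=lambda kv: kv[1]):
                fh.write(f"{token}\t{self.kinds[token]}\t{ident}\n")

    @classmethod
    def from_tsv(cls, path) -> "TermTable":
        ids: dict[str, int] = {}
        kinds: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "token\tkind\tidentifier":
                raise ValueError(f"unexpected term-table header: {header!r}")
            for line in fh:
                token, kind, ident = line.rstrip("\n").split("\t")
                ids[token] = int(ident)
                kinds[token] = kind
        return cls(ids=ids, kinds=kinds)
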
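"""Two-strand DNA secondary-structure notation.

A duplex is written as a *DNA string* over the alphabet ``A C G T ( ) .``:

* nucleotides are written 5'→3' with their one-letter abbreviations;
* every contiguous run of Watson–Crick-paired nucleotides (a *stack
  domain*) is enclosed in one pair of parentheses, unpaired nucleotides
  stay outside;
* a single ``.`` separates the first strand from the second in a
  two-strand string (the second strand is also written 5'→3').

When the second strand is exactly the complement of the first strand's
paired region the single-strand shorthand may be used — ``(CGCG)`` denotes
the perfect four-base-pair duplex with the complementary strand implied.

Stack domains of the first strand are matched with stack domains of the
second strand in nested (last-opened, first-closed) order, the same
convention dot-parens-plus uses for its parentheses.  Coordinates are
0-based internally; user-facing error positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")
STRING_ALPHABET = frozenset("ACGT().")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "Strand",
    "StackDomain",
    "Duplex",
    "NotationError",
    "revcomp",
    "complement",
    "parse_dna_string",
    "encode_duplex",
]


def complement(seq: str) -> str:
    """Watson–Crick complement, same orientation."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a 5'→3' sequence (result again 5'→3')."""
    return seq.translate(_COMPLEMENT)[::-1]


class NotationError(ValueError):
    """Structured error for malformed DNA strings or duplexes.

    ``position`` is the 0-based character index in the offending string,
    reported 1-based in the message.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position + 1})"
        super().__init__(message)


@dataclass(frozen=True)
class Strand:
    """A single DNA strand, fixed 5'→3' orientation."""

    bases: str

    def __post_init__(self):
        if not self.bases:
            raise NotationError("strand must be non-empty")
        for i, b in enumerate(self.bases):
            if b not in DNA_ALPHABET:
                raise NotationError(f"illegal base {b!r}", position=i)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class StackDomain:
    """A contiguous paired run: strand1[i_start + k] pairs strand2[j_start + length - 1 - k]."""

    i_start: int
    j_start: int
    length: int

    @property
    def i_stop(self) -> int:  # half-open
        return self.i_start + self.length

    @property
    def j_stop(self) -> int:  # half-open
        return self.j_start + self.length


@dataclass(frozen=True)
class Duplex:
    """One or two strands plus an explicit base-pairing map.

    ``pairing`` holds 0-based index pairs ``(i, j)``: position *i* on
    ``strand1`` pairs with position *j* on ``strand2``.  Paired bases must
    be Watson–Crick complements and within each strand the paired indices
    must form contiguous antiparallel runs (stack domains).
    """

    strand1: Strand
    strand2: Strand | None = None
    pairing: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "pairing", frozenset(self.pairing))
        if self.pairing and self.strand2 is None:
            raise NotationError("pairing given but strand2 is missing")
        seen_i, seen_j = set(), set()
        for i, j in self.pairing:
            if not (0 <= i < len(self.strand1)):
                raise NotationError(f"pair index {i} out of range on strand1")
            if not (0 <= j < len(self.strand2)):
                raise NotationError(f"pair index {j} out of range on strand2")
            if i in seen_i or j in seen_j:
                raise NotationError(f"index appears in more than one pair: ({i}, {j})")
            seen_i.add(i)
            seen_j.add(j)
            b1 = self.strand1.bases[i]
            b2 = self.strand2.bases[j]
            if complement(b1) != b2:
                raise NotationError(
                    f"non-complementary pair {b1}·{b2} at (strand1:{i + 1}, strand2:{j + 1})"
                )
        self.stack_domains()  # validates contiguity

    def stack_domains(self) -> list[StackDomain]:
        """Stack domains in strand1 order (5'→3')."""
        if not self.pairing:
            return []
        pairs = sorted(self.pairing)
        domains: list[StackDomain] = []
        run = [pairs[0]]
        for i, j in pairs[1:]:
            pi, pj = run[-1]
            if i == pi + 1 and j == pj - 1:
                run.append((i, j))
            elif i == pi + 1 and j != pj - 1:
                raise NotationError(
                    "paired indices on strand1 are contiguous but strand2 partners are not "
                    f"antiparallel-contiguous near strand1 position {i + 1}"
                )
            else:
                domains.append(self._close_run(run))
                run = [(i, j)]
        domains.append(self._close_run(run))
        # strand2 occupancy of each domain must also be one contiguous block,
        # which _close_run guarantees; check blocks do not interleave on strand2
        blocks = sorted((d.j_start, d.j_stop) for d in domains)
        for (_, stop), (start, _) in zip(blocks, blocks[1:]):
            if start < stop:
                raise NotationError("stack domains overlap on strand2")
        return domains

    @staticmethod
    def _close_run(run: list) -> StackDomain:
        i0, j0 = run[0]
        return StackDomain(i_start=i0, j_start=j0 - len(run) + 1, length=len(run))

    def paired_indices1(self) -> set:
        return {i for i, _ in self.pairing}

    def paired_indices2(self) -> set:
        return {j for _, j in self.pairing}


def _scan_segment(seg: str, offset: int) -> tuple[str, list]:
    """Scan one strand segment: return (bases, [(open_nt_idx, length)]).

    ``open_nt_idx`` is the index of the first paired nucleotide within the
    segment's base sequence.  ``offset`` is the character offset of the
    segment in the full string, used only for error positions.
    """
    bases: list[str] = []
    domains: list[tuple[int, int]] = []
    open_at: int | None = None
    for k, ch in enumerate(seg):
        pos = offset + k
        if ch == "(":
            if open_at is not None:
                raise NotationError("nested parentheses are not allowed", position=pos)
            open_at = len(bases)
        elif ch == ")":
            if open_at is None:
                raise NotationError("unmatched ')'", position=pos)
            length = len(bases) - open_at
            if length == 0:
                raise NotationError("empty parentheses", position=pos)
            domains.append((open_at, length))
            open_at = None
        elif ch in DNA_ALPHABET:
            bases.append(ch)
        else:
            raise NotationError(f"illegal character {ch!r}", position=pos)
    if open_at is not None:
        raise NotationError("unmatched '('", position=offset + len(seg) - 1)
    return "".join(bases), domains


def parse_dna_string(text: str) -> Duplex:
    """Parse a DNA string into a :class:`Duplex`.

    Single-strand shorthand (no ``.``) with parentheses yields a duplex
    whose second strand is the implied complement of the paired domains.
    """
    if not text:
        raise NotationError("empty DNA string")
    if text.count(".") > 1:
        raise NotationError("more than one '.'", position=text.index(".", text.index(".") + 1))
    for i, ch in enumerate(text):
        if ch not in STRING_ALPHABET:
            raise NotationError(f"illegal character {ch!r}", position=i)

    if "." in text:
        dot = text.index(".")
        seg1, seg2 = text[:dot], text[dot + 1 :]
        bases1, doms1 = _scan_segment(seg1, 0)
        bases2, doms2 = _scan_segment(seg2, dot + 1)
        if not bases1 or not bases2:
            raise NotationError("both strands of a two-strand string must be non-empty")
        if len(doms1) != len(doms2):
            raise NotationError(
                f"strand1 has {len(doms1)} stack domains but strand2 has {len(doms2)}"
            )
        pairing = set()
        for k, (i0, ln1) in enumerate(doms1):
            j0, ln2 = doms2[len(doms2) - 1 - k]  # nested matching
            if ln1 != ln2:
                raise NotationError(
                    f"stack domain {k + 1} has length {ln1} on strand1 but its partner has {ln2}"
                )
            for t in range(ln1):
                pairing.add((i0 + t, j0 + ln1 - 1 - t))
        return Duplex(Strand(bases1), Strand(bases2), frozenset(pairing))

    bases1, doms1 = _scan_segment(text, 0)
    if not doms1:
        return Duplex(Strand(bases1))
    # implied complementary strand: reverse-complement of the paired
    # domains, concatenated in reverse domain order (nested matching)
    parts = [revcomp(bases1[i0 : i0 + ln]) for i0, ln in reversed(doms1)]
    bases2 = "".join(parts)
    pairing = set()
    j_cursor = 0
    for k, (i0, ln) in enumerate(reversed(doms1)):
        for t in range(ln):
            pairing.add((i0 + t, j_cursor + ln - 1 - t))
        j_cursor += ln
    return Duplex(Strand(bases1), Strand(bases2), frozenset(pairing))


def _segment_text(bases: str, domains: list) -> str:
    out = []
    opens = {i0 for i0, _ in domains}
    closes = {i0 + ln for i0, ln in domains}
    for idx, b in enumerate(bases):
        if idx in opens:
            out.append("(")
        if idx in closes:
            out.append(")")
        out.append(b)
    if len(bases) in closes:
        out.append(")")
    return "".join(out)


def encode_duplex(d: Duplex, allow_shorthand: bool = True) -> str:
    """Encode a duplex as a DNA string.

    Paired runs are wrapped in parentheses; if ``allow_shorthand`` and the
    second strand is exactly the complement of strand1's paired region
    (fully paired, nested order), the single-strand shorthand is emitted.
    Raises :class:`NotationError` for pairings that cannot be written with
    one parenthesis pair per stack domain in nested order.
    """
    domains = d.stack_domains()
    if d.strand2 is None:
        return d.strand1.bases

    # nested order: as i_start increases, j-blocks must strictly descend
    j_blocks = [(dom.j_start, dom.j_stop) for dom in domains]
    for k in range(len(j_blocks) - 1):
        if not j_blocks[k + 1][1] <= j_blocks[k][0]:
            raise NotationError(
                "pairing is not nested: cannot be expressed with one parenthesis "
                "pair per stack domain"
            )

    doms1 = [(dom.i_start, dom.length) for dom in domains]
    seg1 = _segment_text(d.strand1.bases, doms1)

    fully_paired2 = d.paired_indices2() == set(range(len(d.strand2)))
    if allow_shorthand and domains and fully_paired2:
        return seg1

    doms2 = sorted((dom.j_start, dom.length) for dom in domains)
    seg2 = _segment_text(d.strand2.bases, doms2)
    return seg1 + "." + seg2
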
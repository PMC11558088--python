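"""Sequence-pool generators for the two prediction campaigns.

**Hybridization pool** — 10 000 perfect duplexes plus 10 000 duplexes
with dangles by default.  Stack domains span 5–14 nt (shorter duplexes
denature near room temperature; longer ones risk intramolecular
structure), dangles span 1–4 nt (longer dangles contribute like 4-nt
ones).  Counting the perfect arrangement, ten structural duplex types
are generated, indexed by which of the four strand termini carry a
dangle: none; each single terminus (4); both termini of one strand (2);
the two diagonal one-per-strand arrangements (2); and all four (1).

**Strand-displacement pool** — 10 000 sequence sets by default.  Each
set has an invading strand (toehold ``t`` of 4–14 nt, spacer ``s1`` of
0–10 thymines with the spacer kept shorter than the toehold, branch
migration domain ``b`` of 22 nt), a substrate complex (incumbent ``b``
bound to the template, toehold exposed) and the product complex (invader
bound to the template, spacers unpaired).

Generation is a pure function of (spec, seed).  A hygiene filter
(switchable) rejects runs of five or more identical bases and
self-reverse-complementary stack domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .notation import Duplex, Strand, encode_duplex, revcomp

_BASES = "ACGT"

# dangle occupancy bits: (strand1 5', strand1 3', strand2 5', strand2 3')
PERFECT_TYPE = (0, 0, 0, 0)
DANGLE_TYPES = (
    (1, 0, 0, 0),
    (0, 1, 0, 0),
    (0, 0, 1, 0),
    (0, 0, 0, 1),
    (1, 1, 0, 0),
    (0, 0, 1, 1),
    (1, 0, 1, 0),  # diagonal: both 5' ends (opposite duplex ends)
    (0, 1, 0, 1),  # diagonal: both 3' ends
    (1, 1, 1, 1),
)
ALL_TYPES = (PERFECT_TYPE,) + DANGLE_TYPES

__all__ = [
    "PERFECT_TYPE",
    "DANGLE_TYPES",
    "ALL_TYPES",
    "PoolError",
    "HybridizationPoolSpec",
    "PoolDuplex",
    "DisplacementPoolSpec",
    "SequenceSet",
    "duplex_type",
    "generate_hybridization_pool",
    "generate_displacement_pool",
]


class PoolError(ValueError):
    """Structured error for infeasible pool specifications."""


@dataclass(frozen=True)
class HybridizationPoolSpec:
    n_perfect: int = 10_000
    n_dangled: int = 10_000
    stack_length: tuple = (5, 14)
    dangle_length: tuple = (1, 4)
    seed: int = 0
    filter_runs: bool = True

    def __post_init__(self):
        if self.n_perfect < 0 or self.n_dangled < 0:
            raise PoolError("pool sizes must be non-negative")
        if not (2 <= self.stack_length[0] <= self.stack_length[1]):
            raise PoolError(f"invalid stack length range {self.stack_length}")
        if not (1 <= self.dangle_length[0] <= self.dangle_length[1]):
            raise PoolError(f"invalid dangle length range {self.dangle_length}")


@dataclass(frozen=True)
class PoolDuplex:
    """One pool member: duplex, its DNA string, and its structural type."""

    id: int
    duplex: Duplex
    string: str
    type_bits: tuple


@dataclass(frozen=True)
class DisplacementPoolSpec:
    n_sets: int = 10_000
    toehold_length: tuple = (4, 14)
    spacer_max: int = 10
    branch_length: int = 22
    seed: int = 0
    filter_runs: bool = True

    def __post_init__(self):
        if self.n_sets < 0:
            raise PoolError("pool size must be non-negative")
        if not (1 <= self.toehold_length[0] <= self.toehold_length[1]):
            raise PoolError(f"invalid toehold length range {self.toehold_length}")
        if self.spacer_max < 0 or self.branch_length < 1:
            raise PoolError("invalid spacer/branch specification")


@dataclass(frozen=True)
class SequenceSet:
    """One strand-displacement design: toehold + spacer + branch domains.

    The invading strand is ``t + s1 + b`` (5'→3'); the template is
    ``b* + s2 + t*`` so the invader pairs antiparallel with both the
    toehold and branch domains.  Spacer ``s1`` is poly-T; ``s2`` is a
    non-complementary poly-C spacer of the same length.
    """

    id: int
    toehold: str
    spacer1: str
    branch: str

    @property
    def spacer2(self) -> str:
        return "C" * len(self.spacer1)

    @property
    def invading_strand(self) -> str:
        return self.toehold + self.spacer1 + self.branch

    @property
    def template_strand(self) -> str:
        return revcomp(self.branch) + self.spacer2 + revcomp(self.toehold)

    @property
    def invading_string(self) -> str:
        """The invader alone, fully unpaired."""
        return self.invading_strand

    @property
    def product_string(self) -> str:
        """Invader bound to the template; spacers remain unpaired."""
        t, s1, b = self.toehold, self.spacer1, self.branch
        return (
            f"({t}){s1}({b})." + f"({revcomp(b)}){self.spacer2}({revcomp(t)})"
        )

    @property
    def substrate_string(self) -> str:
        """Incumbent branch strand bound to the template; toehold exposed."""
        b = self.branch
        return f"({b}).({revcomp(b)}){self.spacer2}{revcomp(self.toehold)}"


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[k] for k in rng.integers(0, 4, size=length))


def _has_run(seq: str, k: int = 5) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= k:
            return True
    return False


def _draw_seq(rng, length: int, filter_runs: bool, reject_palindrome: bool = False) -> str:
    for _ in range(1000):
        seq = _random_seq(rng, length)
        if filter_runs and _has_run(seq):
            continue
        if reject_palindrome and seq == revcomp(seq):
            continue
        return seq
    raise PoolError(f"could not draw an admissible sequence of length {length}")


def duplex_type(d: Duplex) -> tuple:
    """Dangle-occupancy bits of a (loop-free) pool duplex."""
    p1, p2 = d.paired_indices1(), d.paired_indices2()
    bits1 = (int(min(p1) > 0), int(max(p1) < len(d.strand1) - 1))
    if d.strand2 is None:
        return bits1 + (0, 0)
    return bits1 + (int(min(p2) > 0), int(max(p2) < len(d.strand2) - 1))


def _make_duplex(rng, spec: HybridizationPoolSpec, bits: tuple) -> Duplex:
    lo, hi = spec.stack_length
    L = int(rng.integers(lo, hi + 1))
    stack = _draw_seq(rng, L, spec.filter_runs, reject_palindrome=spec.filter_runs)
    dlo, dhi = spec.dangle_length
    dangles = [
        _draw_seq(rng, int(rng.integers(dlo, dhi + 1)), spec.filter_runs) if bit else ""
        for bit in bits
    ]
    d5a, d3a, d5b, d3b = dangles
    s1 = d5a + stack + d3a
    s2 = d5b + revcomp(stack) + d3b
    off1, off2 = len(d5a), len(d5b)
    pairing = frozenset(
        (off1 + k, off2 + L - 1 - k) for k in range(L)
    )
    return Duplex(Strand(s1), Strand(s2), pairing)


def generate_hybridization_pool(spec: HybridizationPoolSpec) -> list:
    """Generate the deduplicated hybridization pool, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    items: list[PoolDuplex] = []
    seen: set = set()

    def add(bits: tuple) -> None:
        for _ in range(1000):
            d = _make_duplex(rng, spec, bits)
            key = (d.strand1.bases, d.strand2.bases, bits)
            if key in seen:
                continue
            seen.add(key)
            items.append(
                PoolDuplex(
                    id=len(items),
                    duplex=d,
                    string=encode_duplex(d),
                    type_bits=bits,
                )
            )
            return
        raise PoolError("could not generate a fresh duplex; spec too constrained")

    for _ in range(spec.n_perfect):
        add(PERFECT_TYPE)
    for k in range(spec.n_dangled):
        add(DANGLE_TYPES[k % len(DANGLE_TYPES)])
    return items


def generate_displacement_pool(spec: DisplacementPoolSpec) -> list:
    """Generate the deduplicated strand-displacement pool."""
    rng = np.random.default_rng(spec.seed)
    items: list[SequenceSet] = []
    seen: set = set()
    lo, hi = spec.toehold_length
    for _ in range(spec.n_sets):
        for _attempt in range(1000):
            toe_len = int(rng.integers(lo, hi + 1))
            x_max = min(spec.spacer_max, toe_len - 1)
            s_len = int(rng.integers(0, x_max + 1))
            toehold = _draw_seq(rng, toe_len, spec.filter_runs)
            branch = _draw_seq(rng, spec.branch_length, spec.filter_runs)
            key = (toehold, s_len, branch)
            if key in seen:
                continue
            seen.add(key)
            items.append(
                SequenceSet(
                    id=len(items),
                    toehold=toehold,
                    spacer1="T" * s_len,
                    branch=branch,
                )
            )
            break
        else:
            raise PoolError("could not generate a fresh sequence set")
    return items
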
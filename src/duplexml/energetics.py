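"""Assembly of per-term interaction energies (kcal/mol).

A stacking quartet involves four bases (Base1–Base2 stacked on one
strand, Base4–Base3 on the other; 1·4 and 2·3 are the Watson–Crick
pairs).  Its energy is the sum of a hydrogen-bond part and a stacking
part built from six pairwise interaction energies::

    E       = E_HB + E_stack
    E_HB    = E_int,1-4 + E_int,2-3
    E_stack = E_int,1-2 + E_int,3-4 + E_int,1-3 + E_int,2-4

A dangling term keeps one hydrogen-bond pair plus the two stacking
interactions of the dangle base (``E_int,1-3`` intra-strand and
``E_int,3-4`` inter-strand).  Each pairwise interaction energy is
counterpoise-corrected (Boys–Bernardi): the dimer energy minus each
monomer's energy evaluated in the full dimer basis, which removes
basis-set superposition error.  When several structural conformations
are supplied per interaction, their corrected energies are averaged
before summation.

The ``(XY)`` double-parenthesis terms are not computed directly: among
the 25 combinations ``xXYy`` with ``x ∈ {A,C,G,T,(}`` and
``y ∈ {A,C,G,T,)}``, the energy of ``(XY)`` is the mean of the other 24.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

import numpy as np

from .descriptors import canonicalize_stacking, enumerate_terms
from .notation import NotationError  # noqa: F401  (re-exported error family)

STACKING_COMPONENTS = ("1-4", "2-3", "1-2", "3-4", "1-3", "2-4")
DANGLING_COMPONENTS = ("hb", "1-3", "3-4")

DEFAULT_STACKING_RANGE = (-52.174, -20.615)
DEFAULT_DANGLING_RANGE = (-15.0, -2.0)

_BASES = "ACGT"

__all__ = [
    "STACKING_COMPONENTS",
    "DANGLING_COMPONENTS",
    "DEFAULT_STACKING_RANGE",
    "DEFAULT_DANGLING_RANGE",
    "EnergeticsError",
    "InteractionEnergySet",
    "EnergyTable",
    "counterpoise_pair_energy",
    "stacking_term_energy",
    "dangling_term_energy",
    "double_paren_contributors",
    "fill_double_paren_terms",
    "generate_synthetic_energy_table",
]


class EnergeticsError(ValueError):
    """Structured error for missing components or invalid energy inputs."""


def counterpoise_pair_energy(e_ab: float, e_a: float, e_b: float) -> float:
    """Counterpoise-corrected interaction energy ``E_AB − E_A − E_B``.

    All three energies are evaluated in the full dimer basis.
    """
    for name, v in (("E_AB", e_ab), ("E_A", e_a), ("E_B", e_b)):
        if not np.isfinite(v):
            raise EnergeticsError(f"{name} is not finite: {v!r}")
    return e_ab - e_a - e_b


@dataclass
class InteractionEnergySet:
    """Pairwise interaction components of one term.

    ``components`` maps a component name (see :data:`STACKING_COMPONENTS`
    / :data:`DANGLING_COMPONENTS`) to a list of per-conformation
    counterpoise triples ``(E_AB, E_A, E_B)``; the corrected energies of
    the conformations are averaged.
    """

    kind: str  # "stacking" or "dangling"
    components: dict = field(default_factory=dict)

    def component_energy(self, name: str) -> float:
        if name not in self.components or not self.components[name]:
            raise EnergeticsError(f"missing interaction component {name!r}")
        return fmean(
            counterpoise_pair_energy(*triple) for triple in self.components[name]
        )


def stacking_term_energy(ie: InteractionEnergySet) -> float:
    """E = (E₁₄ + E₂₃) + (E₁₂ + E₃₄ + E₁₃ + E₂₄), conformation-averaged."""
    return sum(ie.component_energy(name) for name in STACKING_COMPONENTS)


def dangling_term_energy(ie: InteractionEnergySet) -> float:
    """E = E_HB + E₁₃ + E₃₄ for a dangling term.

    Only three interactions exist for a dangle: the retained base pair's
    hydrogen bond plus the dangle base's intra- and inter-strand stacking.
    """
    return sum(ie.component_energy(name) for name in DANGLING_COMPONENTS)


def double_paren_contributors(core: str) -> list[str]:
    """The 24 terms whose mean defines ``(XY)`` for a core dimer ``XY``.

    The 25 combinations are ``xXYy`` with ``x ∈ {A,C,G,T,(}`` and
    ``y ∈ {A,C,G,T,)}`` read jointly so that parentheses stay matched:
    16 middle, 4 left-end, 4 right-end terms, plus ``(XY)`` itself which
    is excluded.
    """
    if len(core) != 2 or any(b not in _BASES for b in core):
        raise EnergeticsError(f"illegal core dimer {core!r}")
    middle = [x + core + y for x in _BASES for y in _BASES]
    left = ["(" + core + y for y in _BASES]
    right = [x + core + ")" for x in _BASES]
    return middle + left + right


@dataclass
class EnergyTable:
    """Per-term energies in kcal/mol over the full 449-token alphabet.

    Looping, initiating and starred (``*N``) dangling terms carry zero
    energy; only stacking terms and parenthesis-bearing dangling terms
    are nonzero.
    """

    energies: dict

    def energy(self, token: str) -> float:
        return self.energies[token]

    def __contains__(self, token: str) -> bool:
        return token in self.energies

    def stacking_values(self) -> np.ndarray:
        stack = set(enumerate_terms("stacking"))
        return np.array([v for t, v in self.energies.items() if t in stack])

    @property
    def min_energy(self) -> float:
        return min(self.energies.values())

    def to_tsv(self, path) -> None:
        kind_of = _kind_lookup()
        with open(path, "w") as fh:
            fh.write("token\tkind\tenergy_kcal_mol\n")
            for token in sorted(self.energies):
                fh.write(f"{token}\t{kind_of[token]}\t{self.energies[token]!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "EnergyTable":
        energies: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "token\tkind\tenergy_kcal_mol":
                raise ValueError(f"unexpected energy-table header: {header!r}")
            for line in fh:
                token, _, value = line.rstrip("\n").split("\t")
                energies[token] = float(value)
        return cls(energies=energies)


def _kind_lookup() -> dict:
    kind_of = {}
    for kind in ("stacking", "dangling", "looping", "initiating"):
        for token in enumerate_terms(kind):
            kind_of[token] = kind
    return kind_of


def fill_double_paren_terms(table: EnergyTable) -> EnergyTable:
    """Fill every ``(XY)`` entry with the mean of its 24 contributors.

    Non-``(XY)`` entries are returned unchanged; missing contributors
    raise :class:`EnergeticsError`.
    """
    energies = dict(table.energies)
    for x in _BASES:
        for y in _BASES:
            core = x + y
            contributors = double_paren_contributors(core)
            missing = [t for t in contributors if t not in energies]
            if missing:
                raise EnergeticsError(
                    f"cannot fill '({core})': missing contributors {missing[:4]}..."
                    if len(missing) > 4
                    else f"cannot fill '({core})': missing contributors {missing}"
                )
            energies["(" + core + ")"] = fmean(energies[t] for t in contributors)
    return EnergyTable(energies=energies)


def generate_synthetic_energy_table(
    seed: int = 0,
    range_lo: float = DEFAULT_STACKING_RANGE[0],
    range_hi: float = DEFAULT_STACKING_RANGE[1],
    dangle_lo: float = DEFAULT_DANGLING_RANGE[0],
    dangle_hi: float = DEFAULT_DANGLING_RANGE[1],
) -> EnergyTable:
    """A synthetic but structurally faithful energy table.

    Stacking energies are drawn uniformly in ``[range_lo, range_hi]`` —
    one draw per reverse-complement equivalence class, so physically
    identical quartets share one value — and the 16 ``(XY)`` terms are
    then derived by the 24-contributor averaging rule.
    Parenthesis-bearing dangling terms are drawn in the weaker
    ``[dangle_lo, dangle_hi]`` range; all remaining dangling, looping and
    initiating terms are zero.  Deterministic given ``seed``.
    """
    if not (range_lo < range_hi < 0):
        raise EnergeticsError(
            f"invalid stacking range [{range_lo}, {range_hi}]: need lo < hi < 0"
        )
    if not (dangle_lo < dangle_hi < 0):
        raise EnergeticsError(
            f"invalid dangling range [{dangle_lo}, {dangle_hi}]: need lo < hi < 0"
        )
    rng = np.random.default_rng(seed)
    energies: dict[str, float] = {}

    drawable = [t for t in enumerate_terms("stacking") if not (t[0] == "(" and t[-1] == ")")]
    classes = sorted({canonicalize_stacking(t) for t in drawable})
    class_energy = {c: float(rng.uniform(range_lo, range_hi)) for c in classes}
    for token in drawable:
        energies[token] = class_energy[canonicalize_stacking(token)]

    for token in sorted(enumerate_terms("dangling")):
        if token.startswith("*"):
            energies[token] = 0.0
        else:
            energies[token] = float(rng.uniform(dangle_lo, dangle_hi))
    for token in enumerate_terms("looping") + enumerate_terms("initiating"):
        energies[token] = 0.0

    return fill_double_paren_terms(EnergyTable(energies=energies))
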
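"""Nearest-neighbor (NN) additive free-energy model for DNA duplexes.

The NN model writes the hybridization free energy of a duplex as a sum
of non-overlapping motif contributions::

    ΔG°(duplex) = Σ initiations + Σ stack dimers + Σ dangle terms

with 44 parameters: 2 helix-initiation terms (terminal A·T vs terminal
G·C pair), 10 stack dimer parameters (16 dimers reduced by
reverse-complement symmetry) and 32 single-nucleotide dangling-end
parameters (dangle base × adjacent paired base × 5'/3' side).  Because
the model is linear in its parameters, they are fitted by ordinary
multiple linear regression on (duplex, ΔG) data.

This module serves both as the classical benchmark for the descriptor-
matrix regressor and as the backbone of the synthetic free-energy
oracle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .notation import Duplex, revcomp

_BASES = "ACGT"

__all__ = [
    "INITIATION_MOTIFS",
    "DIMER_CLASSES",
    "DANGLE_MOTIFS",
    "ALL_MOTIFS",
    "NNParameterSet",
    "NNModelError",
    "RankDeficiencyError",
    "canonical_dimer",
    "duplex_motifs",
    "nn_free_energy",
    "fit_nn_parameters",
    "NearestNeighborModel",
    "illustrative_parameters",
]


class NNModelError(ValueError):
    """Structured error for NN-model contract violations."""


class RankDeficiencyError(NNModelError):
    """Design matrix of motif counts is rank deficient."""

    def __init__(self, motifs: list):
        self.motifs = list(motifs)
        super().__init__(
            "design matrix is rank deficient; unidentifiable motifs: "
            + ", ".join(self.motifs)
        )


def canonical_dimer(dimer: str) -> str:
    """Reverse-complement class representative of a 5'→3' stack dimer."""
    if len(dimer) != 2 or any(b not in _BASES for b in dimer):
        raise NNModelError(f"illegal dimer {dimer!r}")
    return min(dimer, revcomp(dimer))


INITIATION_MOTIFS = ("init_AT", "init_GC")
DIMER_CLASSES = tuple(
    sorted({canonical_dimer(a + b) for a in _BASES for b in _BASES})
)  # 10 classes
DANGLE_MOTIFS = tuple(
    [f"{n}({m}" for n in _BASES for m in _BASES]
    + [f"{m}){n}" for m in _BASES for n in _BASES]
)  # 32 motifs
ALL_MOTIFS = INITIATION_MOTIFS + DIMER_CLASSES + DANGLE_MOTIFS  # 44 parameters


@dataclass
class NNParameterSet:
    """The 44 NN parameters (kcal/mol): 2 initiations + 10 stacks + 32 dangles."""

    values: dict

    def __post_init__(self):
        missing = [m for m in ALL_MOTIFS if m not in self.values]
        extra = [m for m in self.values if m not in ALL_MOTIFS]
        if missing or extra:
            raise NNModelError(
                f"parameter set must cover exactly the 44 motifs; "
                f"missing={missing[:5]}, extra={extra[:5]}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, motif: str) -> float:
        return self.values[motif]

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[m] for m in ALL_MOTIFS])

    @classmethod
    def from_vector(cls, vec) -> "NNParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(ALL_MOTIFS),):
            raise NNModelError(f"expected {len(ALL_MOTIFS)} values, got {vec.shape}")
        return cls(values=dict(zip(ALL_MOTIFS, vec.tolist())))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("motif\tvalue_kcal_mol\n")
            for motif in ALL_MOTIFS:
                fh.write(f"{motif}\t{self.values[motif]!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "NNParameterSet":
        values: dict[str, float] = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                motif, value = line.rstrip("\n").split("\t")
                values[motif] = float(value)
        return cls(values=values)


def _strand_dangles(bases: str, paired: set) -> list:
    """Dangle motifs of one physical strand given its paired index set.

    Only the unpaired nucleotide directly adjacent to a paired run
    contributes (the classical single-nucleotide dangling end).
    """
    if not paired:
        return []
    motifs = []
    first, last = min(paired), max(paired)
    if first > 0:
        motifs.append(f"{bases[first - 1]}({bases[first]}")
    if last < len(bases) - 1:
        motifs.append(f"{bases[last]}){bases[last + 1]}")
    # loop nucleotides between interior stack domains carry no NN
    # parameter in the 44-motif model
    return motifs


def duplex_motifs(d: Duplex) -> Counter:
    """Multiset of NN motifs of a duplex.

    Extraction is per physical strand and per stack domain, so the
    result is invariant under swapping the two strand labels (i.e.,
    reverse-complementing the duplex).
    """
    domains = d.stack_domains()
    if not domains:
        raise NNModelError("duplex has no stack domain")
    motifs: Counter = Counter()
    for dom in domains:
        seq1 = d.strand1.bases[dom.i_start : dom.i_stop]
        for k in range(dom.length - 1):
            motifs[canonical_dimer(seq1[k : k + 2])] += 1
        for terminal in (seq1[0], seq1[-1]):
            motifs["init_AT" if terminal in "AT" else "init_GC"] += 1
    for m in _strand_dangles(d.strand1.bases, d.paired_indices1()):
        motifs[m] += 1
    if d.strand2 is not None:
        for m in _strand_dangles(d.strand2.bases, d.paired_indices2()):
            motifs[m] += 1
    return motifs


def nn_free_energy(d: Duplex, params: NNParameterSet) -> float:
    """ΔG° of a duplex under the additive NN model (kcal/mol)."""
    total = 0.0
    for motif, count in duplex_motifs(d).items():
        if motif not in params.values:
            raise NNModelError(f"no parameter for motif {motif!r}")
        total += count * params[motif]
    return total


class NearestNeighborModel(RegressorMixin, BaseEstimator):
    """Sklearn-style NN regression model.

    ``fit`` solves the multiple linear regression of observed free
    energies on the 44 motif counts by least squares; the design matrix
    must have full column rank over the 44 motifs, otherwise a
    :class:`RankDeficiencyError` lists the unidentifiable motifs.
    """

    def fit(self, X, y):
        """X: sequence of :class:`Duplex`; y: ΔG° values (kcal/mol)."""
        duplexes = list(X)
        y = np.asarray(y, dtype=float)
        if len(duplexes) != y.size:
            raise NNModelError(f"{len(duplexes)} duplexes but {y.size} labels")
        A = np.zeros((len(duplexes), len(ALL_MOTIFS)))
        index = {m: k for k, m in enumerate(ALL_MOTIFS)}
        for r, d in enumerate(duplexes):
            for motif, count in duplex_motifs(d).items():
                A[r, index[motif]] = count
        rank = np.linalg.matrix_rank(A)
        if rank < len(ALL_MOTIFS):
            unseen = [m for m in ALL_MOTIFS if not A[:, index[m]].any()]
            if len(ALL_MOTIFS) - rank > len(unseen):
                # dependent columns beyond the unobserved ones: flag the
                # motifs whose removal restores full rank
                dependent = []
                keep = [k for k in range(len(ALL_MOTIFS)) if ALL_MOTIFS[k] not in unseen]
                for k in list(keep):
                    others = [c for c in keep if c != k and ALL_MOTIFS[c] not in dependent]
                    if np.linalg.matrix_rank(A[:, others]) == rank:
                        dependent.append(ALL_MOTIFS[k])
                unseen = unseen + dependent
            raise RankDeficiencyError(unseen)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.parameters_ = NNParameterSet.from_vector(coef)
        self.n_features_in_ = len(ALL_MOTIFS)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "parameters_")
        return np.array([nn_free_energy(d, self.parameters_) for d in X])


def fit_nn_parameters(duplexes, free_energies) -> NNParameterSet:
    """Least-squares NN parameters from (duplex, ΔG°) data."""
    model = NearestNeighborModel().fit(duplexes, free_energies)
    return model.parameters_


def illustrative_parameters() -> NNParameterSet:
    """A literature-style illustrative parameter set (NOT fitted values).

    Magnitudes are plausible for DNA in 1 M NaCl at 37 °C — stacks near
    −1 to −2 kcal/mol, small positive initiations, weakly stabilizing
    dangles — but the numbers are round illustrative placeholders for
    demos and documentation; fitted or synthetic parameters should be
    used for any quantitative work.
    """
    values: dict[str, float] = {"init_AT": 1.0, "init_GC": 1.0}
    base_strength = {"A": -1.0, "T": -1.0, "C": -1.5, "G": -1.5}
    for dimer in DIMER_CLASSES:
        values[dimer] = round((base_strength[dimer[0]] + base_strength[dimer[1]]) / 2, 2)
    for motif in DANGLE_MOTIFS:
        values[motif] = -0.3
    return NNParameterSet(values=values)
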
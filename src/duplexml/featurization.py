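"""Descriptor matrices: featurized, normalized, zero-padded model inputs.

A DNA string becomes a ``features × positions`` matrix.  Columns are its
descriptors in a fixed order (stacking, dangling, looping, initiating;
string order within each kind), zero-padded on the right to a
dataset-wide width.  Hybridization inputs carry three rows — Number
(term identifier), Energy (kcal/mol) and Entropy — and strand-
displacement inputs add two more: the per-descriptor equilibrium
unpaired probability and the reaction temperature.  A displacement
sample is a pair of 5-row matrices, one for the invading strand and one
for the product complex.

Default normalization uses fixed, data-independent scalers: identifier /
max identifier, energy magnitude / magnitude of the table minimum
(sign-preserving, so zero-energy terms and padding both map to 0),
entropy / rotatable-bond count, and temperature mapped linearly from the
design range 13–49 °C onto [0, 1].  A batch min-max scaler with frozen
training statistics is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .descriptors import Descriptor, TermTable, extract_all
from .energetics import EnergyTable
from .entropy import EntropyParams, entropy_coefficient, entropy_values
from .notation import parse_dna_string

HYBRIDIZATION_ROWS = ("number", "energy", "entropy")
DISPLACEMENT_ROWS = HYBRIDIZATION_ROWS + ("unpaired_prob", "temperature")
TEMPERATURE_RANGE = (13.0, 49.0)

__all__ = [
    "HYBRIDIZATION_ROWS",
    "DISPLACEMENT_ROWS",
    "TEMPERATURE_RANGE",
    "FeaturizationError",
    "DescriptorMatrix",
    "normalize_temperature",
    "unpaired_probability",
    "build_matrix",
    "build_dataset",
    "DescriptorFeaturizer",
    "MatrixScaler",
]


class FeaturizationError(ValueError):
    """Structured error for featurization contract violations."""


@dataclass
class DescriptorMatrix:
    """A single featurized matrix plus its populated-column count."""

    values: np.ndarray  # (n_rows, width)
    n_populated: int
    descriptors: list

    @property
    def width(self) -> int:
        return self.values.shape[1]


def normalize_temperature(temperature_c: float) -> float:
    """Map a Celsius temperature onto [0, 1] over the 13–49 °C design range."""
    lo, hi = TEMPERATURE_RANGE
    return (temperature_c - lo) / (hi - lo)


def unpaired_probability(s: str, override=None) -> np.ndarray:
    """Equilibrium unpaired probability per nucleotide of the string.

    Structure-derived stub: 0 for nucleotides inside a stack domain, 1
    otherwise.  ``override`` (sequence of per-nucleotide values in
    [0, 1], e.g. from an external partition-function calculation) is
    used verbatim when given.
    """
    duplex = parse_dna_string(s)
    n1 = len(duplex.strand1)
    n2 = len(duplex.strand2) if duplex.strand2 is not None else 0
    text_has_dot = "." in s
    n_total = n1 + n2 if text_has_dot else n1
    if override is not None:
        values = np.asarray(override, dtype=float)
        if values.shape != (n_total,):
            raise FeaturizationError(
                f"unpaired-probability override has length {values.size}, "
                f"expected {n_total}"
            )
        if np.any((values < 0) | (values > 1)):
            raise FeaturizationError("override probabilities must lie in [0, 1]")
        return values
    prob = np.ones(n_total)
    for i in duplex.paired_indices1():
        prob[i] = 0.0
    if text_has_dot:
        for j in duplex.paired_indices2():
            prob[n1 + j] = 0.0
    return prob


def _descriptor_unpaired(descriptors: list, prob: np.ndarray) -> np.ndarray:
    """Per-descriptor mean unpaired probability over covered nucleotides."""
    out = np.zeros(len(descriptors))
    for k, d in enumerate(descriptors):
        if d.positions:
            out[k] = float(np.mean([prob[p] for p in d.positions]))
    return out


def build_matrix(
    s: str,
    term_table: TermTable,
    energy_table: EnergyTable,
    entropy_params: EntropyParams | None = None,
    width: int | None = None,
    temperature: float | None = None,
    unpaired_override=None,
    both_strands: bool = False,
    normalize: bool = True,
) -> DescriptorMatrix:
    """Featurize one DNA string.

    With ``temperature=None`` a 3-row hybridization matrix is built;
    otherwise the 5-row displacement layout (unpaired probability and
    constant temperature rows) is used.  ``width`` pads columns on the
    right with zeros; it must not be smaller than the natural width.
    Unknown tokens raise :class:`~duplexml.descriptors.UnknownTermError`.
    """
    entropy_params = entropy_params or EntropyParams()
    descriptors = extract_all(s, both_strands=both_strands)
    n = len(descriptors)
    if width is None:
        width = n
    if width < n:
        raise FeaturizationError(f"width {width} is smaller than descriptor count {n}")

    n_rows = 3 if temperature is None else 5
    mat = np.zeros((n_rows, width))
    for k, d in enumerate(descriptors):
        mat[0, k] = term_table.identifier(d.token)
        mat[1, k] = energy_table.energy(d.token)
    mat[2, :n] = entropy_values(descriptors, entropy_params)
    if temperature is not None:
        prob = unpaired_probability(s, override=unpaired_override)
        mat[3, :n] = _descriptor_unpaired(descriptors, prob)
        mat[4, :n] = temperature if not normalize else normalize_temperature(temperature)

    if normalize:
        mat[0, :n] /= term_table.max_identifier
        e_min = energy_table.min_energy
        if e_min < 0:
            mat[1, :n] /= e_min  # sign-preserving: most negative -> 1, zero -> 0
            mat[1, :n] += 0.0  # normalize -0.0
        mat[2, :n] /= entropy_params.rotatable_bonds
    return DescriptorMatrix(values=mat, n_populated=n, descriptors=descriptors)


def build_dataset(
    strings: list,
    term_table: TermTable,
    energy_table: EnergyTable,
    entropy_params: EntropyParams | None = None,
    width: int | None = None,
    **kwargs,
) -> np.ndarray:
    """Stack matrices for many strings into one ``(n, rows, W)`` array.

    ``W`` defaults to the longest descriptor list in the batch, so every
    matrix in a dataset shares one width.
    """
    if width is None:
        width = max(len(extract_all(s, both_strands=kwargs.get("both_strands", False)))
                    for s in strings)
    mats = [
        build_matrix(s, term_table, energy_table, entropy_params, width=width, **kwargs)
        for s in strings
    ]
    return np.stack([m.values for m in mats])


class DescriptorFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from DNA strings to descriptor matrices.

    ``fit`` freezes the dataset-wide matrix width (the longest descriptor
    list seen); ``transform`` returns a ``(n, 3, W)`` array ready for the
    convolutional regressor.
    """

    def __init__(
        self,
        term_table: TermTable | None = None,
        energy_table: EnergyTable | None = None,
        entropy_params: EntropyParams | None = None,
        both_strands: bool = False,
        normalize: bool = True,
    ):
        self.term_table = term_table
        self.energy_table = energy_table
        self.entropy_params = entropy_params
        self.both_strands = both_strands
        self.normalize = normalize

    def fit(self, X, y=None):
        if self.energy_table is None:
            raise FeaturizationError("DescriptorFeaturizer requires an energy_table")
        self.term_table_ = self.term_table or TermTable.default()
        self.entropy_params_ = self.entropy_params or EntropyParams()
        self.width_ = max(
            len(extract_all(s, both_strands=self.both_strands)) for s in X
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "width_")
        return build_dataset(
            list(X),
            self.term_table_,
            self.energy_table,
            self.entropy_params_,
            width=self.width_,
            both_strands=self.both_strands,
            normalize=self.normalize,
        )


class MatrixScaler(TransformerMixin, BaseEstimator):
    """Per-feature-row min-max scaler with frozen training statistics.

    Statistics are computed over populated (non-padding) columns only —
    padding is identified by a zero Number row and is preserved as exact
    zeros.  A constant feature row maps to 0.  The frozen scaler is
    serializable to JSON and applying it to the same raw batch twice
    gives identical output.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        mask = X[:, 0, :] > 0  # (n, W) populated columns
        n_rows = X.shape[1]
        self.row_min_ = np.zeros(n_rows)
        self.row_max_ = np.zeros(n_rows)
        for r in range(n_rows):
            vals = X[:, r, :][mask]
            self.row_min_[r] = vals.min() if vals.size else 0.0
            self.row_max_[r] = vals.max() if vals.size else 0.0
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "row_min_")
        X = np.asarray(X, dtype=float)
        out = np.zeros_like(X)
        mask = X[:, 0, :] > 0
        for r in range(X.shape[1]):
            span = self.row_max_[r] - self.row_min_[r]
            if span == 0:
                continue  # constant row maps to 0
            scaled = (X[:, r, :] - self.row_min_[r]) / span
            out[:, r, :] = np.where(mask, scaled, 0.0)
        return out

    def to_json(self, path) -> None:
        check_is_fitted(self, "row_min_")
        with open(path, "w") as fh:
            json.dump(
                {"row_min": self.row_min_.tolist(), "row_max": self.row_max_.tolist()},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "MatrixScaler":
        with open(path) as fh:
            data = json.load(fh)
        scaler = cls()
        scaler.row_min_ = np.asarray(data["row_min"], dtype=float)
        scaler.row_max_ = np.asarray(data["row_max"], dtype=float)
        return scaler


def displacement_input(
    invading_string: str,
    product_string: str,
    temperature: float,
    term_table: TermTable,
    energy_table: EnergyTable,
    entropy_params: EntropyParams | None = None,
    width: int | None = None,
    invading_unpaired=None,
    product_unpaired=None,
) -> np.ndarray:
    """The two-matrix ``(2, 5, W)`` input of one strand-displacement sample.

    The first matrix encodes the invading strand, the second the product
    complex; both carry the same constant temperature row.
    """
    mats = []
    for s, override in (
        (invading_string, invading_unpaired),
        (product_string, product_unpaired),
    ):
        n = len(extract_all(s))
        mats.append((s, override, n))
    if width is None:
        width = max(n for _, _, n in mats)
    built = [
        build_matrix(
            s,
            term_table,
            energy_table,
            entropy_params,
            width=width,
            temperature=temperature,
            unpaired_override=override,
        ).values
        for s, override, _ in mats
    ]
    return np.stack(built)


__all__.append("displacement_input")
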
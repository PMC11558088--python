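"""Synthetic label oracles for hybridization ΔG° and displacement log₁₀(k).

The package is fully testable without wet-lab measurements: these
oracles stand in for high-resolution-melting free energies and
fluorescence-kinetics rate constants.

* :class:`HybridizationOracle` labels a duplex with the additive
  nearest-neighbor free energy under a synthetic parameter set plus
  Gaussian noise.  The default backbone parameters are solved from the
  experimental ΔG° window of −14.7 to −5.58 kcal/mol over stack lengths
  5–14: per-dimer mean ≈ −1.01 kcal/mol and initiation −0.78 kcal/mol,
  so the pool-wide label range reproduces that window.

* :class:`DisplacementOracle` uses a saturating-toehold phenomenological
  backbone — openly synthetic, mimicking toehold-exchange kinetics::

      log₁₀ k = a + b·min(L_toehold, L_sat) − c·L_spacer + d·(T − 25 °C)

  with defaults chosen so the pool-wide span across the 13–49 °C design
  range is ≈ 2.5 orders of magnitude and higher temperature speeds the
  reaction up.

Both oracles are pure functions of (item, config, seed): the noise
stream is keyed by (seed, item id), so repeated calls agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn_baseline import (
    ALL_MOTIFS,
    DANGLE_MOTIFS,
    DIMER_CLASSES,
    NNParameterSet,
    nn_free_energy,
)
from .notation import Duplex
from .pools import SequenceSet

__all__ = [
    "default_hybridization_parameters",
    "HybridizationOracle",
    "DisplacementOracle",
]


def default_hybridization_parameters(seed: int = 0) -> NNParameterSet:
    """Synthetic NN backbone parameters p* matched to the experimental
    ΔG° window (see module docstring)."""
    rng = np.random.default_rng(seed)
    values = {"init_AT": -0.78, "init_GC": -0.78}
    for dimer in DIMER_CLASSES:
        values[dimer] = float(rng.uniform(-1.05, -0.97))
    for motif in DANGLE_MOTIFS:
        values[motif] = float(rng.uniform(-0.10, -0.02))
    assert set(values) == set(ALL_MOTIFS)
    return NNParameterSet(values=values)


def _item_rng(seed: int, item_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, item_id]))


@dataclass
class HybridizationOracle:
    """ΔG° label oracle: NN backbone plus Gaussian noise (kcal/mol)."""

    parameters: NNParameterSet = None
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.parameters is None:
            self.parameters = default_hybridization_parameters(self.seed)

    def __call__(self, duplex: Duplex, item_id: int = 0) -> float:
        dg = nn_free_energy(duplex, self.parameters)
        if self.noise_sd > 0:
            dg += float(_item_rng(self.seed, item_id).normal(0.0, self.noise_sd))
        return dg


@dataclass
class DisplacementOracle:
    """log₁₀(k) label oracle with a saturating-toehold backbone."""

    intercept: float = 3.5
    toehold_slope: float = 0.3
    saturation_length: int = 7
    spacer_slope: float = 0.18
    temperature_slope: float = 0.02  # per °C relative to 25 °C
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def backbone(self, seqset: SequenceSet, temperature_c: float) -> float:
        return (
            self.intercept
            + self.toehold_slope * min(len(seqset.toehold), self.saturation_length)
            - self.spacer_slope * len(seqset.spacer1)
            + self.temperature_slope * (temperature_c - 25.0)
        )

    def __call__(
        self, seqset: SequenceSet, temperature_c: float = 25.0, item_id: int = 0
    ) -> float:
        if not (13.0 <= temperature_c <= 49.0):
            raise ValueError(
                f"temperature {temperature_c} °C outside the design range [13, 49]"
            )
        logk = self.backbone(seqset, temperature_c)
        if self.noise_sd > 0:
            logk += float(_item_rng(self.seed, item_id).normal(0.0, self.noise_sd))
        return logk
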
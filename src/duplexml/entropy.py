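"""Conformational-entropy feature for descriptors.

Unpaired nucleotides retain rotational freedom; paired ones are locked
in the helix.  The entropy value of a descriptor is the product of an
entropy coefficient and the number of rotatable single bonds per
unpaired nucleotide (glycosidic C–N, the C–O and C–C bonds of the
sugar, and the backbone P–O bonds — six by default).  The coefficient
ramps down toward a stack domain: 1.0 far away, 0.67 for the second
nucleotide from the helix, 0.33 directly adjacent, and exactly 0 for
stacking and initiating terms, whose nucleotides are structurally
constrained.  Loop nucleotides use the distance to the nearer of their
two flanking stack domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import Descriptor

__all__ = ["EntropyParams", "entropy_coefficient", "entropy_values"]


@dataclass(frozen=True)
class EntropyParams:
    """Coefficient ladder and rotatable-bond count.

    ``rotatable_bonds`` is the number of rotatable single bonds per
    unpaired nucleotide (dimensionless count; default 6).
    """

    coeff_adjacent: float = 0.33
    coeff_second: float = 0.67
    coeff_far: float = 1.0
    rotatable_bonds: int = 6

    def __post_init__(self):
        if not (0 <= self.coeff_adjacent <= self.coeff_second <= self.coeff_far):
            raise ValueError("entropy coefficients must satisfy 0 <= c1 <= c2 <= c3")
        if self.rotatable_bonds < 1:
            raise ValueError("rotatable_bonds must be >= 1")


def entropy_coefficient(distance: int | None, params: EntropyParams) -> float:
    """Ladder value for an unpaired nucleotide at ``distance`` (in
    nucleotides) from the nearest stack domain; ``None`` means no stack
    domain exists on the segment and counts as far."""
    if distance is None or distance >= 3:
        return params.coeff_far
    if distance == 2:
        return params.coeff_second
    return params.coeff_adjacent


def entropy_values(
    descriptors: list[Descriptor], params: EntropyParams | None = None
) -> np.ndarray:
    """Per-descriptor entropy feature, aligned with the input order."""
    params = params or EntropyParams()
    out = np.zeros(len(descriptors))
    for k, d in enumerate(descriptors):
        if d.kind in ("dangling", "looping"):
            out[k] = entropy_coefficient(d.distance, params) * params.rotatable_bonds
    return out
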
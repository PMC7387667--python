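"""Isoeffective dose conversion (EQD2) and phase summation.

Under the linear-quadratic model a total dose D delivered in fractions of
size d is converted to the equivalent dose in 2 Gy fractions as

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

with alpha/beta the tissue sensitivity ratio (Gy); 3 Gy is the conventional
value for late-responding normal tissue and is the default here.  Dose per
fraction is computed per voxel (d_v = D_v / n_fractions), the standard
convention for spatial EQD2 maps; the prescription-based alternative is not
offered because the per-voxel form is what a summed multi-phase map needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid_io import GridError, VoxelGrid, require_compatible

DEFAULT_ALPHA_BETA = 3.0


@dataclass
class PhaseDose:
    """One treatment phase: a physical dose grid and its fractionation."""

    grid: VoxelGrid
    n_fractions: int
    alpha_beta: float = DEFAULT_ALPHA_BETA

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions}")
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha/beta must be positive, got {self.alpha_beta}")
        if self.grid.payload_kind != "dose":
            raise ValueError("PhaseDose requires a dose payload")


def eqd2_convert(phase: PhaseDose) -> VoxelGrid:
    """Convert a physical-dose phase to EQD2, voxel by voxel."""
    D = np.asarray(phase.grid.data, dtype=float)
    d = D / phase.n_fractions
    ab = phase.alpha_beta
    eqd2 = D * (d + ab) / (2.0 + ab)
    return phase.grid.with_payload(eqd2, "dose")


def sum_phases(phases: Sequence[PhaseDose]) -> VoxelGrid:
    """Sum EQD2 over treatment phases into one distribution per patient."""
    if len(phases) == 0:
        raise ValueError("sum_phases requires at least one phase")
    require_compatible([p.grid for p in phases])
    total = None
    for p in phases:
        g = eqd2_convert(p)
        total = g.data if total is None else total + g.data
    return phases[0].grid.with_payload(total, "dose")
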
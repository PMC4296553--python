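"""Linear-quadratic conversion of physical dose to EQD2.

All doses delivered in a fractionation other than 2 Gy per fraction are
mapped to the equieffective dose in 2-Gy fractions (EQD2) before any
cross-session accumulation:

    EQD2 = D * (d + α/β) / (2 + α/β),   d = D / n

where D is the total physical dose, n the number of equal fractions, and
α/β the tissue fractionation-sensitivity ratio in Gy.  Tumor tissue uses
α/β = 10 Gy and late-responding normal tissue α/β = 3 Gy by default.  A
dose of exactly 2 Gy per fraction is the fixed point of the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UnitError
from .grids import GY_EQD2, GY_PHYSICAL, DoseGrid

__all__ = ["LQParameters", "LQ_TUMOR", "LQ_NORMAL", "eqd2_scalar", "eqd2_grid"]


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic tissue parameters.

    alpha_beta:
        α/β ratio in Gy (> 0).  10 Gy for tumor, 3 Gy for normal tissue.
    reference_fraction_dose:
        The fraction size defining the equieffective scale; 2 Gy.
    """

    alpha_beta: float
    reference_fraction_dose: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise DomainError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        if self.reference_fraction_dose <= 0:
            raise DomainError("reference_fraction_dose must be > 0")


LQ_TUMOR = LQParameters(alpha_beta=10.0)
LQ_NORMAL = LQParameters(alpha_beta=3.0)


def eqd2_scalar(total_dose, n_fractions: int, lq: LQParameters):
    """EQD2 of ``total_dose`` Gy delivered in ``n_fractions`` equal fractions.

    Accepts scalars or arrays (applied element-wise with a shared n).
    """
    dose = np.asarray(total_dose, dtype=float)
    if np.any(dose < 0):
        raise DomainError("total_dose must be non-negative")
    if n_fractions < 1:
        raise DomainError("n_fractions must be >= 1")
    d = dose / n_fractions
    ab = lq.alpha_beta
    out = dose * (d + ab) / (lq.reference_fraction_dose + ab)
    return float(out) if np.isscalar(total_dose) else out


def eqd2_grid(grid: DoseGrid, lq: LQParameters) -> DoseGrid:
    """Voxel-wise EQD2 conversion of a physical dose grid.

    Each voxel's fraction dose is d(v) = D(v)/n with n = ``grid.n_fractions``
    (equal fractions assumed).  The output is tagged ``Gy_EQD2`` on the same
    geometry; converting an already-converted grid is an error.
    """
    if grid.unit != GY_PHYSICAL:
        raise UnitError(
            f"eqd2_grid expects a physical-dose grid, got unit {grid.unit!r} "
            "(double conversion?)"
        )
    values = eqd2_scalar(grid.values, grid.n_fractions, lq)
    return DoseGrid(
        geometry=grid.geometry,
        values=values,
        unit=GY_EQD2,
        n_fractions=grid.n_fractions,
        provenance=list(grid.provenance)
        + [f"eqd2(alpha_beta={lq.alpha_beta}, n={grid.n_fractions})"],
    )
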
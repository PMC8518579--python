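"""Cooperative two-species Moreau isotherm and the potential-free loading.

The Moreau model is a multispecies Langmuir-type isotherm with pairwise
interaction energies between adsorbed molecules.  For two adsorbing
species A (monovalent anion) and B (divalent anion) the fractional
loading of A is

    q_A / q_max = [2·K_A·c_A + 2·c_A²·K_A²·e^(−βU_AA)
                   + 2·c_A·K_A·c_B·K_B·e^(−βU_AB)] / D

    D = 1 + 2·c_A·K_A + c_A²·K_A²·e^(−βU_AA) + 2·c_B·K_B
        + c_B²·K_B²·e^(−βU_BB) + 2·c_A·K_A·c_B·K_B·e^(−βU_AB)

with β = 1/(R·T) and U in kJ/mol (positive U = repulsion between adsorbed
molecules).  q_B is obtained by exchanging the roles of A and B.  Note
the single-species limit saturates at 2·q_max because of the doubled
linear and quadratic numerator terms.

The potential-free loading (PFL) weights the species loadings by their
charge magnitudes, PFL = |z_A|·q_A + |z_B|·q_B, giving an equivalent
loading (meq/g) on the electrode-pair mass basis — the coion reservoir
that later degrades charge efficiency.  The neutral acid H2A is excluded:
it neither adsorbs appreciably in the relevant pH range nor carries
charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import RT_KJ_MOL
from .speciation import AcidDefinition, species_fractions

__all__ = [
    "MoreauParameters",
    "LoadingResult",
    "TABLE_PARAMS_MALEIC",
    "moreau_loadings",
    "pfl",
    "pfl_grid",
]

#: GA search bounds, shared with the fitting module:
#: affinities K in L/mol, q_max in mmol/g, interaction energies U in kJ/mol.
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "K_A": (0.0, 1e5),
    "K_B": (0.0, 1e5),
    "q_max": (0.0, 2.5),
    "U_AA": (-30.0, 30.0),
    "U_AB": (-30.0, 30.0),
    "U_BB": (-30.0, 30.0),
}

PARAMETER_ORDER = ("K_A", "K_B", "q_max", "U_AA", "U_AB", "U_BB")


@dataclass(frozen=True)
class MoreauParameters:
    """Six Moreau isotherm parameters plus the working temperature.

    K_A, K_B: adsorption affinities (L/mol) of the mono-/divalent species;
    q_max: maximal loading (mmol/g, electrode-pair mass basis);
    U_AA, U_AB, U_BB: pairwise interaction energies (kJ/mol, positive =
    repulsive).
    """

    K_A: float
    K_B: float
    q_max: float
    U_AA: float
    U_AB: float
    U_BB: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if min(self.K_A, self.K_B, self.q_max) < 0:
            raise ValueError("K_A, K_B and q_max must be non-negative")

    @property
    def beta(self) -> float:
        """1/(R·T) in mol/kJ."""
        return 1.0 / (RT_KJ_MOL * self.temperature / 298.15)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAMETER_ORDER])

    @classmethod
    def from_array(cls, values, temperature: float = 298.15) -> "MoreauParameters":
        return cls(*map(float, values), temperature=temperature)


#: Fitted parameters for maleic acid on the activated-carbon electrodes of
#: the commercial flow-by cell studied here (restart-mean GA estimates).
TABLE_PARAMS_MALEIC = MoreauParameters(
    K_A=23.4, K_B=5.3, q_max=1.23, U_AA=-0.36, U_AB=29.9, U_BB=3.04,
)


@dataclass(frozen=True)
class LoadingResult:
    """Species loadings q_A, q_B (mmol/g) and the charge-weighted PFL (meq/g)."""

    q_A: float
    q_B: float

    @property
    def q_total(self) -> float:
        return self.q_A + self.q_B

    @property
    def pfl(self) -> float:
        return 1.0 * self.q_A + 2.0 * self.q_B


def moreau_loadings(c_A, c_B, params: MoreauParameters):
    """Evaluate the two-species Moreau isotherm.

    ``c_A``, ``c_B`` are equilibrium concentrations in mol/L of the
    monovalent and divalent species (scalars or broadcastable arrays).
    Returns a :class:`LoadingResult` for scalar input, else a pair of
    arrays (q_A, q_B) in mmol/g.
    """
    c_a = np.asarray(c_A, dtype=float)
    c_b = np.asarray(c_B, dtype=float)
    if np.any(c_a < 0) or np.any(c_b < 0):
        raise ValueError("concentrations must be non-negative")
    beta = params.beta
    e_aa = np.exp(-beta * params.U_AA)
    e_ab = np.exp(-beta * params.U_AB)
    e_bb = np.exp(-beta * params.U_BB)
    ka, kb = params.K_A, params.K_B
    cross = 2.0 * c_a * ka * c_b * kb * e_ab
    denom = (
        1.0
        + 2.0 * c_a * ka + c_a**2 * ka**2 * e_aa
        + 2.0 * c_b * kb + c_b**2 * kb**2 * e_bb
        + cross
    )
    q_a = params.q_max * (2.0 * ka * c_a + 2.0 * c_a**2 * ka**2 * e_aa + cross) / denom
    q_b = params.q_max * (2.0 * kb * c_b + 2.0 * c_b**2 * kb**2 * e_bb + cross) / denom
    if q_a.ndim == 0:
        return LoadingResult(q_A=float(q_a), q_B=float(q_b))
    return q_a, q_b


def q_total_grid(c_A, c_B, params: MoreauParameters):
    """Total loading q_A + q_B (mmol/g) for array inputs; used by fitting."""
    out = moreau_loadings(c_A, c_B, params)
    if isinstance(out, LoadingResult):
        return out.q_total
    q_a, q_b = out
    return q_a + q_b


def pfl(
    c_total: float,
    pH: float,
    params: MoreauParameters,
    acid: AcidDefinition,
    mode: str = "ideal",
    ionic_strength: float | None = None,
) -> float:
    """Potential-free loading (meq/g) of a feed at (c_total, pH).

    Speciates the acid, evaluates the Moreau isotherm for the two charged
    species, and returns PFL = q_A + 2·q_B.
    """
    _, f_ha, f_a2 = species_fractions(pH, acid, mode, ionic_strength)
    res = moreau_loadings(c_total * f_ha, c_total * f_a2, params)
    return res.pfl


def pfl_grid(
    ph_values,
    c_values,
    params: MoreauParameters,
    acid: AcidDefinition,
    mode: str = "ideal",
) -> pd.DataFrame:
    """Tabulate (pH, c, q_A, q_B, q_total, PFL) over a pH × concentration grid.

    ``c_values`` in mol/L; output concentrations echoed in mM.
    """
    rows = []
    for ph in np.atleast_1d(ph_values):
        _, f_ha, f_a2 = species_fractions(float(ph), acid, mode)
        for c in np.atleast_1d(c_values):
            res = moreau_loadings(float(c) * f_ha, float(c) * f_a2, params)
            rows.append({
                "pH": float(ph),
                "c_total_mM": float(c) * 1e3,
                "q_A_mmol_g": res.q_A,
                "q_B_mmol_g": res.q_B,
                "q_total_mmol_g": res.q_total,
                "pfl_meq_g": res.pfl,
            })
    return pd.DataFrame(rows)
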
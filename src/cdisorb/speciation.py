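"""pH-dependent speciation of a diprotic weak acid in NaOH-adjusted solution.

A diprotic acid H2A dissociates in two steps (H2A <-> H+ + HA-,
HA- <-> H+ + A2-) governed by pKa1 < pKa2.  Given total acid concentration
and pH, the module resolves the full ionic composition (acid species plus
Na+, H+, OH-), the ionic strength, Davies activity coefficients, and the
electrolyte conductivity.  The sodium concentration follows from
electroneutrality: in the systems modelled here the pH is adjusted with
NaOH only, so Na+ is the single counter-cation.

Two modes are supported everywhere:

``ideal``
    concentration-based equilibrium constants; pH read as -log10 c_H.
``activity_corrected``
    Davies activity coefficients shift the concentration-based pKa values
    and scale the per-species molar conductivities; the ionic-strength /
    activity loop is iterated to a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .constants import DAVIES_A, KW

__all__ = [
    "AcidDefinition",
    "SolutionState",
    "MALEIC_ACID",
    "species_fractions",
    "davies_log_gamma",
    "solve_solution_state",
    "conductivity",
    "invert_conductivity",
]

#: Limiting molar conductivities of the background ions, S·cm²/mol.
LAMBDA0_NA = 50.1
LAMBDA0_H = 349.8
LAMBDA0_OH = 198.0


@dataclass(frozen=True)
class AcidDefinition:
    """Dissociation, charge and conductivity constants of a diprotic acid.

    ``lambda0_mono`` / ``lambda0_di`` are the limiting molar conductivities
    (S·cm²/mol) of the singly and doubly charged anions; values for the
    background ions Na+, H+ and OH- can be overridden as well.
    """

    name: str
    pKa1: float
    pKa2: float
    molar_mass: float  # g/mol
    lambda0_mono: float  # S·cm²/mol, HA-
    lambda0_di: float  # S·cm²/mol, A2-
    lambda0_na: float = LAMBDA0_NA
    lambda0_h: float = LAMBDA0_H
    lambda0_oh: float = LAMBDA0_OH
    species_charges: tuple[int, int, int] = (0, -1, -2)

    def __post_init__(self) -> None:
        if not self.pKa1 < self.pKa2:
            raise ValueError(f"pKa1 ({self.pKa1}) must be < pKa2 ({self.pKa2})")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        for lam in (self.lambda0_mono, self.lambda0_di, self.lambda0_na,
                    self.lambda0_h, self.lambda0_oh):
            if lam <= 0:
                raise ValueError("limiting molar conductivities must be positive")


#: Maleic acid on the cell studied here.  pKa and molar mass are measured
#: values; the maleate conductivities are standard-table estimates for
#: similar dicarboxylates (overridable via config).
MALEIC_ACID = AcidDefinition(
    name="maleic acid",
    pKa1=1.92,
    pKa2=6.23,
    molar_mass=116.07,
    lambda0_mono=41.0,
    lambda0_di=120.0,
)


@dataclass
class SolutionState:
    """Fully resolved ionic composition at one (c_total, pH) point.

    Concentrations in mol/L, ionic strength in mol/L, conductivity in S/m.
    ``alpha_mono`` is the fraction of *dissolved charged* acid that is
    monovalent, c_HA / (c_HA + c_A2); it sets the mean charge
    z̄ = α + 2(1−α) used in capacity bookkeeping.
    """

    c_total: float
    pH: float
    c_H2A: float
    c_HA: float
    c_A2: float
    c_Na: float
    c_H: float
    c_OH: float
    ionic_strength: float
    conductivity: float
    mode: str = "ideal"
    log_gamma_by_charge: dict[int, float] = field(default_factory=dict)

    @property
    def alpha_mono(self) -> float:
        charged = self.c_HA + self.c_A2
        if charged <= 0.0:
            return 0.0
        return self.c_HA / charged

    @property
    def z_mean(self) -> float:
        """Mean charge magnitude of the dissolved charged acid, eq/mol."""
        a = self.alpha_mono
        return 1.0 * a + 2.0 * (1.0 - a)

    def electroneutrality_residual(self) -> float:
        return self.c_Na + self.c_H - self.c_HA - 2.0 * self.c_A2 - self.c_OH


def davies_log_gamma(charge: int, ionic_strength: float) -> float:
    """Davies log10 activity coefficient for an ion of the given charge.

    log γ = −A·z²·(√I/(1+√I) − 0.3·I) with A = 0.509 at 25 °C.  Valid up
    to roughly I ≈ 0.5 mol/L; γ = 1 for neutral species and at I = 0.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if charge == 0 or ionic_strength == 0.0:
        return 0.0
    sqrt_i = math.sqrt(ionic_strength)
    return -DAVIES_A * charge * charge * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)


def _check_mode(mode: str) -> None:
    if mode not in ("ideal", "activity_corrected"):
        raise ValueError(f"unknown mode {mode!r}")


def species_fractions(
    pH: float,
    acid: AcidDefinition,
    mode: str = "ideal",
    ionic_strength: float | None = None,
) -> tuple[float, float, float]:
    """Equilibrium fractions (H2A, HA-, A2-) of the total dissolved acid.

    In ``activity_corrected`` mode the concentration-based pKa values are
    shifted by the Davies log γ terms (pKa1 by log γ₁, pKa2 by
    log γ₂ − log γ₁), which requires ``ionic_strength``.
    """
    _check_mode(mode)
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    pKa1, pKa2 = acid.pKa1, acid.pKa2
    if mode == "activity_corrected":
        if ionic_strength is None:
            raise ValueError("activity_corrected mode requires ionic_strength")
        lg1 = davies_log_gamma(1, ionic_strength)
        lg2 = davies_log_gamma(2, ionic_strength)
        # Ka1 = aH·γ1·cHA/cH2A, Ka2 = aH·γ2·cA2/(γ1·cHA); move γ onto pKa.
        pKa1 = pKa1 + lg1
        pKa2 = pKa2 + lg2 - lg1
    r1 = 10.0 ** (pH - pKa1)
    r2 = 10.0 ** (pH - pKa2)
    f_h2a = 1.0 / (1.0 + r1 + r1 * r2)
    f_ha = f_h2a * r1
    f_a2 = f_ha * r2
    return f_h2a, f_ha, f_a2


def solve_solution_state(
    c_total: float,
    pH: float,
    acid: AcidDefinition,
    mode: str = "ideal",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> SolutionState:
    """Resolve the full ionic composition of a NaOH-adjusted acid solution.

    Ideal mode solves in one pass.  Activity-corrected mode iterates the
    fixed point speciation → Na+ (electroneutrality) → ionic strength →
    Davies γ → speciation until |ΔI| < ``tol`` mol/L.
    """
    _check_mode(mode)
    if c_total < 0:
        raise ValueError("c_total must be non-negative")
    c_h = 10.0 ** (-pH)
    c_oh = KW / c_h
    if mode == "activity_corrected":
        # pH meters report H+ activity; Kw is thermodynamic.
        ionic_strength = c_total  # starting guess
        prev = math.inf
        g1 = 1.0
        for _ in range(max_iter):
            lg1 = davies_log_gamma(1, ionic_strength)
            g1 = 10.0 ** lg1
            c_h = 10.0 ** (-pH) / g1
            c_oh = KW / (c_h * g1 * g1)
            f0, f1, f2 = species_fractions(pH, acid, mode, ionic_strength)
            c_h2a, c_ha, c_a2 = (f * c_total for f in (f0, f1, f2))
            c_na = max(c_ha + 2.0 * c_a2 + c_oh - c_h, 0.0)
            ionic_strength = 0.5 * (c_na + c_h + c_oh + c_ha + 4.0 * c_a2)
            if abs(ionic_strength - prev) < tol:
                break
            prev = ionic_strength
        else:
            raise RuntimeError(
                f"ionic-strength fixed point did not converge in {max_iter} iterations"
            )
    else:
        f0, f1, f2 = species_fractions(pH, acid, mode)
        c_h2a, c_ha, c_a2 = (f * c_total for f in (f0, f1, f2))
        c_na = max(c_ha + 2.0 * c_a2 + c_oh - c_h, 0.0)
        ionic_strength = 0.5 * (c_na + c_h + c_oh + c_ha + 4.0 * c_a2)

    log_gamma = {
        z: davies_log_gamma(z, ionic_strength) for z in (1, 2)
    } if mode == "activity_corrected" else {1: 0.0, 2: 0.0}

    state = SolutionState(
        c_total=c_total, pH=pH,
        c_H2A=c_h2a, c_HA=c_ha, c_A2=c_a2,
        c_Na=c_na, c_H=c_h, c_OH=c_oh,
        ionic_strength=ionic_strength,
        conductivity=0.0, mode=mode,
        log_gamma_by_charge=log_gamma,
    )
    state.conductivity = conductivity(state, acid, mode)
    return state


def conductivity(state: SolutionState, acid: AcidDefinition, mode: str = "ideal") -> float:
    """Electrolyte conductivity κ in S/m from the resolved composition.

    κ = Σ λᵢ·cᵢ over all ionic species; λᵢ = λᵢ°·γ(|zᵢ|) in
    activity-corrected mode, λᵢ° otherwise.  S·cm²/mol × mol/L → S/m is a
    division by 10.
    """
    _check_mode(mode)
    if mode == "activity_corrected":
        g1 = 10.0 ** davies_log_gamma(1, state.ionic_strength)
        g2 = 10.0 ** davies_log_gamma(2, state.ionic_strength)
    else:
        g1 = g2 = 1.0
    total = (
        acid.lambda0_na * g1 * state.c_Na
        + acid.lambda0_h * g1 * state.c_H
        + acid.lambda0_oh * g1 * state.c_OH
        + acid.lambda0_mono * g1 * state.c_HA
        + acid.lambda0_di * g2 * state.c_A2
    )
    return total / 10.0


def invert_conductivity(
    kappa: float,
    pH: float,
    acid: AcidDefinition,
    mode: str = "ideal",
    c_max: float = 1.0,
) -> tuple[float, float]:
    """Recover (c_total, c_Na) from a measured conductivity and pH.

    Solves the one-dimensional root problem κ(c_total; pH) = κ_measured by
    bracketed search; electroneutrality then fixes c_Na.  Raises if the
    measured κ lies below the H+/OH- floor at this pH or above κ(c_max).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")

    def residual(c_total: float) -> float:
        return solve_solution_state(c_total, pH, acid, mode).conductivity - kappa

    floor = residual(0.0)
    if floor > 0:
        raise ValueError(
            f"conductivity {kappa} S/m is below the H+/OH- floor at pH {pH}"
        )
    if residual(c_max) < 0:
        raise ValueError(f"no root: conductivity exceeds the model at c_total={c_max}")
    c_total = brentq(residual, 0.0, c_max, xtol=1e-12, rtol=1e-12)
    state = solve_solution_state(c_total, pH, acid, mode)
    return c_total, state.c_Na
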
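"""Recompute the headline model figures from the default parameterisation.

Each row of the reproduction table recomputes one quantity from scratch
through the library — nothing is looked up — and compares it with the
value expected for the maleic-acid / commercial-cell parameterisation at
the stated tolerance.
"""

from __future__ import annotations

import pandas as pd

from .config import RunConfig
from .donnan import charge_efficiency_static, specific_charge
from .isotherm import pfl
from .operation import (
    OperatingPoint,
    lag_time,
    micropore_ph_shift,
    micropore_ratio_bound,
    predict_constant_current,
)

__all__ = ["reproduction_table"]


def reproduction_table(cfg: RunConfig) -> pd.DataFrame:
    """All deterministic headline checks as a pass/fail table."""
    rows = []

    def check(name, computed, expected, tol):
        rows.append({
            "quantity": name, "computed": computed, "expected": expected,
            "tolerance": tol, "pass": abs(computed - expected) <= tol,
        })

    sigma = specific_charge(1.2, cfg.cell) * 1e3  # meq/g
    check("capacitive charge at 1.2 V (meq/g)", round(sigma, 2), 0.14, 0.005)

    check("ohmic drop at 50 mA (mV)", cfg.cell.R_setup * 0.05 * 1e3, 45.0, 0.5)

    for ph, expected in ((4.0, 42.0), (8.0, 63.0)):
        loading = pfl(5e-3, ph, cfg.isotherm, cfg.acid, cfg.speciation_mode)
        _, lam = charge_efficiency_static(1.2, loading, cfg.cell, cfg.pfl_basis)
        check(f"charge efficiency pH {ph:g}, 5 mM, 1.2 V (%)",
              lam * 100.0, expected, 3.0)

    op = OperatingPoint(mode="constant_current", dphi_pot=1.3, current=0.05,
                        c_feed=10e-3, pH_feed=8.0)
    res = predict_constant_current(op, cfg.isotherm, cfg.acid, cfg.cell,
                                   cfg.speciation_mode, cfg.kappa_mode,
                                   pfl_basis=cfg.pfl_basis)
    check("Donnan potential, 10 mM pH 8, 1.3 V / 50 mA", res.phi_D, 0.97, 0.05)

    t_e = lag_time(pfl(10e-3, 8.5, cfg.isotherm, cfg.acid, cfg.speciation_mode),
                   cfg.cell, 0.05, cfg.pfl_basis)
    check("coion-expulsion lag, 10 mM pH 8.5, 50 mA (min)", t_e / 60.0, 13.0, 1.0)

    check("micropore pH shift at phi_D = 0.97", micropore_ph_shift(0.97), 0.42, 0.005)

    ratio, dph = micropore_ratio_bound(0.600, 0.020)
    check("micropore/bulk H+ ratio (600 mM / 20 mM)", ratio, 30.0, 0.5)
    check("pH bound from that ratio", dph, 1.48, 0.05)

    return pd.DataFrame(rows)
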
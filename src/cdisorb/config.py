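"""YAML run configuration: acid, cell, isotherm and mode settings.

All defaults equal the maleic-acid / commercial-cell parameterisation, so
every CLI subcommand runs without a config file.  Keys carry explicit
units (``molar_mass_g_mol``, ``lambda0_mono_S_cm2_mol``, ...).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .donnan import CellSpec
from .isotherm import MoreauParameters, TABLE_PARAMS_MALEIC
from .speciation import AcidDefinition, MALEIC_ACID

__all__ = ["RunConfig", "load_config", "default_config_dict"]


def default_config_dict() -> dict:
    """The built-in configuration as a plain dictionary."""
    return {
        "acid": {
            "name": MALEIC_ACID.name,
            "pKa1": MALEIC_ACID.pKa1,
            "pKa2": MALEIC_ACID.pKa2,
            "molar_mass_g_mol": MALEIC_ACID.molar_mass,
            "lambda0_mono_S_cm2_mol": MALEIC_ACID.lambda0_mono,
            "lambda0_di_S_cm2_mol": MALEIC_ACID.lambda0_di,
            "lambda0_na_S_cm2_mol": MALEIC_ACID.lambda0_na,
            "lambda0_h_S_cm2_mol": MALEIC_ACID.lambda0_h,
            "lambda0_oh_S_cm2_mol": MALEIC_ACID.lambda0_oh,
        },
        "cell": {
            "Cg_F_g": 45.0,
            "electrode_mass_each_g": 1.66,
            "vm_cm3_g": 0.62,
            "R_setup_ohm": 0.9,
            "k_cell_per_A_m": 6.0,
            "tafel_a_A": 1.0e-3,
            "tafel_b_V": 0.12,
            "dphi_crit_V": 1.0,
            "inner_volume_mL": 10.8,
        },
        "isotherm": {
            "K_A_L_mol": TABLE_PARAMS_MALEIC.K_A,
            "K_B_L_mol": TABLE_PARAMS_MALEIC.K_B,
            "q_max_mmol_g": TABLE_PARAMS_MALEIC.q_max,
            "U_AA_kJ_mol": TABLE_PARAMS_MALEIC.U_AA,
            "U_AB_kJ_mol": TABLE_PARAMS_MALEIC.U_AB,
            "U_BB_kJ_mol": TABLE_PARAMS_MALEIC.U_BB,
        },
        "modes": {
            "speciation": "ideal",
            "kappa": "activity_corrected",
            "pfl_basis": "electrode",
        },
        "seed": 0,
    }


@dataclass
class RunConfig:
    """Validated run configuration resolved to domain objects."""

    acid: AcidDefinition
    cell: CellSpec
    isotherm: MoreauParameters
    speciation_mode: str = "ideal"
    kappa_mode: str = "activity_corrected"
    pfl_basis: str = "electrode"
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def digest(self) -> str:
        """Stable hash of the resolved configuration, for run logging."""
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:12]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, filling unspecified keys with the defaults."""
    data = default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh)
        if not isinstance(user, dict):
            raise ValueError(f"malformed config file {path}: expected a mapping")
        data = _merge(data, user)
    try:
        a = data["acid"]
        acid = AcidDefinition(
            name=a["name"],
            pKa1=float(a["pKa1"]),
            pKa2=float(a["pKa2"]),
            molar_mass=float(a["molar_mass_g_mol"]),
            lambda0_mono=float(a["lambda0_mono_S_cm2_mol"]),
            lambda0_di=float(a["lambda0_di_S_cm2_mol"]),
            lambda0_na=float(a["lambda0_na_S_cm2_mol"]),
            lambda0_h=float(a["lambda0_h_S_cm2_mol"]),
            lambda0_oh=float(a["lambda0_oh_S_cm2_mol"]),
        )
        c = data["cell"]
        cell = CellSpec(
            Cg=float(c["Cg_F_g"]),
            electrode_mass_each=float(c["electrode_mass_each_g"]),
            vm=float(c["vm_cm3_g"]),
            R_setup=float(c["R_setup_ohm"]),
            k_cell=float(c["k_cell_per_A_m"]),
            tafel_a=float(c["tafel_a_A"]),
            tafel_b=float(c["tafel_b_V"]),
            dphi_crit=float(c["dphi_crit_V"]),
            inner_volume=float(c["inner_volume_mL"]) * 1e-3,
        )
        iso = data["isotherm"]
        params = MoreauParameters(
            K_A=float(iso["K_A_L_mol"]),
            K_B=float(iso["K_B_L_mol"]),
            q_max=float(iso["q_max_mmol_g"]),
            U_AA=float(iso["U_AA_kJ_mol"]),
            U_AB=float(iso["U_AB_kJ_mol"]),
            U_BB=float(iso["U_BB_kJ_mol"]),
        )
        modes = data["modes"]
        return RunConfig(
            acid=acid,
            cell=cell,
            isotherm=params,
            speciation_mode=str(modes["speciation"]),
            kappa_mode=str(modes["kappa"]),
            pfl_basis=str(modes["pfl_basis"]),
            seed=int(data["seed"]),
            raw=data,
        )
    except KeyError as exc:
        raise ValueError(f"malformed config: missing key {exc}") from exc
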
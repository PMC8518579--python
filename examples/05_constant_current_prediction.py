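"""Full constant-current prediction with all non-ideal corrections.

Runs the study's operating point - 10 mM maleic acid at pH 8, 50 mA up
to a 1.3 V threshold - through the complete chain: Davies-corrected
conductivity, ohmic and electrolyte voltage drops, Tafel parasitic
charge, corrected efficiency, capacity, and the coion-expulsion lag.
"""

from cdisorb import (
    ECOMITE_CELL,
    MALEIC_ACID,
    OperatingPoint,
    TABLE_PARAMS_MALEIC,
    predict_constant_current,
)

op = OperatingPoint(mode="constant_current", dphi_pot=1.3, current=0.05,
                    c_feed=0.010, pH_feed=8.0, flow_rate=2e-3)
res = predict_constant_current(op, TABLE_PARAMS_MALEIC, MALEIC_ACID, ECOMITE_CELL)

print("10 mM maleic acid, pH 8, 50 mA to 1.3 V:")
print(f"  feed conductivity     : {res.kappa:.3f} S/m")
print(f"  effective voltage     : {res.dphi_eff:.3f} V "
      f"(45 mV ohmic + {1.3 - 0.045 - res.dphi_eff:.3f} V electrolyte drop)")
print(f"  specific charge Sigma : {res.sigma * 1e3:.3f} meq/g")
print(f"  PFL (pair basis)      : {res.pfl:.4f} meq/g")
print(f"  Donnan potential      : {res.phi_D:.3f} (dimensionless)")
print(f"  charge efficiency     : {res.lambda_eff * 100:.1f} %")
print(f"  parasitic charge      : {res.q_redox_fraction * 100:.1f} % of total")
print(f"  corrected efficiency  : {res.lambda_corr * 100:.1f} %")
print(f"  SAC                   : {res.sac_eq * 1e3:.3f} meq/g "
      f"= {res.sac_mol * 1e6:.1f} mmol/kg")
print(f"  coion-expulsion lag   : {res.t_E / 60:.1f} min")
print("\nThe Donnan potential of ~0.96 implies a micropore-bulk pH shift of"
      " only ~0.4 units, and the ~13 min lag is the time the 50 mA current"
      " needs to expel the potential-free coion loading before any net"
      " capture shows in the effluent.")
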
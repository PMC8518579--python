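"""Close the loop: synthesize an effluent trace, then analyze it.

Forward-generates a cyclic conductivity/pH trace consistent with the
constant-current prediction (lag phase, depletion dip with cell-volume
washout, desorption overshoot, 1% sensor noise), then runs the analysis
pipeline an experimentalist would use on real probe data: conductivity
inversion per sample, cycle detection from the current program, SAC by
trapezoidal integration, charge efficiency from the supplied charge.
"""

from cdisorb import (
    ECOMITE_CELL,
    MALEIC_ACID,
    OperatingPoint,
    TABLE_PARAMS_MALEIC,
    analyze_cycles,
    predict_constant_current,
    synthesize_trace,
)

op = OperatingPoint(mode="constant_current", dphi_pot=1.3, current=0.05,
                    c_feed=0.010, pH_feed=8.0, flow_rate=2e-3)
pred = predict_constant_current(op, TABLE_PARAMS_MALEIC, MALEIC_ACID, ECOMITE_CELL)
trace = synthesize_trace(op, pred, MALEIC_ACID, ECOMITE_CELL,
                         n_cycles=5, dt=10.0, noise=0.01, seed=11)
print(f"synthesized {trace.time[-1] / 3600:.1f} h trace, "
      f"{trace.time.size} samples, 5 cycles, 1% sensor noise")

cycles, mean = analyze_cycles(trace, MALEIC_ACID, ECOMITE_CELL,
                              skip_first=2, n_average=3)
print(f"\n{'cycle':>6} {'SAC mmol/kg':>12} {'Lambda %':>9}")
for i, r in enumerate(cycles, 1):
    print(f"{i:6d} {r.sac_mol * 1e6:12.1f} {r.lambda_exp:9.1f}")
print(f"{'mean':>6} {mean.sac_mol * 1e6:12.1f} {mean.lambda_exp:9.1f}"
      "   (cycles 3-5, steady state)")
print(f"\nprediction: SAC {pred.sac_mol * 1e6:.1f} mmol/kg, "
      f"corrected efficiency {pred.lambda_corr * 100:.1f} %")
print("The steady-state mean recovers the prediction to within the sensor"
      " noise; the first cycles are kept out of the average as start-up.")
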
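"""Decompose one noisy synthetic heartbeat into its five waves.

Simulates a typical beat (2% Gaussian noise), runs the MI estimator and
prints the recovered wave parameters next to the generating ones.  The
per-wave PV column is each wave's increment to the explained variance.
"""

from fmmecg import fit_beat, pattern_presets, simulate_beat

preset = pattern_presets()["NORMAL"]
beat = simulate_beat(preset.params, sigma=0.02, n=500, seed=42)
fit = fit_beat(beat)

print(f"status={fit.status}  R^2={fit.r2:.4f}  sigma^2={fit.sigma2:.2e}  "
      f"iterations={fit.n_iter}")
print(f"{'wave':>4} {'A_true':>7} {'A_fit':>7} {'alpha_true':>10} {'alpha_fit':>9} "
      f"{'omega_true':>10} {'omega_fit':>9} {'PV':>7}")
for lab in "PQRST":
    tw = preset.params.waves[lab]
    ew = fit.params.waves[lab]
    print(f"{lab:>4} {tw.A:7.3f} {ew.A:7.3f} {tw.alpha:10.3f} {ew.alpha:9.3f} "
          f"{tw.omega:10.3f} {ew.omega:9.3f} {fit.pv_by_wave[lab]:7.4f}")
print("A in signal units, alpha in radians on [0, 2*pi); a close A/alpha/omega"
      " match means the morphology was recovered, not just the curve.")
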
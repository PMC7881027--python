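"""Tell seven beat morphologies apart from their fitted wave parameters.

Simulates a few beats per morphology preset at low noise, fits each one,
and runs leave-one-out Fisher LDA on the (A, omega, beta) features of the
five waves.  Zero error means the 15 fitted shape parameters are enough to
identify the pattern.
"""

from fmmecg import fit_beat, pattern_presets, simulate_dataset
from fmmecg.evaluation import lda_loocv, wave_feature_matrix

beats, labels = [], []
for name, preset in pattern_presets().items():
    sigma = 0.02 * preset.params.waves["R"].A
    for sim in simulate_dataset(patterns=[name], beats_per_pattern=4,
                                sigma=sigma, seed=1, n=500):
        beats.append(sim.beat)
        labels.append(sim.pattern)

fits = [fit_beat(b) for b in beats]
ok = sum(f.status == "OK" for f in fits)
X, cols = wave_feature_matrix(fits)
error = lda_loocv(X, labels)

print(f"fitted {len(fits)} beats ({ok} with all five waves identified)")
print(f"features: {len(cols)} (amplitude, sharpness, shape angle per wave)")
print(f"leave-one-out LDA misclassification rate: {100 * error:.1f}%")
print("0.0% means every held-out beat was attributed to its generating "
      "morphology from the fitted parameters alone.")
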
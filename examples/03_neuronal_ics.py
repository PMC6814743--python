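"""Build neuronal indifference curves and validate them out of sample.

Pools z-scored responses of a simulated preference population into the
interaction regression, draws iso-response curves, compares their slope with
the behavioral curve, and checks held-out bundles against the 95% band.
"""

import numpy as np

import revpref as rp
from revpref.neuronal_ic import ic_parameters, out_of_sample_distance, response_table
from revpref.protocols import grid_population

trials, names, model = grid_population(n_neurons=15, gain=10.0, seed=3)
table = response_table(trials, names, ("stimulus",))

# hold out 30% of bundles for validation
rng = np.random.default_rng(0)
bundles = table[["qA", "qB"]].drop_duplicates().to_numpy()
held = set(map(tuple, bundles[rng.choice(len(bundles),
                                         size=len(bundles) // 3,
                                         replace=False)]))
mask = np.array([tuple(p) in held for p in table[["qA", "qB"]].to_numpy()])

fit = ic_parameters(table[~mask], n_boot=200, seed=1)
print(f"pooled iso-response fit: b1={fit.beta1:.2f} (reward A), "
      f"b2={fit.beta2:.2f} (reward B), b3={fit.beta3:.2f} (interaction)")
print(f"slope ratio b2/b1 = {fit.slope_ratio:.3f} "
      f"(ground truth a/b = {1.0/1.25:.3f})")
print(f"scale-free curvature b3/b1 = {fit.curvature_scaled:.3f} "
      f"(ground truth c/b = {0.4/1.25:.3f})")

res = out_of_sample_distance(table[mask], fit)
print(f"\nheld-out validation on {mask.sum()} responses: "
      f"mean vertical distance {res['mean_distance']*1000:.0f} microliters, "
      f"{res['fraction_within']*100:.1f}% within the 95% band")
print("Distances are measured in ml of reward A between each held-out bundle "
      "and the\niso-response curve whose level best matches its response "
      "strength.")
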
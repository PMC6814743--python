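"""Pseudo-population decoding of bundle identity across and along curves.

Simulates a revealed-preference population, decodes between the lowest and
highest indifference curves with the leave-one-out linear SVM protocol, and
contrasts it with the within-curve comparisons and the shuffle null.
"""

import numpy as np

import revpref as rp
from revpref.decoding import decode_with_null, trialwise_responses
from revpref.protocols import calibrate_gain, ic_population, mean_response_rho

gain = calibrate_gain(target_rho=0.6, n_neurons=20, seed=0)
trials, names, model, ranks = ic_population(20, gain, seed=0)
rho = mean_response_rho(trials, names, ranks)
print(f"calibrated Poisson gain {gain:.1f} impulses/s per utility unit "
      f"-> mean response-rank rho {rho:.2f}")

resp = trialwise_responses(trials, names, ranks)
low, high = int(ranks.min()), int(ranks.max())
res = decode_with_null(resp, (low, high), iterations=150, seed=1)
print(f"\nacross-curve decoding (curve {low} vs {high}): "
      f"{res.accuracy_mean:.1f}% correct")
print(f"shuffle null: {res.shuffle_mean:.1f}% "
      f"(rank-sum p = {res.p_vs_shuffle:.2g})")

adj = decode_with_null(resp, (low, low + 1), iterations=150, seed=2)
print(f"adjacent curves ({low} vs {low+1}): {adj.accuracy_mean:.1f}% correct")
print("\nAccuracy grows with curve distance; equal-preference bundles on a "
      "single curve\ncarry no decodable distinction (see the within-curve "
      "tests in the suite).")
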
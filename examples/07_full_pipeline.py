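"""Run the whole analysis chain on one simulated session.

Chains simulation, psychometrics, curve fitting, classification, neuronal
curves, chosen value, decoding, and the axiom test; every stage writes flat
CSV/JSON into the session directory and a manifest records seeds and
checksums for reproducibility.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from revpref.pipeline import SessionConfig, run_pipeline

config = SessionConfig(seed=7, n_boot=100, decode_iterations=50)
outdir = run_pipeline(config, Path(tempfile.mkdtemp()) / "session")
print(f"session written to {outdir}\n")

ic = json.loads((outdir / "behavioral_ic.json").read_text())
print(f"behavioral curve: slope {ic['slope']:.2f}, curvature {ic['curvature']:.2f}, "
      f"adj R2 {ic['adj_r2']:.3f}")

census = pd.read_csv(outdir / "classification.csv")
print("\nneuron labels:")
print(census.groupby("neuron_label")["neuron"].nunique().to_string())

dec = json.loads((outdir / "decoding.json").read_text())
print(f"\ndecoding curves {dec['classes']}: {dec['accuracy']:.1f}% "
      f"(shuffle {dec['shuffle']:.1f}%, p = {dec['p_vs_shuffle']:.2g})")

warp = json.loads((outdir / "warp.json").read_text())
print(f"axiom verdict: {warp['behavioral']['verdict']}")
manifest = json.loads((outdir / "manifest.json").read_text())
print(f"\nmanifest: {len(manifest['checksums'])} files, "
      f"master seed {manifest['seed']} (same config reproduces identical checksums)")
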
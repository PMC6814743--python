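"""Session orchestration: configuration, trial-table serialization, staging.

A single :class:`SessionConfig` fully determines a simulated session and its
analysis.  :func:`run_pipeline` chains the stages — simulate, behavioral fits,
response classification, neuronal indifference curves, chosen value, decoding,
and the choice-axiom test — writing each stage's outputs as flat delimited
text or JSON into a session directory, and finishes with a manifest recording
package versions, stage seeds, and file checksums.  All randomness derives
from the master seed through a seed-sequence spawn per stage, so the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import fit_ic, fit_psychometric
from .bundles import Bundle, make_utility
from .chosen_value import classify_value_coding, compute_values, estimate_k1_from_block
from .classify import classify_population, zscore
from .decoding import decode_with_null, trialwise_responses
from .neuronal_ic import compare_slopes, ic_parameters, response_table
from .simulate import (
    NeuronSpec,
    design_bundles_on_ics,
    make_anchor_block,
    make_choice_block,
    make_ip_block,
    make_warp_block,
    simulate_population,
    target_bundle,
)
from .warp import behavioral_warp, neuronal_warp

__all__ = ["SessionConfig", "run_pipeline", "read_trials", "write_trials"]

#: Columns every trial table must carry (spike-count columns are appended).
REQUIRED_COLUMNS = [
    "trial", "block", "n_options",
    "qA0", "qB0", "qA1", "qB1",
    "ref_left", "chosen", "chose_variable", "chose_left",
]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with a JSON sidecar for generator metadata."""
    path = Path(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    trials.to_csv(path, index=False)
    if trials.attrs:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(_jsonable(trials.attrs), fh, indent=1, sort_keys=True)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table, validating the schema and restoring metadata.

    Unknown extra columns are preserved untouched; missing required columns
    raise an error naming them.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns: {missing}")
    for c in ("ref_left", "chose_variable", "chose_left"):
        df[c] = df[c].astype(bool)
    meta = path.with_suffix(path.suffix + ".meta.json")
    if meta.exists():
        with open(meta) as fh:
            df.attrs.update(json.load(fh))
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Everything needed to reproduce one simulated session end to end."""

    # ground-truth preferences
    utility_a: float = 1.0
    utility_b: float = 1.25
    utility_c: float = 0.4
    temperature: float = 0.05
    # trial design
    ic_levels: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    qB_positions: tuple[float, ...] = (0.0, 0.2, 0.4)
    ip_reps: int = 8
    choice_reps: int = 10
    anchor_qB: float = 0.5
    warp_reps: int = 30
    # neuron roster: (label, baseline impulses/s, gain)
    neurons: tuple[tuple[str, float, float], ...] = (
        ("rp_positive", 10.0, 25.0),
        ("rp_positive", 12.0, 20.0),
        ("rp_positive", 8.0, 30.0),
        ("rp_inverse", 20.0, 15.0),
        ("single_A", 10.0, 25.0),
        ("single_B", 10.0, 25.0),
        ("chosen_value_abs", 10.0, 25.0),
        ("unmodulated", 10.0, 0.0),
    )
    responsive_epochs: tuple[str, ...] = ("stimulus", "choice")
    # statistics
    alpha: float = 0.05
    screen_alpha: float = 0.01
    n_boot: int = 200
    decode_iterations: int = 50
    seed: int = 0

    def utility(self):
        return make_utility(self.utility_a, self.utility_b, self.utility_c,
                            self.temperature)

    def neuron_specs(self) -> list[NeuronSpec]:
        return [
            NeuronSpec(label=lab, baseline_rate=base, gain=gain,
                       responsive_epochs=self.responsive_epochs)
            for lab, base, gain in self.neurons
        ]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for k in ("ic_levels", "qB_positions", "responsive_epochs"):
            if k in raw:
                raw[k] = tuple(raw[k])
        if "neurons" in raw:
            raw["neurons"] = tuple(tuple(n) for n in raw["neurons"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)


def run_pipeline(config: SessionConfig, outdir) -> Path:
    """Run the full analysis chain on one simulated session.

    Writes, under ``outdir``: the trial tables (``trials_*.csv``), the
    indifference-point and curve fits, the response classification census,
    the pooled neuronal-curve parameters and behavioral comparison, the
    chosen-value census, the decoding result, the axiom verdicts, and a
    ``manifest.json`` with versions, seeds, and checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    model = config.utility()
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("design", "ip", "choice", "anchor", "warp", "neurons", "analysis"),
        ss.spawn(7))}
    notices: list[str] = []

    # --- stage 1: simulate -------------------------------------------------
    on_ics = design_bundles_on_ics(model, config.ic_levels, config.qB_positions)
    bundles = [b for pts in on_ics.values() for b in pts]
    zero = Bundle(0.0, 0.0)

    ip_blocks = []
    ref_level = config.ic_levels[len(config.ic_levels) // 2]
    ref = Bundle(float(model.ic_qA(ref_level, 0.0)), 0.0)
    ip_qBs = [q for q in config.qB_positions if q > 0] + [0.55]
    for qB, child in zip(ip_qBs, seeds["ip"].spawn(len(ip_qBs))):
        ip_true = model.indifference_qA(ref, qB)
        grid = np.round(np.clip(ip_true + np.array([-0.2, -0.1, 0, 0.1, 0.2]), 0, 0.9), 3)
        ip_blocks.append(
            make_ip_block(model, ref, "A", qB, grid, config.ip_reps,
                          np.random.default_rng(child))
        )

    pairs = [(zero, b) for b in bundles[:12]]
    choice = make_choice_block(model, pairs, config.choice_reps,
                               np.random.default_rng(seeds["choice"]))
    anchor_qA_true = model.indifference_qA(Bundle(0.0, config.anchor_qB), 0.0)
    anchor_grid = np.round(np.clip(
        anchor_qA_true + np.array([-0.2, -0.1, 0, 0.1, 0.2]), 0.0, 0.9), 3)
    anchor = make_anchor_block(model, config.anchor_qB, anchor_grid,
                               config.ip_reps, np.random.default_rng(seeds["anchor"]))
    mid = config.ic_levels[len(config.ic_levels) // 2]
    hi = config.ic_levels[-1]
    a1 = Bundle(float(model.ic_qA(mid, 0.0)), 0.0)
    a2 = Bundle(0.0, float(model.indifference_qB(a1, 0.0)))
    third = Bundle(float(model.ic_qA(hi, 0.25)), 0.25)
    warp_block = make_warp_block(model, a1, a2, third, config.warp_reps,
                                 np.random.default_rng(seeds["warp"]))

    specs = config.neuron_specs()
    names = [f"n{i}" for i in range(len(specs))]
    n_rngs = seeds["neurons"].spawn(max(len(specs), 1) * 2)
    for tab, off in ((choice, 0), (warp_block, len(specs))):
        for i, spec in enumerate(specs):
            from .simulate import simulate_neuron
            simulate_neuron(spec, tab, model,
                            np.random.default_rng(n_rngs[off + i]), names[i])

    for i, blk in enumerate(ip_blocks):
        write_trials(blk, outdir / f"trials_ip{i}.csv")
    write_trials(choice, outdir / "trials_choice.csv")
    write_trials(anchor, outdir / "trials_anchor.csv")
    write_trials(warp_block, outdir / "trials_warp.csv")

    # --- stage 2: behavior -------------------------------------------------
    rng_an = np.random.default_rng(seeds["analysis"])
    fits, ip_rows = [], []
    for i, blk in enumerate(ip_blocks):
        f = fit_psychometric(blk, n_boot=config.n_boot, seed=rng_an)
        fits.append((blk, f))
        qB = blk.attrs["fixed_other"]
        ip_rows.append(dict(block=i, qB=qB, ip_qA=f.ip, ci_lo=f.ci95[0],
                            ci_hi=f.ci95[1], flagged=f.flagged))
    ip_rows.append(dict(block=-1, qB=0.0, ip_qA=ref.qA, ci_lo=np.nan,
                        ci_hi=np.nan, flagged=False))
    ips_df = pd.DataFrame(ip_rows)
    ips_df.to_csv(outdir / "indifference_points.csv", index=False)
    pts = ips_df[["qB", "ip_qA"]].to_numpy()
    wts = np.array([
        1.0 / max(((r.ci_hi - r.ci_lo) / 3.92) ** 2, 1e-6)
        if np.isfinite(r.ci_hi) else 1.0
        for r in ips_df.itertuples()
    ])
    ic = fit_ic(pts, wts, n_boot=config.n_boot, seed=rng_an)
    _dump({"a": ic.a, "b": ic.b, "c": ic.c, "slope": ic.slope,
           "curvature": ic.curvature, "adj_r2": ic.adj_r2,
           "ci_band": ic.ci_band}, outdir / "behavioral_ic.json")

    # --- stage 3+: neural stages ------------------------------------------
    if not names:
        notices.append("no neurons configured: neural stages emit empty outputs")
        for f in ("classification.csv", "value_coding.csv"):
            pd.DataFrame().to_csv(outdir / f, index=False)
        for f in ("neuronal_ic.json", "decoding.json", "warp.json"):
            _dump({"notice": "no neurons"}, outdir / f)
    else:
        census = classify_population(
            choice, names, model.utility_xy, levels=list(config.ic_levels),
            alpha=config.alpha, screen_alpha=config.screen_alpha)
        census.to_csv(outdir / "classification.csv", index=False)
        rp_epochs = census[census["label"].isin(["rp_positive", "rp_inverse"])]
        rp_neurons = sorted(rp_epochs["neuron"].unique())
        if len(rp_neurons) >= 2:
            tab = pd.concat([
                response_table(choice, [n], (ep,))
                for n, ep in rp_epochs[["neuron", "epoch"]].itertuples(index=False)
            ], ignore_index=True)
            pooled = ic_parameters(tab, n_boot=min(config.n_boot, 200), seed=rng_an)
            comp = compare_slopes(pooled, ic)
            _dump({"beta0": pooled.beta0, "beta1": pooled.beta1,
                   "beta2": pooled.beta2, "beta3": pooled.beta3,
                   "err0": pooled.err0, "slope_ratio": pooled.slope_ratio,
                   "comparison": comp}, outdir / "neuronal_ic.json")
        else:
            notices.append("fewer than two preference neurons: pooled curve skipped")
            _dump({"notice": "insufficient preference responses"},
                  outdir / "neuronal_ic.json")

        k1 = estimate_k1_from_block(anchor, n_boot=0)
        cv, ucv = compute_values(choice, k1)
        value_rows = []
        for n in names:
            z = zscore(choice, n, "stimulus")
            try:
                v = classify_value_coding(z, cv, ucv, alpha=config.alpha)
                value_rows.append(dict(neuron=n, category=v.category, sign=v.sign))
            except ValueError as e:
                value_rows.append(dict(neuron=n, category="refused", sign=0))
                notices.append(f"value coding {n}: {e}")
        pd.DataFrame(value_rows).to_csv(outdir / "value_coding.csv", index=False)
        _dump({"k1": k1}, outdir / "value_summary.json")

        tb = np.array([target_bundle(r).as_tuple() for _, r in choice.iterrows()])
        from .classify import assign_ic_ranks
        ranks, _ = assign_ic_ranks(tb[:, 0], tb[:, 1], model.utility_xy,
                                   levels=list(config.ic_levels))
        use = rp_neurons if len(rp_neurons) >= 2 else names
        resp = trialwise_responses(choice, use, ranks)
        lo_hi = (int(ranks.min()), int(ranks.max()))
        try:
            dec = decode_with_null(resp, lo_hi, config.decode_iterations,
                                   seed=int(rng_an.integers(2**31)))
            _dump({"classes": lo_hi, "accuracy": dec.accuracy_mean,
                   "shuffle": dec.shuffle_mean, "p_vs_shuffle": dec.p_vs_shuffle},
                  outdir / "decoding.json")
        except ValueError as e:
            notices.append(f"decoding skipped: {e}")
            _dump({"notice": str(e)}, outdir / "decoding.json")

        bw = behavioral_warp(warp_block)
        nw = {}
        for n in names:
            try:
                nw[n] = neuronal_warp(warp_block, n)
            except ValueError as e:
                nw[n] = {"notice": str(e)}
        _dump({"behavioral": {"verdict": bw.verdict, "best3": bw.best3,
                              "best2": bw.best2},
               "neuronal": nw}, outdir / "warp.json")

    # --- manifest ----------------------------------------------------------
    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {k: list(v.spawn_key) for k, v in seeds.items()},
        "notices": notices,
        "checksums": {f: _checksum(outdir / f) for f in files},
    }
    _dump(manifest, outdir / "manifest.json")
    return outdir
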
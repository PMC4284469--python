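#!/usr/bin/env python
"""Fit the post-reversal decay law to the generated tracks.

Runs the measurement pipeline (velocity -> reversal detection -> cycle
segmentation -> pooled nonlinear fit) on the track sets written by
01_generate_tracks.py and reports, per condition, the recovered terminal
velocity, burst speed, time constant and median reversal interval, next to
the generating values.  Also writes the per-cycle duration/displacement
table whose upper envelope is the maximum-speed line.
"""

import json
from pathlib import Path

import numpy as np

from phormidium import io as pio
from phormidium.kinetics import params_for_agar
from phormidium.tracks import analyze_track, displacement_duration_table, fit_decay

ROOT = Path(__file__).resolve().parents[1]
TRACKS = ROOT / "results" / "tracks"
OUT = ROOT / "results"

report = {}
for agar in (1.5, 2.0):
    files = sorted((TRACKS / f"agar_{agar:.1f}").glob("track_*.csv"))
    if not files:
        raise SystemExit("run 01_generate_tracks.py first")
    cycles, intervals = [], []
    for path in files:
        res = analyze_track(pio.read_track_csv(path))
        cycles.extend(res["cycles"])
        if len(res["reversals"]) >= 2:
            intervals.extend(np.diff(res["reversals"]))
    fit = fit_decay(cycles, t_min=2.0)
    df, slope = displacement_duration_table(cycles)
    df.to_csv(OUT / f"cycles_agar_{agar:.1f}.tsv", sep="\t", index=False,
              float_format="%.4f")
    truth = params_for_agar(agar)
    report[f"{agar}"] = {
        "n_tracks": len(files),
        "n_cycles": len(cycles),
        "v_term_um_s": fit.v_term,
        "v_term_true": truth.v_term,
        "v_max_um_s": fit.v_max,
        "v_max_true": truth.v_max,
        "tau_s": fit.tau,
        "tau_true": truth.tau,
        "se_v_term": fit.se_v_term,
        "se_tau": fit.se_tau,
        "median_reversal_interval_min": float(np.median(intervals)) / 60.0,
        "upper_limit_slope_um_s": slope,
        "converged": fit.converged,
    }
    print(f"agar {agar}%: {len(cycles)} cycles | "
          f"v_term {fit.v_term:.3f} (true {truth.v_term:.3f}) um/s | "
          f"tau {fit.tau:.0f} (true {truth.tau:.0f}) s | "
          f"v_max {fit.v_max:.3f} (true {truth.v_max:.3f}) um/s | "
          f"median interval {np.median(intervals)/60:.1f} min")

with open(OUT / "kinetics_fits.json", "w") as fh:
    json.dump(report, fh, indent=2)
print(f"wrote {OUT / 'kinetics_fits.json'}")
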
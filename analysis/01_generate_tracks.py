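#!/usr/bin/env python
"""Generate the synthetic time-lapse track sets for both agar conditions.

No trajectory data were deposited with the original plate experiments, so
all downstream analyses run on synthetic tip tracks carrying the measured
statistical structure: reversal intervals of 5-10 min, exponential speed
decay to the condition's terminal velocity, and Gaussian tracking noise.
Writes per-condition track CSVs under results/tracks/.
"""

from pathlib import Path

from phormidium import io as pio
from phormidium.synthetic import tracks_for_condition

OUT = Path(__file__).resolve().parents[1] / "results" / "tracks"
N_TRACKS = 30
DURATION_S = 3600.0
SEED = 20260901

for agar in (1.5, 2.0):
    out_dir = OUT / f"agar_{agar:.1f}"
    out_dir.mkdir(parents=True, exist_ok=True)
    batch = tracks_for_condition(agar, N_TRACKS, duration_s=DURATION_S,
                                 seed=SEED + int(agar * 10))
    n_reversals = 0
    for k, (track, truth) in enumerate(batch):
        pio.write_track_csv(out_dir / f"track_{k:03d}.csv", track)
        n_reversals += len(truth)
    print(f"agar {agar}%: wrote {N_TRACKS} tracks "
          f"({DURATION_S:.0f} s at 1 fps, {n_reversals} scheduled reversals) "
          f"-> {out_dir}")
print("done")
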
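"""Simulate the synthetic swimming study.

Generates the full factorial design — 5 fish × 2 viscosities (1/40 cP) ×
2 light levels × 2 lateral-line states × 2 trials = 80 trials at 500
frames/s, 2 s each — with condition-dependent kinematic shifts, per-fish
random intercepts and per-trial noise.  Landmark tracks and the ground-truth
table go to results/study/; a handful of rendered silhouette stacks (large,
binary) go to scratch/frames/.

Per-trial raw data (tracks, frames) are bulky and go under scratch/; only
the small ground-truth table lands in results/.

Run from the repository root:  python analysis/01_simulate_study.py
"""

from pathlib import Path

from swimkin.io import write_frames, write_pose_csv
from swimkin.synthetic import (
    SwimmerParams,
    emit_tracks,
    generate_midline_sequence,
    generate_study,
    render_silhouette,
)

SEED = 20230915
OUT = Path("results/study")
SCRATCH = Path("scratch/frames")
N_RENDERED = 2  # silhouette stacks are ~30 MB of raw boolean frames each


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    trials, truth = generate_study(base=SwimmerParams(), seed=SEED)
    truth.to_csv(OUT / "ground_truth.csv", index=False)
    print(f"study: {len(trials)} trials, {truth.fish_id.nunique()} fish")
    print(
        "mean truth wave_freq_f by viscosity:\n",
        truth.groupby("viscosity").wave_freq_f.mean().round(3).to_string(),
    )
    print(
        "fin state counts by viscosity:\n",
        truth.groupby(["viscosity", "fin_state"]).size().to_string(),
    )

    tracks_dir = Path("scratch/study/tracks")
    tracks_dir.mkdir(exist_ok=True)
    for i, trial in enumerate(trials):
        mls = generate_midline_sequence(trial.params)
        track = emit_tracks(mls, trial.params)
        write_pose_csv(track, tracks_dir / f"{trial.design.trial_id}.csv")
        if i < N_RENDERED:
            stack = render_silhouette(mls, trial.params)
            write_frames(stack, SCRATCH / f"{trial.design.trial_id}.tif")
    print(f"wrote {len(trials)} track files to {tracks_dir}")
    print(f"wrote {N_RENDERED} silhouette stacks to {SCRATCH}")


if __name__ == "__main__":
    main()
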
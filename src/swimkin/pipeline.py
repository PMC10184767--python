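"""Study-level drivers: run trials end to end and collect the trial table."""

from __future__ import annotations

import warnings

import pandas as pd

from .exceptions import TrialRejected
from .kinematics import assemble_trial
from .midline import Midline, MidlineSequence, extract_midline
from .synthetic import StudyTrial, emit_tracks, generate_midline_sequence, render_silhouette

__all__ = ["process_trial_tracks", "process_trial_frames", "run_study_tracks", "midlines_from_stack"]


def midlines_from_stack(stack, track, n_points: int = 100) -> MidlineSequence:
    """Extract a midline per frame, anchored by the per-frame nose/tail track."""
    nose = track.require("nose")
    tail = track.require("tail")
    mls = [
        extract_midline(frame, nose[i], tail[i], n_points=n_points)
        for i, frame in enumerate(stack.frames)
    ]
    return MidlineSequence(midlines=mls, fps=stack.fps)


def process_trial_tracks(trial: StudyTrial, **kwargs):
    """Tracks-path pipeline for one synthetic trial (analytic midlines)."""
    mls = generate_midline_sequence(trial.params)
    track = emit_tracks(mls, trial.params)
    meta = {
        "trial_id": trial.design.trial_id,
        "fish_id": trial.design.fish_id,
        "viscosity": trial.design.viscosity,
        "light": trial.design.light,
        "lateral_line": trial.design.lateral_line,
        "trial_index": trial.design.trial_index,
    }
    return assemble_trial(track, mls, metadata=meta, **kwargs)


def process_trial_frames(trial: StudyTrial, shape=(256, 1024), **kwargs):
    """Frames-path pipeline: render silhouettes, re-extract midlines, measure."""
    mls_true = generate_midline_sequence(trial.params)
    track = emit_tracks(mls_true, trial.params)
    stack = render_silhouette(mls_true, trial.params, shape=shape)
    mls = midlines_from_stack(stack, track)
    meta = {"trial_id": trial.design.trial_id, "fish_id": trial.design.fish_id}
    return assemble_trial(track, mls, metadata=meta, **kwargs)


def run_study_tracks(trials, **kwargs) -> pd.DataFrame:
    """Run the tracks-path pipeline over a study; rejected trials keep their reasons."""
    rows = []
    for trial in trials:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tk = process_trial_tracks(trial, **kwargs)
            row = tk.to_dict()
            row["rejection_reason"] = ""
        except TrialRejected as exc:
            row = {
                "trial_id": trial.design.trial_id,
                "fish_id": trial.design.fish_id,
                "viscosity": trial.design.viscosity,
                "light": trial.design.light,
                "lateral_line": trial.design.lateral_line,
                "trial_index": trial.design.trial_index,
                "rejection_reason": "; ".join(exc.reasons),
            }
        rows.append(row)
    return pd.DataFrame(rows)
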
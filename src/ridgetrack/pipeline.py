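"""End-to-end tracking pipeline: segmentation, forward and backward
linking, trajectory assembly and summary statistics."""

from __future__ import annotations

from typing import List, Optional, Tuple

from .foreground import ForegroundConfig, segment_stack
from .io import FrameStack
from .linking import TemplateParams, TrackState, backward_pass, forward_pass
from .matching import MatchingConfig
from .trajectories import Trajectory, assemble_trajectories, classify_trajectory

__all__ = ["track_stack", "track_events", "summarize_tracking"]


def track_events(
    events_by_frame: List[list],
    match_cfg: Optional[MatchingConfig] = None,
    template_params: Optional[TemplateParams] = None,
) -> TrackState:
    """Run the forward and backward linking passes over pre-segmented
    per-frame event lists."""
    state = TrackState(events_by_frame=events_by_frame)
    forward_pass(state, match_cfg, template_params)
    backward_pass(state, match_cfg, template_params)
    return state


def track_stack(
    stack: FrameStack,
    fg_cfg: Optional[ForegroundConfig] = None,
    match_cfg: Optional[MatchingConfig] = None,
    template_params: Optional[TemplateParams] = None,
) -> TrackState:
    """Segment every frame of a stack and link the events into cells."""
    events = segment_stack(stack, fg_cfg)
    return track_events(events, match_cfg, template_params)


def summarize_tracking(
    state: TrackState,
    frame_shape: Tuple[int, int],
    margin: float = 10.0,
) -> dict:
    """Classify trajectories and summarize the run.

    Reports frame and event counts, the frame-occupancy histogram
    (empty / one event / two or more events) and the percentage of
    events lying on correctly tracked trajectories (those that both
    start and end at the field-of-view boundary).
    """
    trajectories = assemble_trajectories(state)
    for traj in trajectories:
        classify_trajectory(traj, frame_shape, margin)

    n_frames = state.n_frames
    occupancy = {"empty": 0, "one": 0, "multi": 0}
    for frame_events in state.events_by_frame:
        if len(frame_events) == 0:
            occupancy["empty"] += 1
        elif len(frame_events) == 1:
            occupancy["one"] += 1
        else:
            occupancy["multi"] += 1

    n_events = sum(len(fr) for fr in state.events_by_frame)
    n_correct_events = sum(
        t.n_records for t in trajectories if t.classification == "correct"
    )
    return {
        "n_frames": n_frames,
        "n_events": n_events,
        "n_trajectories": len(trajectories),
        "n_correct_trajectories": sum(
            1 for t in trajectories if t.classification == "correct"
        ),
        "occupancy": occupancy,
        "pct_events_correct": (
            100.0 * n_correct_events / n_events if n_events else float("nan")
        ),
        "trajectories": trajectories,
    }
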
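import copy

import pytest

from ridgetrack.pipeline import summarize_tracking, track_stack
from ridgetrack.synthetic import (
    collision_swap_config,
    evaluate_tracking,
    ridge_cohort_config,
    simulate_video,
    three_cell_merge_split_scenario,
)


def _run_pipeline(cfg):
    stack, truth = simulate_video(cfg)
    state = track_stack(stack)
    summary = summarize_tracking(state, stack.frame_shape)
    report = evaluate_tracking(summary["trajectories"], truth)
    return {
        "cfg": cfg,
        "stack": stack,
        "truth": truth,
        "state": state,
        "summary": summary,
        "report": report,
    }


@pytest.fixture(scope="session")
def swap_run():
    """Full pipeline on the collision-swap recording (two cells collide,
    the doublet rotates, the follower exits as the leader)."""
    return _run_pipeline(collision_swap_config(seed=1))


@pytest.fixture(scope="session")
def stiff_run():
    """Full pipeline on the stiff cohort (slowed on ridges, drifting up)."""
    return _run_pipeline(ridge_cohort_config(stiff=True, seed=5))


@pytest.fixture(scope="session")
def soft_run():
    """Full pipeline on the softened cohort (constant speed, slight
    downward drift)."""
    return _run_pipeline(ridge_cohort_config(stiff=False, seed=5))


@pytest.fixture()
def scenario_events():
    """Fresh copy of the scripted four-frame merge/split scenario."""
    events, expected = three_cell_merge_split_scenario()
    return copy.deepcopy(events), expected
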
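import numpy as np
import pytest

from activegaze.merge import merge_streams, segment_trials
from activegaze.events import detect_fixations
from activegaze.intersect import classify_fixation
from activegaze.scene import builtin_layout
from activegaze.simulate import TrialCondition, generate_trial


@pytest.fixture(scope="session")
def layout():
    return builtin_layout(1)


@pytest.fixture(scope="session")
def all_layouts():
    return [builtin_layout(i) for i in (1, 2, 3, 4)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_trial(layout):
    """One noise-free present trial plus its ground truth."""
    cond = TrialCondition(
        target_present=True, set_size=40, visible_from_start=False,
        target_orientation="upright", target_surface="C3",
    )
    rec, gt = generate_trial(layout, cond, seed=7)
    return rec, gt, cond


@pytest.fixture(scope="session")
def clean_run(layout, clean_trial):
    """The clean trial pushed through merge -> detect -> classify."""
    rec, gt, cond = clean_trial
    merged = merge_streams(rec)
    trial = segment_trials(merged, rec.markers, conditions={1: cond})[0]
    fixations, saccades = detect_fixations(trial)
    for f in fixations:
        f.lookat_label = classify_fixation(f, layout)
    return {
        "recording": rec, "truth": gt, "merged": merged, "trial": trial,
        "fixations": fixations, "saccades": saccades,
    }
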
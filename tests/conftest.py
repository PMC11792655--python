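import pandas as pd
import pytest

from priomatch.synth import TaskDesign, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 FP + 4 SP subjects, 40 trials/condition (kept small for speed)."""
    design = TaskDesign(trials_per_condition=40)
    truths, trials = generate_cohort(4, 4, 0.8, seed=11, design=design)
    return truths, trials


@pytest.fixture(scope="session")
def grouped_trials(small_cohort):
    """Trial table with the latent group as the analysis group column."""
    _, trials = small_cohort
    return trials.rename(columns={"group_truth": "group"}).assign(
        group_truth=lambda d: d["group"])


def make_trials(rows):
    """Tiny hand-built trial table for arithmetic oracles."""
    base = dict(subject="s1", group_truth="FP", label="self", match="match",
                response="yes", rt_ms=600.0, accuracy=1.0, v_true=1.0,
                coupling_gain=0.0)
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base, **r)
        rec["trial_index"] = i
        recs.append(rec)
    return pd.DataFrame(recs)
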
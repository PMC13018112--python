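import numpy as np
import pandas as pd
import pytest

from posturestats import CopTrial, SimConfig
from posturestats.posturography import POSITIONS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A light-weight study: fewer subjects, short ROI series."""
    return SimConfig(n_per_group=(6, 5), n_volumes=60, seed=7)


@pytest.fixture
def bodypart_counts():
    """The packaged participant-level code presence counts (5 codes x 4
    group-time conditions)."""
    from importlib import resources

    ref = resources.files("posturestats.data") / "bodypart_counts.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, index_col=0)


def make_trial(samples, position="center", participant="P1", time="T0", group="SDE"):
    return CopTrial(
        participant=participant,
        group=group,
        time=time,
        position=position,
        samples=np.asarray(samples, float),
    )


def make_session(rng, participant="P1", time="T0", group="SDE", n=200, spread=1.0):
    """Five random-walk-free OU-ish trials, one per position."""
    centers = {
        "center": (0, 0),
        "anterior": (5, 0),
        "posterior": (-5, 0),
        "right": (0, 4),
        "left": (0, -4),
    }
    trials = []
    for pos in POSITIONS:
        c = np.asarray(centers[pos], float)
        trials.append(
            make_trial(
                c + rng.normal(0, spread, size=(n, 2)),
                position=pos,
                participant=participant,
                time=time,
                group=group,
            )
        )
    return trials
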
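import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from isascore.design import DesignSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_trials(rows):
    """Build a trial frame from (subject, block, trial, rt, acc, *factors) tuples."""
    n_extra = len(rows[0]) - 5
    cols = ["subject", "block", "trial", "rt", "acc"] + [
        f"f{i + 1}" for i in range(n_extra)
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20240115)


@pytest.fixture
def design_2x2():
    return DesignSpec(
        factors=(
            ("task", ("repeat", "switch")),
            ("dimension", ("repeat", "switch")),
        )
    )


@pytest.fixture
def random_trials(rng):
    """Small complete 2-subject 2x2 experiment with random RTs/accuracy."""
    rows = []
    for s in ("s1", "s2"):
        t = 0
        for task in ("repeat", "switch"):
            for dim in ("repeat", "switch"):
                for _ in range(20):
                    t += 1
                    rows.append(
                        (
                            s, 1, t,
                            float(rng.normal(600, 80) + rng.exponential(100)),
                            int(rng.random() > 0.08),
                            task, dim,
                        )
                    )
    df = make_trials(rows)
    return df.rename(columns={"f1": "task", "f2": "dimension"})


def random_cell_scores(rng, n_subjects, n_cells, mean=600.0, sd=80.0):
    return rng.normal(mean, sd, size=(n_subjects, n_cells))
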
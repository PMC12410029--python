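import warnings

import numpy as np
import pandas as pd
import pytest

from aequity.cohort import Cohort

warnings.filterwarnings("ignore", message="Precision loss occurred")


def make_cohort(
    n: int = 600,
    d: int = 6,
    groups: tuple[str, ...] = ("A", "B"),
    outcomes: tuple[str, ...] = ("outcome",),
    seed: int = 0,
) -> Cohort:
    """Small i.i.d. Gaussian cohort with logistic outcomes, for unit tests."""
    rng = np.random.default_rng(seed)
    per = n // len(groups)
    frames = []
    sid = 0
    for g in groups:
        x = rng.standard_normal((per, d))
        df = pd.DataFrame(x, columns=[f"f{j}" for j in range(d)])
        df.insert(0, "group", g)
        df.insert(0, "subject_id", [f"s{sid + i:05d}" for i in range(per)])
        sid += per
        for name in outcomes:
            z = x.sum(axis=1) / np.sqrt(d)
            df[f"y_{name}"] = (rng.random(per) < 1 / (1 + np.exp(-z))).astype(int)
        frames.append(df)
    return Cohort(pd.concat(frames, ignore_index=True), [f"f{j}" for j in range(d)])


@pytest.fixture
def small_cohort() -> Cohort:
    return make_cohort()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
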
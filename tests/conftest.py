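import numpy as np
import pytest
from hypothesis import settings

from bwasbias import EffectTable, generate_subject_null_sample

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sample():
    """A small null subject-level sample shared across read-only tests."""
    return generate_subject_null_sample(
        n_subjects=80, n_nodes=10, ts_length=40, seed=11
    )


def make_table(r, n, label="full_sample", **kwargs):
    return EffectTable.from_correlations(np.asarray(r, dtype=float), n=n,
                                         label=label, **kwargs)


@pytest.fixture(scope="session")
def eight_effect_tables():
    """A hand-built full/replication pair covering every significance/sign case.

    At n = 100 and alpha = 0.05 the two-tailed critical correlation is about
    0.197, so values of magnitude >= 0.25 are significant and values of
    magnitude <= 0.10 are not.
    """
    full = make_table(
        [0.30, 0.40, 0.35, 0.30, -0.45, 0.05, -0.10, -0.25], n=100
    )
    rep = make_table(
        [0.50, 0.25, 0.10, -0.30, -0.50, 0.40, 0.02, 0.05], n=100,
        label="resample",
    )
    return full, rep
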
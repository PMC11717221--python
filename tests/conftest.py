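import numpy as np
import pytest

from gmgait import synthetic as syn
from gmgait.core import ENVELOPE_COLUMNS


@pytest.fixture(scope="session")
def archetypes():
    return syn.load_default_archetypes()


@pytest.fixture(scope="session")
def outcome_specs():
    return syn.load_default_outcomes()


@pytest.fixture(scope="session")
def small_cohort(archetypes):
    """A small mixed cohort reused by feature / pipeline tests."""
    return syn.generate_cohort(
        {"TD": 12, "cluster_1": 8, "cluster_2": 10, "cluster_3": 6},
        seed=42, archetypes=archetypes)


def envelope_block(cohort):
    return cohort.envelopes[ENVELOPE_COLUMNS].to_numpy()
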
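"""Shared fixtures: default unit templates and scaled-down mini units.

The mini unit keeps the six-subregion architecture of a real 35S rDNA
unit at ~1/7 scale so that mapping-heavy tests stay fast; the full-size
pair is session-scoped and reused wherever the real geometry matters.
"""

import numpy as np
import pytest

from rdnaprof import synthetic

MINI_LENGTHS = {
    "18S": 300, "ITS1": 80, "5.8S": 60, "ITS2": 80, "25S": 400, "IGS": 280,
}
MINI_TOTAL = sum(MINI_LENGTHS.values())


@pytest.fixture(scope="session")
def default_units():
    return synthetic.make_default_units(seed=7)


@pytest.fixture(scope="session")
def d_unit(default_units):
    return default_units[0]


@pytest.fixture(scope="session")
def s_unit(default_units):
    return default_units[1]


def make_mini_unit(seed=0, site_plan=(), genome_label="D"):
    return synthetic.build_unit_template(
        genome_label,
        total_length=MINI_TOTAL,
        subregion_lengths=dict(MINI_LENGTHS),
        site_plan=list(site_plan),
        seed=seed,
    )


@pytest.fixture()
def mini_unit():
    return make_mini_unit(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
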
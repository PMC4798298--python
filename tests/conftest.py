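import numpy as np
import pytest

from gxemap.genome import build_default_map, default_cross_design
from gxemap.rules import RuleSet


@pytest.fixture(scope="session")
def gmap():
    return build_default_map()


@pytest.fixture(scope="session")
def ruleset():
    return RuleSet.default()


@pytest.fixture(scope="session")
def by_design(gmap):
    return default_cross_design(gmap, "BY")


@pytest.fixture(scope="session")
def s3_design(gmap):
    return default_cross_design(gmap, "3S")


@pytest.fixture()
def rng():
    return np.random.default_rng(20160318)


def ns_genotype(**overrides):
    """The fully non-sensitive multi-locus genotype, with optional allele swaps."""
    g = {
        "END3": "BY",
        "FLO8": "3S",
        "FLO11": "3S",
        "IRA2": "MUT",
        "MGA1": "BY",
        "MSS11": "BY",
        "SFL1": "BY",
        "TRR1": "3S",
        "XII": "BY",
    }
    g.update(overrides)
    return g


def hsb_genotype(**overrides):
    """The MSS11^3S-dependent highly sensitive genotype."""
    g = {
        "END3": "BY",
        "FLO8": "3S",
        "FLO11": "3S",
        "IRA2": "MUT",
        "MGA1": "BY",
        "MSS11": "3S",
        "SFL1": "BY",
        "TRR1": "3S",
        "XII": "3S",
    }
    g.update(overrides)
    return g
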
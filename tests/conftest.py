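import numpy as np
import pytest

from genenet import BarcodeSpace, RuleSet, parse_rule
from genenet.rg import RGParams, sample_rg_ruleset


@pytest.fixture
def fig1_ruleset() -> RuleSet:
    """The single-rule biclique example: (101XX)O(110XX) at b=5."""
    return RuleSet(BarcodeSpace(5), [parse_rule("101XX -> 110XX", 5)])


@pytest.fixture
def overlapping_pair_ruleset() -> RuleSet:
    """Two b=7 rules sharing their source set and part of the destination."""
    return RuleSet(
        BarcodeSpace(7),
        [
            parse_rule("101XXXX -> 0XX10XX", 7),
            parse_rule("101XXXX -> 010XXXX", 7),
        ],
    )


def random_ruleset(b: int, x: int, r: int, seed: int) -> RuleSet:
    """Seeded random rule set used by cross-module equivalence tests."""
    return sample_rg_ruleset(RGParams(b=b, x=x, r=r, seed=seed))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
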
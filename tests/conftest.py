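import numpy as np
import pytest

from imotif.structure import assign_charges, default_charge_set
from imotif.synth import BuildSpec, build_imotif, build_cc_pair


@pytest.fixture(scope="session")
def charge_set():
    return default_charge_set()


@pytest.fixture(scope="session")
def acidic_fragment():
    """Idealized acidic-like i-motif: 4 C:C+ pairs + two G:T:G:T tetrads."""
    return build_imotif(BuildSpec(n_cc_pairs=4, capping="GTGT", topology="3E"))


@pytest.fixture(scope="session")
def neutral_fragment():
    """Idealized neutral-like i-motif: 2 C:C+ pairs + two G:C:G:C tetrads."""
    return build_imotif(BuildSpec(n_cc_pairs=2, capping="GCGC", topology="3E"))


@pytest.fixture(scope="session")
def bare_stack():
    return build_imotif(BuildSpec(n_cc_pairs=2, capping="none"))


@pytest.fixture(scope="session")
def charged_neutral(neutral_fragment, charge_set):
    return assign_charges(neutral_fragment, charge_set)


@pytest.fixture(scope="session")
def cc_pair():
    return build_cc_pair(protonated=True)
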
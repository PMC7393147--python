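import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracle

from smpcom import apply_medium
from smpcom.synthetic import (
    ToyCommunitySpec,
    community_medium,
    heterotroph_medium,
    make_toy_community,
    make_toy_heterotroph,
    make_toy_phototroph,
    phototroph_medium,
)


@pytest.fixture(scope="session")
def spec():
    return ToyCommunitySpec()


@pytest.fixture()
def phototroph(spec):
    return make_toy_phototroph(spec)


@pytest.fixture()
def heterotroph(spec):
    return make_toy_heterotroph(spec)


@pytest.fixture()
def phototroph_fed(spec, phototroph):
    return apply_medium(phototroph, phototroph_medium(spec))


@pytest.fixture()
def heterotroph_fed(heterotroph):
    return apply_medium(heterotroph, heterotroph_medium(sucrose=10.0))


@pytest.fixture()
def community(spec):
    """Toy community with the sucrose-secretion floor applied."""
    return make_toy_community(spec)


@pytest.fixture()
def community_no_floor(spec):
    return make_toy_community(spec, with_floor=False)


@pytest.fixture()
def community_no_aa(spec):
    """Community whose evidence table omits amino-acid sharing."""
    from dataclasses import replace

    return make_toy_community(replace(spec, share_amino_acid=False))


def stoich_residual(model, fluxes):
    """Max |S.v| over metabolites for a flux vector (steady-state check)."""
    worst = 0.0
    for met in model.metabolites:
        total = sum(
            coef * float(fluxes[rxn.id])
            for rxn in met.reactions
            for m2, coef in rxn.metabolites.items()
            if m2 is met
        )
        worst = max(worst, abs(total))
    return worst
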
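import pytest

from tagknock import (
    OptKnockConfig,
    make_linear_chain,
    make_redox_coupled_toy,
    make_tag_toy,
)


@pytest.fixture()
def chain():
    model, truth = make_linear_chain(10.0)
    return model, truth


@pytest.fixture()
def redox():
    model, truth = make_redox_coupled_toy()
    return model, truth


@pytest.fixture()
def tag_toy():
    model, truth = make_tag_toy(n_extra_branches=4, seed=1)
    return model, truth


def tag_config(K: int = 1, n: int = 10) -> OptKnockConfig:
    return OptKnockConfig(
        target_reaction_id="DM_tag",
        biomass_reaction_id="BIO",
        max_deletions=K,
        n_candidates=n,
    )
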
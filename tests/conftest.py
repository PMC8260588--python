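import pytest

import clz_cea as cc


@pytest.fixture(scope="session")
def jp_params():
    return cc.study_fixture("JPN")


@pytest.fixture(scope="session")
def uk_params():
    return cc.study_fixture("UK")


@pytest.fixture(scope="session")
def base_pair():
    """HLA-guided vs unguided at the 1500 cutoff (the base-case comparison)."""
    return (
        cc.Strategy(anc_cutoff=1500, hla_guided=True),
        cc.Strategy(anc_cutoff=1500, hla_guided=False),
    )
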
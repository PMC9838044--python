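import warnings

import pytest

from hdzip import family, simulate


@pytest.fixture(scope="session")
def family_fixture():
    """Planted {73, 13, 11, 20} + 10 rejected domain-hit fixture with truth."""
    df, truth = simulate.gen_domain_table(seed=11)
    hits = [
        family.DomainHit(r.transcript_id, family.Domain(r.domain),
                         int(r.start), int(r.end), float(r.evalue))
        for r in df.itertuples(index=False)
    ]
    return hits, truth


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
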
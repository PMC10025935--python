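import numpy as np
import pytest

from metagsim.fixtures import FixtureSpec, make_community, make_trained_models


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def community(spec):
    genomes, truth = make_community(spec)
    return genomes, truth


@pytest.fixture(scope="session")
def genome_map(community):
    genomes, _ = community
    return {g.species: g for g in genomes}


@pytest.fixture(scope="session")
def trained_models(spec):
    return make_trained_models(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sub(read_id="r", qs=0, qe=100, species="A", seq="A_c1", rs=0, re_=None,
             strand="+", aligned=None, mapq=60, **kw):
    """Shorthand SubAlignment constructor for planted test cases."""
    from metagsim.io_formats import SubAlignment

    if re_ is None:
        re_ = rs + (qe - qs)
    if aligned is None:
        aligned = qe - qs
    return SubAlignment(
        read_id=read_id, query_start=qs, query_end=qe, ref_species=species,
        ref_seq=seq, ref_start=rs, ref_end=re_, strand=strand,
        aligned_bases=aligned, mapq=mapq, **kw,
    )
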
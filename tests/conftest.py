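"""Shared fixtures: small simulated panels built once per session."""

import numpy as np
import pytest

import paleoquartet as pq


@pytest.fixture(scope="session")
def hominid_spec_loci():
    return pq.hominid_like()


@pytest.fixture(scope="session")
def hominid_panel(hominid_spec_loci):
    spec, loci = hominid_spec_loci
    return pq.build_panel(spec, loci, individuals_per_taxon=2, rng_seed=101)


@pytest.fixture(scope="session")
def hominin_panel():
    spec, loci = pq.hominin_like()
    return pq.build_panel(spec, loci, individuals_per_taxon=2, rng_seed=202)


@pytest.fixture(scope="session")
def admixed_hominin_panel():
    spec, loci = pq.hominin_like(
        admixture=(pq.hominin_admixture_event(proportion=0.5),)
    )
    return pq.build_panel(
        spec,
        loci,
        individuals_per_taxon=6,
        rng_seed=303,
        panel_labels={"Sapiens": ["AFRICAN", "ADMIXED"]},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_quartet(seqs, taxa=("A", "B", "C", "D"), alphabet=None, name="toy"):
    return pq.Alignment(
        ids=[f"{t}|i1|{name}" for t in taxa], seqs=list(seqs),
        alphabet=alphabet, name=name,
    )


@pytest.fixture()
def toy_quartet():
    return make_quartet
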
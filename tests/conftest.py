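import logging

import numpy as np
import pytest

from dscamkit.model_io import DomainArchitecture, GeneModel
from dscamkit.synthetic_data import SimulationConfig, simulate_family

logging.getLogger("dscamkit").setLevel(logging.ERROR)


def make_architecture(gene_id, tokens):
    """Build a DomainArchitecture from an ordered token list."""
    domains, pos = [], 1
    for t in tokens:
        domains.append((t, pos, pos + 50))
        pos += 50
    return DomainArchitecture(gene_id, tuple(domains))


def make_gene(
    gene_id="g1",
    species="spX",
    tokens=(),
    cassettes=0,
    ig_count=1,
    internal_clusters=(),
    strand="+",
):
    """Minimal in-memory gene model; cassette i occupies [1000*i, 1000*i + 400)."""
    from dscamkit.model_io import CassetteRepeat

    array = [
        CassetteRepeat(
            index=i + 1,
            interval=(1000 * (i + 1), 1000 * (i + 1) + 400),
            exons=((1000 * (i + 1), 1000 * (i + 1) + 180),
                   (1000 * (i + 1) + 250, 1000 * (i + 1) + 400)),
            variable_exon=(1000 * (i + 1), 1000 * (i + 1) + 180),
            encoded_ig_count=ig_count,
            intron_count=1,
        )
        for i in range(cassettes)
    ]
    return GeneModel(
        gene_id=gene_id,
        species=species,
        seqid="chr1",
        strand=strand,
        constant_exons=[(100_000, 100_500), (100_700, 101_200)],
        cassette_array=array,
        internal_clusters=list(internal_clusters),
        architecture=make_architecture(gene_id, list(tokens)),
    )


@pytest.fixture(scope="session")
def small_family():
    """A small two-species simulated family used across modules."""
    return simulate_family(SimulationConfig(seed=7, n_species=2))


@pytest.fixture(scope="session")
def family_dir(small_family, tmp_path_factory):
    out = tmp_path_factory.mktemp("family")
    small_family.write(out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
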
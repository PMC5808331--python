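"""Shared fixtures: a small planted genome run end-to-end once per session."""

import numpy as np
import pytest

from lncfam import (
    SynthesisConfig,
    discover_families,
    generate_genome,
)
from lncfam.match_filtering import TaxonMap


@pytest.fixture(scope="session")
def toy_cfg():
    return SynthesisConfig(
        seed=7,
        family_sizes=(3, 4, 5),
        n_background_lnc=10,
    )


@pytest.fixture(scope="session")
def toy_genome(toy_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_genome")
    return generate_genome(toy_cfg, out)


@pytest.fixture(scope="session")
def toy_taxa(toy_genome):
    return TaxonMap.from_files(toy_genome.accession2taxid, toy_genome.taxon_names)


@pytest.fixture(scope="session")
def toy_result(toy_genome, toy_taxa):
    return discover_families(
        toy_genome.annotation_gff3,
        toy_genome.genome_fasta,
        te_fasta=toy_genome.te_fasta,
        external_fasta=toy_genome.external_fasta,
        taxa=toy_taxa,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(rng, seq, rate):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < rate):
        out[i] = [b for b in "ACGT" if b != out[i]][rng.integers(3)]
    return "".join(out)
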